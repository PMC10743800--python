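"""Three-stack 2D CNN for age regression over per-axis projection channels.

One independent convolutional stack per anatomical axis consumes that axis's
channel images (moment maps and/or eigenslices).  Each stack is a sequence of
units

    conv(3x3, stride 2, doubles features) -> ReLU ->
    conv(3x3, stride 1) -> batch norm -> ReLU -> dropout

starting at 4 filters, so six units progress 4-8-16-32-64-128 while halving
each spatial dimension with ceiling semantics (256 -> 4 and 208 -> 4 after six
halvings).  A capping convolution spanning the remaining spatial extent turns
each stack's feature map into a one-dimensional feature vector; the three
vectors are concatenated and fed to a small dense head that emits one scalar
age estimate.  With the capping width of 156 features and head widths
(256, 166), the full-scale model has exactly 2,009,261 trainable parameters
with one input channel per axis, growing by 108 per added channel (3 stacks x
4 first-layer filters x 9 kernel weights).

A ``reduced`` variant (4 units, narrower cap and head) exists for desk-scale
experiments on 64x64x52 phantoms; it shares the architecture family but not
the parameter-count anchors.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .nn import Adam, BatchNorm2d, Concat, Conv2d, Dense, Dropout, Flatten, ReLU, Sequential

FULL_GRID_INPUT_SHAPES = ((256, 208), (256, 208), (256, 256))

_VARIANT_DEFAULTS = {
    "full": {"n_units": 6, "cap_features": 156, "head_widths": (256, 166)},
    "reduced": {"n_units": 4, "cap_features": 16, "head_widths": (32,)},
}


class ConfigurationError(ValueError):
    pass


def _ceil_halvings(size: int, times: int) -> int:
    for _ in range(times):
        size = -(-size // 2)
    return size


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture and training-relevant settings of the projection CNN.

    ``channels_per_axis`` lists the channel names each stack consumes, in
    input order; per-axis lists may differ in content but must share length.
    """

    channels_per_axis: tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]
    input_shapes: tuple[tuple[int, int], ...] = FULL_GRID_INPUT_SHAPES
    first_layer_filters: int = 4
    n_units: int = 6
    dropout_rate: float = 0.2
    loss: str = "mse"
    scale_variant: str = "full"
    cap_features: int | None = None
    head_widths: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_variant not in _VARIANT_DEFAULTS:
            raise ConfigurationError(f"unknown scale_variant {self.scale_variant!r}")
        if len(self.channels_per_axis) != 3 or len(self.input_shapes) != 3:
            raise ConfigurationError("exactly three axes expected")
        counts = {len(c) for c in self.channels_per_axis}
        if len(counts) != 1 or 0 in counts:
            raise ConfigurationError("each axis needs the same, nonzero number of channels")
        if self.loss not in ("mse", "mae"):
            raise ConfigurationError("loss must be 'mse' or 'mae'")

    @property
    def n_channels(self) -> int:
        return len(self.channels_per_axis[0])

    @property
    def conv_layers_per_stack(self) -> int:
        return 2 * self.n_units + 1

    def resolved(self, field: str):
        v = getattr(self, field)
        return _VARIANT_DEFAULTS[self.scale_variant][field] if v is None else v

    @property
    def feature_widths(self) -> tuple[int, ...]:
        return tuple(self.first_layer_filters * 2**i for i in range(self.n_units))

    @classmethod
    def full(cls, channels_per_axis, **kw) -> "ModelConfig":
        return cls(channels_per_axis=_as_channel_tuple(channels_per_axis), scale_variant="full", **kw)

    @classmethod
    def reduced(cls, channels_per_axis, input_shapes, **kw) -> "ModelConfig":
        kw.setdefault("n_units", _VARIANT_DEFAULTS["reduced"]["n_units"])
        return cls(
            channels_per_axis=_as_channel_tuple(channels_per_axis),
            input_shapes=tuple(tuple(s) for s in input_shapes),
            scale_variant="reduced",
            **kw,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, blob: str) -> "ModelConfig":
        d = json.loads(blob)
        d["channels_per_axis"] = tuple(tuple(c) for c in d["channels_per_axis"])
        d["input_shapes"] = tuple(tuple(s) for s in d["input_shapes"])
        if d.get("head_widths") is not None:
            d["head_widths"] = tuple(d["head_widths"])
        return cls(**d)


def _as_channel_tuple(channels_per_axis) -> tuple[tuple[str, ...], ...]:
    return tuple(tuple(str(c) for c in axis_channels) for axis_channels in channels_per_axis)


class ThreeStackCNN:
    """The assembled network: three conv stacks, concatenation, dense head.

    Predictions are produced in standardized target units internally;
    ``target_mean``/``target_sd`` (set by the training harness, stored in
    checkpoints) map them back to years in :meth:`predict`.
    """

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        n_units = config.n_units
        widths = config.feature_widths
        cap_features = config.resolved("cap_features")
        head_widths = tuple(config.resolved("head_widths"))
        rate = config.dropout_rate

        self.stacks: list[Sequential] = []
        for axis in range(3):
            in_ch = len(config.channels_per_axis[axis])
            h, w = config.input_shapes[axis]
            layers: list = []
            for f in widths:
                layers += [
                    Conv2d(in_ch, f, 3, stride=2, padding="same", rng=rng),
                    ReLU(),
                    Conv2d(f, f, 3, stride=1, padding="same", rng=rng),
                    BatchNorm2d(f),
                    ReLU(),
                    Dropout(rate, rng),
                ]
                in_ch = f
            fh, fw = _ceil_halvings(h, n_units), _ceil_halvings(w, n_units)
            layers += [
                Conv2d(in_ch, cap_features, (fh, fw), stride=1, padding="valid", rng=rng),
                ReLU(),
                Flatten(),
            ]
            self.stacks.append(Sequential(layers))

        head_layers: list = []
        d = 3 * cap_features
        for hw in head_widths:
            head_layers += [Dense(d, hw, rng=rng), ReLU()]
            d = hw
        head_layers.append(Dense(d, 1, rng=rng))
        self.head = Sequential(head_layers)
        self.concat = Concat()
        self.target_mean = 0.0
        self.target_sd = 1.0

    # -- forward / backward -------------------------------------------------
    def forward(self, xs: list[np.ndarray], train: bool) -> np.ndarray:
        if len(xs) != 3:
            raise ConfigurationError("expected three per-axis input stacks")
        for axis, x in enumerate(xs):
            want = len(self.config.channels_per_axis[axis])
            if x.ndim != 4 or x.shape[1] != want:
                raise ConfigurationError(
                    f"axis {axis}: expected (N, {want}, H, W) input, got shape {x.shape}"
                )
        feats = [stack.forward(x, train) for stack, x in zip(self.stacks, xs)]
        return self.head.forward(self.concat.forward(feats), train)[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dfeat = self.head.backward(dpred[:, None])
        for stack, df in zip(self.stacks, self.concat.backward(dfeat)):
            stack.backward(df)

    def predict(self, xs: list[np.ndarray], batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode predictions in years."""
        n = xs[0].shape[0]
        out = np.empty(n)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl] = self.forward([x[sl] for x in xs], train=False)
        return out * self.target_sd + self.target_mean

    # -- parameter plumbing --------------------------------------------------
    def named_params(self):
        for i, stack in enumerate(self.stacks):
            yield from stack.named_params(f"stack{i}.")
        yield from self.head.named_params("head.")

    def named_buffers(self):
        for i, stack in enumerate(self.stacks):
            yield from stack.named_buffers(f"stack{i}.")
        yield from self.head.named_buffers("head.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{name}": layer.params[key] for name, layer, key in self.named_params()}
        state.update({f"buffer:{name}": layer.buffers[key] for name, layer, key in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer, key in self.named_params():
            layer.params[key] = np.array(state[f"param:{name}"])
        for name, layer, key in self.named_buffers():
            layer.buffers[key] = np.array(state[f"buffer:{name}"])

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}


def build_model(config: ModelConfig) -> ThreeStackCNN:
    return ThreeStackCNN(config)


def count_parameters(model: ThreeStackCNN) -> int:
    """Total trainable scalars (weights, biases, batch-norm affine terms).

    Batch-norm running statistics are buffers and excluded.
    """
    return int(sum(layer.params[key].size for _, layer, key in model.named_params()))


def make_optimizer(model: ThreeStackCNN, lr: float = 0.003) -> Adam:
    return Adam(model.named_params(), lr=lr)


def ensemble_predict(models: list[ThreeStackCNN], xs: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of member predictions (years)."""
    if not models:
        raise ValueError("ensemble needs at least one model")
    ref = models[0].config.channels_per_axis
    for m in models[1:]:
        if m.config.channels_per_axis != ref:
            raise ConfigurationError("ensemble members must share channel configuration")
    return np.mean([m.predict(xs) for m in models], axis=0)


def save_checkpoint(model: ThreeStackCNN, path: str | Path, history: list[dict] | None = None) -> None:
    """Single-file checkpoint: parameters, buffers, config, target scaling."""
    payload = dict(model.state_dict())
    payload["__config__"] = np.array(model.config.to_json())
    payload["__target__"] = np.array([model.target_mean, model.target_sd])
    if history is not None:
        payload["__history__"] = np.array(json.dumps(history))
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[ThreeStackCNN, list[dict] | None]:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.from_json(str(data["__config__"]))
        model = build_model(config)
        model.load_state_dict({k: data[k] for k in data.files if ":" in k})
        model.target_mean, model.target_sd = (float(v) for v in data["__target__"])
        history = json.loads(str(data["__history__"])) if "__history__" in data.files else None
    return model, history
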
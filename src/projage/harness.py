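"""Experiment harness: splits, projection cache, training and evaluation.

Ties the projection modules to the regression CNN: subjects are split
70/15/15 into train/validation/test with three disjoint-validation folds,
projection channels are computed once and cached to permanent storage, and
models are trained with Adam (learning rate 0.003, batch size 32) for a fixed
epoch count while the parameter state with the best validation MAE is kept
(early stopping).  The channel-grid driver reproduces the "channels 1..n vs
channel n only" experiment layout at any scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .eigenslices import eigenslices
from .model import (
    ModelConfig,
    ThreeStackCNN,
    build_model,
    count_parameters,
    ensemble_predict,
    make_optimizer,
)
from .moments import moment_map
from .nn import mae_loss, mse_loss
from .volume_io import GreyMatterVolume, SubjectRecord, load_volume, pad_to_grid


class TrainingError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int, message: str) -> None:
        super().__init__(message)
        self.epoch = epoch


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test partition with 3 disjoint-validation folds.

    ``train_ids``/``val_ids`` correspond to fold 0; every fold shares the same
    test set and draws its validation block, without replacement, from the
    combined train+validation pool.
    """

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    fractions: tuple[float, float, float]
    seed: int


def make_splits(
    subject_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    n_folds: int = 3,
    seed: int = 0,
) -> SplitPlan:
    """Split subjects with the floor-and-remainder convention.

    Test and validation sizes are ``floor(fraction * N)``; training takes the
    remainder (29,035 subjects -> 20,325 / 4,355 / 4,355).  Deterministic
    under ``seed``.
    """
    ids = [str(s) for s in subject_ids]
    n = len(ids)
    n_test = int(np.floor(fractions[2] * n))
    n_val = int(np.floor(fractions[1] * n))
    pool_size = n - n_test
    if n_val == 0 or pool_size < n_folds * n_val:
        raise ValueError(
            f"too few subjects ({n}) for {n_folds} disjoint validation blocks of size {n_val}"
        )
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    test = tuple(shuffled[:n_test])
    pool = shuffled[n_test:]
    pool_perm = [pool[i] for i in rng.permutation(pool_size)]
    folds = []
    for f in range(n_folds):
        val = tuple(pool_perm[f * n_val : (f + 1) * n_val])
        val_set = set(val)
        train = tuple(s for s in pool if s not in val_set)
        folds.append((train, val))
    return SplitPlan(
        train_ids=folds[0][0],
        val_ids=folds[0][1],
        test_ids=test,
        folds=tuple(folds),
        fractions=fractions,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Channel specs and projection
# ---------------------------------------------------------------------------

#: A per-axis channel request: for each storage axis, an ordered tuple of
#: (family, index) pairs, family in {"moment", "eigen"}, index 1-based.
AxisSpec = tuple[tuple[str, int], ...]
ChannelSpec = tuple[AxisSpec, AxisSpec, AxisSpec]


def uniform_channel_spec(family: str, indices: Sequence[int]) -> ChannelSpec:
    """The same channel list on all three axes (the common case)."""
    if family not in ("moment", "eigen"):
        raise ValueError(f"unknown channel family {family!r}")
    axis = tuple((family, int(i)) for i in indices)
    return (axis, axis, axis)


def parse_channel_spec(text: str) -> ChannelSpec:
    """Parse e.g. ``"moments:1-2"`` or ``"moments:1-2 eigen:1-16"``.

    Multiple clauses are concatenated in order; ranges are inclusive.
    """
    family_alias = {"moments": "moment", "moment": "moment", "eigen": "eigen", "eigenslices": "eigen"}
    channels: list[tuple[str, int]] = []
    for clause in text.split():
        try:
            fam_raw, rng_raw = clause.split(":")
            fam = family_alias[fam_raw]
        except (ValueError, KeyError):
            raise ValueError(f"bad channel clause {clause!r}") from None
        for part in rng_raw.split(","):
            if "-" in part:
                lo, hi = part.split("-")
                channels.extend((fam, i) for i in range(int(lo), int(hi) + 1))
            else:
                channels.append((fam, int(part)))
    if not channels:
        raise ValueError(f"empty channel spec {text!r}")
    axis = tuple(channels)
    return (axis, axis, axis)


def channel_name(family: str, index: int, axis_label: str) -> str:
    """Canonical cache key, e.g. ``moment_k2_sagittal`` or ``eigen_1_coronal``."""
    if family == "moment":
        return f"moment_k{index}_{axis_label}"
    return f"eigen_{index}_{axis_label}"


def compute_channels(vol: GreyMatterVolume, spec: ChannelSpec) -> dict[str, np.ndarray]:
    """Compute every requested channel image for one volume.

    Eigenslices are decomposed once per axis up to the highest requested
    index; moment maps are computed per order.
    """
    out: dict[str, np.ndarray] = {}
    for axis in range(3):
        label = vol.axis_labels[axis]
        moment_orders = sorted({i for fam, i in spec[axis] if fam == "moment"})
        eigen_indices = sorted({i for fam, i in spec[axis] if fam == "eigen"})
        for k in moment_orders:
            if not 1 <= k <= 4:
                raise ValueError(f"moment order {k} out of range 1..4")
            out[channel_name("moment", k, label)] = moment_map(vol, axis, k).image
        if eigen_indices:
            slices = eigenslices(vol, axis, max(eigen_indices))
            for i in eigen_indices:
                out[channel_name("eigen", i, label)] = slices[i - 1]
    return out


class ProjectionCache:
    """One ``.npz`` container of channel images per subject, plus a JSON
    sidecar of generation parameters.

    A parameter-hash mismatch (changed grid, sign convention, code version)
    invalidates the whole entry, which is then regenerated; this keeps
    invalidation atomic per subject.  ``compute_count`` counts cache misses,
    which tests use to verify warm-cache behavior.
    """

    FORMAT_VERSION = 1

    def __init__(self, directory: str | Path, params: dict | None = None) -> None:
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        payload = {"format_version": self.FORMAT_VERSION, **(params or {})}
        self.params_hash = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        self.compute_count = 0

    def _paths(self, subject_id: str) -> tuple[Path, Path]:
        return self.directory / f"{subject_id}.npz", self.directory / f"{subject_id}.json"

    def _load_entry(self, subject_id: str) -> dict[str, np.ndarray]:
        npz_path, json_path = self._paths(subject_id)
        if not npz_path.exists() or not json_path.exists():
            return {}
        sidecar = json.loads(json_path.read_text())
        if sidecar.get("params_hash") != self.params_hash:
            return {}  # stale: parameters changed since generation
        with np.load(npz_path) as data:
            return {k: data[k].copy() for k in data.files}

    def get_or_compute(
        self,
        subject_id: str,
        names: Sequence[str],
        compute: Callable[[], dict[str, np.ndarray]],
    ) -> dict[str, np.ndarray]:
        entry = self._load_entry(subject_id)
        if not all(name in entry for name in names):
            self.compute_count += 1
            entry.update(compute())
            npz_path, json_path = self._paths(subject_id)
            np.savez(npz_path, **entry)
            json_path.write_text(
                json.dumps({"params_hash": self.params_hash, "channels": sorted(entry)})
            )
        return {name: entry[name] for name in names}


def project_volume(vol: GreyMatterVolume, spec: ChannelSpec) -> list[np.ndarray]:
    """Assemble per-axis channel stacks (C, H, W) for one volume, spec order."""
    channels = compute_channels(vol, spec)
    stacks = []
    for axis in range(3):
        label = vol.axis_labels[axis]
        stacks.append(np.stack([channels[channel_name(f, i, label)] for f, i in spec[axis]]))
    return stacks


def project_subject(
    subject: SubjectRecord,
    spec: ChannelSpec,
    cache: ProjectionCache | None = None,
    target_grid: Sequence[int] | None = None,
    volume: GreyMatterVolume | None = None,
) -> list[np.ndarray]:
    """Per-axis channel stacks for one subject, via the cache when present.

    The volume is loaded from ``subject.volume_path`` (or taken from
    ``volume`` if supplied), clamped, and padded to ``target_grid`` before
    projection.
    """
    axis_labels = (volume.axis_labels if volume is not None else None)

    def load() -> GreyMatterVolume:
        vol = volume if volume is not None else load_volume(subject.volume_path)
        return pad_to_grid(vol, target_grid) if target_grid is not None else vol

    if cache is None:
        return project_volume(load(), spec)

    if axis_labels is None:
        from .volume_io import DEFAULT_AXIS_LABELS

        axis_labels = DEFAULT_AXIS_LABELS
    names = [
        channel_name(f, i, axis_labels[axis]) for axis in range(3) for f, i in spec[axis]
    ]
    channels = cache.get_or_compute(
        subject.subject_id, names, lambda: compute_channels(load(), spec)
    )
    stacks = []
    for axis in range(3):
        label = axis_labels[axis]
        stacks.append(np.stack([channels[channel_name(f, i, label)] for f, i in spec[axis]]))
    return stacks


class ChannelDataset:
    """Binds subject records to projected input stacks and ages.

    ``volumes`` may hold in-memory volumes keyed by subject id (phantom
    cohorts); otherwise volumes are loaded from the manifest paths.
    """

    def __init__(
        self,
        records: Sequence[SubjectRecord],
        cache: ProjectionCache | None = None,
        target_grid: Sequence[int] | None = None,
        volumes: dict[str, GreyMatterVolume] | None = None,
    ) -> None:
        self.records = {r.subject_id: r for r in records}
        self.cache = cache
        self.target_grid = target_grid
        self.volumes = volumes or {}

    def stacks(self, ids: Sequence[str], spec: ChannelSpec) -> tuple[list[np.ndarray], np.ndarray]:
        """(per-axis input arrays (N, C, H, W), recorded ages (N,))."""
        per_subject = []
        ages = []
        for sid in ids:
            rec = self.records[sid]
            per_subject.append(
                project_subject(
                    rec, spec, self.cache, self.target_grid, self.volumes.get(sid)
                )
            )
            ages.append(rec.age_years)
        xs = [np.stack([subj[axis] for subj in per_subject]) for axis in range(3)]
        return xs, np.asarray(ages, dtype=np.float64)

    def input_shapes(self, spec: ChannelSpec) -> tuple[tuple[int, int], ...]:
        sid = next(iter(self.records))
        stacks = project_subject(
            self.records[sid], spec, self.cache, self.target_grid, self.volumes.get(sid)
        )
        return tuple(s.shape[1:] for s in stacks)


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainedModel:
    """A trained network plus its per-epoch history and selected epoch."""

    model: ThreeStackCNN
    history: list[dict]
    best_epoch: int

    @property
    def config(self) -> ModelConfig:
        return self.model.config


def train_model(
    model: ThreeStackCNN,
    train_data: tuple[list[np.ndarray], np.ndarray],
    val_data: tuple[list[np.ndarray], np.ndarray],
    epochs: int = 400,
    batch_size: int = 32,
    lr: float = 0.003,
    seed: int = 0,
    standardize_targets: bool = True,
) -> TrainedModel:
    """Fixed-epoch training with best-validation-MAE model selection.

    Targets are standardized over the training fold (and inverted at
    prediction) so the optimizer starts centered on the cohort's age range;
    the transform is stored with the model.  The returned state is that of
    the epoch minimizing validation MAE in years.
    """
    xs_train, y_train = train_data
    xs_val, y_val = val_data
    n = y_train.size
    if n == 0 or y_val.size == 0:
        raise ValueError("training and validation folds must be non-empty")

    if standardize_targets:
        model.target_mean = float(y_train.mean())
        sd = float(y_train.std())
        model.target_sd = sd if sd > 0 else 1.0
    else:
        model.target_mean, model.target_sd = 0.0, 1.0
    y_std = (y_train - model.target_mean) / model.target_sd

    loss_fn = mse_loss if model.config.loss == "mse" else mae_loss
    optimizer = make_optimizer(model, lr=lr)
    shuffle_rng = np.random.default_rng(seed)

    history: list[dict] = []
    best_state = model.copy_state()
    best_mae = np.inf
    best_epoch = -1
    for epoch in range(epochs):
        perm = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            pred = model.forward([x[idx] for x in xs_train], train=True)
            loss, dpred = loss_fn(pred, y_std[idx])
            if not np.isfinite(loss):
                raise TrainingError(epoch, f"non-finite training loss at epoch {epoch}")
            model.backward(dpred)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        val_mae = float(np.mean(np.abs(model.predict(xs_val) - y_val)))
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_mae": val_mae}
        )
        if val_mae < best_mae:
            best_mae = val_mae
            best_epoch = epoch
            best_state = model.copy_state()
    model.load_state_dict(best_state)
    return TrainedModel(model=model, history=history, best_epoch=best_epoch)


@dataclasses.dataclass(frozen=True)
class EvalReport:
    """MAE and RMSE (years) of a prediction set."""

    mae: float
    rmse: float
    n: int
    per_subject_residuals: tuple[float, ...]


def evaluate(predictions: Sequence[tuple[float, float]]) -> EvalReport:
    """MAE/RMSE from (predicted age, recorded age) pairs."""
    if len(predictions) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    arr = np.asarray(predictions, dtype=np.float64)
    resid = arr[:, 0] - arr[:, 1]
    return EvalReport(
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=resid.size,
        per_subject_residuals=tuple(resid.tolist()),
    )


def constant_predictor_mae(train_ages: np.ndarray, test_ages: np.ndarray) -> float:
    """MAE of always predicting the training-set mean age (the floor any
    useful model must beat)."""
    return float(np.mean(np.abs(np.asarray(test_ages) - float(np.mean(train_ages)))))


# ---------------------------------------------------------------------------
# Channel-grid experiment driver
# ---------------------------------------------------------------------------

def run_channel_grid(
    family: str,
    mode: str,
    n_max: int,
    dataset: ChannelDataset,
    plan: SplitPlan,
    repeats: int = 4,
    epochs: int = 400,
    model_kwargs: dict | None = None,
    ensemble: bool = False,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Train ``repeats`` models per channel configuration; summarize test MAE.

    ``mode`` is ``"1..n"`` (channels 1 through n, n >= 2) or ``"n_only"``
    (single channel n, n >= 1).  Each configuration reports mean and SD of
    test MAE/RMSE over the repeats (SD absent for a single repeat) plus the
    model's parameter count, mirroring the results-table layout.  With
    ``ensemble=True`` and at least 4 repeats, a 4-member mean-prediction
    ensemble is evaluated as well.
    """
    if family not in ("moment", "eigen"):
        raise ValueError(f"unknown channel family {family!r}")
    if mode not in ("1..n", "n_only"):
        raise ValueError(f"unknown mode {mode!r}")
    model_kwargs = dict(model_kwargs or {})
    ns = range(2, n_max + 1) if mode == "1..n" else range(1, n_max + 1)

    rows = []
    for n in ns:
        indices = list(range(1, n + 1)) if mode == "1..n" else [n]
        spec = uniform_channel_spec(family, indices)
        names = tuple(f"{family}_{i}" for i in indices)
        shapes = dataset.input_shapes(spec)
        xs_train, y_train = dataset.stacks(plan.train_ids, spec)
        xs_val, y_val = dataset.stacks(plan.val_ids, spec)
        xs_test, y_test = dataset.stacks(plan.test_ids, spec)

        members = []
        maes, rmses = [], []
        for r in range(repeats):
            config = ModelConfig.reduced(
                (names, names, names), shapes, seed=base_seed + r, **model_kwargs
            )
            trained = train_model(
                build_model(config),
                (xs_train, y_train),
                (xs_val, y_val),
                epochs=epochs,
                seed=base_seed + r,
            )
            report = evaluate(list(zip(trained.model.predict(xs_test), y_test)))
            members.append(trained.model)
            maes.append(report.mae)
            rmses.append(report.rmse)

        row = {
            "family": family,
            "mode": mode,
            "n": n,
            "n_subjects": len(plan.train_ids),
            "mae_mean": float(np.mean(maes)),
            "mae_sd": float(np.std(maes, ddof=1)) if repeats > 1 else None,
            "rmse_mean": float(np.mean(rmses)),
            "rmse_sd": float(np.std(rmses, ddof=1)) if repeats > 1 else None,
            "parameters": count_parameters(members[0]),
        }
        if ensemble and repeats >= 4:
            ens_pred = ensemble_predict(members[:4], xs_test)
            ens = evaluate(list(zip(ens_pred, y_test)))
            row["ensemble_mae"] = ens.mae
            row["ensemble_rmse"] = ens.rmse
        rows.append(row)
    return pd.DataFrame(rows)
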
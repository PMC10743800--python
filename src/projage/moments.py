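"""Per-axis 2D maps of statistical moments of gray-matter likelihood.

Collapsing one grid axis of a volume yields a 2D image whose pixel at (a, b)
summarizes the line of voxels running perpendicular to the projection plane.
Four moment channels are defined:

* k=1 — mean of the full line,
* k=2 — population standard deviation of the full line,
* k=3 — skewness (standardized third central moment) over the *support hull*,
* k=4 — excess kurtosis (standardized fourth central moment minus 3) over the
  support hull.

The support hull of a line x is the index interval [alpha, omega] from the
first to the last nonzero value — the in-brain extent after skull stripping.
For k in {3, 4} the standardized moment

    mu~_k = n^(k/2 - 1) * sum_{i=alpha}^{omega} (x_i - mu_1)^k
            / (sum_{i=alpha}^{omega} (x_i - mu_1)^2)^(k/2)  -  C

is computed with mu_1 the hull mean, n = omega - alpha + 1 and C = 0 (k=3) or
3 (k=4, making it kurtosis in excess of a normal distribution).  Short hulls
(n < 8), all-zero lines and zero-variance hulls are numerically unstable or
undefined and map to exactly 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import GreyMatterVolume

#: Hulls shorter than this yield a moment of exactly 0 for k in {3, 4}.
MIN_HULL_LENGTH = 8

#: Offset constant per moment order (k=4 is reported as *excess* kurtosis).
C_CONSTANT = {1: 0.0, 2: 0.0, 3: 0.0, 4: 3.0}


@dataclasses.dataclass(frozen=True)
class LineSample:
    """One perpendicular line of voxel values with its support-hull bounds."""

    x: np.ndarray
    alpha: int
    omega: int

    @property
    def n(self) -> int:
        return self.omega - self.alpha + 1

    @property
    def hull(self) -> np.ndarray:
        return self.x[self.alpha : self.omega + 1]


@dataclasses.dataclass(frozen=True)
class MomentMap:
    """A 2D moment image for one collapsed axis."""

    image: np.ndarray
    axis: str
    order_k: int

    @property
    def c_constant(self) -> float:
        return C_CONSTANT[self.order_k]


def support_hull(x: np.ndarray) -> tuple[int, int] | None:
    """Indices of the first and last nonzero entries, or None if all-zero."""
    nz = np.flatnonzero(x)
    if nz.size == 0:
        return None
    return int(nz[0]), int(nz[-1])


def line_sample(x: np.ndarray) -> LineSample | None:
    hull = support_hull(x)
    if hull is None:
        return None
    return LineSample(np.asarray(x, dtype=np.float64), hull[0], hull[1])


def standardized_moment(line: LineSample | None, k: int) -> float:
    """Standardized central moment of order ``k`` in {3, 4} over the hull.

    Degenerate cases (all-zero line, hull shorter than ``MIN_HULL_LENGTH``,
    zero within-hull variance) return exactly 0.0 by contract.
    """
    if k not in (3, 4):
        raise ValueError(f"k must be 3 or 4, got {k}")
    if line is None or line.n < MIN_HULL_LENGTH:
        return 0.0
    h = line.hull
    mu1 = h.mean()
    dev = h - mu1
    s2 = float(np.sum(dev * dev))
    if s2 == 0.0:
        return 0.0
    sk = float(np.sum(dev**k))
    n = line.n
    return float(n ** (k / 2.0 - 1.0) * sk / s2 ** (k / 2.0) - C_CONSTANT[k])


def _hull_bounds(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (alpha, omega, any_nonzero) along the last axis."""
    nz = arr != 0.0
    any_nz = nz.any(axis=-1)
    alpha = np.argmax(nz, axis=-1)
    omega = arr.shape[-1] - 1 - np.argmax(nz[..., ::-1], axis=-1)
    return alpha, omega, any_nz

def moment_map(vol: GreyMatterVolume, axis: int | str, k: int) -> MomentMap:
    """Collapse one volume axis into the order-``k`` moment image.

    ``axis`` is a storage-axis index or an anatomical label.  Mean and SD use
    the full line (outside-hull zeros included); skewness and excess kurtosis
    use only the support hull.  Pixel order follows the two remaining volume
    axes in their original order.
    """
    if k not in (1, 2, 3, 4):
        raise ValueError(f"moment order k must be in 1..4, got {k}")
    ax = vol.axis_index(axis) if isinstance(axis, str) else int(axis)
    if not 0 <= ax <= 2:
        raise ValueError(f"axis index out of range: {ax}")
    label = vol.axis_labels[ax]
    arr = np.moveaxis(vol.values, ax, -1).astype(np.float64)

    if k == 1:
        return MomentMap(arr.mean(axis=-1), label, k)
    if k == 2:
        return MomentMap(arr.std(axis=-1), label, k)

    alpha, omega, any_nz = _hull_bounds(arr)
    n = np.where(any_nz, omega - alpha + 1, 0)
    idx = np.arange(arr.shape[-1])
    in_hull = (idx >= alpha[..., None]) & (idx <= omega[..., None]) & any_nz[..., None]
    n_safe = np.maximum(n, 1)
    mu1 = np.sum(arr * in_hull, axis=-1) / n_safe
    dev = (arr - mu1[..., None]) * in_hull
    s2 = np.sum(dev * dev, axis=-1)
    sk = np.sum(dev**k, axis=-1)
    valid = any_nz & (n >= MIN_HULL_LENGTH) & (s2 > 0.0)
    s2_safe = np.where(valid, s2, 1.0)
    out = n_safe ** (k / 2.0 - 1.0) * sk / s2_safe ** (k / 2.0) - C_CONSTANT[k]
    return MomentMap(np.where(valid, out, 0.0), label, k)


def moment_maps(vol: GreyMatterVolume, axis: int | str, orders=(1, 2, 3, 4)) -> list[MomentMap]:
    """All requested moment channels for one axis, in the given order."""
    return [moment_map(vol, axis, k) for k in orders]
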
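"""Per-volume eigenslices via the snapshot (Gram-matrix) PCA trick.

A volume is viewed as a stack of 2D slices perpendicular to one axis.  Each
slice, flattened to a long vector, becomes a column of a matrix M.  The
eigenvectors of the huge covariance-like matrix M Mᵀ (65,536×65,536 for
256×256 slices) capture the most slice-to-slice variance, but M has rank at
most the number of nonzero slices, so — exactly as in classic eigenface
work — they are obtained from the small Gram matrix MᵀM:

    MᵀM vᵢ = λᵢ vᵢ   ⇒   (M Mᵀ)(M vᵢ) = λᵢ (M vᵢ).

Reshaping the normalized M vᵢ back to the slice grid yields *eigenslices*,
used as 2D input channels for the regression CNN.  No mean-centering is
applied: the decomposition acts on the raw slice stack.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .volume_io import GreyMatterVolume

#: Relative eigenvalue cutoff: λ below RANK_RTOL·max(λ₁, tiny) counts as zero.
RANK_RTOL = 1e-10


@dataclasses.dataclass(frozen=True)
class SliceMatrix:
    """Flattened slice stack of one volume along one axis.

    Columns are slices in grid order, each flattened row-major (C order) over
    the two remaining axes; ``unflatten`` is the exact inverse.
    """

    m: np.ndarray
    slice_shape: tuple[int, int]
    axis: str

    @property
    def n_slices(self) -> int:
        return self.m.shape[1]

    def unflatten(self, column: np.ndarray) -> np.ndarray:
        return column.reshape(self.slice_shape)


@dataclasses.dataclass(frozen=True)
class EigensliceDecomposition:
    """Sorted eigenpairs of MᵀM plus the derived unit-norm eigenslices.

    ``eigenvalues`` are non-increasing; entries below the rank tolerance are
    zeroed and their eigenslices are zero images.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns v_i of MᵀM
    eigenslices: np.ndarray  # (n_slices, rows, cols); unit norm above rank
    slice_shape: tuple[int, int]
    axis: str

    @property
    def rank(self) -> int:
        return int(np.count_nonzero(self.eigenvalues))


def slice_matrix(vol: GreyMatterVolume, axis: int | str) -> SliceMatrix:
    """Assemble M for one axis: one flattened slice per column, grid order."""
    ax = vol.axis_index(axis) if isinstance(axis, str) else int(axis)
    if not 0 <= ax <= 2:
        raise ValueError(f"axis index out of range: {ax}")
    label = vol.axis_labels[ax]
    stack = np.moveaxis(vol.values, ax, 0).astype(np.float64)  # (n_slices, r, c)
    n_slices = stack.shape[0]
    slice_shape = stack.shape[1:]
    m = stack.reshape(n_slices, -1).T.copy()  # (rows*cols, n_slices)
    return SliceMatrix(m, slice_shape, label)


def _fix_sign(image_flat: np.ndarray) -> np.ndarray:
    """Flip sign so the element of largest magnitude is positive.

    Eigenvectors are defined only up to sign; a fixed rule keeps caches and
    repeated runs bit-identical.  Ties resolve to the first extremal element.
    """
    j = int(np.argmax(np.abs(image_flat)))
    if image_flat[j] < 0:
        return -image_flat
    return image_flat


def gram_eigendecomposition(sm: SliceMatrix) -> EigensliceDecomposition:
    """Eigendecompose MᵀM; derive unit-norm eigenslices Mvᵢ/√λᵢ.

    The large MMᵀ is never formed.  Eigenvalues are clipped at the relative
    rank tolerance; positions at or below it get zero eigenslices, since
    boundary zero-slices routinely make the stack rank-deficient.
    """
    m = sm.m
    if not np.isfinite(m).all():
        raise ValueError("slice matrix contains non-finite entries")
    gram = m.T @ m
    evals, evecs = scipy.linalg.eigh(gram)  # ascending
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = RANK_RTOL * max(float(evals[0]) if evals.size else 0.0, np.finfo(np.float64).tiny)
    evals = np.where(evals > tol, evals, 0.0)

    n = sm.n_slices
    slices = np.zeros((n,) + tuple(sm.slice_shape), dtype=np.float64)
    for i in range(n):
        if evals[i] <= 0.0:
            break
        flat = m @ evecs[:, i] / np.sqrt(evals[i])
        slices[i] = sm.unflatten(_fix_sign(flat))
    return EigensliceDecomposition(evals, evecs, slices, tuple(sm.slice_shape), sm.axis)


def eigenslices(vol: GreyMatterVolume, axis: int | str, k: int) -> np.ndarray:
    """First ``k`` eigenslices of a volume along ``axis``, shape (k, r, c).

    Positions beyond the numerical rank are zero images, never errors: a
    nearly empty volume is valid input, just low-rank.
    """
    sm = slice_matrix(vol, axis)
    if not 1 <= k <= sm.n_slices:
        raise ValueError(f"k must be in 1..{sm.n_slices}, got {k}")
    dec = gram_eigendecomposition(sm)
    return dec.eigenslices[:k]
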
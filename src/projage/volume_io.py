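"""Reading, validation and padding of gray-matter probability volumes.

Volumes are per-voxel gray-matter likelihood maps (values in [0, 1]) produced
by tissue segmentation of skull-stripped T1-weighted MRI.  They live on their
native scanner grid; the pipeline clamps values into [0, 1] and zero-pads
every volume symmetrically to a common grid so that downstream 2D projections
share a shape.  No registration, resampling or intensity normalization is
performed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Common grid used for full-scale volumes (voxel counts per axis).
DEFAULT_TARGET_GRID = (256, 256, 208)

#: Anatomical label attached to each storage axis.  The projection method
#: operates on raw grid axes; labels are bookkeeping for channel names only.
DEFAULT_AXIS_LABELS = ("sagittal", "coronal", "transversal")


class VolumeIOError(ValueError):
    """Unreadable, non-volumetric or non-finite input volume."""


@dataclasses.dataclass(frozen=True)
class GreyMatterVolume:
    """A 3D grid of gray-matter likelihood values in [0, 1].

    Parameters
    ----------
    values
        3D float array, every element in the closed interval [0, 1].
    voxel_size_mm
        Physical edge lengths of one voxel.
    axis_labels
        Anatomical tag for each storage axis.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3:
            raise VolumeIOError(f"expected a 3D volume, got ndim={v.ndim}")
        if not np.isfinite(v).all():
            raise VolumeIOError("volume contains non-finite voxels")
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise VolumeIOError("likelihood values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_index(self, label: str) -> int:
        """Storage axis carrying anatomical label ``label``."""
        try:
            return self.axis_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown axis label {label!r}; have {self.axis_labels}") from None


@dataclasses.dataclass(frozen=True)
class SubjectRecord:
    """One manifest row: a subject, the recorded age and the volume location.

    Ages are whole years; the recording process rounds the true age to the
    nearest year, which alone bounds any predictor's MAE from below by
    0.25 years on a uniform age distribution.
    """

    subject_id: str
    age_years: int
    volume_path: Path

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")


def clamp(values: np.ndarray) -> np.ndarray:
    """Clamp likelihoods into [0, 1]; reject non-finite voxels."""
    if not np.isfinite(values).all():
        raise VolumeIOError("volume contains NaN/Inf voxels")
    return np.clip(values, 0.0, 1.0)


def load_volume(
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] | None = None,
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS,
) -> GreyMatterVolume:
    """Load a NIfTI-1 gray-matter volume, clamping values into [0, 1].

    Slightly out-of-range values (a common artifact of interpolation during
    segmentation) are clamped rather than rejected; non-finite voxels raise.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeIOError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a single 3D image, got shape {data.shape}")
    if voxel_size_mm is None:
        zooms = img.header.get_zooms()[:3]
        voxel_size_mm = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
    return GreyMatterVolume(clamp(data), voxel_size_mm, axis_labels)


def save_volume(vol: GreyMatterVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine from the voxel size."""
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def pad_to_grid(vol: GreyMatterVolume, target_shape: Sequence[int] = DEFAULT_TARGET_GRID) -> GreyMatterVolume:
    """Zero-pad a volume symmetrically onto ``target_shape``.

    The original values occupy a centered block; an odd padding remainder puts
    the extra plane on the high-index side.  This convention is fixed so that
    cached projections are reproducible.
    """
    target = tuple(int(t) for t in target_shape)
    if len(target) != 3:
        raise ValueError("target_shape must have three components")
    pads = []
    for cur, tgt in zip(vol.shape, target):
        extra = tgt - cur
        if extra < 0:
            raise ValueError(f"target grid {target} smaller than volume {vol.shape}")
        pads.append((extra // 2, extra - extra // 2))
    if all(p == (0, 0) for p in pads):
        return vol
    padded = np.pad(vol.values, pads, mode="constant", constant_values=0.0)
    return GreyMatterVolume(padded, vol.voxel_size_mm, vol.axis_labels)


MANIFEST_COLUMNS = ("subject_id", "age_years", "volume_path")


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    """Parse a subject manifest CSV (``subject_id,age_years,volume_path``).

    Ages must be integral; subject ids must be unique.  Relative volume paths
    are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes[:5]}")
    ages = df["age_years"].to_numpy()
    if not np.all(ages == np.floor(ages)):
        raise ValueError("manifest ages must be whole years")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        vp = Path(row.volume_path)
        if not vp.is_absolute():
            vp = base / vp
        records.append(SubjectRecord(str(row.subject_id), int(row.age_years), vp))
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age_years": [r.age_years for r in records],
            "volume_path": [str(r.volume_path) for r in records],
        }
    )
    df.to_csv(path, index=False)
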
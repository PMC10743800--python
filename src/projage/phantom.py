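"""Synthetic aging brain phantoms: gray-matter likelihood volumes.

The generator emulates skull-stripped gray-matter probability maps whose
spatial structure varies monotonically with age, so the full projection and
regression pipeline can be exercised end to end without restricted imaging
data.  Three effects drive the age signal, all linear in age:

* the cortical shell (high gray-matter likelihood) thins,
* its likelihood declines,
* a central zero-likelihood "ventricle" ellipsoid grows.

Fixed high-likelihood "deep gray" blobs and a low-likelihood white-matter
interior complete the geometry.  Everything outside the ellipsoidal brain
mask is exactly zero, as after skull stripping.  Each subject's brain center
is jittered by up to 5% of the grid, standing in for native-space variation
across unregistered scans.  Recorded ages are the true (continuous) ages
rounded to whole years, reproducing the rounding floor of real cohorts.

These phantoms make no claim of anatomical realism; see docs/methods.md for
what passing tests on them do and do not show about real data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import GreyMatterVolume, SubjectRecord, save_volume, write_manifest


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic cohort.

    Defaults are a 1:4 scaling of the full 256x256x208 acquisition grid and a
    U.K.-Biobank-like age span; rates are per year of age beyond
    ``age_range[0]``.
    """

    grid: tuple[int, int, int] = (64, 64, 52)
    age_range: tuple[float, float] = (45.0, 80.0)
    shell_thickness_base: float = 4.0       # voxels at age_range[0]
    shell_thinning_rate: float = 0.03       # voxels / year
    ventricle_base: float = 0.18            # fraction of brain radius
    ventricle_growth_rate: float = 0.006    # fraction / year
    cortex_intensity_base: float = 0.85     # likelihood at age_range[0]
    intensity_decline_rate: float = 0.004   # likelihood / year
    white_matter_intensity: float = 0.15    # residual GM likelihood interior
    deep_gray_intensity: float = 0.6
    noise_sd: float = 0.05                  # likelihood units
    smoothing_sd: float = 1.0               # voxels, applied to the noise field
    center_jitter_frac: float = 0.05        # of each grid dimension
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        for name in (
            "shell_thinning_rate",
            "ventricle_growth_rate",
            "intensity_decline_rate",
            "noise_sd",
            "smoothing_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.shell_thickness_base <= 0:
            raise ValueError("shell_thickness_base must be positive")


@dataclasses.dataclass(frozen=True)
class PhantomSubject:
    """A simulated subject: continuous truth, rounded record, volume."""

    subject_id: str
    true_age: float
    recorded_age: int
    volume: GreyMatterVolume


#: Deep-gray blob centers in normalized ellipsoid coordinates, and radius.
_BLOB_CENTERS = (
    (-0.38, 0.22, 0.05),
    (0.38, 0.22, 0.05),
    (-0.32, -0.28, 0.10),
    (0.32, -0.28, 0.10),
)
_BLOB_RADIUS = 0.10


def generate_phantom(age: float, config: PhantomConfig, rng: np.random.Generator) -> GreyMatterVolume:
    """One gray-matter likelihood volume at a given (continuous) age.

    Deterministic given (age, rng state): identical streams give bit-identical
    volumes.  All values lie in [0, 1] and are exactly zero outside the brain
    mask.
    """
    lo, hi = config.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside configured range {config.age_range}")
    years = age - lo

    thickness = max(1.0, config.shell_thickness_base - config.shell_thinning_rate * years)
    cortex = float(np.clip(config.cortex_intensity_base - config.intensity_decline_rate * years, 0.0, 1.0))
    vent_frac = config.ventricle_base + config.ventricle_growth_rate * years

    nx, ny, nz = config.grid
    jitter = rng.uniform(-config.center_jitter_frac, config.center_jitter_frac, size=3)
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2]) + jitter * np.array([nx, ny, nz])
    semi = np.array([0.42 * nx, 0.45 * ny, 0.42 * nz])

    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    u = (x - center[0]) / semi[0]
    v = (y - center[1]) / semi[1]
    w = (z - center[2]) / semi[2]
    rho = np.sqrt(u * u + v * v + w * w)

    mask = rho <= 1.0
    mean_radius = float(semi.mean())
    rho_inner = 1.0 - thickness / mean_radius
    if rho_inner <= 0:
        raise ValueError("degenerate geometry: shell fills the whole brain")

    values = np.zeros(config.grid, dtype=np.float64)
    values[mask & (rho < rho_inner)] = config.white_matter_intensity
    values[mask & (rho >= rho_inner)] = cortex
    for bx, by, bz in _BLOB_CENTERS:
        blob = np.sqrt((u - bx) ** 2 + (v - by) ** 2 + (w - bz) ** 2) <= _BLOB_RADIUS
        values[blob & (rho < rho_inner)] = config.deep_gray_intensity
    values[rho <= vent_frac] = 0.0

    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=config.grid)
        if config.smoothing_sd > 0:
            noise = gaussian_filter(noise, config.smoothing_sd)
        values = values + noise

    values = np.clip(values, 0.0, 1.0)
    values[~mask] = 0.0
    return GreyMatterVolume(values)


def generate_cohort(n: int, config: PhantomConfig) -> list[PhantomSubject]:
    """Simulate ``n`` subjects with ages uniform on the configured range.

    Fully reproducible from ``config.seed``; recorded ages are the true ages
    rounded to the nearest whole year.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(config.seed)
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    width = max(4, len(str(n)))
    subjects = []
    for i, age in enumerate(ages):
        vol = generate_phantom(float(age), config, rng)
        subjects.append(
            PhantomSubject(
                subject_id=f"phantom_{i:0{width}d}",
                true_age=float(age),
                recorded_age=int(np.rint(age)),
                volume=vol,
            )
        )
    return subjects


def write_cohort(subjects: list[PhantomSubject], outdir: str | Path) -> Path:
    """Write volumes as NIfTI plus a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for s in subjects:
        vol_path = outdir / f"{s.subject_id}.nii.gz"
        save_volume(s.volume, vol_path)
        records.append(SubjectRecord(s.subject_id, s.recorded_age, vol_path))
    manifest = outdir / "manifest.csv"
    write_manifest(records, manifest)
    return manifest
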
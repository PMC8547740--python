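"""Synthetic cohorts of deformation-like volumes with planted asymmetries.

No imaging data ship with this package, so validation runs on simulated
log-Jacobian volumes whose ground truth is known exactly.  Each
participant's volume is

    symmetric smooth baseline
    + sum of Gaussian blobs (planted asymmetric structures)
    + i.i.d. Gaussian voxel noise,

where blob amplitudes may depend linearly on standardized participant
covariates (sex, age), mimicking the linear-regression analysis model.
The baseline is identical across participants and exactly mirror
symmetric, so it cancels in the asymmetry image and every downstream
structure traces back to a planted blob or to noise.

Cohort covariates emulate the marginals of a multi-site pediatric
sample: 212 children, ages uniform on 6.39-16.92 years, 39% female, 10
sites, verbal-IQ standard scores ~ N(113, 14.1), and a total brain
volume independent of the planted asymmetries.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid
from .roi import RoiMask


@dataclass(frozen=True)
class CohortMarginals:
    """Marginal distributions for the synthetic covariate table."""

    age_range: tuple[float, float] = (6.39, 16.92)
    female_fraction: float = 0.39
    n_sites: int = 10
    viq_mean: float = 113.0
    viq_sd: float = 14.1
    tbv_mean: float = 1250.0
    tbv_sd: float = 110.0

    @property
    def age_mean(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def age_sd(self) -> float:
        # uniform distribution: sd = range / sqrt(12)
        return (self.age_range[1] - self.age_range[0]) / np.sqrt(12.0)

    @property
    def male_mean(self) -> float:
        return 1.0 - self.female_fraction

    @property
    def male_sd(self) -> float:
        p = self.female_fraction
        return float(np.sqrt(p * (1.0 - p)))


DEFAULT_MARGINALS = CohortMarginals()


@dataclass(frozen=True)
class BlobSpec:
    """One planted Gaussian structure.

    ``amplitude`` is in log-Jacobian contrast units; positive amplitude
    means more volumetric displacement at the blob.  ``side`` states the
    hemisphere the blob lives in; a right-hemisphere blob of positive
    amplitude produces a *rightward* asymmetry (a negative well in the
    left-grid asymmetry image at the mirrored location).
    """

    center: tuple[int, int, int]
    sigma_mm: float
    amplitude: float
    side: str = "right"
    covariate_dependent: bool = False

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError(f"sigma_mm must be positive, got {self.sigma_mm}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    lr_axis: int = 0
    left_is_low_index: bool = True
    blobs: list[BlobSpec] = field(default_factory=list)
    noise_sd: float = 0.02
    #: between-participant SD of each blob's amplitude (contrast units);
    #: individual anatomical variability dominates covariate effects in
    #: real cohorts, which is what keeps effect sizes small
    amplitude_sd: float = 0.1
    n_participants: int = 212
    beta_sex: float = 0.0
    beta_age: float = 0.0
    baseline_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[self.lr_axis] % 2 != 0:
            raise ValueError("left-right axis length must be even")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.amplitude_sd < 0:
            raise ValueError(f"amplitude_sd must be >= 0, got {self.amplitude_sd}")
        half = self.shape[self.lr_axis] // 2
        for b in self.blobs:
            if not all(0 <= c < s for c, s in zip(b.center, self.shape)):
                raise ValueError(f"blob center {b.center} outside grid {self.shape}")
            i = b.center[self.lr_axis]
            on_left = i < half if self.left_is_low_index else i >= half
            if (b.side == "left") != on_left:
                raise ValueError(
                    f"blob at {b.center} declared side={b.side!r} but lies "
                    f"on the other side of the midline"
                )

    def empty_grid(self) -> VoxelGrid:
        return VoxelGrid(np.zeros(self.shape),
                         voxel_size_mm=(self.voxel_size_mm,) * 3,
                         lr_axis=self.lr_axis,
                         left_is_low_index=self.left_is_low_index)


def generate_cohort(n: int, seed: int,
                    marginals: CohortMarginals = DEFAULT_MARGINALS) -> pd.DataFrame:
    """Sample a covariate table: id, age, sex, site, viq, tbv.

    Deterministic given the seed; no missing values.  Ages are uniform on
    the configured range, sex Bernoulli(female_fraction), sites uniform.
    """
    if n < 2:
        raise ValueError(f"need at least 2 participants, got {n}")
    rng = np.random.default_rng(seed)
    age = rng.uniform(*marginals.age_range, size=n)
    female = rng.random(n) < marginals.female_fraction
    site = rng.integers(1, marginals.n_sites + 1, size=n)
    viq = rng.normal(marginals.viq_mean, marginals.viq_sd, size=n)
    tbv = rng.normal(marginals.tbv_mean, marginals.tbv_sd, size=n)
    return pd.DataFrame(
        {
            "id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "sex": np.where(female, "female", "male"),
            "site": [f"site{s:02d}" for s in site],
            "viq": viq,
            "tbv": tbv,
        }
    )


def _participant_rng(config_seed: int, participant_id: str) -> np.random.Generator:
    # stable 32-bit stream id from the participant label
    pid = zlib.crc32(participant_id.encode())
    return np.random.default_rng(np.random.SeedSequence([config_seed, pid]))


def _gaussian_blob(shape: tuple[int, int, int], center: tuple[int, int, int],
                   sigma_vox: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2.0 * sigma_vox ** 2))


def _symmetric_baseline(config: SimulationConfig) -> np.ndarray:
    """Smooth mirror-symmetric field shared by the whole cohort."""
    if config.baseline_amplitude == 0:
        return np.zeros(config.shape)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
    coarse = rng.normal(size=tuple(max(2, s // 6) for s in config.shape))
    zoom = [s / c for s, c in zip(config.shape, coarse.shape)]
    fine = ndimage.zoom(coarse, zoom, order=3)[
        tuple(slice(0, s) for s in config.shape)
    ]
    sym = 0.5 * (fine + np.flip(fine, axis=config.lr_axis))
    peak = np.abs(sym).max()
    if peak > 0:
        sym *= config.baseline_amplitude / peak
    return sym


def effective_amplitude(blob: BlobSpec, participant: pd.Series,
                        config: SimulationConfig,
                        marginals: CohortMarginals = DEFAULT_MARGINALS) -> float:
    """Blob amplitude after linear covariate modulation.

    For covariate-dependent blobs the amplitude is shifted by
    beta_sex * z(male indicator) + beta_age * z(age), with z-scores taken
    against the cohort marginals so the mapping is the same for every
    participant.
    """
    if not blob.covariate_dependent:
        return blob.amplitude
    z_sex = ((1.0 if participant["sex"] == "male" else 0.0) - marginals.male_mean) \
        / marginals.male_sd
    z_age = (float(participant["age"]) - marginals.age_mean) / marginals.age_sd
    return blob.amplitude + config.beta_sex * z_sex + config.beta_age * z_age


def generate_jacobian_image(participant: pd.Series, config: SimulationConfig,
                            marginals: CohortMarginals = DEFAULT_MARGINALS
                            ) -> VoxelGrid:
    """One participant's synthetic log-Jacobian volume.

    Baseline + planted blobs + voxel noise; reproducible given
    (config.seed, participant id).  Blob amplitudes carry an individual
    N(0, amplitude_sd) deviation on top of any covariate modulation, and
    voxel noise is added here, before the downstream smoothing step,
    mimicking acquisition noise.
    """
    field_ = _symmetric_baseline(config).copy()
    rng = _participant_rng(config.seed, str(participant["id"]))
    jitter = (rng.normal(0.0, config.amplitude_sd, size=len(config.blobs))
              if config.amplitude_sd > 0 else np.zeros(len(config.blobs)))
    for blob, extra in zip(config.blobs, jitter):
        amp = effective_amplitude(blob, participant, config, marginals) + extra
        sigma_vox = blob.sigma_mm / config.voxel_size_mm
        field_ += amp * _gaussian_blob(config.shape, blob.center, sigma_vox)
    if config.noise_sd > 0:
        field_ += rng.normal(0.0, config.noise_sd, size=config.shape)
    return VoxelGrid(field_, voxel_size_mm=(config.voxel_size_mm,) * 3,
                     lr_axis=config.lr_axis,
                     left_is_low_index=config.left_is_low_index)


@dataclass(frozen=True)
class RoiSpec:
    """Requested synthetic ROI: a sphere or box in the left hemisphere."""

    label: str
    center: tuple[int, int, int]
    radius_vox: float
    shape: str = "sphere"


def generate_roi_masks(config: SimulationConfig,
                       specs: list[RoiSpec]) -> list[RoiMask]:
    """Binary left-hemisphere masks for the requested ROI specs.

    A sphere of radius 0 is a single voxel.  Masks crossing the midline
    are rejected.
    """
    masks = []
    for spec in specs:
        grids = np.ogrid[tuple(slice(0, s) for s in config.shape)]
        if spec.shape == "sphere":
            d2 = sum((g - c) ** 2 for g, c in zip(grids, spec.center))
            arr = (d2 <= spec.radius_vox ** 2).astype(float)
        elif spec.shape == "box":
            inside = [np.abs(g - c) <= spec.radius_vox
                      for g, c in zip(grids, spec.center)]
            arr = (inside[0] & inside[1] & inside[2]).astype(float)
        else:
            raise ValueError(f"unknown ROI shape {spec.shape!r}")
        grid = VoxelGrid(arr, voxel_size_mm=(config.voxel_size_mm,) * 3,
                         lr_axis=config.lr_axis,
                         left_is_low_index=config.left_is_low_index)
        masks.append(RoiMask(spec.label, grid))  # validates hemisphere
    return masks


def write_fixture_dataset(cohort: pd.DataFrame, config: SimulationConfig,
                          out_dir: str | Path,
                          marginals: CohortMarginals = DEFAULT_MARGINALS) -> dict:
    """Write a complete on-disk dataset and return its file manifest.

    Emits one NIfTI volume per participant, the covariate table as CSV,
    and the planted ground truth (blobs, effect sizes) as JSON.  The
    manifest lists every file with a SHA-256 checksum, so identical seeds
    yield identical manifests.
    """
    from .io import write_volume  # deferred: io imports nibabel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for _, row in cohort.iterrows():
        grid = generate_jacobian_image(row, config, marginals)
        # plain .nii: gzip embeds a timestamp, which would break
        # checksum determinism under a fixed seed
        path = out / f"{row['id']}_jacobian.nii"
        write_volume(grid, path)
        files.append(path)
    cov_path = out / "covariates.csv"
    cohort.to_csv(cov_path, index=False, float_format="%.10g")
    files.append(cov_path)
    truth = {
        "config": {**asdict(config), "blobs": [asdict(b) for b in config.blobs]},
        "marginals": asdict(marginals),
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    files.append(truth_path)
    manifest = {
        "n_participants": int(len(cohort)),
        "files": [
            {"path": f.name,
             "sha256": hashlib.sha256(f.read_bytes()).hexdigest()}
            for f in files
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
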
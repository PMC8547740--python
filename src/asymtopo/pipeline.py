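"""End-to-end pipeline: volumes -> asymmetry -> diagrams -> landscapes -> stats.

Every stage writes its artifacts to disk (asymmetry NIfTIs, diagram and
landscape CSVs, stats tables, a JSON run manifest) so stages can be
audited or rerun independently.  Reruns with an identical config and
seed reproduce all CSV outputs bit-identically: permutation seeds are
derived deterministically from the run seed and each analysis cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .asymmetry import compute_asymmetry
from .cubical import compute_persistence
from .grid import VoxelGrid
from .io import read_covariates, read_volume, write_diagram_csv, write_volume
from .landscapes import LandscapeGrid, density_difference, global_value_range, make_landscape
from .roi import RoiMask, assign_pairs, mean_roi_asymmetry
from .stats import build_covariate_matrix, density_difference_summary, perm_lm

log = logging.getLogger("asymtopo")


@dataclass
class PipelineConfig:
    """All settings of one analysis run; the seed is mandatory."""

    volumes: list[str]
    covariates: str
    roi_masks: dict[str, str]      # label -> NIfTI path
    out_dir: str
    seed: int
    fwhm_mm: float = 8.0
    connectivity: int = 6
    n_positions: int = 15
    landscape_aggregate: str = "sum-of-levels"
    landscape_level: int = 1
    t_min: float | None = None
    t_max: float | None = None
    n_perm: int = 4999
    adjust: str = "none"            # 'none' or 'bh'
    require_positive_death: bool = False
    predictors: tuple[str, ...] = ("age", "sex", "viq")
    lr_axis: int | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cell_seed(run_seed: int, *parts) -> int:
    """Stable per-analysis-cell seed below 2**31."""
    tag = "|".join(str(p) for p in parts)
    return (run_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2 ** 31)


def _volume_for(participant_id: str, paths: list[Path]) -> Path:
    hits = [p for p in paths if p.name.startswith(str(participant_id))]
    if len(hits) != 1:
        raise FileNotFoundError(
            f"expected exactly one volume for participant {participant_id!r}, "
            f"found {len(hits)}"
        )
    return hits[0]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the run manifest (also written to disk)."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = read_covariates(config.covariates)
    vol_paths = [Path(p) for p in config.volumes]
    for p in vol_paths:
        if not p.exists():
            raise FileNotFoundError(f"input volume does not exist: {p}")
    rois = {}
    for label, path in config.roi_masks.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"ROI mask does not exist: {path}")
        rois[label] = RoiMask(label, read_volume(path, lr_axis=config.lr_axis))

    # stage 1+2: asymmetry images and persistence diagrams
    asym_images: dict[str, VoxelGrid] = {}
    diagrams = {}
    outputs: list[Path] = []
    for _, row in cohort.iterrows():
        pid = str(row["id"])
        t0 = time.time()
        vol = read_volume(_volume_for(pid, vol_paths), lr_axis=config.lr_axis)
        for roi in rois.values():
            if roi.mask.values.shape != vol.values.shape:
                raise ValueError(
                    f"grid mismatch: volume {vol.values.shape} vs ROI "
                    f"{roi.label!r} {roi.mask.values.shape}"
                )
        asym = compute_asymmetry(vol, config.fwhm_mm)
        apath = out / f"{pid}_asym.nii"
        write_volume(asym, apath)
        outputs.append(apath)
        diagram = compute_persistence(asym, config.connectivity, source_id=pid)
        dpath = out / f"{pid}_diagram.csv"
        write_diagram_csv(diagram, dpath)
        outputs.append(dpath)
        asym_images[pid] = asym
        diagrams[pid] = diagram
        log.info("stage=asymmetry+ph id=%s wall=%.2fs out=%s",
                 pid, time.time() - t0, dpath)

    # stage 3: landscapes on a cohort-global value grid
    if config.t_min is not None and config.t_max is not None:
        lgrid = LandscapeGrid(config.t_min, config.t_max, config.n_positions)
    else:
        lgrid = global_value_range(list(asym_images.values()), config.n_positions)
    land_rows = []
    land_values: dict[tuple[str, str, int], np.ndarray] = {}
    for pid, diagram in diagrams.items():
        for label, roi in rois.items():
            sub = assign_pairs(diagram, roi, config.require_positive_death)
            for dim in (0, 2):
                ls = make_landscape(sub.of_dim(dim), lgrid,
                                    k=config.landscape_level,
                                    aggregate=config.landscape_aggregate)
                land_values[(pid, label, dim)] = ls.values
                row = {"participant": pid, "roi": label, "dim": dim}
                row.update({f"pos{i + 1}": v for i, v in enumerate(ls.values)})
                land_rows.append(row)
    land_df = pd.DataFrame(land_rows)
    lpath = out / "landscapes.csv"
    land_df.to_csv(lpath, index=False, float_format="%.12g")
    outputs.append(lpath)
    log.info("stage=landscapes rows=%d out=%s", len(land_df), lpath)

    # stage 4: permutation regressions per (roi, dim, position, predictor)
    ids = [str(r) for r in cohort["id"]]
    stats_rows = []
    for label in rois:
        for dim in (0, 2):
            mat = np.stack([land_values[(pid, label, dim)] for pid in ids])
            for pos in range(config.n_positions):
                y = mat[:, pos]
                if np.ptp(y) == 0:
                    continue  # no structure at this position anywhere
                for predictor in config.predictors:
                    x = build_covariate_matrix(cohort, [predictor])[:, 0]
                    others = [p for p in config.predictors if p != predictor]
                    Z = build_covariate_matrix(cohort, others + ["site"])
                    res = perm_lm(
                        y, x, Z, n_perm=config.n_perm,
                        seed=_cell_seed(config.seed, label, dim, pos, predictor),
                        predictor_name=predictor,
                    )
                    stats_rows.append(
                        dict(roi=label, dim=dim, position=pos + 1,
                             predictor=predictor, coef=res.coefficient,
                             t=res.t_statistic, df=res.df,
                             p_perm=res.p_permutation, d=res.cohens_d,
                             r=res.r_equivalent)
                    )
    stats_df = pd.DataFrame(stats_rows)
    if config.adjust == "bh" and len(stats_df):
        stats_df["p_adj"] = multipletests(stats_df["p_perm"], method="fdr_bh")[1]
    spath = out / "regressions.csv"
    stats_df.to_csv(spath, index=False, float_format="%.12g")
    outputs.append(spath)

    # stage 5: density-difference summary and mean ROI asymmetry per ROI
    dens_rows = []
    for label in rois:
        diffs = np.array([
            density_difference_value(land_values, pid, label) for pid in ids
        ])
        summ = density_difference_summary(
            diffs, n_perm=config.n_perm,
            seed=_cell_seed(config.seed, "density", label), roi_label=label,
        )
        dens_rows.append(
            dict(roi=label, mean_difference=summ.mean, p=summ.p_value,
                 percent_positive=summ.percent_positive)
        )
    dens_df = pd.DataFrame(dens_rows)
    dpath = out / "density_difference.csv"
    dens_df.to_csv(dpath, index=False, float_format="%.12g")
    outputs.append(dpath)

    mean_rows = [
        dict(participant=pid, roi=label,
             mean_asymmetry=mean_roi_asymmetry(asym_images[pid], roi))
        for pid in ids for label, roi in rois.items()
    ]
    mpath = out / "mean_roi_asymmetry.csv"
    pd.DataFrame(mean_rows).to_csv(mpath, index=False, float_format="%.12g")
    outputs.append(mpath)

    manifest = {
        "software": "asymtopo",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_participants": len(cohort),
        "landscape_grid": {"t_min": lgrid.t_min, "t_max": lgrid.t_max,
                           "n_positions": lgrid.n_positions},
        "outputs": [p.name for p in outputs],
        "wall_seconds": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def density_difference_value(land_values: dict, pid: str, label: str) -> float:
    """Per-participant mean of (0-cycle - 2-cycle) landscape values."""
    return float(np.mean(land_values[(pid, label, 0)] - land_values[(pid, label, 2)]))
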
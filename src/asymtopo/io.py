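"""NIfTI and tabular I/O for the analysis pipeline.

Volumes travel as NIfTI-1 (.nii or .nii.gz); the left-right axis is
inferred from the header affine (the axis whose nearest canonical
direction is L or R) and can be overridden explicitly.  Diagrams and
landscape matrices are written as tidy CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cubical import PersistenceDiagram, PersistencePair
from .grid import VoxelGrid


def _affine_for(grid: VoxelGrid) -> np.ndarray:
    """Affine mapping array axes to world axes with lr_axis on world x.

    Left at low index maps to the +x (toward-right) world direction, so
    orientation round-trips through the header.
    """
    world_axes = [1, 2]  # y (A), z (S) for the two non-LR axes, in order
    affine = np.zeros((4, 4))
    affine[3, 3] = 1.0
    for array_axis in range(3):
        if array_axis == grid.lr_axis:
            world = 0
            sign = 1.0 if grid.left_is_low_index else -1.0
        else:
            world = world_axes.pop(0)
            sign = 1.0
        affine[world, array_axis] = sign * grid.voxel_size_mm[array_axis]
    return affine


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a VoxelGrid as NIfTI-1 with spacing and orientation recorded."""
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine_for(grid))
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def read_volume(path: str | Path, lr_axis: int | None = None,
                left_is_low_index: bool | None = None) -> VoxelGrid:
    """Read a NIfTI volume; infer the left-right axis unless overridden."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    codes = nib.orientations.aff2axcodes(img.affine)
    if lr_axis is None:
        candidates = [i for i, c in enumerate(codes) if c in ("L", "R")]
        if len(candidates) != 1:
            raise ValueError(
                f"{path}: cannot infer the left-right axis from orientation "
                f"{codes}; pass lr_axis explicitly"
            )
        lr_axis = candidates[0]
    if left_is_low_index is None:
        # 'R' = index increases toward the right, so low index is left
        left_is_low_index = codes[lr_axis] == "R"
    return VoxelGrid(values, voxel_size_mm=zooms, lr_axis=lr_axis,
                     left_is_low_index=left_is_low_index)


def write_diagram_csv(diagram: PersistenceDiagram, path: str | Path) -> None:
    diagram.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def read_diagram_csv(path: str | Path, source_id: str = "") -> PersistenceDiagram:
    df = pd.read_csv(path)
    pairs = []
    for row in df.itertuples(index=False):
        bv = None if row.bx < 0 else (int(row.bx), int(row.by), int(row.bz))
        dv = None if row.dx < 0 else (int(row.dx), int(row.dy), int(row.dz))
        pairs.append(
            PersistencePair(int(row.dim), float(row.birth), float(row.death),
                            bv, dv, bool(row.essential))
        )
    return PersistenceDiagram(pairs, source_id)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate table: id, age, sex, site, viq, tbv; rejects missing values."""
    df = pd.read_csv(path)
    required = ["id", "age", "sex", "site", "viq", "tbv"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df[required].isna().any().any():
        bad = df.columns[df[required].isna().any()].tolist()
        raise ValueError(
            f"{path}: missing values in {bad}; impute upstream — this "
            f"pipeline requires complete covariates"
        )
    return df
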
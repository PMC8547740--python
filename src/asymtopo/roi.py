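"""ROI restriction of persistence diagrams and mean ROI asymmetry.

Topological structures can extend beyond an ROI, so assignment is based
on critical voxels and is deliberately asymmetric between dimensions:

* a 0-cycle (rightward structure) belongs to an ROI only if it was *born*
  inside the ROI and its birth value is negative — this guarantees the
  structure really is rightward-asymmetric;
* a 2-cycle (leftward structure) belongs to an ROI if its peak voxel
  (death) lies inside the ROI.  Requiring a positive death value in
  addition — the mirror-image of the 0-cycle rule — is available via
  ``require_positive_death`` but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cubical import PersistenceDiagram
from .grid import AsymmetryImage, VoxelGrid


@dataclass
class RoiMask:
    """A labelled binary region-of-interest on the analysis grid.

    The mask must lie entirely within the left hemisphere half of the
    grid (asymmetry values are read on the left-hemisphere convention).
    """

    label: str
    mask: VoxelGrid

    def __post_init__(self) -> None:
        values = self.mask.values
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError(f"ROI {self.label!r}: mask must be binary")
        half = self.mask.left_half_slice()
        outside = values.copy()
        outside[half] = 0
        if outside.any():
            raise ValueError(
                f"ROI {self.label!r}: mask crosses the midline into the "
                f"right hemisphere"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.values.sum())

    def contains(self, voxel: tuple[int, int, int] | None) -> bool:
        if voxel is None:
            return False
        return bool(self.mask.values[voxel])


def assign_pairs(diagram: PersistenceDiagram, roi: RoiMask,
                 require_positive_death: bool = False) -> PersistenceDiagram:
    """Restrict a diagram to the pairs belonging to one ROI.

    0-pairs are kept iff the birth voxel lies in the ROI and the birth
    value is negative; 2-pairs iff the death (peak) voxel lies in the ROI
    (and, when ``require_positive_death`` is set, the death value is
    positive).  Essential 0-pairs are filtered like any other pair.
    """
    kept = []
    for p in diagram.pairs:
        if p.dim == 0:
            if roi.contains(p.birth_voxel) and p.birth_value < 0:
                kept.append(p)
        else:
            if roi.contains(p.death_voxel) and (
                not require_positive_death or p.death_value > 0
            ):
                kept.append(p)
    return PersistenceDiagram(kept, diagram.source_id)


def mean_roi_asymmetry(asym: AsymmetryImage, roi: RoiMask) -> float:
    """Arithmetic mean of the asymmetry values over the ROI voxels.

    This is the conventional gross-morphometric summary the topological
    densities are compared against; it averages leftward and rightward
    structures together.
    """
    if asym.values.shape != roi.mask.values.shape:
        raise ValueError(
            f"grid mismatch: image {asym.values.shape} vs "
            f"mask {roi.mask.values.shape}"
        )
    m = roi.mask.values.astype(bool)
    if not m.any():
        raise ValueError(f"ROI {roi.label!r} is empty")
    return float(asym.values[m].mean())
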
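"""Voxel-grid container shared by all analysis stages.

A :class:`VoxelGrid` is a plain 3D scalar field plus the minimal spatial
metadata the asymmetry analysis needs: voxel spacing and which array axis
runs left-right.  The left-right axis must have even length so that the
inter-hemispheric midline falls *between* voxels and no voxel is its own
mirror image; this makes the asymmetry image exactly antisymmetric under
flipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class VoxelGrid:
    """A 3D scalar field with voxel spacing and a designated left-right axis.

    Parameters
    ----------
    values
        3D array of scalar values (finite).
    voxel_size_mm
        Physical voxel edge length per axis, in millimetres.
    lr_axis
        Index of the array axis running left-right.  Must have even length.
    left_is_low_index
        If True (default) the left hemisphere occupies the low-index half
        of ``lr_axis``.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lr_axis: int = 0
    left_is_low_index: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if self.lr_axis not in (0, 1, 2):
            raise ValueError(f"lr_axis must be 0, 1 or 2, got {self.lr_axis}")

    def require_even_lr(self) -> None:
        """Raise unless the left-right axis has even length.

        Hemisphere-dependent operations (flipping, mirroring, hemisphere
        membership) need the midline to fall between voxels; purely
        topological operations do not, so this is not a constructor
        invariant.
        """
        if self.values.shape[self.lr_axis] % 2 != 0:
            raise ValueError(
                f"left-right axis must have even length so the midline lies "
                f"between voxels; axis {self.lr_axis} has length "
                f"{self.values.shape[self.lr_axis]}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """Same metadata, new scalar field."""
        return replace(self, values=np.asarray(values, dtype=float))

    def left_half_slice(self) -> tuple[slice, ...]:
        """Index expression selecting the left-hemisphere half of the grid."""
        self.require_even_lr()
        half = self.shape[self.lr_axis] // 2
        sl = [slice(None)] * 3
        sl[self.lr_axis] = slice(0, half) if self.left_is_low_index else slice(half, None)
        return tuple(sl)

    def is_left_voxel(self, voxel: tuple[int, int, int]) -> bool:
        """True if the voxel lies strictly in the left hemisphere half."""
        self.require_even_lr()
        half = self.shape[self.lr_axis] // 2
        i = voxel[self.lr_axis]
        return i < half if self.left_is_low_index else i >= half

    def mirror_voxel(self, voxel: tuple[int, int, int]) -> tuple[int, int, int]:
        """Index of the voxel's mirror image across the midline."""
        v = list(voxel)
        v[self.lr_axis] = self.shape[self.lr_axis] - 1 - v[self.lr_axis]
        return tuple(v)


# AsymmetryImage is a VoxelGrid whose values are left-minus-right contrasts;
# keeping it a distinct name documents the semantics at call sites.
AsymmetryImage = VoxelGrid
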
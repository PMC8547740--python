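"""Construction of left-right asymmetry images from log-deformation volumes.

The standard deformation-based asymmetry image is built in three steps:
Gaussian smoothing of the log-scaled Jacobian-determinant volume, reversal
along the left-right axis, and subtraction of the flipped copy from the
original.  Because the input is log-scaled the subtraction is a ratio-type
asymmetry index: positive values mean more volumetric displacement on the
left (leftward asymmetry) when read at a left-hemisphere voxel, negative
values mean rightward asymmetry.

The result is exactly antisymmetric, A(x) = -A(flip(x)), because the
left-right axis has even length and flipping is an involution.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .grid import AsymmetryImage, VoxelGrid

#: Conversion factor between Gaussian FWHM and standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: tuple[float, ...]) -> tuple[float, ...]:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size_mm)


def gaussian_smooth(grid: VoxelGrid, fwhm_mm: float) -> VoxelGrid:
    """Smooth with a separable Gaussian kernel of the given FWHM (mm).

    ``fwhm_mm=0`` is the identity.  Boundaries use reflect (mirror)
    padding, which keeps smoothing exactly equivariant under the
    left-right flip.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return grid.with_values(grid.values.copy())
    sigma = fwhm_to_sigma_vox(fwhm_mm, grid.voxel_size_mm)
    smoothed = ndimage.gaussian_filter(grid.values, sigma=sigma, mode="reflect")
    return grid.with_values(smoothed)


def flip_lr(grid: VoxelGrid) -> VoxelGrid:
    """Reverse the grid along its left-right axis (an involution)."""
    grid.require_even_lr()
    return grid.with_values(np.flip(grid.values, axis=grid.lr_axis))


def compute_asymmetry(jacobian: VoxelGrid, fwhm_mm: float = 8.0) -> AsymmetryImage:
    """Smoothed log-Jacobian minus its left-right flipped copy.

    The caller is responsible for the input being log-scaled; only on the
    log scale does the subtraction equal a ratio-based asymmetry index.

    Returns an image that is exactly antisymmetric under ``flip_lr``:
    at a left-hemisphere voxel, positive = leftward, negative = rightward
    asymmetry.
    """
    if not np.all(np.isfinite(jacobian.values)):
        raise ValueError("jacobian volume contains non-finite values")
    jacobian.require_even_lr()
    smoothed = gaussian_smooth(jacobian, fwhm_mm)
    asym = smoothed.values - np.flip(smoothed.values, axis=jacobian.lr_axis)
    return jacobian.with_values(asym)
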
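"""SUV conversion, isotropic resampling, Gaussian smoothing and thresholding.

The chain implemented here turns a raw PET activity image into the binary
high-uptake mask the segmentation stage consumes:

1. ``convert_to_suv``   — decay-corrected activity normalised by dose per body
   mass: ``SUV = C / 2^(-t/T_half) * W / D`` (g/mL).
2. ``resample_isotropic`` — cubic interpolation to an isotropic grid
   (default 5 mm).
3. ``gaussian_smooth``  — normalised isotropic 3-D Gaussian for noise
   reduction (default sigma = 1 voxel).
4. ``threshold_suv``    — inclusive threshold at SUV >= 3.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import (
    BinaryMask,
    GridMismatchError,
    ParameterError,
    PETScan,
    SUVVolume,
)

#: Default SUV threshold separating high-uptake tissue from background.
DEFAULT_SUV_THRESHOLD = 3.0
#: Default isotropic voxel size after resampling, in mm.
DEFAULT_TARGET_MM = 5.0


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Isotropic Gaussian smoothing kernel.

    sigma_vox : kernel width in voxels (default 1, i.e. 5 mm at the default
    grid); truncate : kernel support radius in multiples of sigma.
    """

    sigma_vox: float = 1.0
    truncate: float = 4.0

    def __post_init__(self):
        if not (self.sigma_vox > 0):
            raise ParameterError(f"sigma_vox must be > 0, got {self.sigma_vox}")
        if self.truncate < 2:
            raise ParameterError(f"truncate must be >= 2, got {self.truncate}")


def convert_to_suv(scan: PETScan) -> SUVVolume:
    """Convert an activity image (Bq/mL) to SUV (g/mL).

    Each voxel becomes ``C / 2^(-t/T_half) * W / D``: the measured activity is
    decay-corrected back to injection time and normalised by injected dose per
    gram of body weight.  The voxel grid is unchanged.
    """
    decay = 2.0 ** (-scan.elapsed_min / scan.halflife_min)
    suv = scan.voxels.astype(float) / decay * (scan.weight_g / scan.dose_bq)
    return SUVVolume(voxels=suv, spacing=scan.spacing, origin=scan.origin)


def resample_isotropic(vol, target_mm: float = DEFAULT_TARGET_MM):
    """Resample a volume to an isotropic grid with cubic interpolation.

    Accepts an ``SUVVolume`` or a ``PETScan`` (metadata preserved) and returns
    the same container type.  The physical extent is preserved to within one
    voxel; cubic-spline overshoot below zero is clamped to 0.  When the input
    grid already matches the target spacing the voxel values pass through
    unchanged.
    """
    if not (target_mm > 0):
        raise ParameterError(f"target_mm must be > 0, got {target_mm}")
    spacing = np.asarray(vol.spacing, dtype=float)
    if spacing.size != 3 or np.any(~np.isfinite(spacing)) or np.any(spacing <= 0):
        raise ParameterError("volume lacks valid anisotropy metadata (spacing)")
    shape = np.asarray(vol.voxels.shape)

    if np.allclose(spacing, target_mm):
        return dataclasses.replace(vol, voxels=vol.voxels.copy(),
                                   spacing=(target_mm,) * 3)

    # voxel-center grid: new index j sits at physical offset j*target_mm,
    # i.e. fractional old index j*target_mm/spacing
    new_shape = np.maximum(np.floor((shape - 1) * spacing / target_mm).astype(int) + 1, 1)
    axes = [np.arange(n) * target_mm / s for n, s in zip(new_shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        vol.voxels.astype(float), np.stack(coords), order=3, mode="nearest"
    )
    np.maximum(out, 0.0, out=out)
    return dataclasses.replace(vol, voxels=out, spacing=(target_mm,) * 3)


def gaussian_smooth(vol: SUVVolume, kernel: GaussianKernelSpec | None = None) -> SUVVolume:
    """Smooth an isotropic SUV volume with a normalised 3-D Gaussian.

    The kernel is the standard separable Gaussian of width ``sigma_vox``
    voxels; being normalised it preserves constants and (away from the image
    boundary) the total signal sum.
    """
    kernel = kernel or GaussianKernelSpec()
    vol.iso_spacing()  # enforces isotropy
    out = ndimage.gaussian_filter(
        vol.voxels.astype(float), sigma=kernel.sigma_vox, truncate=kernel.truncate,
        mode="nearest",
    )
    np.maximum(out, 0.0, out=out)
    return SUVVolume(voxels=out, spacing=vol.spacing, origin=vol.origin)


def threshold_suv(vol: SUVVolume, thr: float = DEFAULT_SUV_THRESHOLD) -> BinaryMask:
    """Binary mask of voxels with (smoothed) SUV >= ``thr`` (inclusive)."""
    if not (thr > 0):
        raise ParameterError(f"threshold must be > 0, got {thr}")
    return BinaryMask(voxels=vol.voxels >= thr, spacing=vol.spacing, origin=vol.origin)


def preprocess(
    scan: PETScan,
    target_mm: float = DEFAULT_TARGET_MM,
    kernel: GaussianKernelSpec | None = None,
    threshold: float = DEFAULT_SUV_THRESHOLD,
) -> tuple[SUVVolume, BinaryMask]:
    """Full chain: SUV conversion, resampling, smoothing, thresholding.

    Returns the smoothed isotropic SUV volume and the high-uptake mask.  The
    mask is taken on the smoothed volume, which is also the substrate for
    watershed segmentation and feature sampling downstream.
    """
    suv = convert_to_suv(scan)
    suv = resample_isotropic(suv, target_mm)
    smoothed = gaussian_smooth(suv, kernel)
    mask = threshold_suv(smoothed, threshold)
    return smoothed, mask
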
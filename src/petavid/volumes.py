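"""In-memory containers for PET volumes plus NIfTI and DICOM I/O.

All volumes are plain 3-D numpy arrays with a voxel-center geometry convention:
the physical position of voxel ``(i, j, k)`` is ``origin + index * spacing``
(millimetres).  Activity is carried in Bq/mL and SUV in g/mL, the body-weight
SUV convention.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Half-life of fluorine-18 in minutes.
F18_HALFLIFE_MIN = 109.77


class InvalidMetadataError(ValueError):
    """Acquisition metadata (weight, dose, timing) is missing or non-physical."""


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class ParameterError(ValueError):
    """An operation parameter is outside its valid range."""


def _triple(value, name: str) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float)).ravel()
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3 or not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be a finite scalar or length-3 sequence")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


def _check_volume_array(voxels: np.ndarray, name: str, allow_negative: bool = False) -> np.ndarray:
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError(f"{name} must be a 3-D array, got ndim={voxels.ndim}")
    if voxels.dtype.kind == "f" and not np.all(np.isfinite(voxels)):
        raise ValueError(f"{name} contains non-finite values")
    if not allow_negative and voxels.size and voxels.min() < 0:
        raise ValueError(f"{name} contains negative values")
    return voxels


@dataclass(frozen=True)
class PETScan:
    """Raw PET activity volume (Bq/mL) with acquisition metadata.

    Parameters
    ----------
    voxels : ndarray
        3-D activity concentration image, Bq/mL, finite and non-negative.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm.
    origin : tuple of float
        Physical coordinates of voxel (0, 0, 0) in mm.
    weight_g : float
        Patient body weight in grams.
    dose_bq : float
        Injected activity in Bq.
    elapsed_min : float
        Injection-to-scan time in minutes.
    halflife_min : float
        Radionuclide half-life in minutes (default: F-18).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    weight_g: float
    dose_bq: float
    elapsed_min: float
    halflife_min: float = F18_HALFLIFE_MIN
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "voxels", _check_volume_array(self.voxels, "activity voxels"))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))
        if min(self.spacing) <= 0:
            raise ValueError("spacing components must be > 0")
        if not (self.weight_g > 0):
            raise InvalidMetadataError(f"weight_g must be > 0, got {self.weight_g}")
        if not (self.dose_bq > 0):
            raise InvalidMetadataError(f"dose_bq must be > 0, got {self.dose_bq}")
        if not (self.halflife_min > 0):
            raise InvalidMetadataError(f"halflife_min must be > 0, got {self.halflife_min}")
        if self.elapsed_min < 0:
            raise InvalidMetadataError(f"elapsed_min must be >= 0, got {self.elapsed_min}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class SUVVolume:
    """SUV image (g/mL) on a voxel grid; isotropic after resampling."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "voxels", _check_volume_array(self.voxels, "SUV voxels"))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))
        if min(self.spacing) <= 0:
            raise ValueError("spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_isotropic(self) -> bool:
        dx, dy, dz = self.spacing
        return abs(dx - dy) < 1e-9 and abs(dx - dz) < 1e-9

    def iso_spacing(self) -> float:
        """Isotropic voxel size in mm; raises if the grid is anisotropic."""
        if not self.is_isotropic:
            raise GridMismatchError(f"volume is anisotropic: spacing={self.spacing}")
        return self.spacing[0]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean mask on the same grid as its source SUV volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        object.__setattr__(self, "voxels", voxels.astype(bool, copy=False))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class RegionLabelMap:
    """Integer label image: 0 = background, 1..K = segmented regions."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        voxels = np.asarray(self.voxels)
        if voxels.ndim != 3:
            raise ValueError("label map must be a 3-D array")
        if voxels.dtype.kind not in "iu":
            if not np.array_equal(voxels, np.round(voxels)):
                raise ValueError("label map must hold integer labels")
        object.__setattr__(self, "voxels", voxels.astype(np.int32, copy=False))
        object.__setattr__(self, "spacing", _triple(self.spacing, "spacing"))
        object.__setattr__(self, "origin", _triple(self.origin, "origin"))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_regions(self) -> int:
        return int(self.voxels.max(initial=0))

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.voxels)
        return lab[lab > 0]


def same_grid(a, b, atol: float = 1e-6) -> bool:
    """Whether two volumes share shape, spacing and origin."""
    return (
        a.voxels.shape == b.voxels.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def require_same_grid(a, b) -> None:
    if not same_grid(a, b):
        raise GridMismatchError(
            f"grids differ: shapes {a.voxels.shape} vs {b.voxels.shape}, "
            f"spacing {a.spacing} vs {b.spacing}"
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(vol, path) -> None:
    """Write a volume/mask/label-map container as NIfTI-1."""
    data = vol.voxels
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asanyarray(data), _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(x) for x in aff[:3, 3])
    return data, spacing, origin


def load_suv_nifti(path) -> SUVVolume:
    data, spacing, origin = _load_nifti(path)
    return SUVVolume(np.maximum(data.astype(float), 0.0), spacing, origin)


def load_mask_nifti(path) -> BinaryMask:
    data, spacing, origin = _load_nifti(path)
    return BinaryMask(data > 0.5, spacing, origin)


def load_labels_nifti(path) -> RegionLabelMap:
    data, spacing, origin = _load_nifti(path)
    return RegionLabelMap(np.round(data).astype(np.int32), spacing, origin)


def load_pet_nifti(
    path,
    *,
    weight_kg: float,
    dose_mbq: float,
    elapsed_min: float,
    halflife_min: float = F18_HALFLIFE_MIN,
) -> PETScan:
    """Read a NIfTI activity image (Bq/mL) and attach acquisition metadata.

    Weight is given in kg and dose in MBq at the I/O layer and converted to the
    g / Bq units the SUV formula uses internally.
    """
    data, spacing, origin = _load_nifti(path)
    return PETScan(
        voxels=np.maximum(data.astype(float), 0.0),
        spacing=spacing,
        origin=origin,
        weight_g=weight_kg * 1000.0,
        dose_bq=dose_mbq * 1e6,
        elapsed_min=elapsed_min,
        halflife_min=halflife_min,
    )


# ---------------------------------------------------------------------------
# DICOM PET series (optional; requires pydicom)
# ---------------------------------------------------------------------------

def read_dicom_series(directory, **overrides) -> PETScan:
    """Assemble a PETScan from a single-series DICOM directory.

    Weight, dose and injection-to-scan time are pulled from the standard PET
    DICOM fields when present; keyword overrides (``weight_kg``, ``dose_mbq``,
    ``elapsed_min``, ``halflife_min``) take precedence.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files under {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda d: float(getattr(d, "ImagePositionPatient", [0, 0, 0])[2]))
    first = slices[0]

    arrays = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    # DICOM slices are (row=y, col=x); stack to (x, y, z)
    vol = np.stack(arrays, axis=-1).transpose(1, 0, 2)

    dy, dx = (float(v) for v in first.PixelSpacing)
    if len(slices) > 1:
        z0 = float(slices[0].ImagePositionPatient[2])
        z1 = float(slices[1].ImagePositionPatient[2])
        dz = abs(z1 - z0)
    else:
        dz = float(getattr(first, "SliceThickness", dx))

    weight_kg = overrides.get("weight_kg")
    if weight_kg is None:
        weight_kg = float(getattr(first, "PatientWeight", 0.0))
    dose_mbq = overrides.get("dose_mbq")
    halflife_min = overrides.get("halflife_min")
    elapsed_min = overrides.get("elapsed_min")
    radseq = getattr(first, "RadiopharmaceuticalInformationSequence", None)
    if radseq:
        item = radseq[0]
        if dose_mbq is None and getattr(item, "RadionuclideTotalDose", None) is not None:
            dose_mbq = float(item.RadionuclideTotalDose) / 1e6
        if halflife_min is None and getattr(item, "RadionuclideHalfLife", None) is not None:
            halflife_min = float(item.RadionuclideHalfLife) / 60.0
    if halflife_min is None:
        halflife_min = F18_HALFLIFE_MIN
    if elapsed_min is None:
        elapsed_min = 60.0
    if not weight_kg or dose_mbq is None:
        raise InvalidMetadataError(
            "DICOM series lacks weight/dose fields; pass weight_kg=/dose_mbq= overrides"
        )

    pos = getattr(first, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return PETScan(
        voxels=np.maximum(vol, 0.0),
        spacing=(dx, dy, dz),
        origin=(float(pos[0]), float(pos[1]), float(pos[2])),
        weight_g=float(weight_kg) * 1000.0,
        dose_bq=float(dose_mbq) * 1e6,
        elapsed_min=float(elapsed_min),
        halflife_min=float(halflife_min),
    )


def replace(obj, **changes):
    """dataclasses.replace passthrough, re-exported for convenience."""
    return dataclasses.replace(obj, **changes)
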
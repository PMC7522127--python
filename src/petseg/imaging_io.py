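"""Loading, SUV calibration, resampling and reformation of PET/CT volumes.

Axis convention
---------------
All volumes are stored as ``(z, y, x)`` arrays with a fixed anatomical
orientation:

* ``z`` index 0 is the most **superior** slice (head first),
* ``y`` index 0 is the most **anterior** row,
* ``x`` index 0 is the **patient-right** column.

"Patient right" therefore means *low* x index; on a radiological display
this is the left side of the image.  NIfTI inputs are reoriented from their
stored affine (via the closest canonical RAS orientation) into this
convention; DICOM series are sorted head-first by slice position.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "Modality", "VoxelGrid", "SuvCalibration", "PetCtStudy", "FitGeometry",
    "load_study", "load_volume", "save_volume", "compute_suv",
    "resample_isotropic", "reformat", "restack", "fit_slice", "unfit_slice",
    "F18_HALF_LIFE_S", "CalibrationError", "StudyMismatchError",
]

F18_HALF_LIFE_S = 6586.2  # fluorine-18


class CalibrationError(ValueError):
    """SUV conversion attempted with incomplete or invalid calibration."""


class StudyMismatchError(ValueError):
    """PET and CT inputs do not belong to the same patient/lattice."""


class Modality(enum.Enum):
    CT_HU = "CT_HU"
    PET_ACTIVITY = "PET_ACTIVITY"
    PET_SUV = "PET_SUV"
    MASK = "MASK"
    PROB = "PROB"


@dataclass
class VoxelGrid:
    """A 3D scalar volume with physical spacing, indexed ``(z, y, x)``."""

    data: np.ndarray
    spacing: tuple[float, float, float]  # (sz, sy, sx) in mm
    modality: Modality
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive: {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN/Inf")
        if self.modality is Modality.MASK:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("MASK grids may only contain {0, 1}")
        if self.modality is Modality.PROB:
            if self.data.min() < 0 or self.data.max() > 1:
                raise ValueError("PROB grids must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray, modality: Modality | None = None) -> "VoxelGrid":
        return VoxelGrid(data, self.spacing, modality or self.modality, self.origin)


@dataclass
class SuvCalibration:
    """Metadata needed to convert activity concentration (Bq/mL) to body-weight SUV."""

    injected_dose_bq: float | None = None
    patient_weight_g: float | None = None
    half_life_s: float = F18_HALF_LIFE_S
    injection_time: datetime | None = None
    acquisition_time: datetime | None = None
    rescale_slope: float = 1.0
    rescale_intercept: float = 0.0

    @property
    def is_complete(self) -> bool:
        return (
            self.injected_dose_bq is not None and self.injected_dose_bq > 0
            and self.patient_weight_g is not None and self.patient_weight_g > 0
            and self.half_life_s > 0
            and self.injection_time is not None
            and self.acquisition_time is not None
        )

    @property
    def uptake_time_s(self) -> float:
        if self.injection_time is None or self.acquisition_time is None:
            raise CalibrationError("injection/acquisition times missing")
        return (self.acquisition_time - self.injection_time).total_seconds()

    def to_json(self) -> str:
        d = {
            "injected_dose_bq": self.injected_dose_bq,
            "patient_weight_g": self.patient_weight_g,
            "half_life_s": self.half_life_s,
            "injection_time": self.injection_time.isoformat() if self.injection_time else None,
            "acquisition_time": self.acquisition_time.isoformat() if self.acquisition_time else None,
            "rescale_slope": self.rescale_slope,
            "rescale_intercept": self.rescale_intercept,
        }
        return json.dumps(d, indent=2)


@dataclass
class PetCtStudy:
    """Co-registered PET and CT grids on one lattice."""

    pet: VoxelGrid
    ct: VoxelGrid
    study_id: str = ""
    calibration: SuvCalibration | None = None

    def validate_aligned(self) -> None:
        if self.pet.shape != self.ct.shape or self.pet.spacing != self.ct.spacing:
            raise StudyMismatchError(
                f"PET {self.pet.shape}@{self.pet.spacing} vs "
                f"CT {self.ct.shape}@{self.ct.spacing}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _load_nifti(path: Path, modality: Modality) -> VoxelGrid:
    img = nib.as_closest_canonical(nib.load(str(path)))
    arr = np.asarray(img.get_fdata(), dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 3D NIfTI, got shape {arr.shape}")
    # canonical RAS: axes (x: L->R, y: P->A, z: I->S); ours is (z: S->I,
    # y: A->P, x: R->L), i.e. transpose then flip every axis.
    arr = arr.transpose(2, 1, 0)[::-1, ::-1, ::-1].copy()
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if modality is Modality.MASK:
        arr = (arr > 0.5).astype(np.uint8)
    return VoxelGrid(arr, spacing, modality)


def save_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NIfTI, inverting the canonical reorientation."""
    arr = grid.data[::-1, ::-1, ::-1].transpose(2, 1, 0)
    affine = np.diag([grid.spacing[2], grid.spacing[1], grid.spacing[0], 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(arr).astype(np.float32), affine)
    img.header.set_zooms((grid.spacing[2], grid.spacing[1], grid.spacing[0]))
    nib.save(img, str(path))


def _dicom_time(ds, date_tag: str, time_tag: str) -> datetime | None:
    date = getattr(ds, date_tag, None)
    time = getattr(ds, time_tag, None)
    if not date or not time:
        return None
    time = str(time).split(".")[0].ljust(6, "0")
    frac = str(getattr(ds, time_tag)).split(".")
    micro = int(float("0." + frac[1]) * 1e6) if len(frac) > 1 else 0
    return datetime.strptime(str(date) + time, "%Y%m%d%H%M%S").replace(microsecond=micro)


def _load_dicom_series(path: Path, modality: Modality) -> tuple[VoxelGrid, SuvCalibration, str]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ""} and p.is_file())
    slices = [pydicom.dcmread(str(f)) for f in files]
    if not slices:
        raise ValueError(f"no DICOM files found in {path}")
    # sort superior-first: descending physical z
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]), reverse=True)
    patient_ids = {str(getattr(s, "PatientID", "")) for s in slices}
    if len(patient_ids) != 1:
        raise StudyMismatchError(f"mixed PatientIDs in series: {patient_ids}")

    first = slices[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    arr = np.stack([s.pixel_array.astype(np.float64) * float(getattr(s, "RescaleSlope", 1.0))
                    + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices])
    # DICOM rows go anterior->posterior for HFS axial slices; columns run
    # patient-right -> patient-left, matching the package convention.
    ps = [float(v) for v in getattr(first, "PixelSpacing", [1.0, 1.0])]
    if len(slices) > 1:
        dz = abs(float(slices[0].ImagePositionPatient[2])
                 - float(slices[1].ImagePositionPatient[2]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    spacing = (dz or 1.0, ps[0], ps[1])

    cal = SuvCalibration(rescale_slope=slope, rescale_intercept=intercept)
    weight_kg = getattr(first, "PatientWeight", None)
    if weight_kg:
        cal.patient_weight_g = float(weight_kg) * 1000.0
    rpis = getattr(first, "RadiopharmaceuticalInformationSequence", None)
    if rpis:
        item = rpis[0]
        dose = getattr(item, "RadionuclideTotalDose", None)
        if dose:
            cal.injected_dose_bq = float(dose)
        half_life = getattr(item, "RadionuclideHalfLife", None)
        if half_life:
            cal.half_life_s = float(half_life)
        start = getattr(item, "RadiopharmaceuticalStartTime", None)
        acq_date = getattr(first, "AcquisitionDate", None) or getattr(first, "SeriesDate", None)
        if start and acq_date:
            t = str(start).split(".")[0].ljust(6, "0")
            cal.injection_time = datetime.strptime(str(acq_date) + t, "%Y%m%d%H%M%S")
    acq = _dicom_time(first, "AcquisitionDate", "AcquisitionTime") or \
        _dicom_time(first, "SeriesDate", "SeriesTime")
    cal.acquisition_time = acq
    return VoxelGrid(arr, spacing, modality), cal, str(first.PatientID)


def load_volume(path: str | Path, modality: Modality) -> VoxelGrid:
    """Load a single NIfTI file or DICOM series directory as a grid."""
    path = Path(path)
    if path.is_dir():
        grid, _, _ = _load_dicom_series(path, modality)
        return grid
    return _load_nifti(path, modality)


def load_study(pet_path: str | Path, ct_path: str | Path,
               study_id: str = "") -> PetCtStudy:
    """Load paired PET and CT inputs (NIfTI file or DICOM directory each).

    PET values are returned in stored activity units (after DICOM
    rescale slope/intercept) pending :func:`compute_suv`; calibration is
    populated from DICOM metadata when present and left incomplete
    otherwise (NIfTI carries no dose/weight information).
    """
    pet_path, ct_path = Path(pet_path), Path(ct_path)
    cal = SuvCalibration()
    pet_pid = ct_pid = None
    if pet_path.is_dir():
        pet, cal, pet_pid = _load_dicom_series(pet_path, Modality.PET_ACTIVITY)
    else:
        pet = _load_nifti(pet_path, Modality.PET_ACTIVITY)
    if ct_path.is_dir():
        ct, _, ct_pid = _load_dicom_series(ct_path, Modality.CT_HU)
    else:
        ct = _load_nifti(ct_path, Modality.CT_HU)
    if pet_pid is not None and ct_pid is not None and pet_pid != ct_pid:
        raise StudyMismatchError(f"PatientID mismatch: PET={pet_pid!r} CT={ct_pid!r}")
    return PetCtStudy(pet=pet, ct=ct, study_id=study_id or (pet_pid or ""),
                      calibration=cal)


# ---------------------------------------------------------------------------
# SUV
# ---------------------------------------------------------------------------

def compute_suv(pet_activity: VoxelGrid, cal: SuvCalibration) -> VoxelGrid:
    """Convert an activity-concentration grid (Bq/mL) to body-weight SUV.

    ``SUV(v) = activity(v) * weight_g / (dose_bq * 2^(-dt / half_life))``
    with ``dt`` the uptake time (acquisition - injection).  The denominator
    is the injected dose decay-corrected to acquisition start.
    """
    if pet_activity.modality is not Modality.PET_ACTIVITY:
        raise CalibrationError(f"expected PET_ACTIVITY grid, got {pet_activity.modality}")
    if not cal.is_complete:
        raise CalibrationError("calibration incomplete; cannot derive SUV")
    dt = cal.uptake_time_s
    if dt < 0:
        raise CalibrationError("acquisition precedes injection")
    decayed_dose = cal.injected_dose_bq * math.pow(2.0, -dt / cal.half_life_s)
    suv = pet_activity.data * (cal.patient_weight_g / decayed_dose)
    return pet_activity.with_data(suv, Modality.PET_SUV)


# ---------------------------------------------------------------------------
# Resampling and reformation
# ---------------------------------------------------------------------------

def resample_isotropic(grid: VoxelGrid, target_mm: float = 2.0) -> VoxelGrid:
    """Resample to an isotropic lattice (default 2 mm).

    Linear interpolation for intensity grids, nearest-neighbour for masks;
    output spacing is exactly ``(target, target, target)`` and the physical
    extent is preserved to within one voxel per axis.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    target = (float(target_mm),) * 3
    if grid.spacing == target:
        return VoxelGrid(grid.data.copy(), target, grid.modality, grid.origin)
    factors = tuple(s / target_mm for s in grid.spacing)
    order = 0 if grid.modality in (Modality.MASK,) else 1
    out = ndi.zoom(grid.data.astype(np.float64), factors, order=order,
                   mode="nearest", grid_mode=True)
    if grid.modality is Modality.MASK:
        out = (out > 0.5).astype(np.uint8)
    elif grid.modality is Modality.PROB:
        out = np.clip(out, 0.0, 1.0)
    return VoxelGrid(out, target, grid.modality, grid.origin)


_PLANE_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}


def reformat(grid: VoxelGrid | np.ndarray, plane: str) -> list[np.ndarray]:
    """Split a volume into an ordered stack of 2D slices.

    ``axial`` slices are indexed by z (each ``(y, x)``), ``coronal`` by y
    (each ``(z, x)``), ``sagittal`` by x (each ``(z, y)``).
    """
    data = grid.data if isinstance(grid, VoxelGrid) else np.asarray(grid)
    axis = _PLANE_AXIS[plane]
    return [np.take(data, i, axis=axis) for i in range(data.shape[axis])]


def restack(slices: list[np.ndarray], plane: str) -> np.ndarray:
    """Inverse of :func:`reformat`: rebuild the (z, y, x) volume."""
    axis = _PLANE_AXIS[plane]
    return np.stack(slices, axis=axis)


@dataclass(frozen=True)
class FitGeometry:
    """Exact bookkeeping of one center-crop + zero-pad slice fit."""

    orig_shape: tuple[int, int]
    target_shape: tuple[int, int]
    crop_start: tuple[int, int]   # offset into the original image
    pad_start: tuple[int, int]    # offset of the cropped block in the target
    kept_shape: tuple[int, int]


def fit_slice(img: np.ndarray, target_hw: tuple[int, int] = (448, 512)
              ) -> tuple[np.ndarray, FitGeometry]:
    """Center-crop then zero-pad a 2D slice to exactly ``target_hw``."""
    h, w = img.shape
    th, tw = target_hw
    crop, pad, kept = [], [], []
    for s, t in ((h, th), (w, tw)):
        k = min(s, t)
        crop.append((s - k) // 2)
        pad.append((t - k) // 2)
        kept.append(k)
    out = np.zeros((th, tw), dtype=img.dtype)
    out[pad[0]:pad[0] + kept[0], pad[1]:pad[1] + kept[1]] = \
        img[crop[0]:crop[0] + kept[0], crop[1]:crop[1] + kept[1]]
    geom = FitGeometry((h, w), (th, tw), (crop[0], crop[1]),
                       (pad[0], pad[1]), (kept[0], kept[1]))
    return out, geom


def unfit_slice(fitted: np.ndarray, geom: FitGeometry) -> np.ndarray:
    """Map a fitted slice (or prediction on it) back onto the original lattice.

    Values outside the cropped window are zero.
    """
    if fitted.shape != geom.target_shape:
        raise ValueError(f"expected {geom.target_shape}, got {fitted.shape}")
    out = np.zeros(geom.orig_shape, dtype=fitted.dtype)
    (c0, c1), (p0, p1), (k0, k1) = geom.crop_start, geom.pad_start, geom.kept_shape
    out[c0:c0 + k0, c1:c1 + k1] = fitted[p0:p0 + k0, p1:p1 + k1]
    return out
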
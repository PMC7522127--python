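"""Deterministic brain/liver/lung landmark detection and body-region split.

The pipeline normalises anatomy with three reference structures found by
thresholding + morphology (no learning involved):

* **brain** — the most superior high-uptake PET component of at least
  500 mL (threshold 2.5 SUV by default);
* **liver** — in a search window inferior to the brain and on the
  patient-right half, threshold 1.0 SUV (normal hepatic uptake), fill
  holes, erode with an 8 mm ball, keep the largest component whose centre
  of mass lies in the patient-right third of the x axis;
* **lungs** — CT below -300 HU, keep the 8 largest 3D components, drop
  2D regions touching axial slice borders (removes surrounding air),
  erode, keep the 2 largest components and take their combined centre of
  mass.

The body is then split into three z-slabs: head-neck above the top of the
lungs' bounding box, chest from there down to the liver centre of mass,
abdomen-pelvis below.  All operations use 26-connectivity in 3D and
8-connectivity in 2D, and are bit-deterministic.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from .imaging_io import Modality, VoxelGrid

__all__ = [
    "Landmark", "LandmarkSet", "Region", "RegionMap", "DetectorConfig",
    "detect_brain", "detect_liver", "detect_lungs", "partition_regions",
    "LandmarkError", "BrainNotFound", "LiverNotFound", "LungsNotFound",
    "InconsistentLandmarks",
]

_CONN3D = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity
_CONN2D = np.ones((3, 3), dtype=bool)      # 8-connectivity


class LandmarkError(RuntimeError):
    pass


class BrainNotFound(LandmarkError):
    pass


class LiverNotFound(LandmarkError):
    pass


class LungsNotFound(LandmarkError):
    pass


class InconsistentLandmarks(LandmarkError):
    pass


class Region(enum.IntEnum):
    HEAD_NECK = 0
    CHEST = 1
    ABDOMEN_PELVIS = 2


@dataclass(frozen=True)
class Landmark:
    name: str
    com_voxel: tuple[float, float, float]
    volume_ml: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LandmarkSet:
    brain: Landmark | None = None
    liver: Landmark | None = None
    lungs: Landmark | None = None

    def to_json(self) -> str:
        return json.dumps({k: (v.to_dict() if v else None)
                           for k, v in vars(self).items()}, indent=2)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable thresholds of the morphological detectors (mm / SUV / HU)."""

    brain_suv_threshold: float = 2.5
    brain_min_volume_ml: float = 500.0
    liver_suv_threshold: float = 1.0
    liver_window_offset_mm: tuple[float, float] = (100.0, 500.0)
    liver_erosion_radius_mm: float = 8.0
    liver_on_patient_right: bool = True
    lung_hu_threshold: float = -300.0
    lung_keep_components: int = 8
    lung_erosion_size: int = 3


def _component_landmark(mask: np.ndarray, name: str, voxel_ml: float) -> Landmark:
    idx = np.argwhere(mask)
    com = tuple(float(c) for c in idx.mean(axis=0))
    bbox = tuple((int(idx[:, a].min()), int(idx[:, a].max())) for a in range(3))
    return Landmark(name, com, float(idx.shape[0] * voxel_ml), bbox)  # type: ignore[arg-type]


def detect_brain(suv: VoxelGrid, config: DetectorConfig = DetectorConfig()) -> Landmark:
    """Most superior high-uptake component of at least the minimum brain volume."""
    if suv.modality is not Modality.PET_SUV:
        raise ValueError(f"expected PET_SUV grid, got {suv.modality}")
    voxel_ml = suv.voxel_volume_mm3 / 1000.0
    labels, n = ndi.label(suv.data > config.brain_suv_threshold, structure=_CONN3D)
    if n == 0:
        raise BrainNotFound("no voxels above the brain SUV threshold")
    counts = np.bincount(labels.ravel())
    candidates = [lab for lab in range(1, n + 1)
                  if counts[lab] * voxel_ml >= config.brain_min_volume_ml]
    if not candidates:
        raise BrainNotFound(
            f"no component >= {config.brain_min_volume_ml} mL above "
            f"SUV {config.brain_suv_threshold}")
    # most superior = smallest COM z
    coms = ndi.center_of_mass(np.ones_like(labels), labels, candidates)
    best = candidates[int(np.argmin([c[0] for c in coms]))]
    return _component_landmark(labels == best, "BRAIN", voxel_ml)


def detect_liver(suv: VoxelGrid, brain: Landmark,
                 config: DetectorConfig = DetectorConfig()) -> Landmark:
    """Morphological liver detection in a window inferior to the brain."""
    if suv.modality is not Modality.PET_SUV:
        raise ValueError(f"expected PET_SUV grid, got {suv.modality}")
    nz, ny, nx = suv.shape
    voxel_ml = suv.voxel_volume_mm3 / 1000.0
    sz = suv.spacing[0]
    z0 = brain.bbox[0][1]  # inferior edge of the brain bbox
    win_lo = min(nz, z0 + int(round(config.liver_window_offset_mm[0] / sz)))
    win_hi = min(nz, z0 + int(round(config.liver_window_offset_mm[1] / sz)))
    if win_lo >= win_hi:
        raise LiverNotFound("liver search window empty (volume too short)")

    window = np.zeros(suv.shape, dtype=bool)
    if config.liver_on_patient_right:
        window[win_lo:win_hi, :, : nx // 2] = True   # patient-right = low x
    else:
        window[win_lo:win_hi, :, nx // 2:] = True

    mask = (suv.data >= config.liver_suv_threshold) & window
    if not mask.any():
        raise LiverNotFound("no uptake above the liver threshold in the window")
    mask = ndi.binary_fill_holes(mask)
    radius_vox = max(1, int(round(config.liver_erosion_radius_mm / suv.spacing[1])))
    mask = ndi.binary_erosion(mask, structure=ball(radius_vox))
    labels, n = ndi.label(mask, structure=_CONN3D)
    if n == 0:
        raise LiverNotFound("no component survived erosion")

    third = nx / 3.0
    candidates = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        com = idx.mean(axis=0)
        x_ok = com[2] < third if config.liver_on_patient_right else com[2] > 2 * third
        if x_ok:
            candidates.append((lab, idx.shape[0], com[0]))
    if not candidates:
        raise LiverNotFound("no candidate with COM in the patient-right third")
    # largest volume; ties broken by the more superior COM
    candidates.sort(key=lambda c: (-c[1], c[2]))
    best = candidates[0][0]
    return _component_landmark(labels == best, "LIVER", voxel_ml)


def detect_lungs(ct: VoxelGrid, config: DetectorConfig = DetectorConfig()) -> Landmark:
    """Centre of mass of the two largest low-density components (the lungs)."""
    if ct.modality is not Modality.CT_HU:
        raise ValueError(f"expected CT_HU grid, got {ct.modality}")
    voxel_ml = ct.voxel_volume_mm3 / 1000.0
    air = ct.data < config.lung_hu_threshold
    labels, n = ndi.label(air, structure=_CONN3D)
    if n == 0:
        raise LungsNotFound("no voxels below the HU threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.argsort(counts)[::-1][: config.lung_keep_components]
    keep = [int(k) for k in keep if counts[k] > 0]
    mask = np.isin(labels, keep)

    # remove 2D regions touching axial slice borders (surrounding air)
    for z in range(mask.shape[0]):
        sl = mask[z]
        if not sl.any():
            continue
        lab2, n2 = ndi.label(sl, structure=_CONN2D)
        border = np.unique(np.concatenate([
            lab2[0, :], lab2[-1, :], lab2[:, 0], lab2[:, -1]]))
        border = border[border > 0]
        if border.size:
            sl[np.isin(lab2, border)] = False

    if config.lung_erosion_size > 1:
        mask = ndi.binary_erosion(
            mask, structure=np.ones((config.lung_erosion_size,) * 3, bool))
    labels, n = ndi.label(mask, structure=_CONN3D)
    if n < 2:
        raise LungsNotFound(f"{n} candidate component(s) after erosion, need 2")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    top2 = np.argsort(counts)[::-1][:2]
    union = np.isin(labels, [int(t) for t in top2])
    return _component_landmark(union, "LUNGS", voxel_ml)


@dataclass
class RegionMap:
    """Per-voxel anatomical label, constant within z-slabs."""

    labels: np.ndarray                # int8 of Region values, shape (z, y, x)
    z_chest_top: int
    z_chest_bottom: int

    def region_of(self, z: int) -> Region:
        return Region(int(self.labels[z, 0, 0]))


def partition_regions(shape: tuple[int, int, int], liver: Landmark,
                      lungs: Landmark) -> RegionMap:
    """Split the volume into head-neck / chest / abdomen-pelvis z-slabs.

    Chest top is the superior edge of the lungs' bounding box; chest bottom
    is the liver centre-of-mass slice.
    """
    z_top = int(lungs.bbox[0][0])
    z_bottom = int(round(liver.com_voxel[0]))
    if lungs.com_voxel[0] >= liver.com_voxel[0]:
        raise InconsistentLandmarks(
            f"lungs COM z={lungs.com_voxel[0]:.1f} not superior to "
            f"liver COM z={liver.com_voxel[0]:.1f}")
    if z_top >= z_bottom:
        raise InconsistentLandmarks("chest slab has non-positive height")
    labels = np.full(shape, int(Region.ABDOMEN_PELVIS), np.int8)
    labels[:z_top] = int(Region.HEAD_NECK)
    labels[z_top:z_bottom] = int(Region.CHEST)
    return RegionMap(labels, z_top, z_bottom)
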
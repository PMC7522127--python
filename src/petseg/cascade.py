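"""End-to-end inference: 2D slice probabilities -> region components ->
region-specific 3D refinement on patches -> fused mask -> burden metrics.

Stages
------
1. ``predict_2d`` runs the 2D network slice-by-slice over the axial and
   sagittal reformations independently, maps predictions back to the
   volume and averages the two orientation probability volumes.
2. ``label_components`` thresholds the averaged probabilities at 0.5 and
   labels 26-connected components, assigning each to the anatomical region
   of its centroid voxel.
3. ``extract_patches`` cuts one region-sized cube (head-neck 32, chest 64,
   abdomen-pelvis 96) centred on each component — or a 50%-overlap tiling
   when the component is larger than the cube — with exact inverse
   geometry (zero padding at volume borders).
4. ``refine_3d`` runs the region V-Net on each patch and averages
   overlapping predictions on the volume lattice; voxels outside every
   patch get probability 0.
5. ``fuse_masks`` averages the 2D and 3D probability volumes and
   thresholds at 0.5 (ties positive).

``run_pipeline`` chains everything from file paths, degrading gracefully
to a single whole-volume CHEST region if landmarking fails.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .anatomy import (DetectorConfig, LandmarkError, LandmarkSet, Region,
                      RegionMap, detect_brain, detect_liver, detect_lungs,
                      partition_regions)
from .imaging_io import (Modality, PetCtStudy, VoxelGrid, compute_suv,
                         load_study, reformat, resample_isotropic, restack)
from .losses_metrics import TumorMetrics, tumor_metrics
from .networks import DEFAULT_PATCH_EDGES

logger = logging.getLogger("petseg.cascade")

__all__ = [
    "Component", "ComponentSet", "Patch", "PatchSet", "CascadeConfig",
    "predict_2d", "label_components", "extract_patches", "refine_3d",
    "fuse_masks", "run_pipeline", "PipelineResult",
]


@dataclass(frozen=True)
class CascadeConfig:
    threshold: float = 0.5
    orientations: tuple[str, ...] = ("axial", "sagittal")
    patch_edges: dict = field(default_factory=lambda: dict(DEFAULT_PATCH_EDGES))
    batch_slices: int = 16
    pad_multiple: int = 4     # slice padding so any U-Net depth divides evenly
    target_mm: float = 2.0
    detector: DetectorConfig = DetectorConfig()


# ---------------------------------------------------------------------------
# Stage 1: 2D prediction
# ---------------------------------------------------------------------------

def _normalise_channels(pet: np.ndarray, ct: np.ndarray):
    return pet.astype(np.float32), (ct / 1000.0).astype(np.float32)


def _predict_plane(model, pet: np.ndarray, ct: np.ndarray, plane: str,
                   config: CascadeConfig) -> np.ndarray:
    pet_s, ct_s = reformat(pet, plane), reformat(ct, plane)
    batch = np.stack([np.stack([p, c]) for p, c in zip(pet_s, ct_s)])
    h, w = batch.shape[2:]
    mult = max(config.pad_multiple, getattr(model, "pad_multiple", 1))
    ph, pw = (-h) % mult, (-w) % mult
    batch = np.pad(batch, ((0, 0), (0, 0), (0, ph), (0, pw)))
    out = []
    for i in range(0, batch.shape[0], config.batch_slices):
        out.append(np.asarray(model.predict(batch[i:i + config.batch_slices])))
    prob = np.concatenate(out)[:, 0, :h, :w]
    return restack(list(prob), plane)


def predict_2d(study: PetCtStudy, model,
               config: CascadeConfig = CascadeConfig()) -> VoxelGrid:
    """Orientation-averaged slice-wise tumor probability volume.

    ``model`` must expose ``predict(batch) -> batch`` on (N, 2, H, W)
    float arrays (PET SUV, CT/1000 channels), returning (N, 1, H, W)
    probabilities.
    """
    study.validate_aligned()
    pet, ct = _normalise_channels(study.pet.data, study.ct.data)
    acc = np.zeros(study.pet.shape, np.float64)
    for plane in config.orientations:
        acc += _predict_plane(model, pet, ct, plane, config)
    prob = np.clip(acc / len(config.orientations), 0.0, 1.0)
    return study.pet.with_data(prob, Modality.PROB)


# ---------------------------------------------------------------------------
# Stage 2: component labeling per region
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    id: int
    region: Region
    n_voxels: int
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    centroid: tuple[float, float, float]


@dataclass
class ComponentSet:
    labels: np.ndarray                 # int labels, 0 background
    components: list[Component]

    def __len__(self) -> int:
        return len(self.components)


def label_components(prob: VoxelGrid, regions: RegionMap,
                     threshold: float = 0.5) -> ComponentSet:
    """Binarize at ``threshold`` (>= positive) and label 26-connected blobs.

    Each component is assigned the anatomical region of its centroid voxel
    (rounded), which is deterministic for blobs straddling a region plane.
    """
    mask = prob.data >= threshold
    if mask.shape != regions.labels.shape:
        raise ValueError("probability grid and region map are misaligned")
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
    comps: list[Component] = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        centroid = idx.mean(axis=0)
        cz = int(round(centroid[0]))
        cz = min(max(cz, 0), regions.labels.shape[0] - 1)
        comps.append(Component(
            id=lab,
            region=Region(int(regions.labels[cz, 0, 0])),
            n_voxels=int(idx.shape[0]),
            bbox=tuple((int(idx[:, a].min()), int(idx[:, a].max()))
                       for a in range(3)),  # type: ignore[arg-type]
            centroid=tuple(float(c) for c in centroid),  # type: ignore[arg-type]
        ))
    return ComponentSet(labels, comps)


# ---------------------------------------------------------------------------
# Stage 3: patch extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Patch:
    component_id: int
    region: Region
    start: tuple[int, int, int]    # may be negative (zero-padded gather)
    edge: int
    pet: np.ndarray
    ct: np.ndarray


@dataclass
class PatchSet:
    patches: list[Patch]
    volume_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.patches)


def _gather(vol: np.ndarray, start, edge: int) -> np.ndarray:
    out = np.zeros((edge,) * 3, dtype=vol.dtype)
    src, dst = [], []
    for s, n in zip(start, vol.shape):
        lo, hi = max(s, 0), min(s + edge, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def _tile_starts(lo: int, hi: int, edge: int) -> list[int]:
    """Cube start offsets covering [lo, hi] with 50% overlap."""
    extent = hi - lo + 1
    if extent <= edge:
        return [lo + (extent - edge) // 2]
    step = edge // 2
    starts = list(range(lo, hi + 1 - edge + 1, step))
    if starts[-1] + edge < hi + 1:
        starts.append(hi + 1 - edge)
    return starts


def extract_patches(components: ComponentSet, study: PetCtStudy,
                    config: CascadeConfig = CascadeConfig()) -> PatchSet:
    """Cut 2-channel cubes per component (single centred cube, or a
    50%-overlap tiling when the component outgrows its region's edge)."""
    pet, ct = _normalise_channels(study.pet.data, study.ct.data)
    patches: list[Patch] = []
    for comp in components.components:
        edge = int(config.patch_edges[comp.region])
        fits = all(hi - lo + 1 <= edge for lo, hi in comp.bbox)
        if fits:
            starts = [tuple(int(round(c - edge / 2)) for c in comp.centroid)]
        else:
            per_axis = [_tile_starts(lo, hi, edge) for lo, hi in comp.bbox]
            starts = [(a, b, c) for a in per_axis[0] for b in per_axis[1]
                      for c in per_axis[2]]
        for start in starts:
            patches.append(Patch(
                component_id=comp.id, region=comp.region, start=start,
                edge=edge,
                pet=_gather(pet, start, edge), ct=_gather(ct, start, edge)))
    return PatchSet(patches, study.pet.shape)


# ---------------------------------------------------------------------------
# Stage 4: 3D refinement
# ---------------------------------------------------------------------------

def refine_3d(patches: PatchSet, models: dict,
              study: PetCtStudy | None = None) -> VoxelGrid:
    """Run region V-Nets per patch; average overlaps on the volume lattice.

    ``models`` maps :class:`Region` to an object with
    ``predict(batch) -> batch`` on (N, 2, E, E, E) arrays.  A model may
    instead expose ``predict_patch(patch) -> cube`` to receive the patch
    geometry (used by oracle stubs).  Voxels outside every patch get
    probability 0.
    """
    shape = patches.volume_shape
    acc = np.zeros(shape, np.float64)
    count = np.zeros(shape, np.int32)
    for patch in patches.patches:
        model = models.get(patch.region)
        if model is None:
            raise KeyError(f"no 3D model for region {patch.region.name}")
        if hasattr(model, "predict_patch"):
            pred = np.asarray(model.predict_patch(patch))
        else:
            x = np.stack([patch.pet, patch.ct])[None]
            pred = np.asarray(model.predict(x))[0, 0]
        # scatter back, clipping the parts that fell outside the volume
        src, dst = [], []
        ok = True
        for s, n in zip(patch.start, shape):
            lo, hi = max(s, 0), min(s + patch.edge, n)
            if lo >= hi:
                ok = False
                break
            dst.append(slice(lo, hi))
            src.append(slice(lo - s, hi - s))
        if not ok:
            continue
        acc[tuple(dst)] += pred[tuple(src)]
        count[tuple(dst)] += 1
    prob = np.where(count > 0, acc / np.maximum(count, 1), 0.0)
    spacing = study.pet.spacing if study is not None else (2.0, 2.0, 2.0)
    return VoxelGrid(np.clip(prob, 0.0, 1.0), spacing, Modality.PROB)


# ---------------------------------------------------------------------------
# Stage 5: fusion
# ---------------------------------------------------------------------------

def fuse_masks(p2d: VoxelGrid | np.ndarray, p3d: VoxelGrid | np.ndarray,
               threshold: float = 0.5) -> np.ndarray:
    """Average the 2D and 3D probability volumes and threshold (>= positive)."""
    a = p2d.data if isinstance(p2d, VoxelGrid) else np.asarray(p2d)
    b = p3d.data if isinstance(p3d, VoxelGrid) else np.asarray(p3d)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return ((a + b) / 2.0 >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    mask: VoxelGrid
    prob_2d: VoxelGrid
    prob_3d: VoxelGrid
    metrics: TumorMetrics
    landmarks: LandmarkSet
    regions: RegionMap | None
    timings_s: dict[str, float]


def run_pipeline(study: PetCtStudy, model_2d, models_3d: dict,
                 config: CascadeConfig = CascadeConfig(),
                 truth_mask: np.ndarray | None = None) -> PipelineResult:
    """Execute landmarks -> regions -> 2D -> components -> 3D -> fusion -> metrics.

    ``study`` must already be SUV-calibrated and isotropic (see
    :func:`prepare_study` for the raw-file path).  If landmark detection
    fails, the whole volume is treated as CHEST and processing continues.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    study.validate_aligned()

    landmarks = LandmarkSet()
    regions: RegionMap | None = None
    try:
        landmarks.brain = detect_brain(study.pet, config.detector)
        landmarks.liver = detect_liver(study.pet, landmarks.brain, config.detector)
        landmarks.lungs = detect_lungs(study.ct, config.detector)
        regions = partition_regions(study.pet.shape, landmarks.liver,
                                    landmarks.lungs)
    except LandmarkError as exc:
        logger.warning("landmark detection failed (%s); treating the whole "
                       "volume as CHEST", exc)
        labels = np.full(study.pet.shape, int(Region.CHEST), np.int8)
        regions = RegionMap(labels, 0, study.pet.shape[0])
    timings["landmarks"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    prob2d = predict_2d(study, model_2d, config)
    timings["predict_2d"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comps = label_components(prob2d, regions, config.threshold)
    patches = extract_patches(comps, study, config)
    logger.info("labelled %d component(s) -> %d patch(es)", len(comps), len(patches))
    timings["components"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    prob3d = refine_3d(patches, models_3d, study)
    timings["refine_3d"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mask = fuse_masks(prob2d, prob3d, config.threshold)
    metrics = tumor_metrics(mask, study.pet.data, study.pet.spacing)
    timings["fuse_metrics"] = time.perf_counter() - t0

    return PipelineResult(
        mask=VoxelGrid(mask, study.pet.spacing, Modality.MASK),
        prob_2d=prob2d, prob_3d=prob3d, metrics=metrics,
        landmarks=landmarks, regions=regions, timings_s=timings)


def prepare_study(pet_path, ct_path, config: CascadeConfig = CascadeConfig(),
                  suv_already: bool = False) -> PetCtStudy:
    """Load raw files, convert PET to SUV and resample both to isotropic 2 mm."""
    study = load_study(pet_path, ct_path)
    if suv_already:
        pet = VoxelGrid(study.pet.data, study.pet.spacing, Modality.PET_SUV)
    else:
        pet = compute_suv(study.pet, study.calibration)
    pet = resample_isotropic(pet, config.target_mm)
    ct = resample_isotropic(study.ct, config.target_mm)
    return PetCtStudy(pet=pet, ct=ct, study_id=study.study_id,
                      calibration=study.calibration)
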
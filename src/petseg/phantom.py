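"""Seeded synthetic whole-body FDG-PET/CT phantom with ground truth.

The phantom emulates the uptake structure an eyes-to-thighs FDG scan
presents to the pipeline: a soft-tissue body envelope (40 HU) in air
(-1000 HU), two low-density lungs (-700 HU, faint uptake), a hot brain
(SUV ~6, > 500 mL, the most superior high-uptake structure), a moderate
liver (SUV ~2, patient-right upper abdomen), heart and bladder hotspots
(SUV 5 / 8) that a segmenter must learn to ignore, a mildly avid blood-pool
background (SUV 0.7) and ellipsoidal tumors of configurable count, size and
uptake.  Organs are rendered as hard-edged ellipsoids; additive Gaussian
noise is applied per modality afterwards.  Rendering is deterministic per
seed.

Geometry uses the package's fixed (z, y, x) convention: z index 0 superior,
y index 0 anterior, x index 0 patient-right.  The liver is therefore centred
at *low* x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging_io import Modality, PetCtStudy, VoxelGrid, save_volume

__all__ = [
    "PhantomSpec", "OrganTruth", "PhantomTruth",
    "generate_phantom", "generate_dataset", "PlacementError",
]


class PlacementError(RuntimeError):
    """Tumor placement failed under the phantom's geometric constraints."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic study; defaults span a torso at 2 mm."""

    seed: int = 0
    shape: tuple[int, int, int] = (220, 112, 128)   # (z, y, x) voxels
    spacing_mm: float = 2.0

    # body envelope: elliptic cylinder along z
    body_center_yx: tuple[float, float] = (56.0, 64.0)
    body_semiaxes_yx: tuple[float, float] = (52.0, 60.0)
    body_z_range: tuple[int, int] = (4, 216)
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    background_suv: float = 0.7

    # organs (centers/semiaxes in voxels)
    brain_center: tuple[float, float, float] = (32.0, 56.0, 64.0)
    brain_radius: float = 25.0            # 50 mm -> ~524 mL
    brain_suv: float = 6.0
    lung_center_z: float = 88.0
    lung_center_y: float = 54.0
    lung_offset_x: float = 31.0
    lung_semiaxes: tuple[float, float, float] = (28.0, 20.0, 14.0)
    lung_hu: float = -700.0
    lung_suv: float = 0.3
    heart_center: tuple[float, float, float] = (100.0, 62.0, 74.0)
    heart_radius: float = 11.0
    heart_suv: float = 5.0
    liver_center: tuple[float, float, float] = (150.0, 56.0, 40.0)
    liver_semiaxes: tuple[float, float, float] = (34.0, 40.0, 30.0)  # ~1.37 L
    liver_suv: float = 2.0
    bladder_center: tuple[float, float, float] = (200.0, 60.0, 64.0)
    bladder_radius: float = 8.0
    bladder_suv: float = 8.0

    # tumors
    n_tumors: int = 3
    tumor_radius_mm: tuple[float, float] = (6.0, 15.0)
    tumor_suv_range: tuple[float, float] = (3.0, 10.0)
    region_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)  # head-neck/chest/abd
    tumor_ct_hu: float = 50.0

    # additive Gaussian noise
    noise_suv_sigma: float = 0.1
    noise_hu_sigma: float = 20.0

    max_placement_tries: int = 2000


@dataclass(frozen=True)
class OrganTruth:
    com_voxel: tuple[float, float, float]
    volume_ml: float
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class PhantomTruth:
    """Generator-side ground truth for a rendered phantom."""

    tumor_mask: np.ndarray
    organs: dict[str, OrganTruth]
    tumors: list[dict]                     # per-tumor center/radius/suv/region
    z_chest_top: int                       # lungs bbox top
    z_chest_bottom: int                    # liver COM z
    tmtv_ml: float = 0.0
    suv_max: float | None = None


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semiaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _measure(mask: np.ndarray, voxel_ml: float) -> OrganTruth:
    idx = np.argwhere(mask)
    com = tuple(float(c) for c in idx.mean(axis=0))
    bbox = tuple((int(idx[:, a].min()), int(idx[:, a].max())) for a in range(3))
    return OrganTruth(com, float(idx.shape[0] * voxel_ml), bbox)  # type: ignore[arg-type]


def generate_phantom(spec: PhantomSpec) -> tuple[PetCtStudy, PhantomTruth]:
    """Render one phantom study plus ground truth. Deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    voxel_ml = spec.spacing_mm ** 3 / 1000.0
    spacing = (spec.spacing_mm,) * 3

    zz = np.arange(shape[0])[:, None, None]
    yy = np.arange(shape[1])[None, :, None]
    xx = np.arange(shape[2])[None, None, :]
    (cy, cx), (ay, ax) = spec.body_center_yx, spec.body_semiaxes_yx
    body = (((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0) & \
        (zz >= spec.body_z_range[0]) & (zz < spec.body_z_range[1])

    ct = np.full(shape, spec.air_hu, np.float64)
    pet = np.zeros(shape, np.float64)
    ct[body] = spec.soft_tissue_hu
    pet[body] = spec.background_suv

    organs: dict[str, np.ndarray] = {}
    organs["brain"] = _ellipsoid(shape, spec.brain_center, (spec.brain_radius,) * 3)
    lung_r = _ellipsoid(shape, (spec.lung_center_z, spec.lung_center_y,
                                spec.body_center_yx[1] - spec.lung_offset_x),
                        spec.lung_semiaxes)
    lung_l = _ellipsoid(shape, (spec.lung_center_z, spec.lung_center_y,
                                spec.body_center_yx[1] + spec.lung_offset_x),
                        spec.lung_semiaxes)
    organs["lungs"] = lung_r | lung_l
    organs["heart"] = _ellipsoid(shape, spec.heart_center, (spec.heart_radius,) * 3)
    organs["liver"] = _ellipsoid(shape, spec.liver_center, spec.liver_semiaxes)
    organs["bladder"] = _ellipsoid(shape, spec.bladder_center, (spec.bladder_radius,) * 3)

    pet[organs["brain"]] = spec.brain_suv
    ct[organs["lungs"]] = spec.lung_hu
    pet[organs["lungs"]] = spec.lung_suv
    pet[organs["heart"]] = spec.heart_suv
    pet[organs["liver"]] = spec.liver_suv
    pet[organs["bladder"]] = spec.bladder_suv

    truth_organs = {name: _measure(mask, voxel_ml) for name, mask in organs.items()}

    # region ground truth: chest spans [lungs bbox top, liver COM z)
    z_chest_top = truth_organs["lungs"].bbox[0][0]
    z_chest_bottom = int(round(truth_organs["liver"].com_voxel[0]))

    tumors = _place_tumors(spec, rng, body, organs, z_chest_top, z_chest_bottom)
    tumor_mask = np.zeros(shape, np.uint8)
    for t in tumors:
        ball = _ellipsoid(shape, t["center"], (t["radius_vox"],) * 3)
        tumor_mask[ball] = 1
        pet[ball] = t["suv"]
        ct[ball] = spec.tumor_ct_hu

    if spec.noise_hu_sigma > 0:
        ct = ct + rng.normal(0.0, spec.noise_hu_sigma, shape)
    if spec.noise_suv_sigma > 0:
        pet = np.maximum(pet + rng.normal(0.0, spec.noise_suv_sigma, shape), 0.0)

    study = PetCtStudy(
        pet=VoxelGrid(pet, spacing, Modality.PET_SUV),
        ct=VoxelGrid(ct, spacing, Modality.CT_HU),
        study_id=f"phantom-{spec.seed:05d}",
    )
    truth = PhantomTruth(
        tumor_mask=tumor_mask,
        organs=truth_organs,
        tumors=tumors,
        z_chest_top=z_chest_top,
        z_chest_bottom=z_chest_bottom,
        tmtv_ml=float(tumor_mask.sum() * voxel_ml),
        suv_max=(max(t["suv"] for t in tumors) if tumors else None),
    )
    return study, truth


def _place_tumors(spec: PhantomSpec, rng: np.random.Generator,
                  body: np.ndarray, organs: dict[str, np.ndarray],
                  z_chest_top: int, z_chest_bottom: int) -> list[dict]:
    """Rejection-sample disjoint tumor spheres inside the body.

    Tumors avoid the brain, heart and bladder hotspots (so per-tumor SUVmax
    ground truth stays exact) and keep a 2-voxel gap from each other so the
    truth mask has exactly ``n_tumors`` 26-connected components.
    """
    shape = spec.shape
    region_slabs = [(spec.body_z_range[0], z_chest_top),
                    (z_chest_top, z_chest_bottom),
                    (z_chest_bottom, spec.body_z_range[1])]
    names = ["HEAD_NECK", "CHEST", "ABDOMEN_PELVIS"]
    weights = np.asarray(spec.region_weights, float)
    weights = weights / weights.sum()

    keep_away = [  # (center, clearance radius in voxels)
        (spec.brain_center, spec.brain_radius),
        (spec.heart_center, spec.heart_radius),
        (spec.bladder_center, spec.bladder_radius),
    ]
    placed: list[dict] = []
    for k in range(spec.n_tumors):
        region_idx = int(rng.choice(3, p=weights))
        z_lo, z_hi = region_slabs[region_idx]
        r_vox_max = spec.tumor_radius_mm[1] / spec.spacing_mm
        ok = False
        for _ in range(spec.max_placement_tries):
            r_mm = rng.uniform(*spec.tumor_radius_mm)
            r = r_mm / spec.spacing_mm
            cz = rng.uniform(z_lo + r + 1, z_hi - r - 1)
            cy = rng.uniform(2, shape[1] - 2)
            cx = rng.uniform(2, shape[2] - 2)
            # entire sphere inside the body envelope
            (bcy, bcx) = spec.body_center_yx
            (bay, bax) = spec.body_semiaxes_yx
            margin = ((cy - bcy) / (bay - r - 1)) ** 2 + ((cx - bcx) / (bax - r - 1)) ** 2
            if margin > 1.0:
                continue
            if any(np.linalg.norm(np.subtract((cz, cy, cx), c)) < cr + r + 2
                   for c, cr in keep_away):
                continue
            if any(np.linalg.norm(np.subtract((cz, cy, cx), p["center"]))
                   < p["radius_vox"] + r + 3 for p in placed):
                continue
            suv = float(rng.uniform(*spec.tumor_suv_range))
            placed.append({
                "center": (float(cz), float(cy), float(cx)),
                "radius_vox": float(r),
                "radius_mm": float(r_mm),
                "suv": suv,
                "region": names[region_idx],
            })
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place tumor {k + 1}/{spec.n_tumors} in "
                f"{names[region_idx]} (z {z_lo}..{z_hi}, r<= {r_vox_max:.1f} vox)")
    return placed


def generate_dataset(n_studies: int, template: PhantomSpec, seed: int,
                     out_dir: str | Path) -> dict:
    """Render ``n_studies`` phantoms to NIfTI + JSON truth; return the manifest.

    Study k uses seed ``seed + k`` applied to ``template``; the manifest is
    fully reproducible from ``(template, seed)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from dataclasses import replace

    entries = []
    for k in range(n_studies):
        spec = replace(template, seed=seed + k)
        study, truth = generate_phantom(spec)
        sid = study.study_id
        pet_path = out_dir / f"{sid}_pet.nii.gz"
        ct_path = out_dir / f"{sid}_ct.nii.gz"
        mask_path = out_dir / f"{sid}_truth_mask.nii.gz"
        save_volume(study.pet, pet_path)
        save_volume(study.ct, ct_path)
        save_volume(VoxelGrid(truth.tumor_mask, study.pet.spacing, Modality.MASK),
                    mask_path)
        entries.append({
            "study_id": sid,
            "seed": spec.seed,
            "pet": pet_path.name,
            "ct": ct_path.name,
            "truth_mask": mask_path.name,
            "n_tumors": len(truth.tumors),
            "tmtv_ml": truth.tmtv_ml,
            "suv_max": truth.suv_max,
            "tumors": truth.tumors,
        })
    manifest = {"n_studies": n_studies, "seed": seed, "entries": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
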
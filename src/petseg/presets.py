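"""Desk-scale presets: tiny trainable configurations of the full cascade.

The published system trains a depth-6 U-Net on ~98k slices and three
V-Nets on clinical patches for 100 epochs — far beyond a single CPU.  The
presets here keep every architectural ingredient (dilated separable
residual blocks, orientation averaging, region patches, both compound
losses, both optimizers) but shrink capacity and data so a full
train + evaluate cycle runs in minutes: a depth-3, base-8 U-Net trained on
~200 full phantom slices, and one tiny V-Net (filters 4-32, 32^3 patches)
shared across the three regions.  These sizes are the package's fixed
desk-scale study conditions, used by the test-suite and the reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .anatomy import Region
from .cascade import CascadeConfig
from .networks import (NetConfig2D, NetConfig3D, UNet2D, VNet3D,
                       build_unet2d, build_vnet3d)
from .phantom import PhantomSpec, generate_phantom
from .training import (TrainPlan2D, TrainPlan3D, build_patch_dataset,
                       build_slice_dataset, train_2d, train_3d)

__all__ = [
    "tiny_unet2d_config", "tiny_vnet3d_config", "desk_cascade_config",
    "TinyModels", "train_tiny_models", "phantom_series",
]

TINY_PATCH_EDGE = 32
TINY_N_SLICES = 200

# desk-scaled analogues of the published schedules: hold, then halve
TINY_PLAN_2D = TrainPlan2D(epochs=10, batch_size=16, base_lr=2e-3,
                           hold_epochs=6, halve_every=2)
TINY_PLAN_3D = TrainPlan3D(epochs=12, batch_size=4, base_lr=2e-3,
                           schedule=((6, 1.0), (3, 2.0), (3, 4.0)))


def tiny_unet2d_config(seed: int = 0) -> NetConfig2D:
    return NetConfig2D(depth=3, base_filters=8, seed=seed)


def tiny_vnet3d_config(seed: int = 0) -> NetConfig3D:
    return NetConfig3D(down_filters=(4, 8, 16, 32),
                       patch_edges={r: TINY_PATCH_EDGE for r in Region},
                       seed=seed)


def desk_cascade_config(orientations: tuple[str, ...] = ("axial", "sagittal")
                        ) -> CascadeConfig:
    return CascadeConfig(patch_edges={r: TINY_PATCH_EDGE for r in Region},
                         orientations=orientations, batch_slices=8)


def phantom_series(n: int, seed: int, spec: PhantomSpec | None = None):
    """Generate ``n`` phantoms with consecutive seeds starting at ``seed``."""
    spec = spec or PhantomSpec()
    out = []
    for k in range(n):
        out.append(generate_phantom(replace(spec, seed=seed + k)))
    return out


def heldout_cohort(n: int, seed: int):
    """Held-out phantoms with tumor counts cycling 1..5.

    A correlation analysis of estimated vs true tumor burden needs dynamic
    range; like a patient cohort, these phantoms span low to high burden.
    """
    out = []
    for k in range(n):
        spec = PhantomSpec(seed=seed + k, n_tumors=1 + k % 5)
        out.append(generate_phantom(spec))
    return out


@dataclass
class TinyModels:
    model_2d: UNet2D
    models_3d: dict
    config: CascadeConfig
    history_2d: object = None
    history_3d: object = None


def train_tiny_models(seed: int = 0, n_train: int = 16,
                      n_slices: int = TINY_N_SLICES) -> TinyModels:
    """Train the tiny 2D U-Net and shared tiny V-Net on seeded phantoms.

    Training phantoms use seeds ``seed .. seed+n_train-1``; slice training
    keeps all tumor slices, subsamples to ~``n_slices`` (drawing from many
    phantoms buys tumor diversity at a fixed slice budget) and rebalances
    to 10% tumor-free slices; the V-Net trains on one 32^3 patch per truth
    lesion plus an equal number of negative patches (~50 total), half of
    them centred on physiological hotspots.
    """
    rng = np.random.default_rng(seed)
    series = phantom_series(n_train, seed)
    studies = [s for s, _ in series]
    masks = [t.tumor_mask for _, t in series]

    ds = build_slice_dataset(
        studies, masks, orientations=("axial", "coronal", "sagittal"),
        neg_fraction=0.10, seed=seed, crop_hw=(112, 128))
    if len(ds) > n_slices:
        keep = np.sort(rng.choice(len(ds), size=n_slices, replace=False))
        ds.x, ds.y = ds.x[keep], ds.y[keep]

    model_2d = build_unet2d(tiny_unet2d_config(seed))
    hist2d = train_2d(ds, model_2d, TINY_PLAN_2D, seed=seed)

    # ~50 patches: 8 phantoms x ~3 lesions + equal negatives
    pds = build_patch_dataset(studies[:8], masks[:8], edge=TINY_PATCH_EDGE,
                              seed=seed)
    vnet = build_vnet3d(Region.CHEST, tiny_vnet3d_config(seed))
    hist3d = train_3d(pds, vnet, TINY_PLAN_3D, seed=seed)

    models_3d = {r: vnet for r in Region}  # shared tiny refiner
    return TinyModels(model_2d, models_3d, desk_cascade_config(),
                      hist2d, hist3d)


def heldout_2d_stage_dice(model_2d, held, orientations=("axial", "coronal",
                                                        "sagittal")) -> float:
    """Pooled Dice of the orientation-averaged 2D stage on held-out phantoms.

    This is the 2D-only quality measure of the pipeline (the counterpart
    of reporting the cascade with only its 2D masks): predict each
    orientation, average, threshold at 0.5, pool overlap counts across
    studies.
    """
    from .cascade import predict_2d

    cfg = desk_cascade_config(orientations=tuple(orientations))
    num = den = 0
    for study, truth in held:
        prob = predict_2d(study, model_2d, cfg)
        pred = prob.data >= 0.5
        t = truth.tumor_mask > 0
        num += 2 * int((pred & t).sum())
        den += int(pred.sum()) + int(t.sum())
    return num / den if den else 1.0
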
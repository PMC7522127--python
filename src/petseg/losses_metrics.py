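"""Compound segmentation losses and metabolic tumor burden metrics.

Two training losses are used by the cascade:

* **2D loss** — soft Dice plus a class-frequency-weighted binary
  cross-entropy, countering the extreme foreground/background imbalance of
  whole-body slices (often > 99% background):

  ``L2D = [1 - 2|P∩T| / (|P|+|T|)] + mean_v -[w y_v log(ŷ_v) + (1-y_v) log(1-ŷ_v)]``

  with positive-class weight ``w = |V| / Σ_v y_v``.

* **3D loss** — soft Dice plus a sensitivity penalty plus the voxel-mean
  absolute error, which pushes false negatives down and keeps outputs away
  from 0.5:

  ``L3D = [1 - 2|P∩T|/(|P|+|T|)] + [1 - |P∩T|/|T|] + (1/|V|) Σ_v |y_v - ŷ_v|``

Cardinalities are soft (sums of probabilities); every ratio carries an
epsilon of 1e-6 so empty masks are well defined.  The losses accept either
ndarrays (evaluation) or :class:`petseg.nn.Tensor` (training; the returned
report keeps the differentiable total).

Burden metrics: TMTV (total metabolic tumor volume, mL), SUVmax and
per-lesion statistics over 26-connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .nn.tensor import Tensor, as_tensor

__all__ = [
    "LossReport", "TumorMetrics", "LesionStats",
    "soft_dice_term", "weighted_bce_term", "loss_2d", "loss_3d",
    "dice_score", "voxel_sensitivity", "tumor_metrics", "metrics_table",
    "EPS", "CLIP",
]

EPS = 1e-6    # smoothing epsilon on all ratio terms
CLIP = 1e-7   # probability clipping to keep logs finite

_CONN3D = np.ones((3, 3, 3), dtype=bool)


def _check_shapes(pred, target) -> np.ndarray:
    target = np.asarray(target)
    shape = pred.shape if isinstance(pred, Tensor) else np.asarray(pred).shape
    if shape != target.shape:
        raise ValueError(f"shape mismatch: pred {shape} vs target {target.shape}")
    return target


@dataclass(frozen=True)
class LossReport:
    """Term-wise loss breakdown; ``total`` is the sum of the reported terms."""

    terms: dict[str, float]
    total: float
    total_tensor: Tensor | None = field(default=None, compare=False, repr=False)

    def __getitem__(self, key: str) -> float:
        return self.terms[key]


def soft_dice_term(pred, target) -> Tensor:
    """``1 - (2|P∩T| + eps) / (|P| + |T| + eps)`` with soft cardinalities."""
    target = _check_shapes(pred, target)
    p = as_tensor(pred)
    t = target.astype(p.dtype)
    inter = (p * t).sum()
    sizes = p.sum() + float(t.sum())
    return 1.0 - (2.0 * inter + EPS) / (sizes + EPS)


def weighted_bce_term(pred, target, *, literal: bool = False) -> Tensor:
    """Class-frequency-weighted binary cross-entropy, mean over voxels.

    Positive voxels are up-weighted by ``w = |V| / max(Σ y, 1)``.  With
    ``literal=True`` the published algebraic variant (which additionally
    scales the negative term by ``1 - w`` and flips the bracket's sign) is
    evaluated instead; it is provided for comparison only and is not used
    anywhere in training.
    """
    target = _check_shapes(pred, target)
    p = as_tensor(pred).clip(CLIP, 1.0 - CLIP)
    y = target.astype(p.dtype)
    n = float(y.size)
    w = n / max(float(y.sum()), 1.0)
    if literal:
        inner = w * (y * p.log() + (1.0 - w) * (1.0 - y) * (1.0 - p).log())
        return -(inner.sum())
    ce = -(w * y * p.log() + (1.0 - y) * (1.0 - p).log())
    return ce.mean()


def loss_2d(pred, target) -> LossReport:
    """Dice + weighted BCE (the 2D training loss)."""
    dice = soft_dice_term(pred, target)
    bce = weighted_bce_term(pred, target)
    total = dice + bce
    return LossReport(
        terms={"dice_term": float(dice.data), "ce_term": float(bce.data)},
        total=float(total.data),
        total_tensor=total,
    )


def loss_3d(pred, target) -> LossReport:
    """Dice + sensitivity + MAE (the 3D refinement loss); total in [0, 3]."""
    target = _check_shapes(pred, target)
    p = as_tensor(pred)
    t = target.astype(p.dtype)
    dice = soft_dice_term(p, target)
    inter = (p * t).sum()
    sens = 1.0 - (inter + EPS) / (float(t.sum()) + EPS)
    mae = (p - t).abs().mean()
    total = dice + sens + mae
    return LossReport(
        terms={"dice_term": float(dice.data),
               "sensitivity_term": float(sens.data),
               "mae_term": float(mae.data)},
        total=float(total.data),
        total_tensor=total,
    )


# ---------------------------------------------------------------------------
# Evaluation metrics on binary masks
# ---------------------------------------------------------------------------

def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """Hard Dice ``2|A∩B| / (|A|+|B|)``; 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def voxel_sensitivity(pred: np.ndarray, truth: np.ndarray) -> tuple[float, bool]:
    """``|P∩T| / |T|``; returns ``(value, empty_truth_flag)``.

    An empty truth mask makes sensitivity undefined; it is reported as 1.0
    with the flag set so downstream reports can qualify it.
    """
    pred = np.asarray(pred, bool)
    truth = np.asarray(truth, bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    t = int(truth.sum())
    if t == 0:
        return 1.0, True
    return int((pred & truth).sum()) / t, False


@dataclass(frozen=True)
class LesionStats:
    volume_ml: float
    suv_max: float


@dataclass(frozen=True)
class TumorMetrics:
    tmtv_ml: float
    suv_max: float | None
    n_lesions: int
    per_lesion: tuple[LesionStats, ...]


def metrics_table(rows: list[dict], csv_path=None):
    """Tabulate per-scan metric rows (study_id, tmtv_ml, suv_max, ...).

    Returns a :class:`pandas.DataFrame`; optionally writes it as CSV.
    """
    import pandas as pd

    df = pd.DataFrame(rows)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def tumor_metrics(mask: np.ndarray, suv: np.ndarray,
                  spacing_mm: tuple[float, float, float] | float) -> TumorMetrics:
    """TMTV / SUVmax / per-lesion stats from a binary mask and an SUV grid.

    Lesions are 26-connected components; TMTV is the positive voxel count
    times the voxel volume.  An empty mask yields TMTV 0 and SUVmax None.
    """
    mask = np.asarray(mask, bool)
    suv = np.asarray(suv)
    if mask.shape != suv.shape:
        raise ValueError(f"shape mismatch: mask {mask.shape} vs SUV {suv.shape}")
    if np.isscalar(spacing_mm) or isinstance(spacing_mm, (int, float)):
        voxel_ml = float(spacing_mm) ** 3 / 1000.0
    else:
        voxel_ml = float(np.prod(spacing_mm)) / 1000.0
    if not mask.any():
        return TumorMetrics(0.0, None, 0, ())
    labels, n = ndi.label(mask, structure=_CONN3D)
    lesions = []
    for lab in range(1, n + 1):
        comp = labels == lab
        lesions.append(LesionStats(
            volume_ml=float(comp.sum() * voxel_ml),
            suv_max=float(suv[comp].max()),
        ))
    return TumorMetrics(
        tmtv_ml=float(sum(l.volume_ml for l in lesions)),
        suv_max=float(max(l.suv_max for l in lesions)),
        n_lesions=n,
        per_lesion=tuple(lesions),
    )
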
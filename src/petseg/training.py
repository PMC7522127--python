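"""Dataset assembly (slice rebalancing, patch sampling) and training loops.

Training conditions mirror the published recipe:

* 2D: RMSProp, 25 epochs, batch 16, learning rate 1e-5 held for 13 epochs
  then halved every 3 epochs; loss = Dice + weighted BCE.  Because ~90% of
  coronal/sagittal slices contain no tumor, the slice set is rebalanced so
  that only ~10% of retained slices are tumor-free.
* 3D: Adam, 100 epochs, batch 4, learning rate 1e-4 for 50 epochs, 1e-4/2
  for 25, 1e-4/4 for 25; loss = Dice + sensitivity + MAE.

Desk-scale overrides (fewer epochs, smaller networks, cropped slices,
larger learning rates) are plain config values; the published schedules
themselves are implemented exactly and tested epoch by epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging_io import PetCtStudy, reformat
from .losses_metrics import dice_score, loss_2d, loss_3d
from .networks import UNet2D, VNet3D, save_checkpoint
from .nn import Adam, RMSProp, Tensor

__all__ = [
    "TrainPlan2D", "TrainPlan3D", "lr_at",
    "SliceDataset", "build_slice_dataset", "PatchDataset", "build_patch_dataset",
    "TrainHistory", "train_2d", "train_3d", "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainPlan2D:
    epochs: int = 25
    batch_size: int = 16
    base_lr: float = 1e-5
    hold_epochs: int = 13       # epochs at base_lr before decay starts
    halve_every: int = 3
    repeat_halving: bool = True  # halve again every `halve_every` epochs
    neg_fraction: float = 0.10


@dataclass(frozen=True)
class TrainPlan3D:
    epochs: int = 100
    batch_size: int = 4
    base_lr: float = 1e-4
    # (n_epochs, divisor) pieces
    schedule: tuple[tuple[int, float], ...] = ((50, 1.0), (25, 2.0), (25, 4.0))


def lr_at(plan: TrainPlan2D | TrainPlan3D, epoch: int) -> float:
    """Exact learning rate of the published schedules at ``epoch`` (0-based)."""
    if epoch < 0 or epoch >= plan.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {plan.epochs})")
    if isinstance(plan, TrainPlan2D):
        if epoch < plan.hold_epochs:
            return plan.base_lr
        if plan.repeat_halving:
            n_halvings = 1 + (epoch - plan.hold_epochs) // plan.halve_every
        else:
            n_halvings = 1
        return plan.base_lr / 2.0 ** n_halvings
    edge = 0
    for n, divisor in plan.schedule:
        edge += n
        if epoch < edge:
            return plan.base_lr / divisor
    raise ValueError(f"epoch {epoch} beyond schedule pieces")  # pragma: no cover


# ---------------------------------------------------------------------------
# 2D slice dataset with negative-slice rebalancing
# ---------------------------------------------------------------------------

@dataclass
class SliceDataset:
    """Stacked 2-channel slices (PET, CT) with binary targets."""

    x: np.ndarray               # (N, 2, H, W) float32
    y: np.ndarray               # (N, 1, H, W) float32
    n_positive: int
    n_negative: int

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def negative_fraction(self) -> float:
        return self.n_negative / max(len(self), 1)


def _normalise_channels(pet: np.ndarray, ct: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # fixed affine scalings: SUV already a ratio; HU mapped to ~[-1, 1]
    return pet.astype(np.float32), (ct / 1000.0).astype(np.float32)


def build_slice_dataset(studies: list[PetCtStudy], masks: list[np.ndarray],
                        orientations: tuple[str, ...] = ("axial", "sagittal"),
                        neg_fraction: float = 0.10, seed: int = 0,
                        crop_hw: tuple[int, int] | None = None,
                        random_window_fraction: float = 0.5) -> SliceDataset:
    """Enumerate slices, keep all tumor slices, subsample tumor-free ones.

    The retained tumor-free fraction is ``neg_fraction`` (of the final
    dataset).  ``crop_hw`` brings every slice to one common shape (needed
    when orientations of different extents are mixed): larger slices are
    cropped, smaller ones zero-padded — the desk-scale stand-in for full
    448x512 slice fitting.  Tumor-slice windows are centred on the tumor
    COM (with seeded jitter), except that a ``random_window_fraction`` of
    them is positioned uniformly at random: windows that always track the
    tumor would systematically exclude distant physiological-uptake
    structures from supervision.  Labels are cropped with the images, so
    every window remains correctly annotated.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    pos, neg = [], []
    for study, mask in zip(studies, masks):
        pet, ct = _normalise_channels(study.pet.data, study.ct.data)
        for plane in orientations:
            pet_s = reformat(pet, plane)
            ct_s = reformat(ct, plane)
            m_s = reformat(np.asarray(mask), plane)
            for p, c, m in zip(pet_s, ct_s, m_s):
                (pos if m.any() else neg).append((p, c, m))
    if not pos:
        raise ValueError("no tumor-containing slices in the input studies")
    n_neg = int(round(neg_fraction * len(pos) / max(1.0 - neg_fraction, 1e-9)))
    n_neg = min(n_neg, len(neg))
    keep_neg = [neg[i] for i in rng.choice(len(neg), size=n_neg, replace=False)] \
        if n_neg else []

    def window(p, c, m, positive: bool):
        if crop_hw is None:
            return p, c, m
        h, w = m.shape
        th, tw = min(crop_hw[0], h), min(crop_hw[1], w)
        if positive and rng.random() >= random_window_fraction:
            com = np.argwhere(m).mean(axis=0)
            jitter = rng.integers(-4, 5, size=2)
            c0 = int(com[0] - th / 2 + jitter[0])
            c1 = int(com[1] - tw / 2 + jitter[1])
        else:
            # tumor-free slices: centre on physiological uptake when present,
            # so normal hotspots are actually represented in the windows
            hot = np.argwhere(p >= 2.5) if not positive else np.empty((0, 2))
            if hot.shape[0]:
                cz = hot[rng.integers(0, hot.shape[0])]
                jitter = rng.integers(-8, 9, size=2)
                c0 = int(cz[0] - th / 2 + jitter[0])
                c1 = int(cz[1] - tw / 2 + jitter[1])
            else:
                c0 = int(rng.integers(0, h - th + 1))
                c1 = int(rng.integers(0, w - tw + 1))
        c0 = min(max(c0, 0), h - th)
        c1 = min(max(c1, 0), w - tw)
        sl = (slice(c0, c0 + th), slice(c1, c1 + tw))
        p, c, m = p[sl], c[sl], m[sl]
        if (th, tw) != crop_hw:   # slice smaller than the window: zero-pad
            pad = ((0, crop_hw[0] - th), (0, crop_hw[1] - tw))
            p, c, m = (np.pad(arr, pad) for arr in (p, c, m))
        return p, c, m

    samples = [window(*s, True) for s in pos] + [window(*s, False) for s in keep_neg]
    x = np.stack([np.stack([p, c]) for p, c, _ in samples]).astype(np.float32)
    y = np.stack([m[None] for _, _, m in samples]).astype(np.float32)
    return SliceDataset(x, y, n_positive=len(pos), n_negative=len(keep_neg))


# ---------------------------------------------------------------------------
# 3D patch dataset
# ---------------------------------------------------------------------------

@dataclass
class PatchDataset:
    x: np.ndarray   # (N, 2, E, E, E) float32
    y: np.ndarray   # (N, 1, E, E, E) float32
    edge: int

    def __len__(self) -> int:
        return self.x.shape[0]


def _gather_cube(vol: np.ndarray, start: tuple[int, int, int], edge: int) -> np.ndarray:
    """Extract an ``edge``-cube starting at (possibly negative) ``start``; zero fill."""
    out = np.zeros((edge,) * 3, dtype=vol.dtype)
    src, dst = [], []
    for s, n in zip(start, vol.shape):
        lo = max(s, 0)
        hi = min(s + edge, n)
        if lo >= hi:
            return out
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
    out[tuple(dst)] = vol[tuple(src)]
    return out


def build_patch_dataset(studies: list[PetCtStudy], masks: list[np.ndarray],
                        edge: int = 32, n_negative_per_study: int | None = None,
                        seed: int = 0,
                        hard_negative_fraction: float = 0.5,
                        hard_negative_suv: float = 2.5) -> PatchDataset:
    """Component-driven positive patches plus negative patches.

    One cube is centred on each 26-connected truth component; an equal
    number of tumor-free cubes per study is added (override with
    ``n_negative_per_study``).  At inference the refiner only ever sees
    cubes centred on *detected* components — which include physiological
    hotspots the 2D stage mistakes for tumors — so a
    ``hard_negative_fraction`` of the negatives is centred on random
    high-uptake (>= ``hard_negative_suv``) tumor-free voxels instead of
    uniformly random positions.
    """
    from scipy import ndimage as ndi

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for study, mask in zip(studies, masks):
        pet, ct = _normalise_channels(study.pet.data, study.ct.data)
        mask = np.asarray(mask)
        labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), bool))
        n_pos = 0
        for lab in range(1, n + 1):
            com = np.argwhere(labels == lab).mean(axis=0)
            start = tuple(int(round(c - edge / 2)) for c in com)
            xs.append(np.stack([_gather_cube(pet, start, edge),
                                _gather_cube(ct, start, edge)]))
            ys.append(_gather_cube(mask.astype(np.float32), start, edge)[None])
            n_pos += 1
        n_neg = n_pos if n_negative_per_study is None else n_negative_per_study
        n_hard = int(round(hard_negative_fraction * n_neg))
        hot = np.argwhere((study.pet.data >= hard_negative_suv) & (mask == 0))
        for j in range(n_neg):
            start = None
            if j < n_hard and hot.shape[0]:
                for _try in range(100):
                    com = hot[rng.integers(0, hot.shape[0])]
                    cand = tuple(int(round(c - edge / 2)) for c in com)
                    cube = _gather_cube(mask.astype(np.float32), cand, edge)
                    if not cube.any():
                        start = cand
                        break
            if start is None:
                for _try in range(100):
                    cand = tuple(int(rng.integers(0, max(s - edge, 1)))
                                 for s in mask.shape)
                    cube = _gather_cube(mask.astype(np.float32), cand, edge)
                    if not cube.any():
                        start = cand
                        break
            if start is None:
                continue
            xs.append(np.stack([_gather_cube(pet, start, edge),
                                _gather_cube(ct, start, edge)]))
            ys.append(np.zeros((1, edge, edge, edge), np.float32))
    return PatchDataset(np.stack(xs).astype(np.float32),
                        np.stack(ys).astype(np.float32), edge)


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [{"epoch": e, "loss": l, "lr": r}
                for e, l, r in zip(self.epochs, self.loss, self.lr)]


def _run_epochs(model, x, y, loss_fn, opt, plan, seed: int,
                lr_fn) -> TrainHistory:
    rng = np.random.default_rng(seed)
    history = TrainHistory()
    n = x.shape[0]
    bs = plan.batch_size
    for epoch in range(plan.epochs):
        opt.lr = lr_fn(epoch)
        order = rng.permutation(n)
        total, batches = 0.0, 0
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            pred = model(Tensor(x[idx]))
            report = loss_fn(pred, y[idx])
            if not np.isfinite(report.total):
                raise DivergenceError(
                    f"non-finite loss {report.total} at epoch {epoch}")
            opt.zero_grad()
            report.total_tensor.backward()
            opt.step()
            total += report.total
            batches += 1
        history.epochs.append(epoch)
        history.loss.append(total / max(batches, 1))
        history.lr.append(opt.lr)
    return history


def train_2d(dataset: SliceDataset, model: UNet2D,
             plan: TrainPlan2D = TrainPlan2D(), seed: int = 0,
             checkpoint_path: str | Path | None = None,
             lr_override: float | None = None) -> TrainHistory:
    """Train the 2D network with RMSProp under the 2D schedule."""
    model.train()
    opt = RMSProp(model.parameters(), lr=plan.base_lr)
    lr_fn = (lambda e: lr_override) if lr_override else (lambda e: lr_at(plan, e))
    history = _run_epochs(model, dataset.x, dataset.y, loss_2d, opt, plan,
                          seed, lr_fn)
    model.eval()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return history


def train_3d(dataset: PatchDataset, model: VNet3D,
             plan: TrainPlan3D = TrainPlan3D(), seed: int = 0,
             checkpoint_path: str | Path | None = None,
             lr_override: float | None = None) -> TrainHistory:
    """Train a region V-Net with Adam under the 3D schedule."""
    model.train()
    opt = Adam(model.parameters(), lr=plan.base_lr)
    lr_fn = (lambda e: lr_override) if lr_override else (lambda e: lr_at(plan, e))
    history = _run_epochs(model, dataset.x, dataset.y, loss_3d, opt, plan,
                          seed, lr_fn)
    model.eval()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return history


def _slice_overlap_counts(model: UNet2D, study: PetCtStudy, mask: np.ndarray,
                          plane: str, threshold: float,
                          pad_multiple: int) -> tuple[int, int, int]:
    """(intersection, |pred|, |truth|) of slice-wise predictions on one plane."""
    pet, ct = _normalise_channels(study.pet.data, study.ct.data)
    pet_s, ct_s = reformat(pet, plane), reformat(ct, plane)
    batch = np.stack([np.stack([p, c]) for p, c in zip(pet_s, ct_s)])
    h, w = batch.shape[2:]
    pad_multiple = max(pad_multiple, getattr(model, "pad_multiple", 1))
    ph = (-h) % pad_multiple
    pw = (-w) % pad_multiple
    batch = np.pad(batch, ((0, 0), (0, 0), (0, ph), (0, pw)))
    preds = []
    for i in range(0, batch.shape[0], 8):
        preds.append(model.predict(batch[i:i + 8]))
    prob = np.concatenate(preds)[:, 0, :h, :w]
    from .imaging_io import restack
    pred = restack(list(prob), plane) >= threshold
    truth = np.asarray(mask) > 0
    return int((pred & truth).sum()), int(pred.sum()), int(truth.sum())


def heldout_slice_dice(model: UNet2D, studies, masks,
                       planes: tuple[str, ...] = ("axial", "sagittal"),
                       threshold: float = 0.5, pad_multiple: int = 4) -> float:
    """Pooled Dice of slice-wise predictions over held-out studies.

    Each plane's slices are predicted independently (no orientation
    averaging) and the overlap counts are pooled across planes and studies.
    """
    if isinstance(studies, PetCtStudy):
        studies, masks = [studies], [masks]
    inter = psum = tsum = 0
    for study, mask in zip(studies, masks):
        for plane in planes:
            i, p, t = _slice_overlap_counts(model, study, mask, plane,
                                            threshold, pad_multiple)
            inter += i
            psum += p
            tsum += t
    if psum + tsum == 0:
        return 1.0
    return 2.0 * inter / (psum + tsum)
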
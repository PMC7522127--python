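"""Shared fixtures: seeded phantoms, truth-echo stub models, trained tiny nets."""

from __future__ import annotations

import numpy as np
import pytest

from petseg.imaging_io import reformat
from petseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom with 3 tumors (seed 42)."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free phantom with fixed tumor uptake for exact-value checks."""
    spec = PhantomSpec(seed=7, noise_suv_sigma=0.0, noise_hu_sigma=0.0,
                       tumor_suv_range=(5.0, 5.0))
    return generate_phantom(spec)


class TruthEcho2D:
    """Oracle 2D model: streams the ground-truth mask back as probabilities.

    ``predict_2d`` enumerates orientations in config order and slices in
    index order, so a cursor over the same sequence reproduces the truth
    exactly (padded to whatever shape the batch carries).
    """

    def __init__(self, truth_mask: np.ndarray, orientations):
        self._slices = []
        for plane in orientations:
            self._slices.extend(reformat(truth_mask.astype(np.float64), plane))
        self._cursor = 0

    def predict(self, batch: np.ndarray) -> np.ndarray:
        n, _, h, w = batch.shape
        out = np.zeros((n, 1, h, w))
        for i in range(n):
            sl = self._slices[self._cursor]
            out[i, 0, :sl.shape[0], :sl.shape[1]] = sl
            self._cursor += 1
        return out


class TruthEcho3D:
    """Oracle 3D model: returns the ground-truth cube at the patch location."""

    def __init__(self, truth_mask: np.ndarray):
        self.truth = truth_mask.astype(np.float64)

    def predict_patch(self, patch) -> np.ndarray:
        out = np.zeros((patch.edge,) * 3)
        src, dst = [], []
        for s, n in zip(patch.start, self.truth.shape):
            lo, hi = max(s, 0), min(s + patch.edge, n)
            if lo >= hi:
                return out
            src.append(slice(lo, hi))
            dst.append(slice(lo - s, hi - s))
        out[tuple(dst)] = self.truth[tuple(src)]
        return out


class ConstantModel:
    """Stub emitting a constant probability everywhere."""

    def __init__(self, value: float):
        self.value = value

    def predict(self, batch: np.ndarray) -> np.ndarray:
        n, _, *spatial = batch.shape
        return np.full((n, 1, *spatial), self.value)


@pytest.fixture(scope="session")
def tiny_models():
    """Tiny 2D U-Net + shared V-Net trained once per test session."""
    from petseg.presets import train_tiny_models

    return train_tiny_models(seed=0)
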
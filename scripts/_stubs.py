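"""Oracle stub models for the identity-cascade check (mirror of the test stubs)."""

from __future__ import annotations

import numpy as np

from petseg.imaging_io import reformat


class TruthEcho2D:
    """Streams ground-truth mask slices back as probabilities in call order."""

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
    """Returns the ground-truth cube at each patch location."""

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
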
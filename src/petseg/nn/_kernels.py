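"""Optional numba-accelerated kernels for the depthwise convolutions.

The dilated depthwise convolutions dominate CPU time in the 2D network:
they are bandwidth-bound, and the pure-numpy implementation makes one full
array pass per kernel tap.  These fused single-pass kernels are used when
numba is importable; :mod:`petseg.nn.tensor` falls back to numpy otherwise
(results are identical to float rounding).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


if HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=True)
    def dw2d_forward(xp, w2, kh, kw, dil, out):
        n, c, oh, ow = out.shape
        for b in range(n):
            for ch in range(c):
                for i in range(oh):
                    for j in range(ow):
                        acc = 0.0
                        for a in range(kh):
                            ia = i + a * dil
                            for bb in range(kw):
                                acc += xp[b, ch, ia, j + bb * dil] * w2[ch, a * kw + bb]
                        out[b, ch, i, j] = acc

    @numba.njit(cache=False, fastmath=True)
    def dw2d_backward(g, xp, w2, kh, kw, dil, gxp, gw, need_x, need_w):
        n, c, oh, ow = g.shape
        for b in range(n):
            for ch in range(c):
                for i in range(oh):
                    for j in range(ow):
                        gv = g[b, ch, i, j]
                        for a in range(kh):
                            ia = i + a * dil
                            for bb in range(kw):
                                t = a * kw + bb
                                jb = j + bb * dil
                                if need_w:
                                    gw[ch, t] += gv * xp[b, ch, ia, jb]
                                if need_x:
                                    gxp[b, ch, ia, jb] += gv * w2[ch, t]
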
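"""Compiled inner loops for stride-1 convolution on large feature maps.

The generic column-matrix path in :mod:`wheatcount.nn` is memory-bound on
big spatial grids; these numba kernels run the same arithmetic in place.
They are used only when numba imports cleanly and the grid is large enough
to amortise the call; `wheatcount.nn.conv2d` falls back to the column path
otherwise, and the test suite asserts both paths agree.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(fn):
            return fn
        return deco

# use the compiled path only when the output grid has at least this many
# cells; below it, loop overhead exceeds the saved copies
MIN_GRID = 1024


@njit(fastmath=True, cache=True)
def conv_forward(xp, w, b, out):  # pragma: no cover - exercised via nn tests
    """out[n,o] = b[o] + sum_{c,a,t} w[o,c,a,t] * xp[n,c,a:a+H,t:t+W]."""
    n_im, c_in, hp, wp = xp.shape
    o_out = w.shape[0]
    k = w.shape[2]
    h = hp - k + 1
    wd = wp - k + 1
    for n in range(n_im):
        for o in range(o_out):
            acc = np.full((h, wd), b[o], np.float32)
            for c in range(c_in):
                for a in range(k):
                    for t in range(k):
                        wv = w[o, c, a, t]
                        for i in range(h):
                            for j in range(wd):
                                acc[i, j] += wv * xp[n, c, i + a, j + t]
            out[n, o] = acc


@njit(fastmath=True, cache=True)
def conv_grad_weight(xp, g, gw):  # pragma: no cover - exercised via nn tests
    """gw[o,c,a,t] += sum_{n,i,j} g[n,o,i,j] * xp[n,c,i+a,j+t]."""
    n_im, c_in = xp.shape[0], xp.shape[1]
    h, wd = g.shape[2], g.shape[3]
    o_out = g.shape[1]
    k = gw.shape[2]
    for n in range(n_im):
        for o in range(o_out):
            for c in range(c_in):
                for a in range(k):
                    for t in range(k):
                        s = np.float32(0.0)
                        for i in range(h):
                            for j in range(wd):
                                s += g[n, o, i, j] * xp[n, c, i + a, j + t]
                        gw[o, c, a, t] += s
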
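"""Central-difference derivatives used for convergence checks and
observed-information standard errors."""

from __future__ import annotations

import numpy as np


def central_gradient(f, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def central_hessian(f, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Symmetric central-difference Hessian, step rel_step*max(1,|x_i|)."""
    x = np.asarray(x, dtype=float)
    k = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        xp = x.copy()
        xm = x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            xpp = x.copy()
            xpm = x.copy()
            xmp = x.copy()
            xmm = x.copy()
            xpp[[i, j]] += [h[i], h[j]]
            xpm[i] += h[i]
            xpm[j] -= h[j]
            xmp[i] -= h[i]
            xmp[j] += h[j]
            xmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4.0 * h[i] * h[j]
            )
    return H
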
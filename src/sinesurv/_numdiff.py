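"""Small central-difference helpers used by the fitter and the HMC sampler."""

from __future__ import annotations

import numpy as np


def approx_gradient(f, x, h=1e-5):
    """Central-difference gradient of a scalar function."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2.0 * step)
    return g


def approx_hessian(f, x, h=1e-4):
    """Central-difference Hessian of a scalar function (symmetrized)."""
    x = np.asarray(x, dtype=float)
    d = x.size
    H = np.empty((d, d))
    steps = np.array([h * max(1.0, abs(xi)) for xi in x])
    f0 = f(x)
    for i in range(d):
        xp = x.copy()
        xm = x.copy()
        xp[i] += steps[i]
        xm[i] -= steps[i]
        H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / steps[i] ** 2
        for j in range(i + 1, d):
            xpp = x.copy()
            xpm = x.copy()
            xmp = x.copy()
            xmm = x.copy()
            xpp[[i, j]] += steps[[i, j]]
            xmm[[i, j]] -= steps[[i, j]]
            xpm[i] += steps[i]
            xpm[j] -= steps[j]
            xmp[i] -= steps[i]
            xmp[j] += steps[j]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                4.0 * steps[i] * steps[j]
            )
    return H
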
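"""Numba inner loops for the single-site Gibbs updates of marker effects.

These are the only performance-critical scalar loops in the samplers; all
other blocks (intercept, Gaussian-process effects, variance components)
are vectorised numpy in :mod:`forestgs.models`.  Numba's own global
random state is used inside the jitted code and must be seeded through
:func:`seed_numba` once per chain.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def seed_numba(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def update_marker_effects(Xt: np.ndarray, xtx: np.ndarray, a: np.ndarray,
                          var_a: np.ndarray, e: np.ndarray,
                          sigma_e2: float, order: np.ndarray) -> None:
    """One sweep of normal full-conditional draws for marker effects.

    ``Xt`` is the (p, n) transposed design so each marker's column is
    contiguous; ``e`` is the current residual (updated in place), and
    ``order`` the visiting permutation for this sweep.
    """
    n = Xt.shape[1]
    for k in range(order.shape[0]):
        i = order[k]
        ai_old = a[i]
        rhs = xtx[i] * ai_old
        for j in range(n):
            rhs += Xt[i, j] * e[j]
        c = xtx[i] + sigma_e2 / var_a[i]
        ai = rhs / c + np.random.normal() * np.sqrt(sigma_e2 / c)
        diff = ai_old - ai
        for j in range(n):
            e[j] += diff * Xt[i, j]
        a[i] = ai


@njit(cache=True)
def update_marker_variances(a: np.ndarray, var_a: np.ndarray,
                            nu: float, scale: float) -> None:
    """Scaled-inverse-chi-square full conditionals for per-marker variances.

    sigma_i^2 | a_i ~ (nu * S + a_i^2) / chisq(nu + 1).
    """
    for i in range(a.shape[0]):
        chi2 = 2.0 * np.random.gamma(0.5 * (nu + 1.0), 1.0)
        var_a[i] = (nu * scale + a[i] * a[i]) / chi2
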
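"""SMO solver for the soft-margin linear SVM dual.

Solves  min_a 0.5 a'Qa - e'a  s.t.  y'a = 0, 0 <= a <= C,  with
Q_ij = y_i y_j K_ij and K the (precomputed) Gram matrix.  Working-set
selection is second order (maximal-violating pair with best quadratic gain),
the same strategy LIBSVM uses, which converges in a small multiple of n
iterations on the problem sizes seen here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TAU = 1e-12


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):
    """Return (alpha, n_iter, gap) for the dual with Gram matrix K."""
    n = K.shape[0]
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of the dual objective
    it = 0
    gap = np.inf
    while it < max_iter:
        # i: most violating in the "up" set
        Gmax = -np.inf
        i = -1
        for t in range(n):
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                v = -y[t] * G[t]
                if v > Gmax:
                    Gmax = v
                    i = t
        # j: best second-order gain in the "low" set; Gmin for the stop rule
        Gmin = np.inf
        j = -1
        best_gain = -np.inf
        for t in range(n):
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                v = -y[t] * G[t]
                if v < Gmin:
                    Gmin = v
                if i >= 0 and v < Gmax - TAU:
                    b_it = Gmax - v
                    # curvature along the pair direction; label factors cancel
                    eta = K[i, i] + K[t, t] - 2.0 * K[i, t]
                    if eta <= TAU:
                        eta = TAU
                    gain = b_it * b_it / eta
                    if gain > best_gain:
                        best_gain = gain
                        j = t
        gap = Gmax - Gmin
        if i == -1 or j == -1 or gap < tol:
            break
        # two-variable update along the feasible direction
        yi = y[i]
        yj = y[j]
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta <= TAU:
            eta = TAU
        s = (Gmax - (-yj * G[j])) / eta
        # box limits: alpha_i + yi*s in [0, C]; alpha_j - yj*s in [0, C]
        if yi > 0:
            s_max_i = C - alpha[i]
        else:
            s_max_i = alpha[i]
        if yj > 0:
            s_max_j = alpha[j]
        else:
            s_max_j = C - alpha[j]
        if s > s_max_i:
            s = s_max_i
        if s > s_max_j:
            s = s_max_j
        if s <= 0.0:
            break  # numerically stuck; gap is already tiny
        alpha[i] += yi * s
        alpha[j] -= yj * s
        # dG_t = Q[t,i]*dalpha_i + Q[t,j]*dalpha_j = y_t s (K[t,i] - K[t,j])
        for t in range(n):
            G[t] += y[t] * s * (K[t, i] - K[t, j])
        it += 1
    return alpha, it, gap
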
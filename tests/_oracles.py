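"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the SVM oracle solves
the dual quadratic program with a generic constrained optimizer, and the
cluster oracle is a breadth-first flood fill on explicit neighbor offsets.
"""

import numpy as np
from scipy.optimize import minimize


def svm_primal_objective(X, y, w, b, C):
    slack = np.maximum(0.0, 1.0 - y * (X @ w + b))
    return 0.5 * float(w @ w) + C * float(slack.sum())


def qp_dual_svm(X, y, C):
    """Solve the soft-margin SVM dual with a generic QP/NLP solver (SLSQP).

    min 0.5 a'Qa - e'a  s.t.  y'a = 0, 0 <= a <= C, Q = (yy') * (XX').
    Returns (w, b, primal_objective).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def f(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}
    res = minimize(
        f,
        np.zeros(n),
        jac=jac,
        bounds=[(0.0, C)] * n,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    a = np.clip(res.x, 0.0, C)
    w = X.T @ (a * y)
    scores = X @ w
    eps = 1e-6 * max(1.0, C)
    free = (a > eps) & (a < C - eps)
    if np.any(free):
        b = float(np.mean(y[free] - scores[free]))
    else:
        lo, hi = -np.inf, np.inf
        for i in range(n):
            bound = y[i] - scores[i]
            at_c = a[i] >= C - eps
            if (y[i] > 0) != at_c:
                lo = max(lo, bound)
            else:
                hi = min(hi, bound)
        if np.isfinite(lo) and np.isfinite(hi):
            b = 0.5 * (lo + hi)
        else:
            b = lo if np.isfinite(lo) else (hi if np.isfinite(hi) else 0.0)
    return w, b, svm_primal_objective(X, y, w, b, C)


_OFFSETS = {
    6: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) == 1
    ],
    18: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if 1 <= abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    26: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
}


def flood_fill_components(coord_set, connectivity=6):
    """Connected components of a set of (x, y, z) tuples by BFS."""
    remaining = set(map(tuple, coord_set))
    offsets = _OFFSETS[connectivity]
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(frozenset(comp))
    return components
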
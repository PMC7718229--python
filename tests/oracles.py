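"""Independent oracles used by the tests.

Everything here is deliberately written from first principles, separately
from the package's own code paths, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def prony_poles(y: np.ndarray, k: int) -> np.ndarray:
    """Classical Prony estimate of the k poles of y_n = sum r_i z_i^n.

    Linear prediction: y[n] = sum_{j=1..k} c_j y[n-j]; the poles are the
    roots of the characteristic polynomial. Exact for noiseless sums of
    k complex exponentials.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    rows = n - k
    a = np.empty((rows, k))
    for i in range(rows):
        a[i] = y[i : i + k][::-1]
    b = y[k:]
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    poly = np.concatenate(([1.0], -coef))
    return np.roots(poly)


def varpro_refine(y, t, periods, amps, phases, decays, dc):
    """Nonlinear least-squares refinement of damped-cosine parameters,
    initialised at the supplied values (scipy Levenberg-Marquardt)."""
    from scipy.optimize import least_squares

    k = len(periods)

    def unpack(x):
        d = x[0]
        out = []
        for i in range(k):
            T, A, ph, b = x[1 + 4 * i : 5 + 4 * i]
            out.append((T, A, ph, b))
        return d, out

    def resid(x):
        d, comps = unpack(x)
        model = np.full_like(t, d)
        for T, A, ph, b in comps:
            model = model + A * np.exp(b * t) * np.cos(2 * np.pi * (t - ph) / T)
        return model - y

    x0 = [dc]
    for i in range(k):
        x0 += [periods[i], amps[i], phases[i], decays[i]]
    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
    return unpack(sol.x)


def umbrella_stat_direct(groups: list[np.ndarray], p: int) -> float:
    """Mack-Wolfe umbrella statistic with peak at 1-indexed group p,
    computed by direct double loops over observations."""
    m = len(groups)
    s = 0.0
    for i in range(m):
        for j in range(m):
            if i >= j:
                continue
            lo_up = (i + 1, j + 1)  # 1-indexed
            for x in groups[i]:
                for y in groups[j]:
                    if lo_up[1] <= p:  # rising pair i<j<=p counts x<y
                        s += (x < y) + 0.5 * (x == y)
                    elif lo_up[0] >= p:  # falling pair p<=i<j counts x>y
                        s += (x > y) + 0.5 * (x == y)
    return s


def umbrella_exact_enumeration(groups: list[np.ndarray], n_positions: int) -> float:
    """Full-permutation p-value of the umbrella test: min over peak
    positions of P(S*_p >= S_p), Bonferroni-multiplied, capped at 1."""
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    m = len(groups)
    bounds = np.cumsum([0] + sizes)
    observed = [umbrella_stat_direct(groups, p) for p in range(1, m)]
    counts = np.zeros(m - 1)
    total = 0
    for perm in itertools.permutations(pooled.tolist()):
        gs = [np.array(perm[bounds[i] : bounds[i + 1]]) for i in range(m)]
        for p in range(1, m):
            if umbrella_stat_direct(gs, p) >= observed[p - 1] - 1e-12:
                counts[p - 1] += 1
        total += 1
    return float(min(1.0, counts.min() / total * n_positions))


def bh_stepup_direct(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the textbook step-up definition."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * n / rank)
        q[idx] = val
        prev = val
    return q
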
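"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by a deliberately different route
(exhaustive enumeration, dense search, closed form) so the tests never compare
the implementation against itself.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import minimize_scalar


def grid_search_cosinor_sse(times, values, period_h=24.0):
    """Best least-squares SSE of M + A*cos(2*pi*(t-phi)/T) by 1-D search on phi.

    For each candidate acrophase the (M, A) pair is the exact linear solution,
    so the search is only over phi: a dense grid refined by bounded scalar
    minimization.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    w = 2.0 * np.pi / period_h

    def sse(phi):
        X = np.column_stack([np.ones_like(t), np.cos(w * (t - phi))])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    grid = np.arange(0.0, period_h, 0.01)
    best_phi = grid[int(np.argmin([sse(p) for p in grid]))]
    res = minimize_scalar(sse, bounds=(best_phi - 0.02, best_phi + 0.02),
                          method="bounded", options={"xatol": 1e-10})
    return min(float(res.fun), sse(best_phi))


def kendall_tau_b(x, y):
    """O(n^2) pairwise Kendall tau-b with midrank tie handling."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    num = 0
    tx = ty = 0
    n_pairs = 0
    for i, j in combinations(range(x.size), 2):
        n_pairs += 1
        sx = np.sign(x[i] - x[j])
        sy = np.sign(y[i] - y[j])
        num += sx * sy
        tx += sx == 0
        ty += sy == 0
    den = np.sqrt((n_pairs - tx) * (n_pairs - ty))
    return num / den if den > 0 else 0.0


def bh_step_up(p):
    """Independent Benjamini-Hochberg step-up (sort-descending cummin)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)[::-1]            # descending
    adj = np.empty(m)
    running = 1.0
    for pos, idx in enumerate(order):
        rank = m - pos                     # rank of this p among ascending
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def hypergeom_upper_tail(k, N, K, n):
    """Exact P(X >= k) for X ~ Hypergeom(N, K, n) via rational enumeration."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def mann_whitney_exact_p(a, b):
    """Two-sided exact permutation p for the Mann-Whitney U statistic."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = np.array(a + b)
    na = len(a)
    ranks = _midranks(pooled)
    obs = ranks[:na].sum()
    mean = na * (len(pooled) + 1) / 2.0
    count = hits = 0
    for idx in combinations(range(len(pooled)), na):
        s = ranks[list(idx)].sum()
        count += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / count


def wilcoxon_exact_p(a, b):
    """Two-sided exact sign-flip p for the Wilcoxon signed-rank statistic."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = _midranks(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    hits = 0
    for signs in range(2 ** n):
        bits = np.array([(signs >> i) & 1 for i in range(n)], bool)
        w = ranks[bits].sum()
        if abs(w - mean) >= abs(w_plus - mean) - 1e-12:
            hits += 1
    return hits / 2 ** n


def _midranks(x):
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size)
    i = 0
    sx = x[order]
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def circular_mae_h(est, truth, period=24.0):
    """Mean absolute circular difference in hours."""
    d = (np.asarray(est, float) - np.asarray(truth, float) + period / 2) % period \
        - period / 2
    return float(np.mean(np.abs(d)))
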
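"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration, grid refinement — and shares no code with the implementation
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- graphs
def degree_bf(A):
    n = len(A)
    return [sum(1 for j in range(n) if A[i][j]) for i in range(n)]


def clustering_bf(A):
    n = len(A)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        t = sum(1 for a, b in itertools.combinations(nbrs, 2) if A[a][b])
        out.append(2.0 * t / (k * (k - 1)))
    return out


def floyd_warshall_bf(A):
    n = len(A)
    D = [[0 if i == j else (1 if A[i][j] else math.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return D


def global_efficiency_bf(A):
    D = floyd_warshall_bf(A)
    n = len(A)
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(D[i][j]):
                s += 1.0 / D[i][j]
    return s / (n * (n - 1))


def nodal_efficiency_bf(A):
    D = floyd_warshall_bf(A)
    n = len(A)
    return [
        sum(1.0 / D[i][j] for j in range(n) if j != i and math.isfinite(D[i][j])) / (n - 1)
        for i in range(n)
    ]


def local_efficiency_bf(A):
    n = len(A)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[A[a][b] for b in nbrs] for a in nbrs]
        out.append(global_efficiency_bf(sub))
    return out


def assortativity_bf(A):
    n = len(A)
    k = degree_bf(A)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if A[i][j]:
                xs.append(k[i])
                ys.append(k[j])
    if not xs:
        raise ValueError("no edges")
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    sy = math.sqrt(sum((y - my) ** 2 for y in ys))
    if sx == 0 or sy == 0:
        return math.nan
    return sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / (sx * sy)


def hierarchy_bf(A):
    k = degree_bf(A)
    C = clustering_bf(A)
    pts = [(math.log(ki), math.log(ci)) for ki, ci in zip(k, C) if ki >= 2 and ci > 0]
    if len(pts) < 2:
        return math.nan
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    mx, my = sum(xs) / len(xs), sum(ys) / len(ys)
    sxx = sum((x - mx) ** 2 for x in xs)
    if sxx == 0:
        return math.nan
    slope = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / sxx
    return -slope


def synchronization_bf(A):
    n = len(A)
    k = degree_bf(A)
    L = [[(k[i] if i == j else 0) - A[i][j] for j in range(n)] for i in range(n)]
    w = sorted(np.real(np.linalg.eigvals(np.array(L, dtype=float))))
    lam_max = w[-1]
    if lam_max <= 1e-12:
        return 0.0
    lam2 = w[1]
    if lam2 < 1e-8 * max(1.0, lam_max):
        return 0.0
    return lam2 / lam_max


def participation_bf(A, part):
    n = len(A)
    k = degree_bf(A)
    out = []
    for i in range(n):
        if k[i] == 0:
            out.append(0.0)
            continue
        s = 0.0
        for m in set(part):
            k_im = sum(1 for j in range(n) if A[i][j] and part[j] == m)
            s += (k_im / k[i]) ** 2
        out.append(1.0 - s)
    return out


def modularity_bf(A, part):
    n = len(A)
    k = degree_bf(A)
    two_m = sum(k)
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if part[i] == part[j]:
                q += A[i][j] - k[i] * k[j] / two_m
    return q / two_m


# --------------------------------------------------- graphical lasso, 2x2
def glasso_2x2_bf(S, lam, n_refine=12):
    """Grid-refinement maximizer of the penalized log-likelihood over 2x2
    SPD precisions: log det T - tr(S T) - 2 lam |t12|."""

    def obj(a, c, b):
        det = a * c - b * b
        if det <= 0 or a <= 0 or c <= 0:
            return -np.inf
        tr = S[0][0] * a + S[1][1] * c + 2 * S[0][1] * b
        return math.log(det) - tr - 2 * lam * abs(b)

    lo = np.array([0.05, 0.05, -5.0])
    hi = np.array([20.0, 20.0, 5.0])
    best = None
    for _ in range(n_refine):
        grids = [np.linspace(lo[d], hi[d], 25) for d in range(3)]
        vals = [(obj(a, c, b), a, c, b) for a in grids[0] for c in grids[1] for b in grids[2]]
        best = max(vals, key=lambda t: t[0])
        center = np.array(best[1:])
        width = (hi - lo) * 0.12
        lo, hi = center - width, center + width
        lo[0], lo[1] = max(lo[0], 1e-4), max(lo[1], 1e-4)
    _, a, c, b = best
    return np.array([[a, b], [b, c]])


# ----------------------------------------------------------------- stats
def bh_stepup_bf(pvals, q):
    """Explicit sort/scan Benjamini-Hochberg: (reject, adjusted)."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    kmax = 0
    for r in range(1, m + 1):
        if p[order[r - 1]] <= q * r / m:
            kmax = r
    reject = [False] * m
    for r in range(kmax):
        reject[order[r]] = True
    return reject, adj


def trapezoid_bf(values, xs):
    s = 0.0
    for i in range(len(xs) - 1):
        s += 0.5 * (values[i] + values[i + 1]) * (xs[i + 1] - xs[i])
    return s / (xs[-1] - xs[0])
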
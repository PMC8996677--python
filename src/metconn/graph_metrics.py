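"""Graph-theory metrics on binary undirected brain networks.

All functions operate on a dense binary adjacency matrix ``A`` (symmetric,
zero diagonal, entries 0/1).  Metrics follow the standard binary-network
definitions used throughout the PET/fMRI connectome literature: degree,
clustering, shortest paths, global/local/nodal efficiency, degree
assortativity, hierarchy (the exponent of C(k) ~ k^-beta), Laplacian
synchronizability, and the participation coefficient over a module
partition.  Quantities that are undefined for a given graph (assortativity
of a regular graph, hierarchy without degree variation) are returned as
``nan`` rather than silently coerced to 0.

Metrics across a density sweep are summarized by a normalized trapezoidal
area under the curve (:func:`metric_auc`), the standard way to avoid
committing to a single arbitrary sparsity level.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path


def _validate_adjacency(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal (no self-loops)")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency must be binary (0/1)")
    return A.astype(float)


def degree(A: np.ndarray) -> np.ndarray:
    """Nodal degree centrality: number of edges incident to each node."""
    A = _validate_adjacency(A)
    return A.sum(axis=1).astype(int)


def clustering(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficient and its network mean.

    C_i = 2 * triangles_i / (k_i * (k_i - 1)); nodes with degree < 2 get 0.
    """
    A = _validate_adjacency(A)
    k = A.sum(axis=1)
    tri = np.diag(A @ A @ A) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, tri / denom, 0.0)
    return C, float(C.mean())


def shortest_paths(A: np.ndarray) -> np.ndarray:
    """All-pairs hop distances; unreachable pairs are ``inf``."""
    A = _validate_adjacency(A)
    return _csgraph_shortest_path(A, method="D", unweighted=True, directed=False)


def characteristic_path_length(A: np.ndarray) -> tuple[float, int]:
    """Mean hop distance over reachable ordered pairs.

    Returns (L, n_unreachable_pairs).  Disconnection is common in sparse
    thresholded connectomes, so unreachable pairs are excluded from the
    mean and their count is reported alongside.
    """
    D = shortest_paths(A)
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    n_unreachable = int((off & ~np.isfinite(D)).sum())
    if finite.sum() == 0:
        return float("nan"), n_unreachable
    return float(D[finite].mean()), n_unreachable


def nodal_path_length(A: np.ndarray) -> np.ndarray:
    """Per-node mean hop distance to its reachable peers (nan if isolated)."""
    D = shortest_paths(A)
    n = D.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        d = np.delete(D[i], i)
        d = d[np.isfinite(d)]
        if d.size:
            out[i] = d.mean()
    return out


def global_efficiency(A: np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    A = _validate_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires >= 2 nodes")
    D = shortest_paths(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(A: np.ndarray) -> np.ndarray:
    """E_nod(i) = mean over j != i of 1/d(i, j)."""
    A = _validate_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("nodal efficiency requires >= 2 nodes")
    D = shortest_paths(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its network mean.

    E_loc(i) is the global efficiency of the subgraph induced by the
    neighbors of i (0 when i has fewer than 2 neighbors).
    """
    A = _validate_adjacency(A)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if nbrs.size < 2:
            continue
        out[i] = global_efficiency(A[np.ix_(nbrs, nbrs)])
    return out, float(out.mean())


def assortativity(A: np.ndarray) -> float:
    """Newman degree assortativity: Pearson r of degrees at edge endpoints.

    Computed over the doubled edge list (both orientations).  Returns nan
    when the endpoint degrees have zero variance (e.g. regular graphs).
    """
    A = _validate_adjacency(A)
    k = A.sum(axis=1)
    ii, jj = np.nonzero(np.triu(A, 1))
    if ii.size == 0:
        raise ValueError("assortativity requires at least one edge")
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def hierarchy(A: np.ndarray) -> float:
    """Hierarchy exponent beta of the power law C(k) ~ k^-beta.

    Least-squares slope of log C_i on log k_i over eligible nodes
    (k_i >= 2 and C_i > 0), negated.  Returns nan when fewer than two
    eligible nodes or no degree variation among them.  Negative values are
    possible (clustering increasing with degree).
    """
    A = _validate_adjacency(A)
    k = A.sum(axis=1)
    C, _ = clustering(A)
    elig = (k >= 2) & (C > 0)
    if elig.sum() < 2:
        return float("nan")
    x = np.log(k[elig])
    y = np.log(C[elig])
    if np.ptp(x) == 0:
        return float("nan")
    slope = np.polyfit(x, y, 1)[0]
    return float(-slope)


def synchronization(A: np.ndarray) -> float:
    """Synchronizability: lambda_2 / lambda_max of the combinatorial Laplacian.

    0 for disconnected (or edgeless) graphs, 1 for the complete graph.
    """
    A = _validate_adjacency(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("synchronization requires >= 2 nodes")
    L = np.diag(A.sum(axis=1)) - A
    w = np.linalg.eigvalsh(L)
    lam_max = w[-1]
    if lam_max <= 1e-12:  # edgeless
        return 0.0
    lam2 = w[1]
    if lam2 < 1e-10 * max(1.0, lam_max):  # disconnected
        return 0.0
    return float(lam2 / lam_max)


def participation_coefficient(A: np.ndarray, partition: np.ndarray) -> np.ndarray:
    """P_i = 1 - sum_m (k_im / k_i)^2 over modules m; 0 for isolated nodes."""
    A = _validate_adjacency(A)
    partition = np.asarray(partition)
    n = A.shape[0]
    if partition.shape != (n,):
        raise ValueError("partition must assign a module to every node")
    k = A.sum(axis=1)
    mods = np.unique(partition)
    P = np.zeros(n)
    for i in range(n):
        if k[i] == 0:
            continue
        s = 0.0
        for m in mods:
            k_im = A[i, partition == m].sum()
            s += (k_im / k[i]) ** 2
        P[i] = 1.0 - s
    return P


def detect_modules(A: np.ndarray, seed: int = 0) -> np.ndarray:
    """Greedy-modularity module partition (deterministic).

    Returns an integer module id per node; module ids are ordered by the
    lowest node index they contain.  Edgeless graphs yield singletons.
    The seed argument is accepted for interface stability; the greedy
    agglomeration itself is deterministic.
    """
    A = _validate_adjacency(A)
    n = A.shape[0]
    if A.sum() == 0:
        return np.arange(n)
    G = nx.from_numpy_array(A)
    comms = nx.algorithms.community.greedy_modularity_communities(G)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    part = np.empty(n, dtype=int)
    for m, nodes in enumerate(comms):
        part[list(nodes)] = m
    return part


def metric_auc(values, densities) -> float:
    """Trapezoidal area under a metric-vs-density curve, normalized by span.

    A constant metric integrates to itself, so AUC values stay on the
    metric's own scale.
    """
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if values.shape != densities.shape:
        raise ValueError("values and densities must align")
    if densities.size < 2:
        raise ValueError("AUC needs at least two densities")
    span = densities[-1] - densities[0]
    return float(np.trapezoid(values, densities) / span)


@dataclass
class GlobalMetrics:
    """The global network measures reported for group connectomes."""

    assortativity: float
    hierarchy: float
    clustering_coefficient: float
    global_efficiency: float
    local_efficiency: float
    synchronization: float
    characteristic_path_length: float
    n_unreachable_pairs: int

    def as_dict(self) -> dict[str, float]:
        return {
            "assortativity": self.assortativity,
            "hierarchy": self.hierarchy,
            "clustering_coefficient": self.clustering_coefficient,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "synchronization": self.synchronization,
            "characteristic_path_length": self.characteristic_path_length,
        }


@dataclass
class NodalMetrics:
    """Per-node network measures."""

    degree: np.ndarray
    clustering: np.ndarray
    shortest_path_length: np.ndarray
    nodal_efficiency: np.ndarray
    local_efficiency: np.ndarray
    participation_coefficient: np.ndarray


def global_metrics(A: np.ndarray) -> GlobalMetrics:
    """Compute the full global metric panel for one binary network."""
    C, C_mean = clustering(A)
    _, Eloc_mean = local_efficiency(A)
    L, n_unreach = characteristic_path_length(A)
    try:
        r = assortativity(A)
    except ValueError:
        r = float("nan")
    return GlobalMetrics(
        assortativity=r,
        hierarchy=hierarchy(A),
        clustering_coefficient=C_mean,
        global_efficiency=global_efficiency(A),
        local_efficiency=Eloc_mean,
        synchronization=synchronization(A),
        characteristic_path_length=L,
        n_unreachable_pairs=n_unreach,
    )


def nodal_metrics(A: np.ndarray, partition: np.ndarray | None = None) -> NodalMetrics:
    """Compute the per-node metric panel for one binary network.

    If no module partition is supplied one is detected greedily.
    """
    if partition is None:
        partition = detect_modules(A)
    C, _ = clustering(A)
    Eloc, _ = local_efficiency(A)
    return NodalMetrics(
        degree=degree(A),
        clustering=C,
        shortest_path_length=nodal_path_length(A),
        nodal_efficiency=nodal_efficiency(A),
        local_efficiency=Eloc,
        participation_coefficient=participation_coefficient(A, partition),
    )
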
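"""Spatial ICA of subject SUVR images: DMN/SN-like subnetwork discovery.

Subjects are treated as linear mixtures of statistically independent
spatial source maps (voxels are the samples).  The chain is the standard
group-ICA recipe for PET:

1. model-order selection by MDL on the PCA eigenvalue spectrum,
2. PCA whitening to the selected rank,
3. Infomax unmixing — natural-gradient ascent of the entropy of a
   logistic-squashed output, which minimizes mutual information between
   components and favors super-Gaussian (spatially compact) sources,
4. z-scoring of component maps and thresholding at z > 1.96,
5. assignment of components to anatomical template masks by spatial
   correlation.

Infomax is implemented here directly (it is the method under study);
components are ordered by explained variance with signs fixed so each
map's largest-magnitude voxel is positive, making runs reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metconn.io_volumes import SUVRMatrix


@dataclass
class ICAResult:
    n_components: int
    mixing: np.ndarray  # subjects x components
    maps: np.ndarray  # components x voxels
    z_maps: np.ndarray  # components x voxels, zero mean / unit sd per row
    converged: bool
    n_iter: int
    final_update_norm: float
    seed: int


@dataclass
class TemplateSet:
    """Named binary masks on the analysis grid (flattened)."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, m in self.masks.items():
            m = np.asarray(m).astype(bool).ravel()
            if not m.any():
                raise ValueError(f"template '{name}' is empty")
            self.masks[name] = m


def _eigvals(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of the subject-space covariance, descending."""
    Xc = X - X.mean(axis=0, keepdims=True)
    C = Xc @ Xc.T / X.shape[1]
    w = np.linalg.eigvalsh(C)[::-1]
    return np.clip(w, 0.0, None)


def estimate_n_components(X: np.ndarray) -> int:
    """MDL model-order selection on the PCA eigenvalue spectrum.

    The criterion penalizes departure of the trailing eigenvalues from
    sphericity (the likelihood term assumes the residual is an iid
    Gaussian process) plus the usual 0.5 k (2n - k) log N parameter cost.
    Returns k in [1, subjects - 1].
    """
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    w = _eigvals(X)
    if w[0] <= 0:
        raise ValueError("data has zero variance")
    eps = 1e-12 * w[0]
    w = np.clip(w, eps, None)
    best_k, best_mdl = 1, np.inf
    for k in range(0, n - 1):
        tail = w[k:]
        geo = np.exp(np.mean(np.log(tail)))
        arith = np.mean(tail)
        loglik = -N * (n - k) * np.log(geo / arith)
        penalty = 0.5 * k * (2 * n - k) * np.log(N)
        mdl = loglik + penalty
        if mdl < best_mdl:
            best_mdl, best_k = mdl, k
    return int(min(max(best_k, 1), n - 1))


def pca_whiten(X: np.ndarray, k: int):
    """Reduce to k principal components with identity covariance.

    Returns (Y, whitening, dewhitening, row_means) with Y = whitening @ Xc
    (k x voxels, Y Y^T / V = I) and dewhitening @ Y the rank-k
    reconstruction of the centered data.
    """
    X = np.asarray(X, dtype=float)
    n, V = X.shape
    if not 1 <= k <= min(n, V):
        raise ValueError(f"k must be in [1, {min(n, V)}]")
    mu = X.mean(axis=0, keepdims=True)
    Xc = X - mu
    C = Xc @ Xc.T / V
    w, E = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:k]
    w, E = w[order], E[:, order]
    if w[-1] <= 1e-14 * max(w[0], 1.0):
        raise ValueError("requested rank exceeds numerical rank of the data")
    whitening = (E / np.sqrt(w)).T  # k x n
    dewhitening = E * np.sqrt(w)  # n x k
    Y = whitening @ Xc
    return Y, whitening, dewhitening, mu


def infomax_ica(
    Y: np.ndarray,
    seed: int = 0,
    lr: float = 0.05,
    max_iter: int = 512,
    tol: float = 1e-7,
    anneal: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    """Natural-gradient Infomax with the logistic nonlinearity.

    Y is whitened k x samples.  Returns (W, S, converged, n_iter,
    final_update_norm) with sources S = W @ Y.  The learning rate anneals
    whenever an update overshoots (non-finite or exploding weights); a
    non-converged run is reported, not hidden.
    """
    Y = np.asarray(Y, dtype=float)
    k, V = Y.shape
    rng = np.random.default_rng(seed)
    W = np.eye(k) + 0.01 * rng.standard_normal((k, k))
    I = np.eye(k)
    update_norm = np.inf
    prev_norm = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = W @ Y
        g = 1.0 / (1.0 + np.exp(-U))  # logistic
        dW = lr * ((I + (1.0 - 2.0 * g) @ U.T / V) @ W)
        if not np.isfinite(dW).all() or np.linalg.norm(dW) > 1e3:
            lr *= anneal
            W = np.eye(k) + 0.01 * rng.standard_normal((k, k))
            prev_norm = np.inf
            continue
        W = W + dW
        update_norm = float(np.linalg.norm(dW) / max(np.linalg.norm(W), 1e-12))
        # near the optimum the fixed-step natural gradient oscillates;
        # anneal the rate when the update norm clearly grows
        if update_norm > 1.05 * prev_norm:
            lr *= anneal
        prev_norm = update_norm
        if update_norm < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"Infomax did not converge in {max_iter} iterations "
            f"(final relative update {update_norm:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    S = W @ Y
    return W, S, converged, it, update_norm


def run_ica(
    X: np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 512,
) -> ICAResult:
    """Full spatial ICA chain: order selection, whitening, Infomax.

    ``mixing @ maps`` reconstructs the rank-k centered data.  Components
    are ordered by explained variance; each map's largest-magnitude voxel
    is made positive and z_maps are per-component z-scores.
    """
    X = np.asarray(X, dtype=float)
    k = estimate_n_components(X) if n_components is None else int(n_components)
    Y, whitening, dewhitening, _ = pca_whiten(X, k)
    W, S, converged, n_iter, upd = infomax_ica(Y, seed=seed, max_iter=max_iter)
    mixing = dewhitening @ np.linalg.inv(W)  # subjects x k

    # order by explained variance of each component's contribution
    var = np.array([np.sum(np.outer(mixing[:, c], S[c]) ** 2) for c in range(k)])
    order = np.argsort(var)[::-1]
    mixing, S = mixing[:, order], S[order]
    # deterministic sign: largest-|value| voxel of each map positive
    for c in range(k):
        j = np.argmax(np.abs(S[c]))
        if S[c, j] < 0:
            S[c] = -S[c]
            mixing[:, c] = -mixing[:, c]
    sd = S.std(axis=1, keepdims=True)
    z_maps = (S - S.mean(axis=1, keepdims=True)) / sd
    return ICAResult(
        n_components=k, mixing=mixing, maps=S, z_maps=z_maps,
        converged=converged, n_iter=n_iter, final_update_norm=upd, seed=seed,
    )


def threshold_z(z_map: np.ndarray, z_cut: float = 1.96, two_tailed: bool = False) -> np.ndarray:
    """Supra-threshold mask: z > z_cut (strict; positive tail by default)."""
    z = np.asarray(z_map, dtype=float)
    return (np.abs(z) > z_cut) if two_tailed else (z > z_cut)


def match_templates(z_maps: np.ndarray, templates: TemplateSet) -> pd.DataFrame:
    """Assign each template the component with maximal spatial correlation.

    Correlation is between |z| and the binary mask; assignment is greedy
    without replacement in descending correlation order; exact ties go to
    the lowest component index.
    """
    z_maps = np.asarray(z_maps, dtype=float)
    k = z_maps.shape[0]
    names = list(templates.masks)
    if len(names) > k:
        raise ValueError("more templates than components")
    corr = np.zeros((len(names), k))
    for t, name in enumerate(names):
        mask = templates.masks[name].astype(float)
        for c in range(k):
            a = np.abs(z_maps[c])
            if a.std() == 0 or mask.std() == 0:
                corr[t, c] = 0.0
            else:
                corr[t, c] = np.corrcoef(a, mask)[0, 1]
    assigned: dict[str, int] = {}
    used: set[int] = set()
    # greedy: repeatedly take the best remaining (template, component) pair;
    # ties broken toward lower component index, then template order
    while len(assigned) < len(names):
        best = None
        for t, name in enumerate(names):
            if name in assigned:
                continue
            for c in range(k):
                if c in used:
                    continue
                key = (corr[t, c], -c, -t)
                if best is None or key > best[0]:
                    best = (key, name, c)
        _, name, c = best
        assigned[name] = c
        used.add(c)
    return pd.DataFrame(
        {
            "template": list(assigned),
            "component": [assigned[n] for n in assigned],
            "correlation": [corr[names.index(n), assigned[n]] for n in assigned],
        }
    )


def compare_network(
    Xa: SUVRMatrix,
    Xb: SUVRMatrix,
    network_rois,
    density: float = 0.2,
    n_perm: int = 1000,
    seed: int = 0,
    node_p_threshold: float = 0.005,
    edge_p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-network group comparison of edges and nodes.

    Edges: per-edge partial-correlation difference at matched density,
    permutation p (labels shuffled, networks re-estimated), increased /
    decreased labels at p < ``edge_p_threshold``.  Nodes: GLM contrast of
    ROI SUVR with age/sex covariates at uncorrected
    p < ``node_p_threshold``.
    """
    from metconn import sice as _sice
    from metconn import stats as _stats

    rois = list(network_rois)
    if len(rois) < 3:
        raise ValueError("network needs >= 3 ROIs")
    Xa_n, Xb_n = Xa.select_rois(rois), Xb.select_rois(rois)
    p = len(rois)
    iu = np.triu_indices(p, 1)

    def edge_weights(values: np.ndarray) -> np.ndarray:
        S = _sice.sample_covariance(values)
        lam = _sice.lambda_for_density(S, density)
        return _sice.graphical_lasso(S, lam).partial_correlations()[iu]

    Wa, Wb = edge_weights(Xa_n.values), edge_weights(Xb_n.values)
    observed = Wb - Wa
    rng = np.random.default_rng(seed)
    pooled = np.vstack([Xa_n.values, Xb_n.values])
    na = Xa_n.n_subjects
    exceed = np.zeros(observed.size)
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        d = edge_weights(pooled[perm[na:]]) - edge_weights(pooled[perm[:na]])
        exceed += np.abs(d) >= np.abs(observed) - 1e-15
    p_edge = exceed / n_perm
    edge_label = np.where(
        (p_edge < edge_p_threshold) & (observed > 0), "increased",
        np.where((p_edge < edge_p_threshold) & (observed < 0), "decreased", "ns"),
    )
    edges = pd.DataFrame(
        {
            "roi_i": [rois[i] for i in iu[0]],
            "roi_j": [rois[j] for j in iu[1]],
            "weight_a": Wa,
            "weight_b": Wb,
            "diff": observed,
            "p_perm": p_edge,
            "label": edge_label,
        }
    )

    g = np.concatenate([np.zeros(na), np.ones(Xb_n.n_subjects)])
    cov = None
    if Xa_n.covariates is not None and Xb_n.covariates is not None:
        cov = np.vstack([
            Xa_n.covariates[["age", "sex"]].to_numpy(float),
            Xb_n.covariates[["age", "sex"]].to_numpy(float),
        ])
    rows = []
    for r, roi in enumerate(rois):
        y = np.concatenate([Xa_n.values[:, r], Xb_n.values[:, r]])
        beta, t, pv = _stats.glm_contrast(y, g, cov)
        rows.append((roi, beta, t, pv, pv < node_p_threshold))
    nodes = pd.DataFrame(rows, columns=["roi", "beta", "t", "p", "significant"])
    return edges, nodes
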
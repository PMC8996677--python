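"""Sparse inverse covariance estimation (SICE) of group metabolic networks.

The group network is the Gaussian graphical model fitted to the subjects x
ROI SUVR matrix: the graphical-lasso estimate of the precision matrix
Theta maximizing

    log det Theta - trace(S Theta) - lambda * sum_{i != j} |Theta_ij|

with S the (standardized) empirical covariance.  Off-diagonal zeros of
Theta encode conditional independence; retained edges are weighted by the
partial correlation -Theta_ij / sqrt(Theta_ii * Theta_jj).

Because the penalty level the sparsity corresponds to is not comparable
between groups, groups are compared at matched *densities*: for each
target density a penalty is found by bisection (edge count is monotone
non-increasing in lambda), and metrics are integrated across a density
sweep.  The convex solve itself is delegated to scikit-learn's
graphical-lasso coordinate-descent solver (with a LARS fallback at
extreme penalties); this module owns the density matching, the partial
correlations, and the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from metconn.io_volumes import SUVRMatrix

#: off-diagonal entries below this magnitude are treated as exact zeros
ZERO_FLOOR = 1e-8


@dataclass
class PrecisionMatrix:
    """Estimated precision with solver diagnostics."""

    theta: np.ndarray
    lam: float
    converged: bool
    n_iter: int
    objective: float

    def adjacency(self) -> np.ndarray:
        A = (np.abs(self.theta) > ZERO_FLOOR).astype(int)
        np.fill_diagonal(A, 0)
        return A

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.theta))
        W = -self.theta / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        W[np.abs(self.theta) <= ZERO_FLOOR] = 0.0
        return W

    def density(self) -> float:
        p = self.theta.shape[0]
        return self.adjacency().sum() / (p * (p - 1))


@dataclass
class AdjacencySeries:
    """Per-density binary adjacencies and partial-correlation weights."""

    densities: np.ndarray
    adjacency: list  # of p x p int arrays
    weights: list  # of p x p float arrays
    lambdas: np.ndarray
    roi_labels: list = field(default_factory=list)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        labels = self.roi_labels or list(range(1, self.adjacency[0].shape[0] + 1))
        for d, W in zip(self.densities, self.weights):
            ii, jj = np.nonzero(np.triu(W, 1))
            for i, j in zip(ii, jj):
                rows.append((labels[i], labels[j], d, W[i, j]))
        return pd.DataFrame(rows, columns=["roi_i", "roi_j", "density", "weight"])


def sample_covariance(
    X: SUVRMatrix | np.ndarray,
    standardize: bool = True,
    shrinkage: float | str = 0.0,
) -> np.ndarray:
    """Empirical covariance of the subjects x ROI matrix.

    With ``standardize`` (the default) columns are z-scored first, making
    this the correlation matrix — penalization is then invariant to the
    per-ROI intensity scale.

    ``shrinkage`` blends toward the identity, S' = (1 - g) S + g I, the
    Ledoit-Wolf-style conditioning needed when subjects are far fewer than
    ROIs (a singular correlation matrix makes the penalized problem
    unbounded at small penalties and the solver pathologically slow).
    ``"lw"`` estimates g by the Ledoit-Wolf formula; ``"auto"`` applies
    ``"lw"`` only when n <= p; a float in [0, 1) is used as-is.
    """
    V = X.values if isinstance(X, SUVRMatrix) else np.asarray(X, dtype=float)
    n, p = V.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    Vc = V - V.mean(axis=0)
    if standardize:
        sd = Vc.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            bad = np.flatnonzero(sd <= 0)
            raise ValueError(f"zero-variance column(s): {bad.tolist()}")
        Vc = Vc / sd
    S = (Vc.T @ Vc) / n
    if shrinkage == "auto":
        shrinkage = "lw" if n <= p else 0.0
    if shrinkage == "lw":
        from sklearn.covariance import ledoit_wolf_shrinkage

        # LW returns 1.0 for pathological tiny samples; keep some data signal
        shrinkage = float(min(ledoit_wolf_shrinkage(Vc, assume_centered=True), 0.95))
    if not 0.0 <= float(shrinkage) < 1.0:
        raise ValueError("shrinkage must lie in [0, 1)")
    if shrinkage:
        mu = np.trace(S) / p
        S = (1.0 - shrinkage) * S + shrinkage * mu * np.eye(p)
    return S


def _objective(S: np.ndarray, theta: np.ndarray, lam: float) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    pen = lam * (np.abs(theta).sum() - np.abs(np.diag(theta)).sum())
    return float(logdet - np.trace(S @ theta) - pen)


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> PrecisionMatrix:
    """L1-penalized precision estimate (penalty on off-diagonal entries).

    lam = 0 returns the unpenalized MLE inv(S) (requires S nonsingular).
    Non-convergence is reported through the ``converged`` flag and a
    warning, never silently.  Every returned matrix is checked SPD by
    Cholesky.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.any(np.diag(S) <= 0):
        raise ValueError("S must have positive diagonal")
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    if lam == 0:
        theta = np.linalg.inv(S)
        theta = (theta + theta.T) / 2
        np.linalg.cholesky(theta)
        return PrecisionMatrix(theta=theta, lam=0.0, converged=True, n_iter=0,
                               objective=_objective(S, theta, 0.0))

    off = np.abs(S - np.diag(np.diag(S)))
    if lam >= off.max() - 1e-15:
        # penalty dominates every off-diagonal covariance: diagonal solution
        theta = np.diag(1.0 / np.diag(S))
        return PrecisionMatrix(theta=theta, lam=lam, converged=True, n_iter=0,
                               objective=_objective(S, theta, lam))

    converged = True
    n_iter = max_iter
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            _, theta, n_iter = _sk_graphical_lasso(
                S, alpha=lam, tol=tol, max_iter=max_iter, mode="cd", return_n_iter=True
            )
        except (ConvergenceWarning, FloatingPointError, OverflowError):
            try:
                _, theta, n_iter = _sk_graphical_lasso(
                    S, alpha=lam, tol=tol, max_iter=max_iter, mode="lars", return_n_iter=True
                )
            except (ConvergenceWarning, FloatingPointError, OverflowError):
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, theta, n_iter = _sk_graphical_lasso(
                        S, alpha=lam, tol=tol, max_iter=max_iter, mode="cd",
                        return_n_iter=True,
                    )
                warnings.warn(
                    f"graphical lasso did not converge at lambda={lam:.4g}",
                    RuntimeWarning,
                    stacklevel=2,
                )
    theta = (theta + theta.T) / 2
    np.linalg.cholesky(theta)  # SPD contract
    return PrecisionMatrix(theta=theta, lam=float(lam), converged=converged,
                           n_iter=int(n_iter), objective=_objective(S, theta, lam))


def kkt_residual(S: np.ndarray, pm: PrecisionMatrix) -> float:
    """Max violation of the penalized-likelihood stationarity conditions.

    For W = inv(Theta): on the off-diagonal, |S_ij - W_ij| <= lam with
    equality-signed gradient on the active set.  Returns the largest
    violation (0 for an exact solution).
    """
    W = np.linalg.inv(pm.theta)
    G = S - W  # gradient of -loglik wrt theta is S - inv(theta)
    p = S.shape[0]
    viol = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                viol = max(viol, abs(G[i, j]))
            elif abs(pm.theta[i, j]) > ZERO_FLOOR:
                viol = max(viol, abs(G[i, j] + pm.lam * np.sign(pm.theta[i, j])))
            else:
                viol = max(viol, max(0.0, abs(G[i, j]) - pm.lam))
    return viol


def _edge_count(S, lam, tol) -> int:
    """Edge count at penalty lam; solver failure (rank-deficient S at a
    penalty too small to regularize it) counts as denser-than-anything so
    bisection backs away from it."""
    try:
        pm = graphical_lasso(S, lam, tol=tol)
    except (FloatingPointError, OverflowError, np.linalg.LinAlgError):
        return S.shape[0] ** 2
    return int(pm.adjacency().sum() // 2)


def lambda_for_density(
    S: np.ndarray,
    target_density: float,
    tol_density: float = 0.01,
    search_tol: float = 1e-3,
    max_bisect: int = 40,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Bisection for the penalty achieving a target edge density.

    Edge count is (essentially) monotone non-increasing in lambda; the
    solver uses a loosened tolerance during the search (callers refit at
    full tolerance).  If the target sits on a plateau the nearest
    achievable penalty is returned with a warning.  ``bracket`` allows
    warm-starting around a previously found penalty.
    """
    if not 0 < target_density < 1:
        if target_density == 0:
            off = np.abs(S - np.diag(np.diag(S)))
            return float(off.max() + 1e-6)
        raise ValueError("target_density must be in (0, 1)")
    p = S.shape[0]
    max_edges = p * (p - 1) // 2
    target_edges = target_density * max_edges
    # edge counts are integers: never demand finer than half an edge
    tol_density = max(tol_density, 0.5 / max_edges)

    off_max = float(np.abs(S - np.diag(np.diag(S))).max())
    lo, hi = 1e-6, off_max + 1e-6
    if bracket is not None:
        lo = max(lo, bracket[0])
        hi = min(hi, bracket[1])
        # validate warm bracket; fall back to the full range if it fails
        if _edge_count(S, lo, search_tol) < target_edges or _edge_count(S, hi, search_tol) > target_edges:
            lo, hi = 1e-6, off_max + 1e-6

    best_lam, best_gap = hi, np.inf
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        e = _edge_count(S, mid, search_tol)
        gap = abs(e - target_edges)
        if gap < best_gap:
            best_gap, best_lam = gap, mid
        if abs(e / max_edges - target_density) <= tol_density:
            return float(mid)
        if e > target_edges:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-8:
            break
    warnings.warn(
        f"target density {target_density:.3f} not reached within tolerance; "
        f"returning nearest achievable (gap {best_gap / max_edges:.4f})",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(best_lam)


def build_adjacency_series(
    X: SUVRMatrix | np.ndarray,
    densities,
    tol: float = 1e-4,
    tol_density: float = 0.01,
    shrinkage: float | str = "auto",
) -> AdjacencySeries:
    """Density-matched SICE networks across a sparsity sweep."""
    densities = np.asarray(sorted(densities), dtype=float)
    if np.any((densities <= 0) | (densities >= 1)):
        raise ValueError("densities must lie in (0, 1)")
    S = sample_covariance(X, shrinkage=shrinkage)
    adjacency, weights, lambdas = [], [], []
    prev_lam = None
    for d in densities:
        bracket = (0.5 * prev_lam, 1.5 * prev_lam) if prev_lam else None
        lam = lambda_for_density(S, d, tol_density=tol_density, bracket=bracket)
        pm = graphical_lasso(S, lam, tol=tol)
        adjacency.append(pm.adjacency())
        weights.append(pm.partial_correlations())
        lambdas.append(lam)
        prev_lam = lam
    roi_labels = list(X.roi_labels) if isinstance(X, SUVRMatrix) else []
    return AdjacencySeries(
        densities=densities, adjacency=adjacency, weights=weights,
        lambdas=np.asarray(lambdas), roi_labels=roi_labels,
    )


def support_f1(A_est: np.ndarray, support_true: set) -> float:
    """F1 score of the estimated edge set against a planted support."""
    p = A_est.shape[0]
    est = {(i, j) for i, j in zip(*np.nonzero(np.triu(A_est, 1)))}
    true = {(min(i, j), max(i, j)) for i, j in support_true}
    tp = len(est & true)
    if tp == 0:
        return 0.0
    prec = tp / len(est)
    rec = tp / len(true)
    return 2 * prec * rec / (prec + rec)


def bootstrap_edges(
    Xa: SUVRMatrix,
    Xb: SUVRMatrix,
    density: float,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    refit_lambda: bool = False,
    shrinkage: float | str = "auto",
) -> pd.DataFrame:
    """Bootstrap the between-group difference in edge partial correlations.

    Subjects are resampled with replacement within each group; each
    resample is re-estimated at the matched target density.  Per edge the
    percentile CI of the weight difference (B - A) and a two-sided
    bootstrap p are reported; edges whose CI excludes 0 are labeled
    enhanced (diff > 0) or weakened.  By default the density-matching
    penalty is calibrated once per group on the full sample and reused
    across resamples (``refit_lambda=True`` re-bisects each time).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if Xa.n_subjects < 3 or Xb.n_subjects < 3:
        raise ValueError("each group needs >= 3 subjects to resample")
    if Xa.roi_labels != Xb.roi_labels:
        raise ValueError("groups must share ROI labels")
    rng = np.random.default_rng(seed)
    p = Xa.n_rois

    lams = {}
    for key, X in (("a", Xa), ("b", Xb)):
        S = sample_covariance(X, shrinkage=shrinkage)
        lams[key] = lambda_for_density(S, density)

    def _weights(values, lam_full, refit, tol=1e-3, max_iter=100):
        # resample fits only feed the difference distribution; a loosened
        # solver tolerance is ample and much faster on tiny groups
        S = sample_covariance(values, shrinkage=shrinkage)
        lam = (
            lambda_for_density(S, density, bracket=(0.5 * lam_full, 1.5 * lam_full))
            if refit
            else lam_full
        )
        return graphical_lasso(S, lam, tol=tol, max_iter=max_iter).partial_correlations()

    Wa = _weights(Xa.values, lams["a"], False, tol=1e-4, max_iter=200)
    Wb = _weights(Xb.values, lams["b"], False, tol=1e-4, max_iter=200)
    iu = np.triu_indices(p, 1)
    observed = (Wb - Wa)[iu]

    diffs = np.empty((B, observed.size))
    for b in range(B):
        for _attempt in range(20):
            ia = rng.integers(0, Xa.n_subjects, size=Xa.n_subjects)
            ib = rng.integers(0, Xb.n_subjects, size=Xb.n_subjects)
            try:
                Wa_b = _weights(Xa.values[ia], lams["a"], refit_lambda)
                Wb_b = _weights(Xb.values[ib], lams["b"], refit_lambda)
                break
            except (ValueError, np.linalg.LinAlgError, FloatingPointError, OverflowError):
                continue  # degenerate resample (e.g. zero-variance column)
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        diffs[b] = (Wb_b - Wa_b)[iu]

    alpha = 1 - ci_level
    lo = np.percentile(diffs, 100 * alpha / 2, axis=0)
    hi = np.percentile(diffs, 100 * (1 - alpha / 2), axis=0)
    # two-sided bootstrap p: smallest level at which the percentile CI excludes 0
    frac_pos = (diffs > 0).mean(axis=0)
    p_boot = 2 * np.minimum(frac_pos, 1 - frac_pos)
    labels = np.where(lo > 0, "enhanced", np.where(hi < 0, "weakened", "ns"))
    roi = Xa.roi_labels
    return pd.DataFrame(
        {
            "roi_i": [roi[i] for i in iu[0]],
            "roi_j": [roi[j] for j in iu[1]],
            "weight_a": Wa[iu],
            "weight_b": Wb[iu],
            "diff": observed,
            "ci_lo": lo,
            "ci_hi": hi,
            "p_boot": p_boot,
            "label": labels,
        }
    )
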
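"""Permutation inference, GLM contrasts, effect-size filtering, FDR.

Group differences in network measures are tested nonparametrically: group
labels are shuffled (group sizes preserved), the statistic is fully
re-computed on each relabeled split — including, for network statistics,
covariance estimation and sparse inverse covariance fitting — and the
p-value is the fraction of permuted differences at least as extreme as
the observed one.  The default is 5000 permutations, two-sided.

Regional contrasts use an OLS general linear model (two-sample t-test
with nuisance covariates such as age and sex); the group coefficient on
z-scored responses serves as a standardized effect size, filtered at
|beta| > 0.8.  Multiple testing is controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from metconn.io_volumes import SUVRMatrix
from metconn import graph_metrics as gm
from metconn import sice

DEFAULT_N_PERM = 5000


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_permutations: int
    perm_mean: float
    perm_sd: float
    seed: int | None
    two_sided: bool
    exact: bool = False


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, SUVRMatrix) else np.asarray(X, dtype=float)


def network_statistic(metric: str, density: float = 0.2, tol_density: float = 0.01,
                      shrinkage: float | str = "auto"):
    """A group-difference statistic running the full SICE + metrics chain.

    Returns a callable f(values) -> float computing the named global
    metric of the density-matched SICE network estimated from one group's
    subjects x ROI values.
    """

    def stat(values: np.ndarray) -> float:
        S = sice.sample_covariance(values, shrinkage=shrinkage)
        lam = sice.lambda_for_density(S, density, tol_density=tol_density)
        A = sice.graphical_lasso(S, lam).adjacency()
        return gm.global_metrics(A).as_dict()[metric]

    stat.__name__ = f"{metric}@{density}"
    return stat


def network_permutation_test(
    Xa,
    Xb,
    metrics: list[str],
    density: float = 0.2,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    shrinkage: float | str = "auto",
) -> dict[str, PermutationResult]:
    """Permutation test of several global network metrics at once.

    One density-matched SICE network is estimated per group per
    permutation and every requested metric is read off it, so the cost is
    independent of the number of metrics.  The label shuffle is shared
    across metrics (their permutation distributions are therefore
    correlated, as they would be for any single shuffle sequence).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Va, Vb = _as_values(Xa), _as_values(Xb)
    na, nb = Va.shape[0], Vb.shape[0]

    def panel(values: np.ndarray, bracket=None, tol=1e-4, max_iter=200) -> np.ndarray:
        S = sice.sample_covariance(values, shrinkage=shrinkage)
        lam = sice.lambda_for_density(S, density, bracket=bracket)
        g = gm.global_metrics(
            sice.graphical_lasso(S, lam, tol=tol, max_iter=max_iter).adjacency()
        ).as_dict()
        return np.array([g[m] for m in metrics]), lam

    obs_a, lam_a = panel(Va)
    obs_b, lam_b = panel(Vb)
    observed = obs_a - obs_b
    pooled = np.vstack([Va, Vb])
    rng = np.random.default_rng(seed)
    diffs = np.empty((n_perm, len(metrics)))
    idx = np.arange(na + nb)
    # permuted groups have the observed groups' sizes, so the matched
    # penalty lands near the observed one: warm-bracket the bisection and
    # loosen the solver tolerance (replicates only feed the null
    # distribution)
    br_a = (0.5 * lam_a, 2.0 * lam_a)
    br_b = (0.5 * lam_b, 2.0 * lam_b)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        pa, _ = panel(pooled[perm[:na]], bracket=br_a, tol=1e-3, max_iter=100)
        pb, _ = panel(pooled[perm[na:]], bracket=br_b, tol=1e-3, max_iter=100)
        diffs[b] = pa - pb
    out = {}
    with np.errstate(invalid="ignore"):
        for j, m in enumerate(metrics):
            col = diffs[:, j]
            ok = np.isfinite(col)  # nan metrics (e.g. assortativity) dropped
            exceed = int((np.abs(col[ok]) >= abs(observed[j]) - 1e-15).sum())
            denom = max(int(ok.sum()), 1)
            out[m] = PermutationResult(
                observed=float(observed[j]),
                p_value=exceed / denom if np.isfinite(observed[j]) else float("nan"),
                n_permutations=denom,
                perm_mean=float(col[ok].mean()) if ok.any() else float("nan"),
                perm_sd=float(col[ok].std(ddof=1)) if ok.sum() > 1 else float("nan"),
                seed=seed,
                two_sided=True,
            )
    return out


def permutation_test(
    Xa,
    Xb,
    statistic,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    two_sided: bool = True,
    add_one: bool = False,
) -> PermutationResult:
    """Group-label permutation test of diff = statistic(A) - statistic(B).

    ``statistic`` maps one group's subjects x ROI array to a scalar and is
    re-evaluated from scratch on every relabeled split.  The plain
    fraction p = #{perm >= observed}/n_perm is reported by default;
    ``add_one`` applies the (b+1)/(B+1) correction for strictly positive
    p-values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Va, Vb = _as_values(Xa), _as_values(Xb)
    na, nb = Va.shape[0], Vb.shape[0]
    pooled = np.vstack([Va, Vb])
    observed = float(statistic(Va) - statistic(Vb))
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_perm)
    idx = np.arange(na + nb)
    for b in range(n_perm):
        perm = rng.permutation(idx)
        ia, ib = perm[:na], perm[na:]
        assert ia.size == na and ib.size == nb  # group sizes preserved
        diffs[b] = statistic(pooled[ia]) - statistic(pooled[ib])
    if two_sided:
        exceed = int((np.abs(diffs) >= abs(observed) - 1e-15).sum())
    else:
        exceed = int((diffs >= observed - 1e-15).sum())
    p = (exceed + 1) / (n_perm + 1) if add_one else exceed / n_perm
    return PermutationResult(
        observed=observed, p_value=float(min(p, 1.0)), n_permutations=n_perm,
        perm_mean=float(diffs.mean()), perm_sd=float(diffs.std(ddof=1)),
        seed=seed, two_sided=two_sided,
    )


def exact_permutation_pvalue(Xa, Xb, statistic, two_sided: bool = True,
                             max_assignments: int = 200_000) -> PermutationResult:
    """Exhaustive enumeration of all group-label assignments (small n).

    Serves as the exact oracle for the Monte-Carlo permutation test.
    """
    Va, Vb = _as_values(Xa), _as_values(Xb)
    na, nb = Va.shape[0], Vb.shape[0]
    total = comb(na + nb, na)
    if total > max_assignments:
        raise ValueError(f"C({na + nb},{na}) = {total} exceeds {max_assignments}")
    pooled = np.vstack([Va, Vb])
    observed = float(statistic(Va) - statistic(Vb))
    idx = set(range(na + nb))
    diffs = np.empty(total)
    for k, ia in enumerate(combinations(range(na + nb), na)):
        ib = sorted(idx - set(ia))
        diffs[k] = statistic(pooled[list(ia)]) - statistic(pooled[ib])
    if two_sided:
        exceed = int((np.abs(diffs) >= abs(observed) - 1e-15).sum())
    else:
        exceed = int((diffs >= observed - 1e-15).sum())
    return PermutationResult(
        observed=observed, p_value=exceed / total, n_permutations=total,
        perm_mean=float(diffs.mean()), perm_sd=float(diffs.std(ddof=1)),
        seed=None, two_sided=two_sided, exact=True,
    )


def glm_contrast(y, group, covariates=None):
    """OLS group contrast on z-scored responses with nuisance covariates.

    Design: [intercept, group(0/1), covariates...].  Returns
    (standardized beta for group, t, two-sided p).  With no covariates the
    t statistic is algebraically the classical pooled two-sample t.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    n = y.size
    if np.std(y, ddof=1) == 0:
        raise ValueError("response has zero variance")
    yz = (y - y.mean()) / y.std(ddof=1)
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        for k in range(C.shape[1]):
            cols.append(C[:, k])
            names.append(f"cov{k}")
    Xd = np.column_stack(cols)
    if n <= Xd.shape[1]:
        raise ValueError("more design columns than observations")
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # name the offending columns for the caller
        bad = []
        for k in range(Xd.shape[1]):
            keep = [c for c in range(Xd.shape[1]) if c != k]
            if np.linalg.matrix_rank(Xd[:, keep]) == rank:
                bad.append(names[k])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(Xd, yz, rcond=None)
    resid = yz - Xd @ beta
    df = n - Xd.shape[1]
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    if se < 1e-12:
        # exact fit (covariates fully explain y): no evidence about group
        t = 0.0 if abs(beta[1]) < 1e-10 else np.inf * np.sign(beta[1])
    else:
        t = beta[1] / se
    p = 2 * sps.t.sf(abs(t), df)
    return float(beta[1]), float(t), float(p)


def effect_size_filter(betas, threshold: float = 0.8) -> np.ndarray:
    """Flag effects with |beta| strictly above the threshold.

    Magnitude is used so that both decreased and increased effects pass.
    """
    betas = np.asarray(betas, dtype=float)
    if not np.isfinite(betas).all():
        raise ValueError("betas must be finite")
    return np.abs(betas) > threshold


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
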
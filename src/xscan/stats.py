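"""Core statistical primitives for the X-methylation scan.

The global test combines mass-univariate Wald p-values per genetic variant
into one overall p-value with the Simes procedure; replication evidence is
pooled across cohorts with Stouffer's sample-size-weighted Z; per-CpG effect
lists are controlled with Benjamini-Hochberg; direction consistency uses an
exact two-sided sign test.  These primitives are the method's contribution
and are implemented here directly; established library routines are used in
the test suite as independent cross-checks.
"""

from __future__ import annotations

from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "simes_combine",
    "stouffer_combine",
    "bh_qvalues",
    "bonferroni_adjust",
    "sign_test",
    "mass_univariate_ols",
    "hwe_exact_test",
]


def simes_combine(pvals: np.ndarray, return_argmin: bool = False):
    """Combine m two-sided p-values into one overall p with the Simes procedure.

    P = min_j ( m * p_(j) / j ) over the ascending order statistics p_(1..m),
    capped at 1.  Valid as a global test under independence or positive
    dependence of the component tests.

    Parameters
    ----------
    pvals : array of p-values in (0, 1]
    return_argmin : also return the index (into the input) of the p-value
        attaining the Simes minimum.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("simes_combine requires a non-empty 1-d p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = m * p[order] / np.arange(1, m + 1)
    j = int(np.argmin(adjusted))
    overall = min(float(adjusted[j]), 1.0)
    if return_argmin:
        return overall, int(order[j])
    return overall


def stouffer_combine(t_stats: Sequence[float], weights: Sequence[float]) -> float:
    """Stouffer's weighted-Z combination: Z = sum(w_k t_k) / sqrt(sum(w_k^2)).

    Weights are cohort sample sizes.  Entries with missing (NaN) statistics
    are excluded from both numerator and denominator; if all are missing,
    NaN is returned.
    """
    t = np.asarray(t_stats, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape:
        raise ValueError("t_stats and weights must have the same length")
    keep = np.isfinite(t)
    t, w = t[keep], w[keep]
    denom = np.sqrt(np.sum(w ** 2))
    if t.size == 0 or denom == 0:
        return float("nan")
    return float(np.sum(w * t) / denom)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (adjusted p-values).

    q_(i) = min over j >= i of ( m * p_(j) / j ), capped at 1; monotone
    non-decreasing in p by construction.
    """
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(pvals: np.ndarray, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p * m capped at 1; m defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size if n_tests is None else int(n_tests)
    return np.minimum(p * m, 1.0)


def sign_test(k: int, n: int) -> float:
    """Exact two-sided sign test of k successes in n trials against 1/2.

    Two-sided p = 2 * min(P[X <= k], P[X >= k], 1/2), computed with exact
    integer binomial tail sums, capped at 1.
    """
    if n < 1 or k < 0 or k > n:
        raise ValueError("need 0 <= k <= n and n >= 1")
    lower = sum(comb(n, i) for i in range(0, k + 1))
    upper = sum(comb(n, i) for i in range(k, n + 1))
    denom = 2 ** n
    tail = min(lower, upper) / denom
    return min(2.0 * min(tail, 0.5), 1.0)


def _project_out(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residuals of the columns of A after OLS projection on W (via QR)."""
    Q, _ = np.linalg.qr(W)
    return A - Q @ (Q.T @ A)


def mass_univariate_ols(
    X: np.ndarray,
    Y: np.ndarray,
    W: np.ndarray | None = None,
    on_degenerate: str = "raise",
):
    """Per-(predictor, trait) OLS slope, SE, t and two-sided Wald p.

    Fits, for every column x of `X` and every column y of `Y`, the linear
    model y = a + b x + c'W and returns the Wald statistics for b.  Uses the
    Frisch-Waugh-Lovell projection: both x and y are residualized on
    [intercept | W], after which b is the simple-regression slope of the
    residuals.  Exactly equivalent to the full multiple regression, but all
    predictor x trait pairs are computed with two matrix products.

    Parameters
    ----------
    X : (n, v) predictor matrix (e.g. genotype dosages)
    Y : (n, c) trait matrix
    W : (n, k) covariate matrix WITHOUT intercept (added internally), or None

    Returns
    -------
    beta, se, t, p : (v, c) arrays; df : int residual degrees of freedom
        df = n - k - 2 (intercept + covariates + tested predictor).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and Y.shape[0] != 1:
        X = X.T
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y sample dimensions differ")
    ones = np.ones((n, 1))
    W_full = ones if W is None else np.column_stack([ones, W])
    k = W_full.shape[1]
    if np.linalg.matrix_rank(W_full) < k:
        raise ValueError("covariate design is rank-deficient")
    df = n - k - 1
    if df < 1:
        raise ValueError(f"insufficient residual degrees of freedom (n={n}, design columns={k + 1})")
    Xr = _project_out(W_full, X)
    Yr = _project_out(W_full, Y)
    sxx = np.sum(Xr ** 2, axis=0)  # (v,)
    degenerate = sxx <= 1e-10 * n
    if np.any(degenerate):
        if on_degenerate == "raise":
            raise ValueError(
                "a predictor has zero variance after covariate adjustment (collinear design)"
            )
        sxx = np.where(degenerate, np.nan, sxx)
    sxy = Xr.T @ Yr  # (v, c)
    syy = np.sum(Yr ** 2, axis=0)  # (c,)
    beta = sxy / sxx[:, None]
    rss = np.maximum(syy[None, :] - beta * sxy, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return beta, se, t, p, df


def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Sums the conditional probabilities (given allele counts) of all
    heterozygote counts with probability <= that observed, enumerated over
    the same-parity lattice of possible heterozygote counts.
    """
    n_het, n_hom_rare, n_hom_common = int(n_het), int(n_hom_rare), int(n_hom_common)
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # ensure "rare" is the minor allele
        rare = 2 * n - rare
    # possible het counts share the parity of the rare-allele count
    from scipy.special import gammaln

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    log_probs = (
        hets * np.log(2)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:
        return 1.0
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))
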
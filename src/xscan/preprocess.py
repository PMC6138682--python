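"""Variant QC, within-cohort rank-based inverse-normal transformation,
covariate residualization and latent-factor confounder estimation.

The latent-factor estimator is PCA on the covariate-residualized,
feature-standardized trait matrix with the eigenvalue-difference rule for
choosing the number of factors.  It is an approximation to full
confounder-adjustment models fitted jointly with the effects of interest;
estimating factors from residuals makes them orthogonal to the known
covariates by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .config import QCThresholds
from .datatypes import CovariateBundle, GenotypeMatrix, TraitMatrix

logger = logging.getLogger("xscan")


def filter_variants(
    G: GenotypeMatrix, thr: QCThresholds | None = None
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Retain variants with info >= info_min AND hwe_p >= hwe_p_min AND
    call_rate >= call_rate_min AND maf >= maf_min (all boundaries retained).

    Returns the filtered matrix and per-criterion removal counts (a variant
    failing several criteria is counted under each).  Idempotent.
    """
    thr = thr or QCThresholds()
    v = G.variants
    fail = {
        "info": v["info"].values < thr.info_min,
        "hwe_p": v["hwe_p"].values < thr.hwe_p_min,
        "call_rate": v["call_rate"].values < thr.call_rate_min,
        "maf": v["maf"].values < thr.maf_min,
    }
    counts = {k: int(m.sum()) for k, m in fail.items()}
    keep = ~np.logical_or.reduce(list(fail.values()))
    counts["removed_total"] = int((~keep).sum())
    counts["retained"] = int(keep.sum())
    logger.info("variant QC: %s", counts)
    return G.subset_variants(keep), counts


def rank_inverse_normal(
    values: np.ndarray, cohorts: np.ndarray | None = None, offset: float = 3.0 / 8.0
) -> np.ndarray:
    """Rank-based inverse-normal transform, applied within each cohort.

    value -> Phi^{-1}((rank - c) / (n + 1 - 2c)) with the Blom offset
    c = 3/8, i.e. (rank - 3/8)/(n + 1/4); ties receive average ranks.
    Raises if any cohort's values are constant (ranks undefined).
    """
    x = np.asarray(values, dtype=float)
    out = np.empty_like(x)
    labels = np.zeros(x.shape[0]) if cohorts is None else np.asarray(cohorts)
    for lev in pd.unique(labels):
        idx = np.flatnonzero(labels == lev)
        sub = x[idx]
        if idx.size < 2 or np.any(np.all(sub == sub[0:1], axis=0)):
            raise ValueError(f"cohort {lev!r}: constant or singleton values, rank undefined")
        r = rankdata(sub, axis=0, method="average")
        n = idx.size
        out[idx] = ndtri((r - offset) / (n + 1 - 2 * offset))
    return out


def transform_traits(Y: TraitMatrix, C: CovariateBundle) -> TraitMatrix:
    """Within-cohort rank-inverse-normal transform of every feature."""
    if Y.sample_ids != C.sample_ids:
        raise ValueError("traits and covariates must be sample-aligned")
    vals = rank_inverse_normal(Y.values, C.table["cohort"].values)
    return Y.with_values(vals, scale_tag="normalized")


def _design_with_intercept(C: CovariateBundle, include_latent: bool, include_sex=None):
    W, names = C.design(include_latent=include_latent, include_sex=include_sex)
    X = np.column_stack([np.ones(C.n_samples), W])
    names = ["intercept"] + names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via greedy rank growth
        bad = []
        kept = X[:, :1]
        for j in range(1, X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    return X, names


def residualize(
    Y: TraitMatrix, C: CovariateBundle, include_latent: bool = True
) -> TraitMatrix:
    """OLS residuals of every feature on intercept + known covariates
    (+ latent factors if requested).  Residuals are orthogonal to every
    design column."""
    if Y.sample_ids != C.sample_ids:
        raise ValueError("traits and covariates must be sample-aligned")
    X, _ = _design_with_intercept(C, include_latent)
    Q, _r = np.linalg.qr(X)
    resid = Y.values - Q @ (Q.T @ Y.values)
    return Y.with_values(resid, scale_tag="normalized")


def estimate_latent_factors(
    Y_resid: TraitMatrix, q: int | str = "auto", q_max: int = 10
) -> np.ndarray:
    """Leading principal-component scores of the feature-standardized
    residual matrix, scaled to unit variance per factor.

    With ``q="auto"`` the number of factors maximizes the eigenvalue
    difference lambda_k - lambda_{k+1} of the sample covariance spectrum
    over k in 1..q_max.
    """
    Z = Y_resid.values
    n, p = Z.shape
    sd = Z.std(axis=0, ddof=0)
    keep = sd > 0
    Z = (Z[:, keep] - Z[:, keep].mean(axis=0)) / sd[keep]
    limit = min(n, int(keep.sum()))
    if q != "auto":
        q = int(q)
        if q == 0:
            return np.empty((n, 0))
        if q > limit:
            raise ValueError(f"q={q} exceeds min(n_samples, n_features)={limit}")
    U, s, _Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    if q == "auto":
        kmax = min(q_max, limit - 1)
        diffs = eigvals[:kmax] - eigvals[1 : kmax + 1]
        q = int(np.argmax(diffs)) + 1
        logger.info("latent factors: eigenvalue-difference rule selected q=%d", q)
    scores = U[:, :q] * np.sqrt(n)  # unit variance columns (U columns have norm 1)
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
    return scores


def preprocess(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateBundle,
    thr: QCThresholds | None = None,
    latent_q: int | str = "auto",
    latent_q_max: int = 10,
):
    """Full preprocessing: QC filter, missing-dosage imputation, within-
    cohort inverse-normal transform, latent-factor estimation from the
    covariate-residualized traits.

    Returns (G_filtered, Y_transformed, C_with_latent, qc_counts).  Latent
    factors are estimated within the sample stratum passed in.
    """
    G_f, counts = filter_variants(G, thr)
    G_f, n_imputed = G_f.impute_missing()
    if n_imputed:
        logger.info("mean-imputed %d missing dosages", n_imputed)
    Y_t = transform_traits(Y, C)
    if latent_q == 0:
        C_out = C.with_latent(np.empty((C.n_samples, 0)))
    else:
        resid = residualize(Y_t, C.with_latent(np.empty((C.n_samples, 0))),
                            include_latent=False)
        latent = estimate_latent_factors(resid, latent_q, latent_q_max)
        C_out = C.with_latent(latent)
    return G_f, Y_t, C_out, counts
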
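"""Multi-cohort replication of sentinel variants.

Per replication cohort each sentinel is regressed against every X-CpG
(no covariates by default; traits are pre-normalized within cohort), the
per-cohort t statistics are pooled per CpG with Stouffer's sample-size-
weighted Z, each Z is converted to a two-sided normal p, the per-CpG
p-values are Simes-combined per variant, and the per-variant overall
P-values are Bonferroni-adjusted across the sentinels carried to
replication.

t statistics are treated as z-scores for the weighted combination, which is
accurate for the per-cohort sample sizes this stage is meant for (hundreds
per cohort).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import CovariateBundle, GenotypeMatrix, TraitMatrix
from .stats import bonferroni_adjust, mass_univariate_ols, simes_combine, stouffer_combine


@dataclass
class CohortStat:
    """Per-cohort association statistics for one sentinel variant."""

    cohort_id: str
    n: int
    feature_ids: list[str]
    t_stats: np.ndarray  # NaN where the dosage had zero variance in the cohort

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"cohort {self.cohort_id!r} has n < 2")
        self.t_stats = np.asarray(self.t_stats, dtype=float)
        if self.t_stats.size != len(self.feature_ids):
            raise ValueError("one t statistic per tested CpG required")


def per_cohort_assoc(
    x: np.ndarray,
    Y: TraitMatrix,
    cohort_id: str,
    C: CovariateBundle | None = None,
) -> CohortStat:
    """Simple-regression t statistic of every CpG on the dosage within one
    cohort (covariates optional; default none)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("cohort must contain at least 2 samples")
    if np.nanstd(x) == 0:
        t = np.full(Y.n_features, np.nan)
    else:
        W = C.design()[0] if C is not None else None
        _b, _se, t_mat, _p, _df = mass_univariate_ols(x[:, None], Y.values, W)
        t = t_mat[0]
    return CohortStat(cohort_id, n, list(Y.features["id"]), t)


def stouffer_meta(stats: list[CohortStat]) -> pd.DataFrame:
    """Combine per-cohort t statistics per CpG: Z = sum(w_k t_k)/sqrt(sum w_k^2)
    with w_k the cohort sample size; cohorts with a missing t for a CpG are
    excluded from both sums.  Returns per-CpG z and two-sided p."""
    if not stats:
        raise ValueError("no cohort statistics supplied")
    feature_ids = stats[0].feature_ids
    for s in stats[1:]:
        if s.feature_ids != feature_ids:
            raise ValueError("cohorts tested different CpG sets")
    T = np.vstack([s.t_stats for s in stats])  # (k, m)
    w = np.array([s.n for s in stats], dtype=float)
    z = np.array([stouffer_combine(T[:, j], w) for j in range(T.shape[1])])
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame({"feature_id": feature_ids, "z": z, "p": p})


def replication_overall(
    meta_by_variant: dict[str, pd.DataFrame], n_variants_tested: int | None = None
) -> pd.DataFrame:
    """Per-variant Simes overall P over the meta-analytic per-CpG p-values,
    Bonferroni-adjusted across the variants carried to replication."""
    n_var = n_variants_tested or len(meta_by_variant)
    rows = []
    for vid, meta in meta_by_variant.items():
        ok = np.isfinite(meta["p"].values)
        overall = simes_combine(meta["p"].values[ok]) if ok.any() else float("nan")
        rows.append({"variant_id": vid, "overall_p": overall})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = bonferroni_adjust(out["overall_p"].values, n_var)
    out["n_variants_tested"] = n_var
    return out


def replicate(
    sentinel_ids: list[str],
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateBundle,
    use_covariates: bool = False,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Full replication stage on a cohort-structured sample.

    Splits the sample by the covariate bundle's cohort labels, runs the
    per-cohort association for every sentinel, combines with Stouffer +
    Simes, and Bonferroni-adjusts across sentinels.  Returns
    (per-variant summary, per-variant meta tables).
    """
    if G.sample_ids != Y.sample_ids or G.sample_ids != C.sample_ids:
        raise ValueError("replication inputs must be sample-aligned")
    cohorts = pd.unique(C.table["cohort"])
    meta_by_variant: dict[str, pd.DataFrame] = {}
    for sid in sentinel_ids:
        x = G.dosage_vector(sid)
        stats = []
        for coh in cohorts:
            idx = np.flatnonzero(C.table["cohort"].values == coh)
            Ck = C.subset_samples(idx) if use_covariates else None
            stats.append(per_cohort_assoc(x[idx], Y.subset_samples(idx), str(coh), Ck))
        meta_by_variant[sid] = stouffer_meta(stats)
    summary = replication_overall(meta_by_variant, len(sentinel_ids))
    return summary, meta_by_variant
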
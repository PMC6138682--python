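"""The discovery engine: mass-univariate Wald tests per (variant, CpG),
Simes combination into one overall P per variant, iterative conditional
sentinel discovery, male validation with LD proxies, genotype-by-sex
interaction testing, per-CpG FDR effect lists and direction-consistency
tests.

The central objects follow the model/results pattern:
``GlobalMethylationScan(G, Y, C).fit()`` returns a :class:`ScanResults`
carrying per-variant overall P-values; ``fit_conditional()`` returns a
:class:`ConditionalScanResults` with the discovered loci in order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CovariateBundle, GenotypeMatrix, TraitMatrix
from .stats import bh_qvalues, mass_univariate_ols, sign_test, simes_combine

logger = logging.getLogger("xscan")

GENOMEWIDE_ALPHA = 5e-8


# ------------------------------------------------------------ single variant

def wald_assoc(
    x: np.ndarray,
    Y: TraitMatrix,
    C: CovariateBundle | None = None,
    include_latent: bool = True,
    variant_id: str = "x",
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-feature OLS fit of trait ~ intercept + x + covariates, with the
    Wald t and two-sided p for the x coefficient.

    Returns a DataFrame with one row per feature: variant_id, feature_id,
    beta, se, t_stat, df, p.
    """
    W = None
    if C is not None:
        W, _ = C.design(include_latent=include_latent)
    if extra_covariates is not None:
        W = extra_covariates if W is None else np.column_stack([W, extra_covariates])
    beta, se, t, p, df = mass_univariate_ols(np.asarray(x, float)[:, None], Y.values, W)
    return pd.DataFrame(
        {
            "variant_id": variant_id,
            "feature_id": Y.features["id"].values,
            "beta": beta[0],
            "se": se[0],
            "t_stat": t[0],
            "df": df,
            "p": p[0],
        }
    )


# ------------------------------------------------------------------- scan

def _scan_matrix(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateBundle | None,
    include_latent: bool = True,
    extra_covariates: np.ndarray | None = None,
):
    W = None
    if C is not None:
        W, _ = C.design(include_latent=include_latent)
    if extra_covariates is not None:
        W = extra_covariates if W is None else np.column_stack([W, extra_covariates])
    return mass_univariate_ols(G.dosages, Y.values, W, on_degenerate="nan")


def scan_records(
    G: GenotypeMatrix,
    Y: TraitMatrix,
    C: CovariateBundle | None,
    include_latent: bool = True,
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """One GlobalScanRecord per variant: Simes-combined overall_p over the
    per-CpG Wald p-values, the number of tests combined, and the CpG
    attaining the Simes minimum.  Variants collinear with the covariates
    (e.g. conditioned-on sentinels) get overall_p = NaN."""
    _beta, _se, _t, p, _df = _scan_matrix(G, Y, C, include_latent, extra_covariates)
    m = Y.n_features
    feature_ids = Y.features["id"].values
    overall = np.full(G.n_variants, np.nan)
    argmin = np.empty(G.n_variants, dtype=object)
    for i in range(G.n_variants):
        row = p[i]
        if not np.all(np.isfinite(row)):
            argmin[i] = None
            continue
        overall[i], j = simes_combine(row, return_argmin=True)
        argmin[i] = feature_ids[j]
    return pd.DataFrame(
        {
            "variant_id": G.variants["id"].values,
            "chrom": G.variants["chrom"].values,
            "pos": G.variants["pos"].values,
            "overall_p": overall,
            "n_tests": m,
            "argmin_feature": argmin,
        }
    )


@dataclass
class ScanResults:
    """Results of a single global-test scan."""

    records: pd.DataFrame
    alpha: float
    model: "GlobalMethylationScan | None" = None

    @property
    def significant(self) -> pd.DataFrame:
        ok = self.records["overall_p"] < self.alpha
        return self.records[ok.fillna(False)].reset_index(drop=True)

    @property
    def significant_ids(self) -> list[str]:
        return list(self.significant["variant_id"])

    def top_variant(self):
        r = self.records.dropna(subset=["overall_p"])
        if r.empty:
            return None
        return r.loc[r["overall_p"].idxmin()]

    def summary(self) -> str:
        top = self.top_variant()
        lines = [
            "Global methylation scan (Simes overall P per variant)",
            f"  variants tested : {len(self.records)}",
            f"  CpGs per variant: {int(self.records['n_tests'].iloc[0]) if len(self.records) else 0}",
            f"  alpha           : {self.alpha:g}",
            f"  significant     : {len(self.significant)}",
        ]
        if top is not None:
            lines.append(
                f"  top variant     : {top['variant_id']} "
                f"(overall P = {top['overall_p']:.3g}, min at {top['argmin_feature']})"
            )
        return "\n".join(lines)


@dataclass
class ConditionalScanResults:
    """Loci found by iterative conditional discovery, in discovery order."""

    loci: pd.DataFrame  # sentinel_variant_id, iteration, conditioned_on, overall_p_at_discovery
    final_records: pd.DataFrame
    alpha: float

    @property
    def sentinel_ids(self) -> list[str]:
        return list(self.loci["sentinel_variant_id"])

    def summary(self) -> str:
        lines = [
            "Conditional locus discovery",
            f"  alpha: {self.alpha:g}; loci found: {len(self.loci)}",
        ]
        for _, row in self.loci.iterrows():
            lines.append(
                f"  iteration {int(row['iteration'])}: {row['sentinel_variant_id']} "
                f"(overall P = {row['overall_p_at_discovery']:.3g})"
            )
        return "\n".join(lines)


class GlobalMethylationScan:
    """Mass-univariate scan of genotype dosages against a trait matrix.

    Per variant, every trait is regressed on the dosage plus known
    covariates and latent factors; the per-trait Wald p-values are combined
    into one overall P with the Simes procedure, turning the scan into a
    single GWAS-style test per variant for an effect anywhere on the trait
    panel.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        traits: TraitMatrix,
        covariates: CovariateBundle | None = None,
        include_latent: bool = True,
    ):
        if covariates is not None and traits.sample_ids != covariates.sample_ids:
            raise ValueError("traits and covariates must be sample-aligned")
        if genotypes.sample_ids != traits.sample_ids:
            raise ValueError("genotypes and traits must be sample-aligned")
        self.genotypes = genotypes
        self.traits = traits
        self.covariates = covariates
        self.include_latent = include_latent

    def fit(
        self,
        alpha: float = GENOMEWIDE_ALPHA,
        extra_covariates: np.ndarray | None = None,
    ) -> ScanResults:
        records = scan_records(
            self.genotypes, self.traits, self.covariates,
            self.include_latent, extra_covariates,
        )
        return ScanResults(records, alpha, self)

    def fit_conditional(
        self,
        alpha: float = GENOMEWIDE_ALPHA,
        max_iterations: int = 100,
    ) -> ConditionalScanResults:
        """Iterative conditional discovery: re-scan with all previously found
        sentinels as covariates; stop when no variant reaches alpha."""
        sentinels: list[str] = []
        rows = []
        records = None
        for it in range(1, max_iterations + 1):
            extra = (
                np.column_stack([self.genotypes.dosage_vector(s) for s in sentinels])
                if sentinels
                else None
            )
            if extra is not None and np.linalg.matrix_rank(extra) < extra.shape[1]:
                warnings.warn("conditioned sentinels are mutually collinear; stopping")
                break
            records = scan_records(
                self.genotypes, self.traits, self.covariates,
                self.include_latent, extra,
            )
            usable = records.dropna(subset=["overall_p"])
            usable = usable[~usable["variant_id"].isin(sentinels)]
            if usable.empty or usable["overall_p"].min() >= alpha:
                break
            top = usable.loc[usable["overall_p"].idxmin()]
            rows.append(
                {
                    "sentinel_variant_id": top["variant_id"],
                    "iteration": it,
                    "conditioned_on": ",".join(sentinels),
                    "overall_p_at_discovery": top["overall_p"],
                }
            )
            sentinels.append(str(top["variant_id"]))
        else:
            warnings.warn(f"conditional scan stopped at the {max_iterations}-iteration cap")
        loci = pd.DataFrame(
            rows,
            columns=[
                "sentinel_variant_id", "iteration", "conditioned_on",
                "overall_p_at_discovery",
            ],
        )
        if records is None:
            records = scan_records(
                self.genotypes, self.traits, self.covariates, self.include_latent
            )
        return ConditionalScanResults(loci, records, alpha)


# ------------------------------------------------------- male validation

def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    keep = np.isfinite(a) & np.isfinite(b)
    if keep.sum() < 3 or a[keep].std() == 0 or b[keep].std() == 0:
        return 0.0
    return float(np.corrcoef(a[keep], b[keep])[0, 1] ** 2)


def find_proxies(
    G: GenotypeMatrix, sentinel_id: str, window: int = 1_000_000, r2_min: float = 0.8
) -> list[str]:
    """Variants within `window` bp of the sentinel on the same chromosome with
    dosage r^2 >= r2_min (Pearson, pairwise-complete)."""
    j = G.variant_index(sentinel_id)
    chrom = G.variants["chrom"].iloc[j]
    pos = int(G.variants["pos"].iloc[j])
    near = (
        (G.variants["chrom"] == chrom)
        & (np.abs(G.variants["pos"].astype(int) - pos) <= window)
        & (G.variants["id"] != sentinel_id)
    )
    x = G.dosages[:, j]
    out = []
    for k in np.flatnonzero(near.values):
        if _pairwise_r2(x, G.dosages[:, k]) >= r2_min:
            out.append(str(G.variants["id"].iloc[k]))
    return out


def male_validation(
    loci: pd.DataFrame | list[str],
    G_male: GenotypeMatrix,
    Y_male: TraitMatrix,
    C_male: CovariateBundle | None,
    proxy_window: int = 1_000_000,
    proxy_r2_min: float = 0.8,
    male_exclusion_alpha: float = 0.05,
    male_replication_alpha: float = 1.1e-6,
    include_latent: bool = True,
) -> pd.DataFrame:
    """Female-specificity check in the male stratum.

    Per locus, the sentinel and every LD proxy (r^2 >= 0.8 within 1 Mb,
    computed on male dosages) are scanned in males; the locus is
    female-specific iff the minimum overall P across these variants exceeds
    ``male_exclusion_alpha``.  A second reporting column flags loci whose
    male minimum overall P falls below the stricter ``male_replication_alpha``.
    """
    if G_male.n_samples == 0:
        raise ValueError("male stratum is empty")
    sentinel_ids = (
        list(loci["sentinel_variant_id"]) if isinstance(loci, pd.DataFrame) else list(loci)
    )
    rows = []
    for sid in sentinel_ids:
        G_male.variant_index(sid)  # raises if the sentinel is absent in males
        proxies = find_proxies(G_male, sid, proxy_window, proxy_r2_min)
        test_ids = [sid] + proxies
        sub = G_male.subset_variants(
            G_male.variants["id"].isin(test_ids).values
        )
        records = scan_records(sub, Y_male, C_male, include_latent)
        min_p = float(records["overall_p"].min())
        rows.append(
            {
                "sentinel_variant_id": sid,
                "male_overall_p_min": min_p,
                "n_proxies": len(proxies),
                "female_specific": bool(min_p > male_exclusion_alpha),
                "replicates_in_males": bool(min_p < male_replication_alpha),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------- interaction

def interaction_test(
    x: np.ndarray,
    Y: TraitMatrix,
    C: CovariateBundle,
    include_latent: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Genotype-by-sex interaction on the combined-sex sample.

    Per CpG fits y = b1*x + b2*sex + b3*(x*sex) + covariates and tests b3;
    the per-CpG interaction p-values are Simes-combined into one overall P.
    Returns (overall_p, per-CpG DataFrame).
    """
    sexes = set(C.table["sex"].unique())
    if len(sexes) < 2:
        raise ValueError("interaction test requires both sexes in the sample")
    x = np.asarray(x, dtype=float)
    male = (C.table["sex"].values == "male").astype(float)
    W, _ = C.design(include_latent=include_latent, include_sex=True)
    W = np.column_stack([W, x])
    inter = (x * male)[:, None]
    beta, se, t, p, df = mass_univariate_ols(inter, Y.values, W)
    table = pd.DataFrame(
        {
            "feature_id": Y.features["id"].values,
            "beta_interaction": beta[0],
            "se": se[0],
            "t_stat": t[0],
            "df": df,
            "p": p[0],
        }
    )
    return simes_combine(p[0]), table


# ------------------------------------------------------ per-CpG effects

def per_cpg_effects(
    sentinel_id: str,
    G: GenotypeMatrix,
    Y_analysis: TraitMatrix,
    C: CovariateBundle | None,
    Y_beta: TraitMatrix | None = None,
    fdr: float = 0.05,
    include_latent: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Benjamini-Hochberg-controlled list of CpGs affected by a sentinel.

    Tests run on the analysis (inverse-normal) scale; effect sizes are
    additionally re-estimated on the raw beta scale (``Y_beta``) with the
    same covariates, so reported effects read as methylation change per
    allele.  Returns (per-CpG table with q-values, direction summary with
    the exact sign-test p).
    """
    x = G.dosage_vector(sentinel_id)
    stats = wald_assoc(x, Y_analysis, C, include_latent, sentinel_id)
    stats["q"] = bh_qvalues(stats["p"].values)
    if Y_beta is not None:
        raw = wald_assoc(x, Y_beta, C, include_latent, sentinel_id)
        stats["beta_raw_scale"] = raw["beta"].values
    else:
        stats["beta_raw_scale"] = stats["beta"].values
    hits = stats[stats["q"] < fdr].reset_index(drop=True)
    signs = np.sign(hits["beta_raw_scale"].values)
    n_neg = int((signs < 0).sum())
    n_pos = int((signs > 0).sum())
    n = n_neg + n_pos
    summary = {
        "sentinel_variant_id": sentinel_id,
        "n_cpgs_fdr": len(hits),
        "n_hypomethylated": n_neg,
        "n_hypermethylated": n_pos,
        "dominant_direction_fraction": (max(n_neg, n_pos) / n) if n else float("nan"),
        "sign_test_p": sign_test(max(n_neg, n_pos), n) if n else float("nan"),
        "mean_effect_raw_scale": float(hits["beta_raw_scale"].mean()) if len(hits) else float("nan"),
    }
    return hits, summary


def direction_consistency_test(signs) -> float:
    """Exact two-sided sign test that effect signs are balanced (p0 = 1/2)."""
    s = np.sign(np.asarray(signs, dtype=float))
    s = s[s != 0]
    if s.size == 0:
        raise ValueError("no nonzero signs supplied")
    return sign_test(int((s > 0).sum()), int(s.size))
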
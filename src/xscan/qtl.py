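"""QTL mapping around discovered sentinels.

* cis-eQTL: sentinel dosage vs expression of genes within 250 kb
  (covariates + latent factors; Bonferroni over the genes tested).
* CpG-expression coupling: methylation of a CpG vs expression of genes
  within 250 kb (known covariates only).
* trans-meQTL: sentinel vs autosomal CpGs on other chromosomes or more
  than 5 Mb away (combined sexes, sex as covariate; per-variant BH FDR).
* X cis-meQTL + adjusted re-test: per X-CpG strongest cis SNP within
  250 kb, then the autosomal effect re-estimated with that SNP as an
  additional covariate (epistasis/mediation check).

The cis window is closed: a feature at exactly 250,000 bp is tested.
Gene-to-variant distance is the minimum distance from the variant position
to the gene interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import WindowSpec
from .datatypes import CovariateBundle, GenotypeMatrix, TraitMatrix
from .stats import bh_qvalues, bonferroni_adjust
from .scan import wald_assoc


def _interval_distance(pos: int, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Minimum bp distance from a point to 1-based inclusive intervals
    (0 inside the interval)."""
    return np.maximum(0, np.maximum(start - pos, pos - end))


def _cis_mask(anchor_chrom, anchor_pos, features: pd.DataFrame, window: int) -> np.ndarray:
    same = features["chrom"].astype(str).values == str(anchor_chrom)
    dist = _interval_distance(
        int(anchor_pos), features["start"].values.astype(int), features["end"].values.astype(int)
    )
    return same & (dist <= window)


def cis_eqtl(
    variant_id: str,
    G: GenotypeMatrix,
    E: TraitMatrix,
    C: CovariateBundle | None,
    windows: WindowSpec | None = None,
    include_latent: bool = True,
) -> pd.DataFrame:
    """Association of a variant with every gene whose interval lies within
    the cis window; Bonferroni across the genes tested for that variant."""
    windows = windows or WindowSpec()
    j = G.variant_index(variant_id)
    chrom, pos = G.variants["chrom"].iloc[j], int(G.variants["pos"].iloc[j])
    mask = _cis_mask(chrom, pos, E.features, windows.cis_window)
    if not mask.any():
        import warnings

        warnings.warn(f"no genes within {windows.cis_window} bp of {variant_id}")
        return pd.DataFrame(
            columns=["variant_id", "feature_id", "beta", "se", "t_stat", "df", "p",
                     "p_bonferroni", "significant"]
        )
    E_sub = E.subset_features(mask)
    stats = wald_assoc(G.dosages[:, j], E_sub, C, include_latent, variant_id)
    stats["p_bonferroni"] = bonferroni_adjust(stats["p"].values)
    stats["significant"] = stats["p_bonferroni"] < 0.05
    return stats


def cpg_expression_assoc(
    cpg_id: str,
    Y: TraitMatrix,
    E: TraitMatrix,
    C: CovariateBundle | None,
    windows: WindowSpec | None = None,
) -> pd.DataFrame:
    """Association of one CpG's methylation with expression of genes within
    the cis window anchored on the CpG (known covariates only, no latent
    factors)."""
    windows = windows or WindowSpec()
    k = Y.feature_index(cpg_id)
    chrom = Y.features["chrom"].iloc[k]
    pos = int(Y.features["start"].iloc[k])
    mask = _cis_mask(chrom, pos, E.features, windows.cis_window)
    if not mask.any():
        return pd.DataFrame(
            columns=["variant_id", "feature_id", "beta", "se", "t_stat", "df", "p",
                     "p_bonferroni", "significant"]
        )
    E_sub = E.subset_features(mask)
    stats = wald_assoc(Y.values[:, k], E_sub, C, False, cpg_id)
    stats = stats.rename(columns={"variant_id": "cpg_id"})
    stats["p_bonferroni"] = bonferroni_adjust(stats["p"].values)
    stats["significant"] = stats["p_bonferroni"] < 0.05
    return stats


def trans_meqtl(
    variant_id: str,
    G: GenotypeMatrix,
    Y_auto: TraitMatrix,
    C: CovariateBundle | None,
    windows: WindowSpec | None = None,
    fdr: float = 0.05,
    include_latent: bool = True,
) -> pd.DataFrame:
    """Long-range effects of a variant on autosomal CpGs: tests CpGs on
    other chromosomes, or strictly more than `trans_min_distance` away on
    the variant's chromosome; BH within the variant's p-vector."""
    windows = windows or WindowSpec()
    j = G.variant_index(variant_id)
    chrom, pos = str(G.variants["chrom"].iloc[j]), int(G.variants["pos"].iloc[j])
    feats = Y_auto.features
    other = feats["chrom"].astype(str).values != chrom
    dist = _interval_distance(pos, feats["start"].values.astype(int),
                              feats["end"].values.astype(int))
    mask = other | (dist > windows.trans_min_distance)
    Y_sub = Y_auto.subset_features(mask)
    stats = wald_assoc(G.dosages[:, j], Y_sub, C, include_latent, variant_id)
    stats["q"] = bh_qvalues(stats["p"].values)
    stats["significant"] = stats["q"] < fdr
    return stats


def cis_meqtl_x(
    cpg_ids: list[str],
    G_x: GenotypeMatrix,
    Y_x: TraitMatrix,
    C: CovariateBundle | None,
    windows: WindowSpec | None = None,
) -> pd.DataFrame:
    """Strongest significant cis SNP (within 250 kb, Bonferroni < 0.05) per
    X-chromosomal CpG; ties broken toward the lower variant position.
    Known covariates only."""
    windows = windows or WindowSpec()
    rows = []
    for cid in cpg_ids:
        k = Y_x.feature_index(cid)
        pos = int(Y_x.features["start"].iloc[k])
        mask = _cis_mask(Y_x.features["chrom"].iloc[k], pos, _variants_as_features(G_x),
                         windows.cis_window)
        if not mask.any():
            rows.append({"cpg_id": cid, "cis_snp_id": None, "p": np.nan,
                         "p_bonferroni": np.nan})
            continue
        sub = G_x.subset_variants(mask)
        y = Y_x.values[:, [k]]
        from .stats import mass_univariate_ols

        W = C.design(include_latent=False)[0] if C is not None else None
        _b, _se, _t, p, _df = mass_univariate_ols(sub.dosages, y, W, on_degenerate="nan")
        p = p[:, 0]
        p_bonf = bonferroni_adjust(p, int(np.isfinite(p).sum()))
        sig = np.flatnonzero(np.nan_to_num(p_bonf, nan=1.0) < 0.05)
        if sig.size == 0:
            rows.append({"cpg_id": cid, "cis_snp_id": None, "p": np.nan,
                         "p_bonferroni": np.nan})
            continue
        # strongest p; deterministic tie-break on position
        order = sorted(
            sig, key=lambda i: (p[i], int(sub.variants["pos"].iloc[i]))
        )
        best = order[0]
        rows.append(
            {
                "cpg_id": cid,
                "cis_snp_id": str(sub.variants["id"].iloc[best]),
                "p": float(p[best]),
                "p_bonferroni": float(p_bonf[best]),
            }
        )
    return pd.DataFrame(rows)


def _variants_as_features(G: GenotypeMatrix) -> pd.DataFrame:
    v = G.variants
    return pd.DataFrame(
        {"id": v["id"], "chrom": v["chrom"], "start": v["pos"], "end": v["pos"]}
    )


def adjusted_trans_effect(
    variant_id: str,
    cpg_id: str,
    G: GenotypeMatrix,
    G_x: GenotypeMatrix | None,
    cis_snp_id: str | None,
    Y_x: TraitMatrix,
    C: CovariateBundle | None,
) -> dict:
    """Re-test an autosomal variant's effect on an X CpG with the CpG's
    strongest X-linked cis SNP as an extra covariate.

    With no cis SNP the adjusted effect equals the unadjusted one exactly.
    Raises if the cis SNP is collinear with the variant (impossible for
    unlinked chromosomes; signals corrupted input).
    """
    x = G.dosage_vector(variant_id)
    k = Y_x.feature_index(cpg_id)
    Y_one = Y_x.subset_features([k])
    un = wald_assoc(x, Y_one, C, False, variant_id)
    if cis_snp_id is None:
        return {
            "variant_id": variant_id, "cpg_id": cpg_id, "cis_snp_id": None,
            "beta_unadjusted": float(un["beta"].iloc[0]),
            "beta_adjusted": float(un["beta"].iloc[0]),
            "p_adjusted": float(un["p"].iloc[0]),
        }
    cis = G_x.dosage_vector(cis_snp_id)
    r = np.corrcoef(x, cis)[0, 1]
    if abs(r) > 0.999:
        raise ValueError(
            f"cis SNP {cis_snp_id} is collinear with {variant_id}; input data corrupt"
        )
    adj = wald_assoc(x, Y_one, C, False, variant_id, extra_covariates=cis[:, None])
    return {
        "variant_id": variant_id, "cpg_id": cpg_id, "cis_snp_id": cis_snp_id,
        "beta_unadjusted": float(un["beta"].iloc[0]),
        "beta_adjusted": float(adj["beta"].iloc[0]),
        "p_adjusted": float(adj["p"].iloc[0]),
    }
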
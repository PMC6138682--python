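"""Synthetic cohort generator with planted, recoverable ground truth.

Emulates the statistical structure the discovery pipeline assumes: Hardy-
Weinberg genotypes on a miniature multi-chromosome genome, beta-scale
methylation with CpG-specific baselines, female-restricted per-allele
genetic effects at planted CpG sets, cell-count / batch / cohort / latent
confounding, a multi-cohort sample, cis expression effects and annotation
tracks in which affected CpGs are preferentially placed.

The noise model is Gaussian on the beta scale with truncation to [0, 1],
keeping planted effect sizes directly interpretable in % methylation per
allele.  Direction consistency is realized by flipping each target CpG's
effect sign with probability 1 - direction_consistency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PlantedLocus, SimulationConfig
from .datatypes import (
    CELL_COUNT_COLUMNS,
    AnnotationSet,
    CovariateBundle,
    GenotypeMatrix,
    TraitMatrix,
)
from .stats import hwe_exact_test

# stage indices used to derive independent per-stage random streams from the
# single master seed, so any stage can be regenerated in isolation
_STAGES = {
    "genotypes": 1,
    "x_genotypes": 2,
    "covariates": 3,
    "methylation": 4,
    "expression": 5,
    "annotations": 6,
}


def _rng(config: SimulationConfig, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STAGES[stage], extra]))


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream evaluation."""

    planted_loci: list[PlantedLocus] = field(default_factory=list)
    effect_signs: dict[str, dict[str, int]] = field(default_factory=dict)  # variant id -> {cpg id: +-1}
    confounder_loadings: dict = field(default_factory=dict)
    latent_scores: np.ndarray | None = None
    annotation_assignment: dict[str, dict[str, str]] = field(default_factory=dict)
    sentinel_ids: list[str] = field(default_factory=list)
    proxy_ids: dict[str, list[str]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {
            "planted_loci": [
                {
                    "variant_index": pl.variant_index,
                    "maf": pl.maf,
                    "target_cpg_indices": list(pl.target_cpg_indices),
                    "per_allele_effect_beta": pl.per_allele_effect_beta,
                    "female_specific": pl.female_specific,
                    "direction_consistency": pl.direction_consistency,
                    "cis_gene_index": pl.cis_gene_index,
                    "cis_effect": pl.cis_effect,
                    "trans_autosomal_cpg_indices": list(pl.trans_autosomal_cpg_indices),
                    "n_ld_proxies": pl.n_ld_proxies,
                    "proxy_r2": pl.proxy_r2,
                }
                for pl in self.planted_loci
            ],
            "effect_signs": self.effect_signs,
            "annotation_assignment": self.annotation_assignment,
            "sentinel_ids": self.sentinel_ids,
            "proxy_ids": self.proxy_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_loci=[PlantedLocus(**d) for d in payload["planted_loci"]],
            effect_signs=payload["effect_signs"],
            annotation_assignment=payload["annotation_assignment"],
            sentinel_ids=payload.get("sentinel_ids", []),
            proxy_ids=payload.get("proxy_ids", {}),
        )


def _sample_ids(config: SimulationConfig) -> list[str]:
    return [f"S{i + 1:05d}" for i in range(config.n_samples)]


def _draw_positions(rng, chroms: list[str], lengths: dict[str, int], n: int):
    """Chromosome (proportional to length) and uniform position per item."""
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    pos = np.array([rng.integers(1, lengths[chroms[i]] + 1) for i in chrom_idx])
    return np.array([chroms[i] for i in chrom_idx]), pos


def _hwe_dosages(rng, maf: np.ndarray, n_samples: int) -> np.ndarray:
    return rng.binomial(2, maf[None, :], size=(n_samples, maf.size)).astype(float)


def _empirical_hwe_p(dosages: np.ndarray) -> np.ndarray:
    out = np.empty(dosages.shape[1])
    for j in range(dosages.shape[1]):
        g = np.rint(dosages[:, j]).astype(int)
        out[j] = hwe_exact_test(
            int((g == 1).sum()), int((g == 2).sum()), int((g == 0).sum())
        )
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Autosomal variant panel under Hardy-Weinberg proportions.

    Planted loci override the MAF at their variant index; LD proxies for a
    planted locus are created at the immediately following variant indices
    by copying the sentinel's genotypes and resampling each sample's
    genotype with probability 1 - sqrt(proxy_r2) (giving dosage correlation
    r = sqrt(r2) in expectation), placed within 100 kb of the sentinel.
    """
    rng = _rng(config, "genotypes")
    n, v = config.n_samples, config.n_variants
    maf = rng.uniform(*config.maf_range, size=v)
    chrom, pos = _draw_positions(rng, config.autosomes, config.chromosome_lengths, v)
    for pl in config.planted_loci:
        if pl.variant_index >= v:
            raise ValueError("planted variant_index outside the variant panel")
        maf[pl.variant_index] = pl.maf
    dosages = _hwe_dosages(rng, maf, n)
    for pl in config.planted_loci:
        j = pl.variant_index
        for k in range(1, pl.n_ld_proxies + 1):
            jk = j + k
            if jk >= v:
                break
            resample = rng.random(n) < 1 - np.sqrt(pl.proxy_r2)
            proxy = dosages[:, j].copy()
            proxy[resample] = rng.binomial(2, pl.maf, size=int(resample.sum()))
            dosages[:, jk] = proxy
            maf[jk] = pl.maf
            chrom[jk] = chrom[j]
            pos[jk] = min(
                pos[j] + 20_000 * k, config.chromosome_lengths[str(chrom[j])]
            )
    alleles = np.array(["A", "C", "G", "T"])
    variants = pd.DataFrame(
        {
            "id": [f"V{i + 1:05d}" for i in range(v)],
            "chrom": chrom,
            "pos": pos,
            "ref": rng.choice(alleles, size=v),
            "alt": rng.choice(alleles, size=v),
            "maf": maf,
            "hwe_p": _empirical_hwe_p(dosages),
            "call_rate": 1.0,
            "info": 1.0,
        }
    )
    return GenotypeMatrix(_sample_ids(config), variants, dosages)


def simulate_x_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """X-chromosome variant panel (for cis-meQTL mapping on X).

    Modelled with diploid dosages for simplicity: the analysis consumes
    dosage vectors only and the X panel is never part of the autosomal scan.
    """
    rng = _rng(config, "x_genotypes")
    n, v = config.n_samples, config.n_x_variants
    x_len = config.chromosome_lengths.get("chrX", 15_000_000)
    maf = rng.uniform(*config.maf_range, size=v)
    pos = np.sort(rng.integers(1, x_len + 1, size=v))
    dosages = _hwe_dosages(rng, maf, n)
    variants = pd.DataFrame(
        {
            "id": [f"X{i + 1:05d}" for i in range(v)],
            "chrom": "chrX",
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "maf": maf,
            "hwe_p": _empirical_hwe_p(dosages),
            "call_rate": 1.0,
            "info": 1.0,
        }
    )
    return GenotypeMatrix(_sample_ids(config), variants, dosages)


def simulate_covariates(config: SimulationConfig) -> CovariateBundle:
    """Per-sample sex, age, cohort, batch, six positive blood cell counts
    and unit-variance latent factor scores."""
    rng = _rng(config, "covariates")
    n = config.n_samples
    sex = np.array(["female"] * config.n_females + ["male"] * config.n_males)
    cohort = np.array([f"cohort{i % config.n_cohorts + 1}" for i in range(n)])
    batch = np.array([f"batch{'ab'[(i // config.n_cohorts) % 2]}" for i in range(n)])
    age = rng.uniform(18, 80, size=n)
    # typical blood counts (10^9 cells/l); lognormal keeps them positive
    count_means = {
        "lymphocytes": 2.0,
        "neutrophils": 4.0,
        "monocytes": 0.5,
        "eosinophils": 0.2,
        "basophils": 0.05,
        "red_blood_cells": 4.8,
    }
    table = pd.DataFrame({"sex": sex, "age": age, "cohort": cohort, "batch": batch})
    for name in CELL_COUNT_COLUMNS:
        table[name] = np.exp(rng.normal(np.log(count_means[name]), 0.25, size=n))
    q = config.n_latent_factors
    latent = rng.normal(size=(n, q)) if q else np.empty((n, 0))
    if q:
        latent = (latent - latent.mean(axis=0)) / latent.std(axis=0, ddof=0)
    return CovariateBundle(_sample_ids(config), table, latent)


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (a - a.mean(axis=0)) / sd


def _confounding(rng, C: CovariateBundle, n_features: int, cell_sd, latent_sd, cohort_sd):
    """Shared confounding structure: cell-count loadings, latent loadings and
    additive per-cohort intercepts.  Returns (signal matrix, loadings dict)."""
    counts = _standardize(C.table[CELL_COUNT_COLUMNS].values.astype(float))
    cell_load = rng.normal(0, cell_sd, size=(6, n_features))
    signal = counts @ cell_load
    lat_load = np.empty((C.latent.shape[1], n_features))
    if C.latent.shape[1]:
        lat_load = rng.normal(0, latent_sd, size=(C.latent.shape[1], n_features))
        signal = signal + C.latent @ lat_load
    cohorts = sorted(pd.unique(C.table["cohort"]))
    shifts = {c: rng.normal(0, cohort_sd, size=n_features) for c in cohorts}
    for c in cohorts:
        signal[C.table["cohort"].values == c, :] += shifts[c]
    return signal, {"cell": cell_load, "latent": lat_load, "cohort": shifts}


def simulate_methylation(
    G: GenotypeMatrix,
    C: CovariateBundle,
    truth: GroundTruth,
    config: SimulationConfig,
) -> TraitMatrix:
    """Beta-scale methylation at X-chromosomal and autosomal CpGs.

    beta = baseline + planted genetic effects (females only when the locus
    is female-specific) + cell-count loadings + latent loadings + cohort
    intercepts + Gaussian noise, truncated to [0, 1].  X-linked target sets
    use the locus effect with a per-CpG sign kept with probability
    direction_consistency; autosomal trans targets are sex-shared.
    """
    if G.sample_ids != C.sample_ids:
        raise ValueError("genotype and covariate sample sets differ")
    rng = _rng(config, "methylation")
    n = G.n_samples
    n_x, n_auto = config.n_x_cpgs, config.n_autosomal_cpgs
    n_cpg = n_x + n_auto
    x_len = config.chromosome_lengths.get("chrX", 15_000_000)

    x_pos = np.sort(rng.integers(1, x_len + 1, size=n_x))
    auto_chrom, auto_pos = _draw_positions(
        rng, config.autosomes, config.chromosome_lengths, n_auto
    )
    # keep planted trans targets clearly in trans: different chromosome
    for pl in config.planted_loci:
        v_chrom = str(G.variants["chrom"].iloc[pl.variant_index])
        others = [c for c in config.autosomes if c != v_chrom]
        for t in pl.trans_autosomal_cpg_indices:
            if t >= n_auto:
                raise ValueError("trans target index outside the autosomal CpG set")
            if auto_chrom[t] == v_chrom:
                auto_chrom[t] = others[t % len(others)]
    features = pd.DataFrame(
        {
            "id": [f"cgX{i + 1:05d}" for i in range(n_x)]
            + [f"cgA{i + 1:05d}" for i in range(n_auto)],
            "chrom": np.concatenate([np.repeat("chrX", n_x), auto_chrom]),
            "start": np.concatenate([x_pos, auto_pos]),
            "end": np.concatenate([x_pos + 1, auto_pos + 1]),
            "strand": ".",
        }
    )
    baseline = rng.uniform(*config.baseline_beta_range, size=n_cpg)
    conf, loadings = _confounding(
        rng, C, n_cpg, config.cell_count_sd, config.latent_sd, config.cohort_shift_sd
    )
    values = baseline[None, :] + conf
    female = C.is_female()
    for pl in config.planted_loci:
        dose = G.dosages[:, pl.variant_index]
        vid = str(G.variants["id"].iloc[pl.variant_index])
        signs: dict[str, int] = {}
        for t in pl.target_cpg_indices:
            if t >= n_x:
                raise ValueError("target CpG index outside the X CpG set")
            s = 1 if rng.random() < pl.direction_consistency else -1
            cid = str(features["id"].iloc[t])
            signs[cid] = s
            effect = s * pl.per_allele_effect_beta * dose
            if pl.female_specific:
                effect = np.where(female, effect, 0.0)
            values[:, t] += effect
        for t in pl.trans_autosomal_cpg_indices:
            cid = str(features["id"].iloc[n_x + t])
            signs[cid] = 1
            values[:, n_x + t] += pl.per_allele_effect_beta * dose
        truth.effect_signs.setdefault(vid, {}).update(signs)
    if config.noise_sd > 0:
        values = values + rng.normal(0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    truth.confounder_loadings["methylation"] = loadings
    truth.latent_scores = C.latent
    return TraitMatrix(list(G.sample_ids), features, values, "beta")


def simulate_expression(
    G: GenotypeMatrix,
    C: CovariateBundle,
    truth: GroundTruth,
    config: SimulationConfig,
) -> TraitMatrix:
    """Gene expression with planted cis effects.

    expression = baseline + cis_effect * dosage + confounding + noise; the
    planted cis gene is placed within 100 kb of its variant (well inside the
    250 kb cis window).  Raises if a configured cis gene cannot be placed in
    cis (variant too close to a chromosome end is repositioned instead).
    """
    if G.sample_ids != C.sample_ids:
        raise ValueError("genotype and covariate sample sets differ")
    rng = _rng(config, "expression")
    n, g = G.n_samples, config.n_genes
    chrom, start = _draw_positions(rng, config.autosomes, config.chromosome_lengths, g)
    length = rng.integers(5_000, 50_000, size=g)
    for pl in config.planted_loci:
        if pl.cis_gene_index is None:
            continue
        if pl.cis_gene_index >= g:
            raise ValueError("cis_gene_index outside the gene set")
        j = pl.cis_gene_index
        v_chrom = str(G.variants["chrom"].iloc[pl.variant_index])
        v_pos = int(G.variants["pos"].iloc[pl.variant_index])
        chrom[j] = v_chrom
        start[j] = max(1, v_pos + 50_000)
    end = start + length
    features = pd.DataFrame(
        {
            "id": [f"gene{i + 1:04d}" for i in range(g)],
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": np.where(rng.random(g) < 0.5, "+", "-"),
        }
    )
    baseline = rng.normal(5.0, 1.0, size=g)
    conf, loadings = _confounding(
        rng, C, g, config.cell_count_sd * 5, config.latent_sd * 5, config.cohort_shift_sd * 5
    )
    values = baseline[None, :] + conf
    for pl in config.planted_loci:
        if pl.cis_gene_index is None:
            continue
        j = pl.cis_gene_index
        v_pos = int(G.variants["pos"].iloc[pl.variant_index])
        dist = max(0, int(features["start"].iloc[j]) - v_pos, v_pos - int(features["end"].iloc[j]))
        if dist > 250_000:
            raise ValueError("planted cis gene lies outside the 250 kb cis window")
        values[:, j] += pl.cis_effect * G.dosages[:, pl.variant_index]
    values = values + rng.normal(0, config.expression_noise_sd, size=values.shape)
    truth.confounder_loadings["expression"] = loadings
    return TraitMatrix(list(G.sample_ids), features, values, "expression")


def simulate_annotations(
    cpg_features: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
    enrichment_factor: float = 10.0,
    background_rate: float = 0.05,
) -> AnnotationSet:
    """Annotation tracks in which planted target CpGs are preferentially
    placed: a CGI track, two histone-mark datasets, and a TSS table with
    XCI-escape classes.

    A CpG joins a context with probability `background_rate`, elevated to
    min(1, enrichment_factor * background_rate) for planted target CpGs.
    Intervals are emitted as +-250 bp around member CpG positions (merged);
    the TSS table places a class-carrying TSS within 10 kb of ~80% of CpGs,
    leaving the rest unannotated.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = _rng(config, "annotations")
    x = cpg_features[cpg_features["chrom"].astype(str).str.lower().isin(["chrx", "x"])]
    x = x.reset_index(drop=True)
    planted_ids: set[str] = set()
    for vid, signs in truth.effect_signs.items():
        planted_ids |= {c for c in signs if c.startswith("cgX")}
    is_planted = x["id"].isin(planted_ids).values
    p_bg = background_rate
    p_pl = min(1.0, enrichment_factor * background_rate)

    def _member(extra_rng_draws=None):
        p = np.where(is_planted, p_pl, p_bg)
        return rng.random(len(x)) < p

    def _intervals(member_mask):
        pos = x["start"].values[member_mask]
        iv = sorted((max(1, int(p) - 250), int(p) + 250) for p in pos)
        merged: list[list[int]] = []
        for s, e in iv:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return pd.DataFrame(
            {"chrom": "chrX", "start": [m[0] for m in merged], "end": [m[1] for m in merged]}
        )

    cgi_member = _member()
    tracks = {"CGI": _intervals(cgi_member)}
    hk_member = {}
    for ds in ("H3K4me3_gm12878", "H3K4me3_k562"):
        m = _member()
        hk_member[ds] = m
        tracks[ds] = _intervals(m)

    # escape classes via nearest TSS: ~80% of CpGs get a TSS within 10 kb
    has_tss = rng.random(len(x)) < 0.8
    esc_variable = rng.random(len(x)) < np.where(is_planted, min(1.0, enrichment_factor * 0.10), 0.10)
    classes = np.where(
        esc_variable,
        "variable",
        np.where(rng.random(len(x)) < 0.18, "escape", "subject"),
    )
    tss_rows = []
    for i in np.flatnonzero(has_tss):
        offset = int(rng.integers(-5_000, 5_001))
        tss_rows.append(
            {
                "chrom": "chrX",
                "pos": max(1, int(x["start"].iloc[i]) + offset),
                "strand": "+",
                "gene": f"xgene{i + 1:04d}",
                "class": classes[i],
            }
        )
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "gene", "class"])
    for i in range(len(x)):
        truth.annotation_assignment[str(x["id"].iloc[i])] = {
            "cgi": "island" if cgi_member[i] else "non-CGI",
            "escape": str(classes[i]) if has_tss[i] else "unannotated",
        }
    return AnnotationSet(tracks, tss)


def simulate_all(config: SimulationConfig, enrichment_factor: float = 10.0):
    """Run every generator stage; returns (G, G_x, C, Y, E, annotations, truth)."""
    truth = GroundTruth(planted_loci=list(config.planted_loci))
    G = simulate_genotypes(config)
    Gx = simulate_x_genotypes(config)
    C = simulate_covariates(config)
    Y = simulate_methylation(G, C, truth, config)
    E = simulate_expression(G, C, truth, config)
    ann = simulate_annotations(Y.features, truth, config, enrichment_factor)
    truth.sentinel_ids = [
        str(G.variants["id"].iloc[pl.variant_index]) for pl in config.planted_loci
    ]
    for pl in config.planted_loci:
        sid = str(G.variants["id"].iloc[pl.variant_index])
        truth.proxy_ids[sid] = [
            str(G.variants["id"].iloc[pl.variant_index + k])
            for k in range(1, pl.n_ld_proxies + 1)
            if pl.variant_index + k < config.n_variants
        ]
    return G, Gx, C, Y, E, ann, truth


def default_planted_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-scale synthetic configuration with one planted
    female-specific locus: MAF 0.3, -0.015 beta per allele at 50 of 500 X
    CpGs, a cis gene effect of -0.13 and 20 autosomal trans targets."""
    locus = PlantedLocus(
        variant_index=100,
        maf=0.3,
        target_cpg_indices=tuple(range(0, 500, 10)),
        per_allele_effect_beta=-0.015,
        female_specific=True,
        direction_consistency=1.0,
        cis_gene_index=7,
        cis_effect=-0.13,
        trans_autosomal_cpg_indices=tuple(range(0, 40, 2)),
        n_ld_proxies=2,
        proxy_r2=0.9,
    )
    params = dict(seed=seed, planted_loci=[locus])
    params.update(overrides)
    return SimulationConfig(**params)
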
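# Methods

## Scope and model

`xscan` implements a discovery procedure for autosomal variants that alter
DNA methylation across the X chromosome in a female-specific way. The core
is mass-univariate OLS: for variant *i* and trait *j*,
`y_j = β_ij x_i + γM + δU + ε`, Wald t for `β_ij`, two-sided p from the t
distribution with `df = n − (#design columns)`. The two-sided convention is
fixed as `2·(1 − F_t(|t|, df))`. The engine uses the Frisch–Waugh–Lovell
projection (QR-based): dosages and traits are residualized on
`[1 | M | U]` once, after which every (variant, trait) slope is a simple
regression of residuals — exactly equal to the full multiple regression,
computed for all pairs with two matrix products. An independent
statsmodels OLS fit verifies this equivalence in the test suite to 1e-10.

Per variant the per-CpG p-values are combined with the Simes procedure,
`P_i = min_j m·p_(j)/j`, capped at 1 — a valid global test under
independence or positive dependence, here justified because CpGs are
modelled as conditionally independent given covariates and latent factors.
`P_i < 5×10⁻⁸` is genome-wide significant (configurable `genomewide_alpha`).

### Conditional locus discovery

Iterative: scan, take the variant with the smallest overall P below alpha
as the next sentinel, append its dosage to the covariates, rescan; stop
when nothing passes. Variants that become collinear with the conditioned
set (including each sentinel itself) get `overall_p = NaN` and are excluded
rather than aborting the scan. A hard cap of 100 iterations guarantees
termination; mutually collinear sentinels stop the loop with a warning.

### Female-specificity and interaction

A locus is female-specific iff the minimum male overall P across the
sentinel and all LD proxies (Pearson dosage r² ≥ 0.8 within 1 Mb, computed
in the male stratum, pairwise-complete on missing dosages) exceeds 0.05.
A separate reporting column flags male replication at the stricter
1.1×10⁻⁶ threshold: the two thresholds serve different claims (exclusion
vs. positive replication) and are kept as independent configurables.
The genotype×sex interaction fits
`y = β₁x + β₂sex + β₃(x·sex) + γM + δU`, Simes-combines the per-CpG `β₃`
p-values, and compares against 5.9×10⁻⁴ (configurable; its
multiple-testing basis is not derivable, so it is exposed rather than
computed).

Note an inherent property of the exclusion rule: under the null in males
the minimum overall P over the sentinel plus correlated proxies behaves
like roughly one-to-two uniform draws, so a truly female-specific locus is
*expected* to fail the >0.05 rule in a few percent of datasets. The power
benchmarks reflect this (~0.95 pass rate), and it is a property of the
rule, not of the implementation.

### Replication

Per replication cohort, each sentinel is regressed on every X CpG with no
covariates (traits are inverse-normal-transformed within cohort first; a
flag adds covariates). Per CpG the t statistics are combined with
Stouffer's weighted Z using cohort sample sizes as weights; cohorts with a
missing t (zero dosage variance) are excluded from numerator and
denominator alike. Z → two-sided normal p → Simes per variant → Bonferroni
across the sentinels carried to replication (the multiplier is the number
of sentinels actually tested, never a constant). Treating t as z is
accurate at the intended per-cohort sizes (hundreds); the synthetic
benchmarks use n ≥ 100 per cohort.

### QTL mapping

* cis-eQTL: genes whose interval lies within 250 kb (closed window; distance
  = minimum point-to-interval distance) of the sentinel; covariates + latent
  factors; Bonferroni over the genes tested per variant.
* CpG→expression: same window anchored on the CpG; known covariates only.
* trans-meQTL: autosomal CpGs on another chromosome, or strictly >5 Mb away
  on the same chromosome; combined sexes with sex as covariate; BH FDR
  within each variant's p-vector.
* Epistasis check: per associated X CpG, the strongest Bonferroni-significant
  X-linked cis SNP within 250 kb (ties broken toward the lower position) is
  added as a covariate and the autosomal effect re-estimated. With no cis
  SNP the adjusted estimate equals the unadjusted one exactly; a cis SNP
  collinear with the autosomal variant raises an error, since that cannot
  happen for unlinked chromosomes and signals corrupted input.

### Annotation and enrichment

CGI classes: island inside any CGI interval; shore within a closed 2,000 bp
flanking band; else non-CGI. Interval tracks follow the "any dataset of the
mark" rule (track names `MARK_dataset`). XCI-escape class comes from the
nearest TSS if within 10 kb (ties toward the smaller position), else
unannotated. Enrichment of a CpG set against the X-wide background (which
contains the target) uses the exact two-sided Fisher test on
`[[target∩ann, target∖ann], [rest∩ann, rest∖ann]]`. *Fold* is the ratio of
proportions `(k/n)/(K/N)` — not the odds ratio — so depletion can be
reported as `1/fold` on the same scale. All coordinates are 1-based
inclusive internally; BED stays 0-based half-open on disk with a single
conversion site in `xscan.io`.

### Direction consistency

Exact two-sided sign test against 1/2: `p = 2·min(P[X≤k], P[X≥k], 1/2)`,
computed with integer binomial tail sums (10/10 → 2⁻⁹ exactly;
56/57 → 2·58/2⁵⁷ ≈ 8.05×10⁻¹⁶).

## Preprocessing

* Variant QC retains exactly info ≥ 0.5, HWE p ≥ 10⁻⁴ (in-package exact
  HWE test, enumerating heterozygote counts conditional on allele counts),
  call rate ≥ 0.95, MAF ≥ 0.01; boundaries retained; idempotent; per-
  criterion removal counts logged. Missing dosages are mean-imputed per
  variant (and counted) because OLS needs complete predictors and imputed
  dosage data has no missingness in the intended use.
* Rank-based inverse-normal transform within cohort with the Blom offset:
  `Φ⁻¹((r − 3/8)/(n + 1/4))`, average ranks on ties; a constant cohort is
  an error. With heavy ties (e.g. many beta values truncated at 0) the
  within-cohort mean is no longer exactly zero — expected behaviour.
* Categorical covariates (cohort, batch, sex) are reference-coded
  indicators; rank deficiency is reported with the names of the collinear
  columns (greedy rank-growth attribution).
* Latent confounders: PCA on the covariate-residualized,
  feature-standardized trait matrix; scores scaled to unit variance;
  `q = argmax_k (λ_k − λ_{k+1})`, k ≤ q_max (default 10). Estimating from
  residuals makes the factors orthogonal to known covariates by
  construction. This estimator is a deliberately simple, fully specified
  stand-in for joint confounder-adjustment models; factors are estimated
  within the analysis stratum (females for the female scan).

**Known limitation — signal absorption.** When the genetic signal is dense
relative to the panel (≳10–25% of CpGs affected at large effect), the
leading principal components partially absorb it; conditioning on them then
deflates power and inflates the per-CpG empirical FDR around a true
sentinel. At study-like proportions (tens of affected CpGs among hundreds
to thousands) the distortion is negligible — the type-I and FDR benchmarks
run at those proportions, and the test suite documents the degradation at
denser ones. Passing tests therefore speak to the sparse-signal regime the
method targets, not to arbitrarily dense architectures.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, on a
miniature genome (four 30 Mb autosomes + 15 Mb X by default) so that the
250 kb / 1 Mb / 5 Mb / 10 kb window logic is exercised with realistic
arithmetic:

* Genotypes: dosages drawn as Binomial(2, MAF) per sample (Hardy–Weinberg),
  MAF ~ U(0.05, 0.5) unless planted; metadata carries true MAF, empirical
  exact-HWE p, call rate 1, info 1. LD proxies for a planted locus copy the
  sentinel's genotypes and resample each sample with probability
  1 − √r², giving dosage correlation √r² in expectation; proxies sit within
  100 kb of the sentinel.
* Covariates: six blood cell counts, lognormal around typical 10⁹/l values
  (SD 0.25 on the log scale, strictly positive); age U(18, 80); cohorts
  round-robin; batch a crossed two-level factor (batch nested in cohort
  would be collinear with cohort in the fixed-effects design); latent
  scores standard normal, standardized to exactly unit variance.
* Methylation: per-CpG baseline U(0.026, 0.55) (the observed spread of
  mean methylation per CpG); value = baseline + planted genetic effects
  (females only when female-specific; per-CpG sign kept with probability
  `direction_consistency`) + cell-count loadings (SD 0.01) + latent
  loadings (SD 0.01 per factor) + per-cohort intercepts (SD 0.01) +
  Gaussian noise (SD 0.02), truncated to [0, 1]. Gaussian-on-beta keeps
  planted effects directly interpretable in % methylation per allele; the
  truncation attenuates effects at baselines near the boundary, which is
  why effect-recovery figures sit slightly below the planted −1.5%
  (≈ −1.3% recovered). The default planted effect (−0.015 at 50 of 500 X
  CpGs, MAF 0.3) mirrors a per-allele effect of about 1% at dozens of CpGs.
  Residual variance at affected CpGs is chosen for desk-scale power, not
  measured realism.
* Expression: baseline N(5, 1) + cis effect × dosage + (stronger)
  confounding + noise SD 0.3; planted cis genes are placed ~50 kb from
  their variant, inside the 250 kb window; default planted cis effect
  −0.13 per allele.
* Annotations: a CpG joins CGI / chromatin contexts with probability 0.05,
  elevated to `min(1, 10 × 0.05)` for planted targets (enrichment factor
  configurable); intervals are ±250 bp around member CpGs, merged. ~80% of
  CpGs get a TSS within 10 kb carrying an escape class (escape/variable/
  subject ≈ 0.15/0.10/0.75 background; the variable rate is elevated by
  the enrichment factor for planted CpGs). With dense CpG panels the
  ±250 bp intervals would blur target/background membership, so the
  enrichment benchmark spaces 10,050 CpGs over 150 Mb (~15 kb apart),
  matching array-like density.
* Determinism: every stage draws from `SeedSequence([master_seed,
  stage_index])`, so identical configs give bit-identical outputs and any
  stage can be regenerated alone. Not modelled: read-level data, probe
  intensities, imputation uncertainty, realistic LD beyond the proxy
  blocks, sex chromosomes' true copy-number structure (X genotypes are
  drawn diploid; the analysis consumes dosage vectors only).

## Pipeline, seeds and problem sizes

`xscan run` executes simulate → preprocess (per stratum) → scan →
conditional discovery → male validation → interaction → per-CpG effects
(re-estimated on the raw beta scale for reporting, since tests run on the
inverse-normal scale) → replication (an independently simulated 3×500
female sample sharing the planted loci, per-cohort model without
covariates) → QTL mapping → enrichment → evaluation against the truth
sidecar. The manifest records the config snapshot, seed, per-stage counts
and SHA-256 hashes of every result table; a rerun with an unchanged config
whose outputs still hash identically is reused rather than recomputed.
Default scale: 1,000 females + 600 males, 3 cohorts, 2,000 autosomal
variants, 500 X + 300 autosomal CpGs, 50 genes — minutes on one CPU. The
benchmark experiments (`xscan.evaluation`) keep the discovery n and CpG
proportions but use variant panels of 100–1,000 and 5–20 seeds per
experiment; all seeds derive from one base seed via `SeedSequence`.

A discovered locus counts as recovered if its sentinel is the planted
variant or one of its recorded LD proxies; CpG-level recall/FDR and sign
accuracy are computed against the planted target set of the matched locus.

## Design choices on genuinely open points

* Simes ties are handled by a stable sort (the formula is tie-safe).
* The latent-factor count search is bounded at 10; factors for the eQTL
  stage reuse the methylation-derived bundle rather than re-estimating on
  expression (one fewer estimator; the planted confounding is shared).
* "Trans" includes inter-chromosomal pairs; ">5 Mb" is strict.
* The cis window is closed (a gene at exactly 250,000 bp is tested).
* Per-tissue escape classes are carried as one column per tissue and tested
  per designated column; no cross-tissue combination rule.
* The exact sign test is reported as implemented; printed direction
  p-values in the motivating literature for cases like 56/57 do not match
  any exact-binomial convention at these counts, so no attempt is made to
  reproduce them.
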
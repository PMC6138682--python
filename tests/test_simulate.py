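"""Synthetic-cohort generator: planted structure must be statistically
recoverable and generation must be fully deterministic."""

import numpy as np
import pytest

from xscan.config import PlantedLocus, SimulationConfig
from xscan.simulate import (
    GroundTruth,
    simulate_all,
    simulate_annotations,
    simulate_covariates,
    simulate_genotypes,
    simulate_methylation,
    simulate_expression,
)
from xscan.stats import hwe_exact_test
from tests.conftest import small_config


def _truth(cfg):
    return GroundTruth(planted_loci=list(cfg.planted_loci))


class TestGenotypes:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_variants=0)
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(baseline_beta_range=(0.2, 1.2))

    def test_symmetric_maf_recovers_half(self):
        cfg = SimulationConfig(
            n_females=4000, n_males=1000, maf_range=(0.5, 0.5), n_variants=30,
            n_x_variants=5, seed=1,
        )
        G = simulate_genotypes(cfg)
        freq = G.dosages.mean(axis=0) / 2
        se = np.sqrt(0.5 * 0.5 / (2 * cfg.n_samples))
        assert np.all(np.abs(freq - 0.5) < 3.5 * se)

    def test_determinism_bit_identical(self):
        cfg = small_config(seed=11)
        a = simulate_all(cfg)
        b = simulate_all(cfg)
        np.testing.assert_array_equal(a[0].dosages, b[0].dosages)  # autosomal panel
        np.testing.assert_array_equal(a[3].values, b[3].values)    # methylation
        np.testing.assert_array_equal(a[4].values, b[4].values)    # expression
        assert a[0].variants.equals(b[0].variants)
        assert a[5].tss_table.equals(b[5].tss_table)

    def test_hwe_class_proportions(self):
        """n = 10,000 at MAF 0.3: genotype classes near (0.49, 0.42, 0.09)."""
        cfg = SimulationConfig(
            n_females=9000, n_males=1000, maf_range=(0.3, 0.3), n_variants=10,
            seed=3,
        )
        G = simulate_genotypes(cfg)
        n = cfg.n_samples
        for j in range(5):
            g = G.dosages[:, j]
            props = np.array([(g == 0).mean(), (g == 1).mean(), (g == 2).mean()])
            expected = np.array([0.49, 0.42, 0.09])
            se = np.sqrt(expected * (1 - expected) / n)
            assert np.all(np.abs(props - expected) < 3.5 * se)

    def test_hwe_exact_p_rarely_small(self):
        """With n >= 5,000 the exact HWE p exceeds 1e-4 for >= 99% of variants."""
        cfg = SimulationConfig(
            n_females=5000, n_males=1000, n_variants=300, seed=5
        )
        G = simulate_genotypes(cfg)
        assert (G.variants["hwe_p"] > 1e-4).mean() >= 0.99

    def test_ld_proxies_reach_target_r2(self):
        cfg = small_config(seed=2, n_females=2000, n_males=10)
        G = simulate_genotypes(cfg)
        pl = cfg.planted_loci[0]
        x = G.dosages[:, pl.variant_index]
        for k in (1, 2):
            r2 = np.corrcoef(x, G.dosages[:, pl.variant_index + k])[0, 1] ** 2
            assert r2 > 0.8
        # proxies sit on the sentinel's chromosome within the proxy window
        v = G.variants
        assert v["chrom"].iloc[pl.variant_index + 1] == v["chrom"].iloc[pl.variant_index]
        assert abs(v["pos"].iloc[pl.variant_index + 1] - v["pos"].iloc[pl.variant_index]) <= 1_000_000

    def test_metadata_contract(self):
        G = simulate_genotypes(small_config())
        assert (G.variants["call_rate"] == 1.0).all()
        assert (G.variants["info"] == 1.0).all()
        assert set(G.variants["chrom"]) <= {"chr1", "chr2", "chr3", "chr4"}


class TestCovariates:
    def test_cohort_levels_and_positivity(self):
        cfg = small_config(n_cohorts=6)
        C = simulate_covariates(cfg)
        assert C.table["cohort"].nunique() == 6
        from xscan.datatypes import CELL_COUNT_COLUMNS

        assert (C.table[CELL_COUNT_COLUMNS].values > 0).all()

    def test_latent_block_empty_when_disabled(self):
        C = simulate_covariates(small_config(n_latent_factors=0))
        assert C.latent.shape[1] == 0

    def test_latent_unit_variance(self):
        C = simulate_covariates(small_config(n_latent_factors=4))
        np.testing.assert_allclose(C.latent.std(axis=0), 1.0, atol=1e-12)


class TestMethylation:
    def test_planted_effect_size_recovered_per_allele(self):
        """Female dosage-group means differ by the planted per-allele effect."""
        # baselines away from 0 so [0,1] truncation cannot attenuate the slope
        cfg = small_config(
            seed=9, n_females=4000, n_males=100,
            baseline_beta_range=(0.15, 0.5),
            planted_loci=[PlantedLocus(
                variant_index=5, maf=0.4, target_cpg_indices=(3,),
                per_allele_effect_beta=-0.016, female_specific=True,
            )],
        )
        truth = _truth(cfg)
        G = simulate_genotypes(cfg)
        C = simulate_covariates(cfg)
        Y = simulate_methylation(G, C, truth, cfg)
        fem = C.is_female()
        x, y = G.dosages[fem, 5], Y.values[fem, 3]
        slope = np.polyfit(x, y, 1)[0]
        resid_sd = np.std(y - np.polyval(np.polyfit(x, y, 1), x))
        se = resid_sd / (np.std(x) * np.sqrt(fem.sum()))
        assert abs(slope - (-0.016)) < 3 * se
        # males: no effect
        xm, ym = G.dosages[~fem, 5], Y.values[~fem, 3]
        slope_m = np.polyfit(xm, ym, 1)[0]
        se_m = np.std(ym) / (np.std(xm) * np.sqrt((~fem).sum()))
        assert abs(slope_m) < 3 * se_m

    def test_zero_noise_zero_effects_returns_baselines(self):
        cfg = small_config(
            planted_loci=[], noise_sd=0.0, cell_count_sd=0.0,
            latent_sd=0.0, cohort_shift_sd=0.0, n_latent_factors=0,
        )
        truth = _truth(cfg)
        G = simulate_genotypes(cfg)
        C = simulate_covariates(cfg)
        Y = simulate_methylation(G, C, truth, cfg)
        assert np.allclose(Y.values, Y.values[0:1, :])  # every sample identical
        lo, hi = cfg.baseline_beta_range
        assert Y.values.min() >= lo - 1e-12 and Y.values.max() <= hi + 1e-12

    def test_beta_bounds_always_hold(self):
        _, G, Gx, C, Y, E, ann, truth = (None, *simulate_all(small_config(seed=123)))
        assert Y.values.min() >= 0 and Y.values.max() <= 1

    def test_direction_consistency_flips_signs(self):
        cfg = small_config(
            seed=21,
            planted_loci=[PlantedLocus(
                variant_index=5, maf=0.4,
                target_cpg_indices=tuple(range(100)),
                per_allele_effect_beta=-0.02, direction_consistency=0.7,
            )],
        )
        truth = _truth(cfg)
        G = simulate_genotypes(cfg)
        C = simulate_covariates(cfg)
        simulate_methylation(G, C, truth, cfg)
        signs = list(truth.effect_signs.values())[0]
        frac_kept = np.mean([s == 1 for c, s in signs.items() if c.startswith("cgX")])
        assert 0.55 < frac_kept < 0.85  # binomial around 0.7


class TestExpression:
    def test_planted_cis_effect_recovered(self):
        cfg = small_config(seed=31, n_females=2000, n_males=100)
        truth = _truth(cfg)
        G = simulate_genotypes(cfg)
        C = simulate_covariates(cfg)
        E = simulate_expression(G, C, truth, cfg)
        pl = cfg.planted_loci[0]
        x, y = G.dosages[:, pl.variant_index], E.values[:, pl.cis_gene_index]
        slope = np.polyfit(x, y, 1)[0]
        resid_sd = np.std(y - np.polyval(np.polyfit(x, y, 1), x))
        se = resid_sd / (np.std(x) * np.sqrt(len(x)))
        assert abs(slope - pl.cis_effect) < 3 * se
        # an unplanted gene has slope near zero
        other = 0 if pl.cis_gene_index != 0 else 1
        y0 = E.values[:, other]
        slope0 = np.polyfit(x, y0, 1)[0]
        se0 = np.std(y0) / (np.std(x) * np.sqrt(len(x)))
        assert abs(slope0) < 3 * se0

    def test_cis_gene_within_window(self):
        cfg = small_config()
        truth = _truth(cfg)
        G = simulate_genotypes(cfg)
        C = simulate_covariates(cfg)
        E = simulate_expression(G, C, truth, cfg)
        pl = cfg.planted_loci[0]
        v = G.variants.iloc[pl.variant_index]
        g = E.features.iloc[pl.cis_gene_index]
        assert g["chrom"] == v["chrom"]
        dist = max(0, g["start"] - v["pos"], v["pos"] - g["end"])
        assert dist <= 250_000


class TestAnnotations:
    def test_no_enrichment_when_factor_is_one(self):
        """factor 1: planted and background CpGs share the membership rate."""
        rates = {"planted": [], "bg": []}
        for seed in range(6):
            cfg = small_config(seed=seed)
            _, G, Gx, C, Y, E, ann, truth = (None, *simulate_all(cfg))
            ann1 = simulate_annotations(Y.features, truth, cfg, enrichment_factor=1.0)
            planted = {c for s in truth.effect_signs.values() for c in s if c.startswith("cgX")}
            assign = truth.annotation_assignment
            rates["planted"].append(
                np.mean([assign[c]["cgi"] == "island" for c in planted])
            )
            rates["bg"].append(
                np.mean([v["cgi"] == "island" for c, v in assign.items() if c not in planted])
            )
        assert abs(np.mean(rates["planted"]) - np.mean(rates["bg"])) < 0.1

    def test_factor_elevates_planted_membership(self):
        cfg = small_config(seed=3)
        _, G, Gx, C, Y, E, ann, truth = (None, *simulate_all(cfg))
        planted = {c for s in truth.effect_signs.values() for c in s if c.startswith("cgX")}
        assign = truth.annotation_assignment
        p_rate = np.mean([assign[c]["cgi"] == "island" for c in planted])
        b_rate = np.mean([v["cgi"] == "island" for c, v in assign.items() if c not in planted])
        assert p_rate > 3 * b_rate  # factor 10 with background rate 0.05

    def test_round_trip_identical_interval_sets(self, tmp_path):
        from xscan.io import read_annotations, write_annotations

        cfg = small_config(seed=4)
        _, G, Gx, C, Y, E, ann, truth = (None, *simulate_all(cfg))
        write_annotations(ann, tmp_path)
        back = read_annotations(tmp_path)
        assert set(back.interval_tracks) == set(ann.interval_tracks)
        for name in ann.interval_tracks:
            assert back.interval_tracks[name].equals(ann.interval_tracks[name])
        assert back.tss_table["pos"].tolist() == ann.tss_table["pos"].tolist()
        assert back.tss_table["class"].tolist() == ann.tss_table["class"].tolist()

    def test_every_planted_cpg_has_assignment(self):
        cfg = small_config(seed=6)
        _, G, Gx, C, Y, E, ann, truth = (None, *simulate_all(cfg))
        planted = {c for s in truth.effect_signs.values() for c in s if c.startswith("cgX")}
        assert planted <= set(truth.annotation_assignment)

    def test_enrichment_factor_below_one_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            simulate_annotations(
                simulate_all(cfg)[3].features, GroundTruth(), cfg, enrichment_factor=0.5
            )


def test_ground_truth_round_trip(tmp_path, cohort):
    cfg, G, Gx, C, Y, E, ann, truth = cohort
    truth.save(tmp_path / "truth.json")
    back = GroundTruth.load(tmp_path / "truth.json")
    assert back.sentinel_ids == truth.sentinel_ids
    assert back.proxy_ids == truth.proxy_ids
    assert back.effect_signs == truth.effect_signs
    assert back.planted_loci[0].per_allele_effect_beta == pytest.approx(
        truth.planted_loci[0].per_allele_effect_beta
    )
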
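import numpy as np
import pytest

from xscan.config import PlantedLocus, SimulationConfig
from xscan.simulate import simulate_all


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Desk-scale cohort with one strong planted female-specific locus.

    The affected CpGs stay a small fraction of the panel (10%), mirroring
    the sparsity the latent-factor adjustment assumes — a dense genetic
    signal would itself look like a latent confounder.
    """
    locus = PlantedLocus(
        variant_index=10,
        maf=0.3,
        target_cpg_indices=tuple(range(0, 200, 10)),  # 20 of 200 X CpGs
        per_allele_effect_beta=-0.03,
        female_specific=True,
        direction_consistency=1.0,
        cis_gene_index=3,
        cis_effect=-0.5,
        trans_autosomal_cpg_indices=tuple(range(0, 20, 2)),
        n_ld_proxies=2,
        proxy_r2=0.9,
    )
    params = dict(
        n_females=400,
        n_males=250,
        n_cohorts=3,
        n_variants=60,
        n_x_variants=40,
        n_x_cpgs=200,
        n_autosomal_cpgs=60,
        n_genes=20,
        seed=seed,
        planted_loci=[locus],
    )
    params.update(overrides)
    if "planted_loci" not in overrides:
        # keep the planted locus consistent with overridden panel sizes:
        # ~10% of X CpGs affected, trans targets within the autosomal set
        n_x = params["n_x_cpgs"]
        n_auto = params["n_autosomal_cpgs"]
        locus.target_cpg_indices = tuple(range(0, n_x, 10))  # 10% of the panel
        locus.trans_autosomal_cpg_indices = tuple(
            range(0, min(20, n_auto), 2)
        )
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def cohort():
    """(config, G, Gx, C, Y, E, ann, truth) for the small planted cohort."""
    cfg = small_config()
    return (cfg, *simulate_all(cfg))


@pytest.fixture(scope="session")
def female_stratum(cohort):
    """Preprocessed female discovery stratum: (G_f, Yx_f, C_f, Y_x_raw_f)."""
    from xscan.preprocess import preprocess

    cfg, G, Gx, C, Y, E, ann, truth = cohort
    fem = np.flatnonzero(C.is_female())
    is_x = (Y.features["chrom"] == "chrX").values
    Y_x = Y.subset_features(is_x)
    G_f, Yx_f, C_f, _ = preprocess(
        G.subset_samples(fem), Y_x.subset_samples(fem), C.subset_samples(fem)
    )
    return G_f, Yx_f, C_f, Y_x.subset_samples(fem)
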
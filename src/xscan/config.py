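"""Configuration objects: simulation settings, QC thresholds, analysis
windows and significance defaults, with YAML (de)serialization.

Every threshold the pipeline applies lives in one place (`AnalysisDefaults`)
so a run log can be audited against the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PlantedLocus:
    """A ground-truth genetic effect planted by the simulator.

    per_allele_effect_beta is on the methylation beta scale (e.g. -0.015 =
    1.5% hypomethylation per allele); female_specific restricts the effect
    to female samples; direction_consistency is the probability that each
    target CpG keeps the locus' effect sign (the rest are flipped).
    """

    variant_index: int
    maf: float = 0.3
    target_cpg_indices: tuple[int, ...] = ()
    per_allele_effect_beta: float = -0.01
    female_specific: bool = True
    direction_consistency: float = 1.0
    cis_gene_index: int | None = None
    cis_effect: float = 0.0
    trans_autosomal_cpg_indices: tuple[int, ...] = ()
    n_ld_proxies: int = 0
    proxy_r2: float = 0.9

    def __post_init__(self):
        self.target_cpg_indices = tuple(int(i) for i in self.target_cpg_indices)
        self.trans_autosomal_cpg_indices = tuple(int(i) for i in self.trans_autosomal_cpg_indices)
        if not 0 < self.maf <= 0.5:
            raise ValueError("planted MAF must be in (0, 0.5]")
        if not -0.1 < self.per_allele_effect_beta < 0.1:
            raise ValueError("per-allele beta effect must be in (-0.1, 0.1)")
        if not 0.5 <= self.direction_consistency <= 1.0:
            raise ValueError("direction_consistency must be in [0.5, 1]")


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    Defaults mirror the structure of a multi-biobank blood-methylation
    study: ~1000 females and 600 males across 3 cohorts, autosomal variant
    panel, X-chromosome CpGs with baselines between 2.6% and 55%
    methylation, cell-count and batch confounding and 3 latent factors.
    """

    n_females: int = 1000
    n_males: int = 600
    n_cohorts: int = 3
    n_variants: int = 2000
    n_x_variants: int = 200
    n_x_cpgs: int = 500
    n_autosomal_cpgs: int = 300
    n_genes: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    baseline_beta_range: tuple[float, float] = (0.026, 0.55)
    n_latent_factors: int = 3
    noise_sd: float = 0.02
    cell_count_sd: float = 0.01
    latent_sd: float = 0.01
    cohort_shift_sd: float = 0.01
    expression_noise_sd: float = 0.3
    seed: int = 0
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    # miniature genome: 4 autosomes + X, lengths in bp
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 30_000_000,
            "chr2": 30_000_000,
            "chr3": 30_000_000,
            "chr4": 30_000_000,
            "chrX": 15_000_000,
        }
    )

    def __post_init__(self):
        for name in (
            "n_females", "n_males", "n_cohorts", "n_variants", "n_x_cpgs",
            "n_autosomal_cpgs", "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        blo, bhi = self.baseline_beta_range
        if not (0 < blo <= bhi < 1):
            raise ValueError("baseline_beta_range must lie within (0, 1)")
        if self.n_latent_factors < 0:
            raise ValueError("n_latent_factors must be >= 0")
        self.maf_range = (float(lo), float(hi))
        self.baseline_beta_range = (float(blo), float(bhi))
        self.planted_loci = [
            pl if isinstance(pl, PlantedLocus) else PlantedLocus(**pl)
            for pl in self.planted_loci
        ]

    @property
    def n_samples(self) -> int:
        return self.n_females + self.n_males

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosome_lengths if c.lower() not in ("chrx", "x")]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "baseline_beta_range" in d:
            d["baseline_beta_range"] = tuple(d["baseline_beta_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class QCThresholds:
    """Variant QC: retain variants with info >= info_min, HWE p >= hwe_p_min,
    call rate >= call_rate_min and MAF >= maf_min."""

    info_min: float = 0.5
    hwe_p_min: float = 1e-4
    call_rate_min: float = 0.95
    maf_min: float = 0.01

    def __post_init__(self):
        for name in ("info_min", "hwe_p_min", "call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class WindowSpec:
    """Distance windows in bp: cis testing (each side), minimum trans
    distance on the same chromosome, maximum CpG-to-TSS distance for escape
    annotation, and the LD-proxy search window."""

    cis_window: int = 250_000
    trans_min_distance: int = 5_000_000
    escape_tss_max_distance: int = 10_000
    proxy_window: int = 1_000_000
    shore_width: int = 2_000

    def __post_init__(self):
        for name in (
            "cis_window", "trans_min_distance", "escape_tss_max_distance",
            "proxy_window", "shore_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cis_window >= self.trans_min_distance:
            raise ValueError("cis_window must be smaller than trans_min_distance")


@dataclass
class AnalysisDefaults:
    """Every significance threshold the pipeline applies."""

    genomewide_alpha: float = 5e-8
    male_exclusion_alpha: float = 0.05     # overall P <= this in males => not female-specific
    male_replication_alpha: float = 1.1e-6  # reporting threshold: locus replicates in males
    interaction_alpha: float = 5.9e-4
    fdr: float = 0.05
    proxy_r2_min: float = 0.8
    max_conditional_iterations: int = 100
    latent_q: str | int = "auto"
    latent_q_max: int = 10

    qc: QCThresholds = field(default_factory=QCThresholds)
    windows: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self):
        if isinstance(self.qc, dict):
            self.qc = QCThresholds(**self.qc)
        if isinstance(self.windows, dict):
            self.windows = WindowSpec(**self.windows)


@dataclass
class PipelineConfig:
    """Top-level configuration for `xscan run`."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisDefaults = field(default_factory=AnalysisDefaults)
    replication_n_cohorts: int = 3
    replication_n_per_cohort: int = 500
    out_dir: str = "xscan_out"

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisDefaults(**self.analysis)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
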
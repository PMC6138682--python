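"""In-memory containers shared by every pipeline stage.

Coordinates are 1-based inclusive internally (VCF/array-manifest convention);
BED files are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "hwe_p", "call_rate", "info"]
FEATURE_COLUMNS = ["id", "chrom", "start", "end", "strand"]
CELL_COUNT_COLUMNS = [
    "lymphocytes",
    "neutrophils",
    "monocytes",
    "eosinophils",
    "basophils",
    "red_blood_cells",
]


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant QC metadata.

    dosages: (n_samples, n_variants) floats in [0, 2]; NaN marks missing.
    variants: DataFrame with columns id, chrom, pos (1-based), ref, alt,
    maf, hwe_p, call_rate, info.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.variants["id"], "variant ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = float(finite.min()) if finite.min() < 0 else float(finite.max())
            raise ValueError(f"dosage value {bad} outside [0, 2]")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be strictly positive")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], self.variants.copy(), self.dosages[idx, :]
        )

    def subset_variants(self, mask_or_idx) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_idx)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.iloc[arr].reset_index(drop=True),
            self.dosages[:, arr],
        )

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].values == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(hits[0])

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def impute_missing(self) -> tuple["GenotypeMatrix", int]:
        """Mean-impute missing dosages per variant; returns (matrix, n_imputed)."""
        D = self.dosages.copy()
        missing = ~np.isfinite(D)
        n_missing = int(missing.sum())
        if n_missing:
            col_means = np.nanmean(np.where(missing, np.nan, D), axis=0)
            col_means = np.where(np.isfinite(col_means), col_means, 0.0)
            D[missing] = np.broadcast_to(col_means, D.shape)[missing]
        return GenotypeMatrix(list(self.sample_ids), self.variants.copy(), D), n_missing


@dataclass
class TraitMatrix:
    """Sample x feature value matrix (methylation betas, normalized values,
    or expression) with feature genomic coordinates (1-based inclusive)."""

    sample_ids: list[str]
    features: pd.DataFrame
    values: np.ndarray
    scale_tag: str = "beta"  # {beta, normalized, expression}

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.features["id"], "feature ids")
        if self.scale_tag not in {"beta", "normalized", "expression"}:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.shape != (len(self.sample_ids), len(self.features)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.features)} features"
            )
        if self.scale_tag == "beta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                bad = float(finite.min()) if finite.min() < 0 else float(finite.max())
                raise ValueError(f"beta value {bad} outside [0, 1]")
        if "strand" not in self.features.columns:
            self.features = self.features.assign(strand=".")
        self.features = self.features.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_samples(self, idx: np.ndarray) -> "TraitMatrix":
        return TraitMatrix(
            [self.sample_ids[i] for i in idx],
            self.features.copy(),
            self.values[idx, :],
            self.scale_tag,
        )

    def subset_features(self, mask_or_idx) -> "TraitMatrix":
        arr = np.asarray(mask_or_idx)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return TraitMatrix(
            list(self.sample_ids),
            self.features.iloc[arr].reset_index(drop=True),
            self.values[:, arr],
            self.scale_tag,
        )

    def feature_index(self, feature_id: str) -> int:
        hits = np.flatnonzero(self.features["id"].values == feature_id)
        if hits.size == 0:
            raise KeyError(f"feature {feature_id!r} not found")
        return int(hits[0])

    def with_values(self, values: np.ndarray, scale_tag: str | None = None) -> "TraitMatrix":
        return TraitMatrix(
            list(self.sample_ids),
            self.features.copy(),
            values,
            scale_tag or self.scale_tag,
        )


@dataclass
class CovariateBundle:
    """Known covariates M (sex, age, cohort, six cell counts, batch) plus
    estimated latent factors U per sample."""

    sample_ids: list[str]
    table: pd.DataFrame  # columns: sex, age, cohort, batch + CELL_COUNT_COLUMNS
    latent: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample ids")
        required = ["sex", "age", "cohort", "batch"] + CELL_COUNT_COLUMNS
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if len(self.table) != len(self.sample_ids):
            raise ValueError("covariate table length does not match sample ids")
        if self.table[required].isna().any().any():
            raise ValueError("covariate table contains missing values")
        bad_sex = set(self.table["sex"].unique()) - {"female", "male"}
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        self.latent = np.asarray(self.latent, dtype=float)
        if self.latent.size == 0:
            self.latent = np.empty((len(self.sample_ids), 0))
        if self.latent.shape[0] != len(self.sample_ids):
            raise ValueError("latent factor rows do not match sample ids")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].values

    def is_female(self) -> np.ndarray:
        return self.table["sex"].values == "female"

    def subset_samples(self, idx: np.ndarray) -> "CovariateBundle":
        return CovariateBundle(
            [self.sample_ids[i] for i in idx],
            self.table.iloc[idx].reset_index(drop=True),
            self.latent[idx, :],
        )

    def with_latent(self, latent: np.ndarray) -> "CovariateBundle":
        return CovariateBundle(list(self.sample_ids), self.table.copy(), latent)

    def design(
        self,
        include_latent: bool = True,
        include_sex: bool | None = None,
        extra: dict[str, np.ndarray] | None = None,
    ) -> tuple[np.ndarray, list[str]]:
        """Covariate design matrix WITHOUT intercept.

        Categorical covariates (cohort, batch, sex) are reference-coded
        indicator columns; single-level categoricals are dropped.  Sex is
        included by default only when both sexes are present.
        """
        cols: list[np.ndarray] = []
        names: list[str] = []

        cols.append(self.table["age"].values.astype(float))
        names.append("age")
        for c in CELL_COUNT_COLUMNS:
            cols.append(self.table[c].values.astype(float))
            names.append(c)
        for cat in ("cohort", "batch"):
            levels = sorted(pd.unique(self.table[cat].astype(str)))
            for lev in levels[1:]:
                cols.append((self.table[cat].astype(str).values == lev).astype(float))
                names.append(f"{cat}[{lev}]")
        n_sexes = self.table["sex"].nunique()
        if include_sex is None:
            include_sex = n_sexes == 2
        if include_sex:
            if n_sexes < 2:
                raise ValueError("sex covariate requested but only one sex present")
            cols.append((self.table["sex"].values == "male").astype(float))
            names.append("sex[male]")
        if include_latent and self.latent.shape[1]:
            for q in range(self.latent.shape[1]):
                cols.append(self.latent[:, q])
                names.append(f"latent{q + 1}")
        if extra:
            for name, vec in extra.items():
                cols.append(np.asarray(vec, dtype=float))
                names.append(name)
        W = np.column_stack(cols) if cols else np.empty((self.n_samples, 0))
        return W, names


@dataclass
class AnnotationSet:
    """Interval tracks plus a TSS table with XCI-escape classes.

    interval_tracks: track name -> DataFrame(chrom, start, end), 1-based
    inclusive internally, sorted by (chrom, start).
    tss_table: DataFrame(chrom, pos, strand, gene, class) where class in
    {escape, variable, subject} (one column per tissue is allowed; the
    default single-tissue column is named 'class').
    """

    interval_tracks: dict[str, pd.DataFrame]
    tss_table: pd.DataFrame

    def __post_init__(self):
        tracks = {}
        for name, df in self.interval_tracks.items():
            df = df[["chrom", "start", "end"]].copy()
            if (df["end"] < df["start"]).any():
                raise ValueError(f"track {name!r} has negative-length intervals")
            tracks[name] = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        self.interval_tracks = tracks
        if len(self.tss_table):
            classes = [c for c in self.tss_table.columns if c.startswith("class")]
            for c in classes:
                bad = set(self.tss_table[c].unique()) - {"escape", "variable", "subject"}
                if bad:
                    raise ValueError(f"unknown escape classes in {c}: {sorted(bad)}")
        self.tss_table = self.tss_table.reset_index(drop=True)


def align_samples(*objects):
    """Subset every object to the shared samples, in the first object's order.

    Returns (aligned objects tuple, n_dropped total across objects).
    Raises if the intersection is empty.
    """
    shared = set(objects[0].sample_ids)
    for obj in objects[1:]:
        shared &= set(obj.sample_ids)
    if not shared:
        raise ValueError("no samples shared across inputs")
    order = [s for s in objects[0].sample_ids if s in shared]
    n_dropped = sum(len(o.sample_ids) - len(order) for o in objects)
    aligned = []
    for obj in objects:
        pos = {s: i for i, s in enumerate(obj.sample_ids)}
        idx = np.array([pos[s] for s in order], dtype=int)
        aligned.append(obj.subset_samples(idx))
    return tuple(aligned), n_dropped
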
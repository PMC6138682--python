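"""Readers and writers for every on-disk format the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive (VCF/array-manifest style).
* BED files are 0-based half-open on disk; conversion happens here and
  nowhere else (`_bed_to_internal` / `_internal_to_bed` are exact inverses).
* Matrix TSVs have samples as rows (row key = sample id) and feature ids in
  the header; feature/variant metadata travels in a sibling ``*.features.tsv``
  / ``*.variants.tsv`` file.
* Floats are written with 12 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_COUNT_COLUMNS,
    AnnotationSet,
    CovariateBundle,
    GenotypeMatrix,
    TraitMatrix,
    align_samples,
)

logger = logging.getLogger("xscan")

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------- genotypes

_VCF_INFO_FIELDS = ["MAF", "HWE", "CR", "INFO"]


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage VCF (DS format field; QC metadata in INFO)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=HWE,Number=1,Type=Float,Description="Exact HWE test p-value">\n')
        fh.write('##INFO=<ID=CR,Number=1,Type=Float,Description="Call rate">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        order = np.lexsort((G.variants["pos"].values, G.variants["chrom"].values))
        for j in order:
            row = G.variants.iloc[j]
            info = (
                f"MAF={FLOAT_FMT % row['maf']};HWE={FLOAT_FMT % row['hwe_p']};"
                f"CR={FLOAT_FMT % row['call_rate']};INFO={FLOAT_FMT % row['info']}"
            )
            ds = "\t".join(
                "." if not np.isfinite(d) else FLOAT_FMT % d for d in G.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t{info}\tDS\t{ds}\n"
            )


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records, dosage_cols = [], []
    for k, var in enumerate(vcf):
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"{path}: record {k + 1} ({var.ID}) has no DS field")
        ds = np.asarray(ds, dtype=float).reshape(-1)
        ds = np.where(ds < -0.5, np.nan, ds)  # cyvcf2 encodes missing as large negative
        records.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "maf": var.INFO.get("MAF", np.nan),
                "hwe_p": var.INFO.get("HWE", np.nan),
                "call_rate": var.INFO.get("CR", np.nan),
                "info": var.INFO.get("INFO", np.nan),
            }
        )
        dosage_cols.append(ds)
    if not records:
        raise ValueError(f"{path}: no variant records")
    variants = pd.DataFrame(records)
    dosages = np.column_stack(dosage_cols)
    return _finalize_genotypes(sample_ids, variants, dosages)


def _finalize_genotypes(sample_ids, variants, dosages) -> GenotypeMatrix:
    # recompute MAF from dosages where absent
    missing_maf = ~np.isfinite(variants["maf"].values.astype(float))
    if missing_maf.any():
        with np.errstate(invalid="ignore"):
            af = np.nanmean(dosages, axis=0) / 2.0
        variants.loc[missing_maf, "maf"] = np.minimum(af, 1 - af)[missing_maf]
    n_missing = int((~np.isfinite(dosages)).sum())
    if n_missing:
        logger.info("genotypes: %d missing dosage values flagged", n_missing)
    return GenotypeMatrix(sample_ids, variants, dosages)


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(G.dosages, index=pd.Index(G.sample_ids, name="sample_id"),
                      columns=G.variants["id"])
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    G.variants.to_csv(_sidecar(path, "variants"), sep="\t", index=False,
                      float_format=FLOAT_FMT)


def _sidecar(path: Path, kind: str) -> Path:
    return path.with_suffix("").with_suffix(f".{kind}.tsv")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = _sidecar(path, "variants")
    if meta_path.exists():
        variants = pd.read_csv(meta_path, sep="\t")
    else:
        variants = pd.DataFrame(
            {"id": df.columns, "chrom": ".", "pos": np.arange(1, df.shape[1] + 1),
             "ref": ".", "alt": ".", "maf": np.nan, "hwe_p": np.nan,
             "call_rate": np.nan, "info": np.nan}
        )
    if list(variants["id"]) != list(df.columns):
        variants = variants.set_index("id").loc[df.columns].reset_index()
    return _finalize_genotypes(list(df.index.astype(str)), variants, df.values.astype(float))


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (DS field) or TSV (+ variants sidecar)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ------------------------------------------------------------------- traits

def write_traits(Y: TraitMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(Y.values, index=pd.Index(Y.sample_ids, name="sample_id"),
                      columns=Y.features["id"])
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    Y.features.to_csv(_sidecar(path, "features"), sep="\t", index=False)


def read_traits(path: str | Path, scale_tag: str = "beta") -> TraitMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = _sidecar(path, "features")
    if meta_path.exists():
        features = pd.read_csv(meta_path, sep="\t")
        if list(features["id"]) != list(df.columns):
            features = features.set_index("id").loc[df.columns].reset_index()
    else:
        features = pd.DataFrame(
            {"id": df.columns, "chrom": ".", "start": np.arange(1, df.shape[1] + 1),
             "end": np.arange(2, df.shape[1] + 2), "strand": "."}
        )
    return TraitMatrix(list(df.index.astype(str)), features, df.values.astype(float), scale_tag)


# --------------------------------------------------------------- covariates

def write_covariates(C: CovariateBundle, path: str | Path) -> None:
    path = Path(path)
    table = C.table.copy()
    table.insert(0, "sample_id", C.sample_ids)
    for q in range(C.latent.shape[1]):
        table[f"latent{q + 1}"] = C.latent[:, q]
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path: str | Path) -> CovariateBundle:
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "sex", "age", "cohort", "batch"] + CELL_COUNT_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: covariate file missing columns {missing}")
    if df[required].isna().any().any():
        bad = df[required].isna().any()
        raise ValueError(f"{path}: missing covariate values in {list(bad[bad].index)}")
    latent_cols = sorted(
        [c for c in df.columns if c.startswith("latent")],
        key=lambda c: int(c.removeprefix("latent")),
    )
    latent = df[latent_cols].values.astype(float) if latent_cols else np.empty((len(df), 0))
    table = df[["sex", "age", "cohort", "batch"] + CELL_COUNT_COLUMNS].copy()
    return CovariateBundle(list(df["sample_id"].astype(str)), table, latent)


# -------------------------------------------------------------- annotations

def _bed_to_internal(start0: np.ndarray, end0: np.ndarray):
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def _internal_to_bed(start1: np.ndarray, end1: np.ndarray):
    """1-based inclusive -> 0-based half-open (exact inverse of the above)."""
    return start1 - 1, end1


def write_bed(track: pd.DataFrame, path: str | Path) -> None:
    start0, end0 = _internal_to_bed(track["start"].values, track["end"].values)
    pd.DataFrame({"chrom": track["chrom"], "start": start0, "end": end0}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: BED interval with end < start")
    start1, end1 = _bed_to_internal(df["start"].values, df["end"].values)
    out = pd.DataFrame({"chrom": df["chrom"], "start": start1, "end": end1})
    return out.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    tss.to_csv(path, sep="\t", index=False)


def read_tss_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: TSS table needs columns {sorted(required)}")
    return df


def write_annotations(ann: AnnotationSet, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, track in ann.interval_tracks.items():
        write_bed(track, out_dir / f"{name}.bed")
    write_tss_table(ann.tss_table, out_dir / "tss.tsv")


def read_annotations(
    bed_paths: dict[str, str | Path] | str | Path,
    tss_path: str | Path | None = None,
) -> AnnotationSet:
    """Load interval tracks and the TSS table.

    Either pass a directory written by :func:`write_annotations`, or a
    mapping of track name -> BED path plus an explicit ``tss_path``.
    """
    if isinstance(bed_paths, (str, Path)):
        d = Path(bed_paths)
        bed_paths = {p.stem: p for p in sorted(d.glob("*.bed"))}
        tss_path = tss_path or (d / "tss.tsv")
    tracks = {name: read_bed(p) for name, p in bed_paths.items()}
    tss = read_tss_table(tss_path) if tss_path and Path(tss_path).exists() else pd.DataFrame(
        columns=["chrom", "pos", "strand", "gene", "class"]
    )
    return AnnotationSet(tracks, tss)


# ------------------------------------------------------------------ results

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as TSV with deterministic column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in sorted(tables):
        p = out_dir / f"{name}.tsv"
        tables[name].to_csv(p, sep="\t", index=False, float_format=FLOAT_FMT)
        paths[name] = p
    return paths


def read_result(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_aligned(genotypes_path, traits_path, covariates_path, scale_tag="beta",
                 genotype_format=None):
    """Load the three primary inputs and align them on shared samples.

    Returns (G, Y, C); logs the number of dropped samples.  Raises if the
    sample intersection is empty.
    """
    G = read_genotypes(genotypes_path, genotype_format)
    Y = read_traits(traits_path, scale_tag)
    C = read_covariates(covariates_path)
    (G, Y, C), n_dropped = align_samples(G, Y, C)
    if n_dropped:
        logger.info("sample alignment dropped %d non-shared sample rows", n_dropped)
    return G, Y, C
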
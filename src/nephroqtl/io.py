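"""TSV / BED / YAML input-output.

The interchange dialect is tab-delimited UTF-8 with a header row and ``.``
for missing values.  All coordinate-convention conversions live here:
variants and genes are 1-based inclusive everywhere in memory, BED files on
disk are 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GenotypeMatrix

NA = "."


def _write_tsv(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label=index_label)


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA])


def write_genotypes(geno: GenotypeMatrix, outdir) -> None:
    outdir = Path(outdir)
    # dosage matrix is stored variants x samples
    _write_tsv(geno.dosages.T, outdir / "dosages.tsv", index_label="snp")
    _write_tsv(geno.variants, outdir / "variants.tsv", index_label="snp")
    _write_tsv(geno.samples, outdir / "covariates.tsv", index_label="sample")


def read_genotypes(indir) -> GenotypeMatrix:
    indir = Path(indir)
    dosages = _read_tsv(indir / "dosages.tsv").T
    variants = _read_tsv(indir / "variants.tsv")
    variants["chrom"] = variants["chrom"].astype(str)
    samples = _read_tsv(indir / "covariates.tsv")
    dosages.index.name = "sample"
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def write_expression(expr: ExpressionMatrix, outdir) -> None:
    outdir = Path(outdir)
    _write_tsv(expr.values, outdir / "expression.tsv", index_label="gene")
    genes = expr.genes.copy()
    _write_tsv(genes, outdir / "genes.tsv", index_label="gene")
    _write_tsv(expr.batch.to_frame("batch"), outdir / "batches.tsv",
               index_label="sample")


def read_expression(indir, stage: str = "tpm") -> ExpressionMatrix:
    indir = Path(indir)
    values = _read_tsv(indir / "expression.tsv")
    genes = _read_tsv(indir / "genes.tsv")
    genes["chrom"] = genes["chrom"].astype(str)
    batch_path = indir / "batches.tsv"
    batch = _read_tsv(batch_path)["batch"] if batch_path.exists() else None
    return ExpressionMatrix(values=values, genes=genes, stage=stage, batch=batch)


def write_gwas(gwas: pd.DataFrame, path) -> None:
    _write_tsv(gwas, path, index_label="snp")


def read_gwas(path) -> pd.DataFrame:
    return _read_tsv(path)


def read_bed(path) -> pd.DataFrame:
    """Read a BED track; returns columns chrom, start, end (0-based half-open), name."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df:
        df["name"] = [f"ivl{i}" for i in range(len(df))]
    df["chrom"] = df["chrom"].astype(str)
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} BED intervals with start >= end")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def bed_to_1based(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 0-based half-open intervals to 1-based inclusive."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out


def onebased_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
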
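"""Readers and writers for the pipeline's tab-delimited and BED interfaces.

Conventions: manifest probe positions are 1-based; every emitted interval
(windows, regions, tracks, truth) is BED-style 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    mf = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(mf.columns):
        raise ValueError(f"manifest lacks columns {sorted(required - set(mf.columns))}")
    return mf


def read_betas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : max(3, df.shape[1])]
    df.columns = BED_COLUMNS + [f"col{i}" for i in range(3, df.shape[1])]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    """Write BED6+ rows: chrom, start, end, name, score, strand, extras."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df.get("name", pd.Series(range(len(df)), index=df.index)),
            "score": df.get("score", 0),
            "strand": ".",
        }
    )
    for col in extra or []:
        out[col] = df[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, header=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})


def read_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if set(df.columns) >= {"read_id", "call_string"} and "amplicon_id" not in df.columns:
        # two-column per-read variant: single anonymous amplicon and sample
        df["amplicon_id"] = "amplicon"
        df["sample_id"] = "sample"
    return df[["amplicon_id", "sample_id", "read_id", "call_string"]]


def read_associations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_global(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
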
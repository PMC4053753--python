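"""Readers and writers for the plain-text formats the pipeline uses.

Everything is tab-separated text: BED (0-based half-open) for
intervals, refFlat-style TSV for gene models, long TSV for probe
intensities, and matrix TSV (first columns fragment metadata, then
one column per sample) for methylation values.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_truth_table",
    "read_probe_table",
    "read_bed",
    "write_bed",
    "read_fragments_bed",
    "read_gene_models",
    "read_genome_table",
    "read_groups",
    "read_expression_matrix",
    "write_methylation_matrix",
    "read_methylation_matrix",
]

PROBE_COLUMNS = ["probe_id", "fragment_id", "sample_id", "group", "channel", "intensity"]


def read_truth_table(path: str | Path) -> pd.DataFrame:
    """Generator truth TSV; the direction token 'null' is a value, not NA."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def read_probe_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    return df


def read_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    """BED-style TSV; extra columns beyond the given names are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    base = ["chrom", "start", "end"]
    names = names or base + [f"col{i}" for i in range(3, df.shape[1])]
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    df[columns].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    df = read_bed(path, ["chrom", "start", "end", "fragment_id"])
    df["size"] = df["end"] - df["start"]
    return df[["fragment_id", "chrom", "start", "end", "size"]]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_genome_table(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "length"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("sample_id")["group"]


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_methylation_matrix(matrix, fragments: pd.DataFrame, path: str | Path) -> None:
    """Matrix TSV: fragment_id, chrom, start, end, size, then samples."""
    meta = fragments.set_index("fragment_id").reindex(matrix.values.index)
    out = pd.concat(
        [meta[["chrom", "start", "end", "size"]], matrix.values], axis=1
    )
    out.index.name = "fragment_id"
    out.to_csv(path, sep="\t")


def read_methylation_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Returns (values fragments x samples, sizes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = ["chrom", "start", "end", "size"]
    values = df.drop(columns=[c for c in meta_cols if c in df.columns])
    sizes = df["size"] if "size" in df.columns else (df["end"] - df["start"])
    return values, sizes
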
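"""Tabular I/O: TSV/CSV with '#'-prefixed provenance headers, BED genes
and the chromosome table.  BED coordinates are 0-based half-open."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml


def config_hash(obj: Any) -> str:
    """Stable short hash of any YAML-serializable configuration object."""
    text = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, Any] | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    """TSV or CSV by extension, '#' comments skipped."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Probe x sample count matrix (header row = sample ids)."""
    df = read_tsv(path, index_col=0)
    return df.astype(int)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Gene catalog BED: chrom, start, end, gene_id[, score, strand]."""
    names = ["chrom", "start", "end", "gene_id", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: df.shape[1]]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[["chrom", "start", "end", "gene_id", "strand"]]


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["score"] = 0
    out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_chrom_table(path: str | Path) -> pd.DataFrame:
    """Chromosome table TSV: name, length, cen_start, cen_end[, acrocentric]."""
    df = read_tsv(path, index_col=None)
    if "acrocentric" in df.columns:
        df["acrocentric"] = df["acrocentric"].astype(bool)
    return df
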
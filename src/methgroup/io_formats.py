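"""Readers and writers for every external format the pipeline touches.

All internal coordinates are 0-based half-open; readers convert at the
boundary (bismark coverage files are 1-based, BED and bedGraph are already
0-based half-open).  Writers emit deterministic TSV with fixed float
precision so reruns are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CpGSiteRecord",
    "GenomicInterval",
    "FormatError",
    "read_methylation_coverage",
    "write_methylation_coverage",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
    "read_chrom_lengths",
    "write_chrom_lengths",
    "write_results",
]

FLOAT_FORMAT = "%.6f"


class FormatError(ValueError):
    """Raised on malformed input files; message names the offending line."""


@dataclass(frozen=True)
class CpGSiteRecord:
    """A single strand-collapsed CpG observation.

    ``start`` is 0-based; ``end`` is always ``start + 1``.  ``beta`` is the
    methylation fraction (methylated reads / total reads).
    """

    chrom: str
    start: int
    beta: float
    n_meth: int
    n_total: int

    @property
    def end(self) -> int:
        return self.start + 1


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )


# ---------------------------------------------------------------------------
# methylation coverage (bismark coverage / bedGraph dialects)
# ---------------------------------------------------------------------------

def read_methylation_coverage(
    path: str | Path,
    min_coverage: int = 5,
    fmt: str = "bismark",
) -> pd.DataFrame:
    """Read a per-sample CpG methylation table.

    Parameters
    ----------
    path
        Six tab-separated columns: chrom, start, end, %methylation,
        methylated count, unmethylated count.
    min_coverage
        Sites with fewer total reads are flagged ``masked`` (excluded from
        feature matrices downstream, but retained so their read counts still
        inform coverage-based CNV calling).
    fmt
        ``"bismark"`` (1-based positions, start == end) or ``"bedgraph"``
        (0-based half-open).

    Returns
    -------
    DataFrame with columns chrom, start, end, beta, n_meth, n_total, masked,
    sorted by (chrom, start), coordinates 0-based half-open.
    """
    if fmt not in ("bismark", "bedgraph"):
        raise ValueError(f"unknown coverage format: {fmt!r}")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                pct = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from None
            if not 0.0 <= pct <= 100.0:
                raise FormatError(
                    f"{path.name}:{lineno}: %methylation {pct} outside [0, 100]"
                )
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path.name}:{lineno}: negative read count")
            n_total = n_meth + n_unmeth
            if n_total == 0 and pct != 0.0:
                raise FormatError(
                    f"{path.name}:{lineno}: zero coverage with nonzero "
                    f"%methylation {pct}"
                )
            if fmt == "bismark":
                start0 = start - 1
                if start0 < 0:
                    raise FormatError(f"{path.name}:{lineno}: position < 1")
            else:
                start0 = start
                if end != start + 1:
                    raise FormatError(
                        f"{path.name}:{lineno}: bedGraph CpG record must span "
                        f"1 bp (got {end - start})"
                    )
            beta = n_meth / n_total if n_total > 0 else pct / 100.0
            rows.append((chrom, start0, start0 + 1, beta, n_meth, n_total))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "beta", "n_meth", "n_total"]
    )
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df["masked"] = df["n_total"] < int(min_coverage)
    return df


def write_methylation_coverage(
    df: pd.DataFrame, path: str | Path, fmt: str = "bismark"
) -> None:
    """Write a coverage table in the requested dialect (inverse of the reader)."""
    if fmt not in ("bismark", "bedgraph"):
        raise ValueError(f"unknown coverage format: {fmt!r}")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            pct = 100.0 * row.beta
            if fmt == "bismark":
                s, e = row.start + 1, row.start + 1
            else:
                s, e = row.start, row.start + 1
            fh.write(
                f"{row.chrom}\t{s}\t{e}\t{pct:.6f}\t{row.n_meth}\t"
                f"{row.n_total - row.n_meth}\n"
            )


# ---------------------------------------------------------------------------
# BED (islands, genes, exons, output segments)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (>= 3 columns, 0-based half-open).

    Returns a DataFrame with columns chrom, start, end, name, strand
    (name/strand filled with "" / "." when absent), sorted by (chrom, start).
    Unknown chromosome names are permitted — no genome registry is enforced.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: BED requires >= 3 tab-separated columns"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from None
            if start < 0:
                raise FormatError(f"{path.name}:{lineno}: negative start")
            if start >= end:
                raise FormatError(
                    f"{path.name}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df]
    out = df[cols].copy()
    if "strand" in cols and "score" not in cols:
        out.insert(cols.index("strand"), "score", 0)
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene-level counts (TSV: gene_id, length_bp, one column per sample)
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a gene x sample count matrix with gene lengths.

    Returns ``(counts, lengths)`` — counts indexed by gene id with sample
    columns in file order; lengths in bp.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id" or df.columns[1] != "length_bp":
        raise FormatError(
            f"{path.name}: first two columns must be gene_id, length_bp"
        )
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path.name}: duplicate gene id {dup!r}")
    lengths = df.set_index("gene_id")["length_bp"]
    if (lengths <= 0).any():
        raise FormatError(f"{path.name}: gene lengths must be positive")
    counts = df.set_index("gene_id").drop(columns="length_bp")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or (vals < 0).any():
        raise FormatError(f"{path.name}: counts must be non-negative numbers")
    if not np.allclose(vals, np.round(vals)):
        raise FormatError(f"{path.name}: counts must be integers")
    return counts.astype(np.int64), lengths.astype(np.int64)


def write_counts(counts: pd.DataFrame, lengths: pd.Series, path: str | Path) -> None:
    out = counts.copy()
    out.insert(0, "length_bp", lengths.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets (name, description, members...) into name -> set."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT requires >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "who_grade", "location", "breed", "mitotic_index"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV; validates grades and id uniqueness."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path.name}: duplicate sample ids")
    if not df["who_grade"].isin([1, 2, 3]).all():
        raise FormatError(f"{path.name}: who_grade must be 1, 2 or 3")
    if (df["mitotic_index"] < 0).any():
        raise FormatError(f"{path.name}: negative mitotic index")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{Path(path).name}:{lineno}: expected chrom\\tlength")
            out[fields[0]] = int(fields[1])
    return out


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, n in lengths.items():
            fh.write(f"{chrom}\t{n}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV output: stable column order, fixed float precision."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each named table as ``<out_dir>/<name>.tsv``; returns the paths."""
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        write_table(df, p)
        paths.append(p)
    return paths
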
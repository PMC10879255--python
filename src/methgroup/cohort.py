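"""In-memory containers shared by all pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import read_methylation_coverage

__all__ = ["MethylationCohort", "ExpressionCohort", "TruthLedger", "load_methylation_cohort"]


@dataclass
class MethylationCohort:
    """Samples x CpG sites: beta values, read counts, site coordinates.

    ``beta``, ``n_meth``, ``n_total`` and ``masked`` are (n_samples, n_sites)
    arrays aligned with ``sites`` (a DataFrame with chrom/start/end, 0-based
    half-open, sorted by genomic position).  ``masked`` marks low-coverage
    observations excluded from feature matrices but kept for CNV coverage.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    beta: np.ndarray
    n_meth: np.ndarray
    n_total: np.ndarray
    masked: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_table(self, i: int) -> pd.DataFrame:
        """Per-sample site table in the coverage-file layout."""
        df = self.sites[["chrom", "start", "end"]].copy()
        df["beta"] = self.beta[i]
        df["n_meth"] = self.n_meth[i]
        df["n_total"] = self.n_total[i]
        df["masked"] = self.masked[i]
        return df


@dataclass
class ExpressionCohort:
    """Gene x sample counts with gene lengths (bp)."""

    counts: pd.DataFrame
    lengths: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class TruthLedger:
    """Planted structure emitted by the synthetic generator.

    labels: per-sample group label (1..k); hmr_blocks: planted hypomethylated
    blocks with owning group; cnv_segments: planted coverage segments per
    group; de_genes: planted differentially expressed genes per group.
    """

    labels: np.ndarray
    hmr_blocks: pd.DataFrame
    cnv_segments: pd.DataFrame
    de_genes: dict[int, dict[str, list[str]]] = field(default_factory=dict)
    marker_genes: list[str] = field(default_factory=list)
    # per-(group, site) true methylation fractions; diagnostic only, not
    # serialized to JSON
    true_group_beta: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        obj = {
            "labels": [int(x) for x in self.labels],
            "hmr_blocks": self.hmr_blocks.to_dict(orient="list"),
            "cnv_segments": self.cnv_segments.to_dict(orient="list"),
            "de_genes": {str(g): v for g, v in self.de_genes.items()},
            "marker_genes": self.marker_genes,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        obj = json.loads(Path(path).read_text())
        return cls(
            labels=np.asarray(obj["labels"], dtype=int),
            hmr_blocks=pd.DataFrame(obj["hmr_blocks"]),
            cnv_segments=pd.DataFrame(obj["cnv_segments"]),
            de_genes={int(g): v for g, v in obj["de_genes"].items()},
            marker_genes=list(obj["marker_genes"]),
        )


def load_methylation_cohort(
    coverage_paths: dict[str, str | Path],
    min_coverage: int = 5,
    fmt: str = "bismark",
    chrom_lengths: dict[str, int] | None = None,
) -> MethylationCohort:
    """Assemble a cohort from per-sample coverage files.

    Sites are intersected across samples (inner join on chrom/start) so the
    matrices are dense and aligned.
    """
    sample_ids = list(coverage_paths)
    tables = {
        s: read_methylation_coverage(coverage_paths[s], min_coverage, fmt)
        for s in sample_ids
    }
    common: pd.Index | None = None
    for s in sample_ids:
        idx = pd.MultiIndex.from_frame(tables[s][["chrom", "start"]])
        common = idx if common is None else common.intersection(idx)
    assert common is not None
    common = common.sort_values()
    sites = pd.DataFrame(list(common), columns=["chrom", "start"])
    sites["end"] = sites["start"] + 1
    n, m = len(sample_ids), len(sites)
    beta = np.zeros((n, m))
    n_meth = np.zeros((n, m), dtype=np.int64)
    n_total = np.zeros((n, m), dtype=np.int64)
    masked = np.zeros((n, m), dtype=bool)
    for i, s in enumerate(sample_ids):
        t = tables[s].set_index(pd.MultiIndex.from_frame(tables[s][["chrom", "start"]]))
        t = t.loc[common]
        beta[i] = t["beta"].to_numpy()
        n_meth[i] = t["n_meth"].to_numpy()
        n_total[i] = t["n_total"].to_numpy()
        masked[i] = t["masked"].to_numpy()
    return MethylationCohort(
        sample_ids=sample_ids,
        sites=sites,
        beta=beta,
        n_meth=n_meth,
        n_total=n_total,
        masked=masked,
        chrom_lengths=chrom_lengths or {},
    )
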
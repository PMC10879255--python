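"""Shared fixtures: scaled-down synthetic configurations and tiny cohorts."""

import numpy as np
import pandas as pd
import pytest

from methgroup.cohort import MethylationCohort
from methgroup.synthetic import SyntheticConfig


@pytest.fixture
def small_config() -> SyntheticConfig:
    """A scaled-down cohort (18 samples, 4,000 CpGs on two 2 Mb chromosomes)
    preserving the default generator's CpG density and effect sizes, for
    fast unit tests."""
    return SyntheticConfig(
        n_samples=18,
        n_chroms=2,
        chrom_length_bp=2_000_000,
        n_cpgs=4_000,
        n_islands=40,
        blocks_per_group=(15, 30, 15),
        cnv_segments={
            1: [("chr1", 0, 1_000_000, 0.5)],
            2: [("chr2", 0, 1_000_000, 1.5)],
            3: [("chr1", 1_000_000, 2_000_000, 1.5)],
        },
        n_genes=800,
        de_genes_per_group=60,
        n_track_genes=80,
        seed=11,
    )


def make_cohort(beta: np.ndarray, n_total: np.ndarray | int = 30,
                spacing: int = 1_000, chrom: str = "chr1",
                min_coverage: int = 5,
                chrom_length: int | None = None) -> MethylationCohort:
    """Hand-built cohort from a (samples x sites) beta matrix."""
    beta = np.asarray(beta, dtype=float)
    n, m = beta.shape
    if np.isscalar(n_total):
        n_total = np.full((n, m), n_total, dtype=np.int64)
    n_meth = np.round(beta * n_total).astype(np.int64)
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "start": np.arange(m) * spacing,
            "end": np.arange(m) * spacing + 1,
        }
    )
    return MethylationCohort(
        sample_ids=[f"S{i:02d}" for i in range(n)],
        sites=sites,
        beta=beta,
        n_meth=n_meth,
        n_total=np.asarray(n_total, dtype=np.int64),
        masked=np.asarray(n_total) < min_coverage,
        chrom_lengths={chrom: chrom_length or int(m * spacing + spacing)},
    )
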
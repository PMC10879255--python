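"""Synthetic WGBS + RNA cohort with planted group structure.

Emulates the shape of a small tumor methylome cohort: ~30 samples in 3
latent groups; beta values high genome-wide and low in CpG islands;
group-specific planted hypomethylated blocks (one group enriched for them);
binomial methylation counts at Poisson sequencing depth modulated by planted
copy-number segments; negative-binomial expression with planted group
markers; and per-sample mitotic index and WHO grade skewed toward the
proliferative, HMR-enriched group.  Every planted feature is recorded in a
TruthLedger so downstream recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .cohort import ExpressionCohort, MethylationCohort, TruthLedger
from .seeding import child_rng

__all__ = [
    "SyntheticConfig",
    "generate_methylomes",
    "generate_expression",
    "generate_metadata",
    "generate_gene_track",
    "generate_cohort",
    "write_cohort",
    "allocate_group_sizes",
]

ISLAND_FLANK_BP = 4_000  # neighborhood = island +/- shores + shelves

BREEDS = [
    "Boxer", "Golden Retriever", "Labrador Retriever", "Mixed", "Beagle",
    "German Shepherd", "Border Collie", "Poodle", "Dachshund", "Terrier",
]


@dataclass
class SyntheticConfig:
    """Knobs of the planted-structure generator.

    Defaults describe the emulated study conditions: 30 samples in three
    groups (0.40/0.35/0.25), two 10 Mb chromosomes carrying 20,000 CpGs and
    200 regularly spaced 1 kb islands, mean sequencing depth 30x, 150 planted
    hypomethylated blocks per group (300 for the HMR-enriched group 2), one
    planted CNV segment per group, 5,000 genes with 200 planted DE genes per
    group at |log2FC| = 2 and proliferation markers up in group 2.
    """

    n_samples: int = 30
    group_proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    n_chroms: int = 2
    chrom_length_bp: int = 10_000_000
    n_cpgs: int = 20_000
    n_islands: int = 200
    island_width_bp: int = 1_000
    neighborhood_frac: float = 0.60  # CpGs placed within island +/- 4 kb
    beta_open_sea: tuple[float, float] = (8.0, 2.0)   # Beta(a, b)
    beta_island: tuple[float, float] = (1.5, 8.0)
    beta_hypo_block: tuple[float, float] = (1.0, 9.0)
    blocks_per_group: tuple[int, ...] = (150, 300, 150)
    hmr_group: int = 2  # 1-based group enriched for planted blocks / markers
    block_cpgs: tuple[int, int] = (8, 20)
    block_max_gap_bp: int = 400  # planted blocks carved from CpG streaks this dense
    depth_mean: float = 30.0
    min_coverage: int = 5
    cnv_segments: dict[int, list[tuple[str, int, int, float]]] = field(
        default_factory=lambda: {
            1: [("chr1", 0, 5_000_000, 0.5)],
            2: [("chr2", 0, 5_000_000, 1.5)],
            3: [("chr1", 5_000_000, 10_000_000, 1.5)],
        }
    )
    n_genes: int = 5_000
    nb_dispersion: float = 0.1
    de_genes_per_group: int = 200
    de_log2fc: float = 2.0
    marker_genes: tuple[str, ...] = ("MKI67", "TOP2A", "FOXM1")
    marker_log2fc: float = 2.4
    marker_base_mean: tuple[float, ...] = (30.0, 80.0, 40.0)
    mitotic_index_means: tuple[float, ...] = (1.0, 6.0, 1.0)
    high_grade_prob: tuple[float, ...] = (0.15, 0.80, 0.15)
    n_track_genes: int = 400
    seed: int = 7

    def __post_init__(self) -> None:
        # normalize containers that may arrive from YAML/JSON round-trips
        self.group_proportions = tuple(self.group_proportions)
        self.blocks_per_group = tuple(self.blocks_per_group)
        self.marker_genes = tuple(self.marker_genes)
        self.marker_base_mean = tuple(self.marker_base_mean)
        self.mitotic_index_means = tuple(self.mitotic_index_means)
        self.high_grade_prob = tuple(self.high_grade_prob)
        self.block_cpgs = tuple(self.block_cpgs)
        self.cnv_segments = {
            int(g): [(str(c), int(s), int(e), float(m)) for c, s, e, m in segs]
            for g, segs in (self.cnv_segments or {}).items()
        }

    @property
    def n_groups(self) -> int:
        return len(self.group_proportions)

    def validate(self) -> None:
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if len(self.blocks_per_group) != self.n_groups:
            raise ValueError("blocks_per_group must have one entry per group")
        if not 1 <= self.hmr_group <= self.n_groups:
            raise ValueError("hmr_group out of range")
        for name in (
            "n_samples", "n_chroms", "chrom_length_bp", "n_cpgs", "n_islands",
            "island_width_bp", "n_genes", "de_genes_per_group",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.de_genes_per_group * self.n_groups > self.n_genes:
            raise ValueError("de_genes_per_group x n_groups exceeds n_genes")
        for g, segs in self.cnv_segments.items():
            if not 1 <= g <= self.n_groups:
                raise ValueError(f"cnv segment group {g} out of range")
            for chrom, s, e, mult in segs:
                if not 0 <= s < e <= self.chrom_length_bp:
                    raise ValueError(
                        f"cnv segment {chrom}:{s}-{e} outside chromosome bounds"
                    )
                if mult not in (0.5, 1.5):
                    raise ValueError("cnv multiplier must be 0.5 or 1.5")
        lo, hi = self.block_cpgs
        if not 1 <= lo <= hi:
            raise ValueError("block_cpgs must be an increasing positive pair")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def allocate_group_sizes(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n samples to groups.

    Ties on the fractional remainder go to the group with the smaller
    integer quota (then the higher index), so the allocation is deterministic
    and sums exactly to n.
    """
    quotas = [p * n for p in proportions]
    floors = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(floors)
    order = sorted(
        range(len(quotas)),
        key=lambda i: (-(quotas[i] - floors[i]), floors[i], -i),
    )
    sizes = floors[:]
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def _island_track(config: SyntheticConfig) -> pd.DataFrame:
    """Islands on a regular grid, ``n_islands`` split evenly across chroms."""
    per_chrom = config.n_islands // config.n_chroms
    extra = config.n_islands - per_chrom * config.n_chroms
    rows = []
    for ci, chrom in enumerate(config.chrom_names()):
        k = per_chrom + (1 if ci < extra else 0)
        spacing = config.chrom_length_bp / k
        for i in range(k):
            start = int(round((i + 0.5) * spacing - config.island_width_bp / 2))
            start = max(0, min(start, config.chrom_length_bp - config.island_width_bp))
            rows.append((chrom, start, start + config.island_width_bp,
                         f"island_{chrom}_{i}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def _cpg_positions(
    config: SyntheticConfig, islands: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Sample unique CpG positions: 60% in island neighborhoods, rest uniform."""
    n_in = int(round(config.neighborhood_frac * config.n_cpgs))
    n_out = config.n_cpgs - n_in
    chosen: dict[str, set[int]] = {c: set() for c in config.chrom_names()}

    nb = islands.copy()
    nb["lo"] = (nb["start"] - ISLAND_FLANK_BP).clip(lower=0)
    nb["hi"] = (nb["end"] + ISLAND_FLANK_BP).clip(upper=config.chrom_length_bp)
    alloc = rng.multinomial(n_in, np.full(len(nb), 1.0 / len(nb)))
    for (_, row), cnt in zip(nb.iterrows(), alloc):
        pool = chosen[row["chrom"]]
        target = len(pool) + cnt
        while len(pool) < target:
            pos = rng.integers(row["lo"], row["hi"], size=target - len(pool))
            pool.update(int(p) for p in pos)
    per_chrom_out = rng.multinomial(
        n_out, np.full(config.n_chroms, 1.0 / config.n_chroms)
    )
    for chrom, cnt in zip(config.chrom_names(), per_chrom_out):
        pool = chosen[chrom]
        target = len(pool) + cnt
        while len(pool) < target:
            pos = rng.integers(0, config.chrom_length_bp, size=target - len(pool))
            pool.update(int(p) for p in pos)
    rows = []
    for chrom in config.chrom_names():
        for p in sorted(chosen[chrom]):
            rows.append((chrom, p))
    df = pd.DataFrame(rows, columns=["chrom", "start"])
    df["end"] = df["start"] + 1
    return df


def _in_intervals(sites: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites falling inside any interval of the track."""
    mask = np.zeros(len(sites), dtype=bool)
    for chrom, sub in track.groupby("chrom"):
        sel = sites["chrom"] == chrom
        if not sel.any():
            continue
        pos = sites.loc[sel, "start"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        mask[np.flatnonzero(sel)] = ok
    return mask


def _plant_blocks(
    config: SyntheticConfig, sites: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Carve non-overlapping hypomethylated blocks from dense CpG streaks.

    A block is a run of consecutive CpG sites whose inter-site gaps are at
    most ``block_max_gap_bp``, so a planted block is detectable by a
    gap-bounded segmenter.  Blocks from different groups never share a site
    and are separated by at least one buffer site.
    """
    n_total_blocks = int(sum(config.blocks_per_group))
    lo, hi = config.block_cpgs
    pos = sites["start"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    # maximal streaks of sites with small gaps
    brk = np.flatnonzero(
        (chroms[1:] != chroms[:-1])
        | (np.diff(pos) > config.block_max_gap_bp)
    )
    streak_bounds = list(zip(np.r_[0, brk + 1], np.r_[brk + 1, len(pos)]))
    streaks = [(s, e) for s, e in streak_bounds if e - s >= lo]
    order = rng.permutation(len(streaks))
    blocks: list[tuple[int, int]] = []
    for si in order:
        s, e = streaks[si]
        cur = s
        while e - cur >= lo and len(blocks) < n_total_blocks:
            length = int(rng.integers(lo, hi + 1))
            length = min(length, e - cur)
            if length < lo:
                break
            blocks.append((cur, cur + length))
            cur += length + 1  # buffer site separates adjacent blocks
        if len(blocks) >= n_total_blocks:
            break
    if len(blocks) < n_total_blocks:
        raise ValueError(
            f"cannot place {n_total_blocks} non-overlapping blocks: only "
            f"{len(blocks)} dense CpG streak slots available"
        )
    perm = rng.permutation(n_total_blocks)
    rows = []
    cursor = 0
    for g, n_blocks in enumerate(config.blocks_per_group, start=1):
        for j in perm[cursor:cursor + n_blocks]:
            i0, i1 = blocks[j]
            rows.append(
                (chroms[i0], int(pos[i0]), int(pos[i1 - 1]) + 1, g, i0, i1)
            )
        cursor += n_blocks
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "group", "site_lo", "site_hi"]
    )
    if (df["end"] > config.chrom_length_bp).any() or (df["start"] < 0).any():
        raise ValueError("planted block exceeds chromosome bounds")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_methylomes(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[MethylationCohort, TruthLedger, pd.DataFrame]:
    """Simulate the WGBS side of the cohort.

    Returns the cohort, the truth ledger and the island track used for
    placement (so context annotation can reuse the exact same islands).

    Per sample and site the generative model is: a true beta drawn once per
    (group, site) — baseline Beta(8,2) in open sea / Beta(1.5,8) in islands,
    overridden by Beta(1,9) inside that group's planted blocks — then depth
    ~ Poisson(mean x CNV multiplier) and methylated reads ~ Binomial(depth,
    beta).  Fully deterministic for a fixed seed.
    """
    config.validate()
    master = config.seed if seed is None else seed
    islands = _island_track(config)
    sites = _cpg_positions(config, islands, child_rng(master, "cpg_positions"))
    blocks = _plant_blocks(config, sites, child_rng(master, "hmr_blocks"))

    rng_beta = child_rng(master, "baseline_beta")
    in_island = _in_intervals(sites, islands)
    n_sites = len(sites)
    baseline = rng_beta.beta(*config.beta_open_sea, size=n_sites)
    baseline[in_island] = rng_beta.beta(*config.beta_island, size=int(in_island.sum()))
    k = config.n_groups
    group_beta = np.tile(baseline, (k, 1))
    for row in blocks.itertuples(index=False):
        g = row.group - 1
        group_beta[g, row.site_lo:row.site_hi] = rng_beta.beta(
            *config.beta_hypo_block, size=row.site_hi - row.site_lo
        )

    sizes = allocate_group_sizes(config.n_samples, config.group_proportions)
    labels = np.concatenate(
        [np.full(sz, g + 1, dtype=int) for g, sz in enumerate(sizes)]
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]

    # per-group depth multiplier per site from planted CNV segments
    mult = np.ones((k, n_sites))
    cnv_rows = []
    pos = sites["start"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    for g, segs in config.cnv_segments.items():
        for chrom, s, e, m in segs:
            sel = (chroms == chrom) & (pos >= s) & (pos < e)
            mult[g - 1, sel] = m
            cnv_rows.append((g, chrom, s, e, m))
    cnv_truth = pd.DataFrame(
        cnv_rows, columns=["group", "chrom", "start", "end", "multiplier"]
    )

    rng_seq = child_rng(master, "sequencing")
    n = config.n_samples
    depth = np.empty((n, n_sites), dtype=np.int64)
    n_meth = np.empty((n, n_sites), dtype=np.int64)
    for i in range(n):
        g = labels[i] - 1
        depth[i] = rng_seq.poisson(config.depth_mean * mult[g])
        n_meth[i] = rng_seq.binomial(depth[i], group_beta[g])
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(depth > 0, n_meth / np.maximum(depth, 1), 0.0)
    masked = depth < config.min_coverage

    cohort = MethylationCohort(
        sample_ids=sample_ids,
        sites=sites,
        beta=beta,
        n_meth=n_meth,
        n_total=depth,
        masked=masked,
        chrom_lengths=config.chrom_lengths(),
    )
    truth = TruthLedger(
        labels=labels,
        hmr_blocks=blocks[["chrom", "start", "end", "group"]].copy(),
        cnv_segments=cnv_truth,
        marker_genes=list(config.marker_genes),
        true_group_beta=group_beta,
    )
    return cohort, truth, islands


def generate_expression(
    config: SyntheticConfig, labels: np.ndarray, seed: int | None = None
) -> tuple[ExpressionCohort, dict[int, dict[str, list[str]]]]:
    """Simulate negative-binomial counts with planted one-vs-rest DE genes.

    Each group gets ``de_genes_per_group`` planted genes (half up, half down
    at ``de_log2fc``); the proliferation markers are additionally up-shifted
    in the HMR-enriched group.
    """
    config.validate()
    master = config.seed if seed is None else seed
    labels = np.asarray(labels, dtype=int)
    if len(labels) != config.n_samples:
        raise ValueError("labels length must equal n_samples")
    rng = child_rng(master, "expression")
    k = config.n_groups
    markers = list(config.marker_genes)
    gene_ids = markers + [f"G{i:05d}" for i in range(config.n_genes - len(markers))]
    lengths = np.clip(
        np.round(rng.lognormal(np.log(2_500), 0.5, size=config.n_genes)),
        200, 50_000,
    ).astype(np.int64)
    base_mean = rng.lognormal(np.log(50.0), 1.0, size=config.n_genes)
    base_mean[: len(markers)] = np.asarray(config.marker_base_mean)[: len(markers)]

    fold = np.ones((k, config.n_genes))
    candidates = np.arange(len(markers), config.n_genes)
    picked = rng.choice(
        candidates, size=config.de_genes_per_group * k, replace=False
    )
    de_truth: dict[int, dict[str, list[str]]] = {}
    for g in range(1, k + 1):
        block = picked[(g - 1) * config.de_genes_per_group:
                       g * config.de_genes_per_group]
        half = len(block) // 2
        up, down = block[:half], block[half:]
        fold[g - 1, up] *= 2.0 ** config.de_log2fc
        fold[g - 1, down] *= 2.0 ** (-config.de_log2fc)
        de_truth[g] = {
            "up": [gene_ids[j] for j in up],
            "down": [gene_ids[j] for j in down],
        }
    hmr_g = config.hmr_group
    fold[hmr_g - 1, : len(markers)] *= 2.0 ** config.marker_log2fc
    de_truth[hmr_g]["up"] = markers + de_truth[hmr_g]["up"]

    r = 1.0 / max(config.nb_dispersion, 1e-12)
    counts = np.empty((config.n_genes, config.n_samples), dtype=np.int64)
    for i in range(config.n_samples):
        mu = base_mean * fold[labels[i] - 1]
        p = r / (r + mu)
        counts[:, i] = rng.negative_binomial(r, p)
    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    return ExpressionCohort(counts=df, lengths=pd.Series(lengths, index=df.index)), de_truth


def generate_metadata(
    config: SyntheticConfig, labels: np.ndarray, seed: int | None = None
) -> pd.DataFrame:
    """Per-sample metadata: mitotic index Poisson per group; WHO grade with
    the HMR-enriched group skewed toward grades 2-3."""
    config.validate()
    master = config.seed if seed is None else seed
    labels = np.asarray(labels, dtype=int)
    rng = child_rng(master, "metadata")
    n = len(labels)
    mit_means = np.asarray(config.mitotic_index_means)[labels - 1]
    mitotic = rng.poisson(mit_means)
    p_high = np.asarray(config.high_grade_prob)[labels - 1]
    high = rng.random(n) < p_high
    grade = np.where(high, rng.integers(2, 4, size=n), 1)
    location = rng.choice(["intracranial", "spinal"], size=n, p=[0.8, 0.2])
    breed = rng.choice(BREEDS, size=n)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n)],
            "who_grade": grade,
            "location": location,
            "breed": breed,
            "mitotic_index": mitotic,
            "group": labels,
        }
    )


def generate_gene_track(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping gene models (with strand) and their exons, for
    element annotation of HMRs.  Genes sit on a jittered grid; each gets
    2-5 exons evenly spread across its body."""
    config.validate()
    master = config.seed if seed is None else seed
    rng = child_rng(master, "gene_track")
    per_chrom = config.n_track_genes // config.n_chroms
    genes, exons = [], []
    gi = 0
    for chrom in config.chrom_names():
        slot = config.chrom_length_bp // per_chrom
        for j in range(per_chrom):
            span = int(rng.integers(5_000, min(30_000, slot - 1_000)))
            start = j * slot + int(rng.integers(0, slot - span))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"TG{gi:04d}"
            genes.append((chrom, start, end, name, strand))
            n_ex = int(rng.integers(2, 6))
            step = span / n_ex
            for x in range(n_ex):
                ex_len = int(min(rng.integers(150, 1_500), step))
                ex_start = start + int(x * step)
                exons.append((chrom, ex_start, ex_start + ex_len, name, strand))
            gi += 1
    gdf = pd.DataFrame(genes, columns=["chrom", "start", "end", "name", "strand"])
    edf = pd.DataFrame(exons, columns=["chrom", "start", "end", "name", "strand"])
    gdf = gdf.sort_values(["chrom", "start"]).reset_index(drop=True)
    edf = edf.sort_values(["chrom", "start"]).reset_index(drop=True)
    return gdf, edf


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> dict:
    """Run every generator stage; returns a dict with all artifacts."""
    cohort, truth, islands = generate_methylomes(config, seed)
    expr, de_truth = generate_expression(config, truth.labels, seed)
    truth.de_genes = de_truth
    meta = generate_metadata(config, truth.labels, seed)
    genes, exons = generate_gene_track(config, seed)
    return {
        "config": config,
        "methylation": cohort,
        "expression": expr,
        "metadata": meta,
        "truth": truth,
        "islands": islands,
        "genes": genes,
        "exons": exons,
    }


def _truth_gene_sets(config: SyntheticConfig, truth: TruthLedger) -> dict[str, set[str]]:
    """Gene sets mirroring the planted DE programs plus the marker panel."""
    sets: dict[str, set[str]] = {
        "PROLIFERATION_MARKERS": set(truth.marker_genes),
    }
    for g, d in sorted(truth.de_genes.items()):
        sets[f"GROUP{g}_UP_PROGRAM"] = set(d["up"])
        sets[f"GROUP{g}_DOWN_PROGRAM"] = set(d["down"])
    return sets


def write_cohort(artifacts: dict, out_dir: str | Path, fmt: str = "bismark") -> None:
    """Emit the generated cohort in the exact on-disk formats the readers
    accept, so the pipeline can be exercised end-to-end from files."""
    out_dir = Path(out_dir)
    cov_dir = out_dir / "coverage"
    os.makedirs(cov_dir, exist_ok=True)
    cohort: MethylationCohort = artifacts["methylation"]
    for i, s in enumerate(cohort.sample_ids):
        io_formats.write_methylation_coverage(
            cohort.sample_table(i), cov_dir / f"{s}.cov", fmt=fmt
        )
    io_formats.write_bed(artifacts["islands"], out_dir / "islands.bed")
    io_formats.write_bed(artifacts["genes"], out_dir / "genes.bed")
    io_formats.write_bed(artifacts["exons"], out_dir / "exons.bed")
    io_formats.write_chrom_lengths(cohort.chrom_lengths, out_dir / "genome.tsv")
    expr: ExpressionCohort = artifacts["expression"]
    io_formats.write_counts(expr.counts, expr.lengths, out_dir / "counts.tsv")
    io_formats.write_metadata(artifacts["metadata"], out_dir / "metadata.tsv")
    truth: TruthLedger = artifacts["truth"]
    truth.to_json(out_dir / "truth.json")
    io_formats.write_gmt(
        _truth_gene_sets(artifacts["config"], truth), out_dir / "gene_sets.gmt"
    )
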
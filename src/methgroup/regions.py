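"""Hypomethylated-region segmentation, island/shore/shelf context annotation
and coverage-based CNV segmentation.

Context geometry follows the standard CpG-density vocabulary: shores are the
+/- 2 kb flanks of islands, shelves the next +/- 2 kb, with precedence
island > shore > shelf and everything else open sea.  The HMR caller is a
transparent threshold-merge segmenter; CNVs come from summed CpG read counts
in large bins, normalized within sample and against the cohort per-bin
median, segmented by recursive binary splitting on Welch's t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MethylationCohort

__all__ = [
    "ContextTrack",
    "build_context_track",
    "call_hmrs",
    "call_hmrs_cohort",
    "annotate_hmrs",
    "hmr_summary",
    "call_cnvs",
    "genome_fraction_cnv",
]

logger = logging.getLogger("methgroup")

CONTEXT_PRECEDENCE = ["island", "shore", "shelf", "open_sea"]
ELEMENT_PRECEDENCE = ["promoter", "exon", "intron", "intergenic"]
SHORE_BP = 2_000
SHELF_BP = 2_000


# ---------------------------------------------------------------------------
# interval primitives (sorted (start, end) arrays on one chromosome)
# ---------------------------------------------------------------------------

def _merge(iv: np.ndarray) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def _expand(iv: np.ndarray, pad: int, lo: int, hi: int) -> np.ndarray:
    if len(iv) == 0:
        return iv.reshape(0, 2)
    out = np.column_stack(
        [np.clip(iv[:, 0] - pad, lo, hi), np.clip(iv[:, 1] + pad, lo, hi)]
    )
    return _merge(out[out[:, 0] < out[:, 1]])


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a \\ b for merged, sorted interval arrays."""
    if len(a) == 0 or len(b) == 0:
        return a.reshape(-1, 2)
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.asarray(out).reshape(-1, 2)


def _overlap_len(iv: np.ndarray, start: int, end: int) -> int:
    if len(iv) == 0:
        return 0
    lo = np.minimum(iv[:, 1], end)
    hi = np.maximum(iv[:, 0], start)
    return int(np.clip(lo - hi, 0, None).sum())


@dataclass
class ContextTrack:
    """Disjoint labeled intervals partitioning each chromosome into
    island / shore / shelf / open_sea."""

    chrom_lengths: dict[str, int]
    intervals: dict[str, dict[str, np.ndarray]]  # chrom -> label -> (m, 2)

    def overlap_bases(self, chrom: str, start: int, end: int) -> dict[str, int]:
        per = self.intervals.get(chrom)
        if per is None:
            return {lab: 0 for lab in CONTEXT_PRECEDENCE[:-1]} | {
                "open_sea": end - start
            }
        return {lab: _overlap_len(per[lab], start, end) for lab in CONTEXT_PRECEDENCE}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, per in self.intervals.items():
            for lab in CONTEXT_PRECEDENCE:
                for s, e in per[lab]:
                    rows.append((chrom, int(s), int(e), lab))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "context"])
        return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def build_context_track(
    islands: pd.DataFrame, chrom_lengths: dict[str, int]
) -> ContextTrack:
    """Resolve island/shore/shelf/open-sea context with island > shore >
    shelf precedence; all intervals clipped to [0, chrom_length)."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, length in chrom_lengths.items():
        sub = islands[islands["chrom"] == chrom]
        iv = sub[["start", "end"]].to_numpy(dtype=np.int64).reshape(-1, 2)
        if len(iv) and (iv[:, 0].min() < 0 or iv[:, 1].max() > length):
            raise ValueError(f"island outside chromosome bounds on {chrom}")
        isl = _merge(iv)
        z_shore = _expand(isl, SHORE_BP, 0, length)
        z_shelf = _expand(isl, SHORE_BP + SHELF_BP, 0, length)
        shore = _subtract(z_shore, isl)
        shelf = _subtract(z_shelf, z_shore)
        open_sea = _subtract(np.asarray([[0, length]]), z_shelf)
        out[chrom] = {
            "island": isl,
            "shore": shore,
            "shelf": shelf,
            "open_sea": open_sea,
        }
    unknown = set(islands["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"islands on chromosomes without lengths: {sorted(unknown)}")
    return ContextTrack(chrom_lengths=dict(chrom_lengths), intervals=out)


# ---------------------------------------------------------------------------
# HMR calling
# ---------------------------------------------------------------------------

def call_hmrs(
    sites: pd.DataFrame,
    tau: float = 0.3,
    max_gap: int = 500,
    min_cpgs: int = 4,
    min_cov: int = 5,
) -> pd.DataFrame:
    """Threshold-merge HMR segmentation of one sample.

    A site is hypomethylated when beta < tau at coverage >= min_cov; maximal
    runs of hypomethylated sites with successive gaps <= max_gap bp (on one
    chromosome) become segments when they contain >= min_cpgs sites.  Bounds
    run from the first to last+1 member positions; mean_beta is the
    unweighted mean over member sites.
    """
    pos_sorted = (
        sites[["chrom", "start"]]
        .apply(tuple, axis=1)
        .is_monotonic_increasing
        if len(sites)
        else True
    )
    if not pos_sorted:
        raise ValueError("sites must be sorted by (chrom, start)")
    rows = []
    hypo = (sites["beta"] < tau) & (sites["n_total"] >= min_cov)
    for chrom, sub in sites[hypo].groupby("chrom", sort=False):
        pos = sub["start"].to_numpy()
        beta = sub["beta"].to_numpy()
        if len(pos) == 0:
            continue
        brk = np.flatnonzero(np.diff(pos) > max_gap)
        starts = np.r_[0, brk + 1]
        ends = np.r_[brk + 1, len(pos)]
        for i0, i1 in zip(starts, ends):
            if i1 - i0 < min_cpgs:
                continue
            rows.append(
                (
                    chrom,
                    int(pos[i0]),
                    int(pos[i1 - 1]) + 1,
                    int(i1 - i0),
                    float(beta[i0:i1].mean()),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_cpgs", "mean_beta"]
    )


def call_hmrs_cohort(cohort: MethylationCohort, **kwargs) -> pd.DataFrame:
    """HMRs for every sample, stacked with a sample_id column."""
    frames = []
    for i, s in enumerate(cohort.sample_ids):
        df = call_hmrs(cohort.sample_table(i), **kwargs)
        df.insert(0, "sample_id", s)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "n_cpgs", "mean_beta"]
        )
    return pd.concat(frames, ignore_index=True)


def _element_intervals(
    genes: pd.DataFrame | None,
    exons: pd.DataFrame | None,
    promoter_up: int,
    promoter_down: int,
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    if genes is None or len(genes) == 0:
        return out
    proms = []
    for g in genes.itertuples(index=False):
        if getattr(g, "strand", "+") == "-":
            s, e = g.end - promoter_down, g.end + promoter_up
        else:
            s, e = g.start - promoter_up, g.start + promoter_down
        proms.append((g.chrom, max(0, s), max(1, e)))
    prom_df = pd.DataFrame(proms, columns=["chrom", "start", "end"])
    for chrom in set(genes["chrom"]):
        p = prom_df[prom_df["chrom"] == chrom][["start", "end"]].to_numpy()
        gb = genes[genes["chrom"] == chrom][["start", "end"]].to_numpy()
        if exons is not None and len(exons):
            ex = exons[exons["chrom"] == chrom][["start", "end"]].to_numpy()
        else:
            ex = np.zeros((0, 2), dtype=np.int64)
        out[chrom] = {
            "promoter": _merge(p.astype(np.int64)),
            "exon": _merge(ex.astype(np.int64)),
            "gene_body": _merge(gb.astype(np.int64)),
        }
    return out


def annotate_hmrs(
    hmrs: pd.DataFrame,
    context: ContextTrack,
    genes: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    promoter_up: int = 2_000,
    promoter_down: int = 500,
) -> pd.DataFrame:
    """Attach context and genomic-element labels to called HMRs.

    Context = label with maximal base overlap (ties resolved island > shore >
    shelf > open_sea); ``island_or_shore_any`` additionally records any-
    overlap with an island or shore.  Element = first matching class in the
    precedence promoter > exon > intron > intergenic, with promoter =
    [TSS - promoter_up, TSS + promoter_down) on the gene's strand and gene
    body outside exons counting as intron.
    """
    ann = hmrs.copy()
    if len(ann) == 0:
        for col in ("context", "island_or_shore_any", "element"):
            ann[col] = pd.Series(dtype=object)
        return ann
    elems = _element_intervals(genes, exons, promoter_up, promoter_down)
    ctx_labels, any_flags, elem_labels = [], [], []
    for row in ann.itertuples(index=False):
        ov = context.overlap_bases(row.chrom, row.start, row.end)
        best = max(CONTEXT_PRECEDENCE, key=lambda lab: (ov[lab], -CONTEXT_PRECEDENCE.index(lab)))
        ctx_labels.append(best)
        any_flags.append(ov["island"] + ov["shore"] > 0)
        per = elems.get(row.chrom)
        if per is None:
            elem_labels.append("intergenic")
        elif _overlap_len(per["promoter"], row.start, row.end) > 0:
            elem_labels.append("promoter")
        elif _overlap_len(per["exon"], row.start, row.end) > 0:
            elem_labels.append("exon")
        elif _overlap_len(per["gene_body"], row.start, row.end) > 0:
            elem_labels.append("intron")
        else:
            elem_labels.append("intergenic")
    ann["context"] = ctx_labels
    ann["island_or_shore_any"] = any_flags
    ann["element"] = elem_labels
    return ann


def hmr_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-sample HMR summary: count, island-or-shore fractions (maximal-
    overlap and any-overlap variants) and per-element counts."""
    if len(annotated) == 0 or "sample_id" not in annotated:
        return pd.DataFrame(
            columns=["sample_id", "n_hmrs", "frac_island_or_shore",
                     "frac_island_or_shore_any"]
            + [f"n_{e}" for e in ELEMENT_PRECEDENCE]
        )
    rows = []
    for s, sub in annotated.groupby("sample_id"):
        rec = {
            "sample_id": s,
            "n_hmrs": len(sub),
            "frac_island_or_shore": float(
                sub["context"].isin(["island", "shore"]).mean()
            ),
            "frac_island_or_shore_any": float(sub["island_or_shore_any"].mean()),
        }
        for e in ELEMENT_PRECEDENCE:
            rec[f"n_{e}"] = int((sub["element"] == e).sum())
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNV calling
# ---------------------------------------------------------------------------

def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    va = a.var(ddof=1) if len(a) > 1 else 0.0
    vb = b.var(ddof=1) if len(b) > 1 else 0.0
    denom = np.sqrt(va / len(a) + vb / len(b))
    if denom == 0:
        return 0.0 if ma == mb else np.inf
    return float((ma - mb) / denom)


def _split_recursive(
    vals: np.ndarray, t_threshold: float, min_bins: int
) -> list[tuple[int, int]]:
    def rec(lo: int, hi: int) -> list[tuple[int, int]]:
        n = hi - lo
        if n < 2 * min_bins:
            return [(lo, hi)]
        best_t, best_s = 0.0, None
        for s in range(lo + min_bins, hi - min_bins + 1):
            t = abs(_welch_t(vals[lo:s], vals[s:hi]))
            if t > best_t:
                best_t, best_s = t, s
        if best_s is not None and best_t > t_threshold:
            return rec(lo, best_s) + rec(best_s, hi)
        return [(lo, hi)]

    return rec(0, len(vals))


def call_cnvs(
    cohort: MethylationCohort,
    bin_size: int = 500_000,
    t_threshold: float = 4.0,
    min_bins: int = 5,
    call_cutoff: float = 0.3,
) -> pd.DataFrame:
    """Copy-number segments from binned CpG read coverage.

    Bin coverage sums ``n_total`` (including low-coverage masked sites) over
    ``bin_size`` windows.  Each sample's bins are normalized by their own
    median, then log2-scaled against the cohort per-bin median, and each
    chromosome is segmented by recursive binary splitting on Welch's t.
    Segments with |mean log2 ratio| >= ``call_cutoff`` are called gain/loss.
    """
    if cohort.n_samples < 3:
        raise ValueError("need >= 3 samples for a meaningful cohort median")
    if not cohort.chrom_lengths:
        raise ValueError("cohort has no chromosome lengths")
    chroms = list(cohort.chrom_lengths)
    bin_meta = []  # (chrom, start, end)
    for chrom in chroms:
        length = cohort.chrom_lengths[chrom]
        edges = list(range(0, length, bin_size)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            bin_meta.append((chrom, s, e))
    n_bins = len(bin_meta)
    bin_index = {}
    for j, (chrom, s, _e) in enumerate(bin_meta):
        bin_index.setdefault(chrom, []).append((s, j))

    pos = cohort.sites["start"].to_numpy()
    site_chrom = cohort.sites["chrom"].to_numpy()
    site_bin = np.full(len(pos), -1, dtype=int)
    for chrom in chroms:
        sel = site_chrom == chrom
        starts = np.asarray([s for s, _ in bin_index[chrom]])
        idx0 = bin_index[chrom][0][1]
        site_bin[sel] = idx0 + np.searchsorted(starts, pos[sel], side="right") - 1

    cov = np.zeros((cohort.n_samples, n_bins))
    for i in range(cohort.n_samples):
        np.add.at(cov[i], site_bin, cohort.n_total[i])

    sample_med = np.median(cov, axis=1, keepdims=True)
    if (sample_med <= 0).any():
        raise ValueError("a sample has zero median bin coverage")
    r = cov / sample_med
    bin_med = np.median(r, axis=0)
    valid = bin_med > 0
    if (~valid).any():
        logger.warning("masking %d bins with zero cohort median coverage",
                       int((~valid).sum()))
    l2 = np.full_like(r, np.nan)
    l2[:, valid] = np.log2(np.maximum(r[:, valid], 1e-6) / bin_med[valid])

    rows = []
    for i, sid in enumerate(cohort.sample_ids):
        for chrom in chroms:
            bins_here = [j for _s, j in bin_index[chrom] if valid[j]]
            if not bins_here:
                continue
            vals = l2[i, bins_here]
            for lo, hi in _split_recursive(vals, t_threshold, min_bins):
                seg_bins = bins_here[lo:hi]
                mean_l2 = float(vals[lo:hi].mean())
                call = "neutral"
                if mean_l2 >= call_cutoff:
                    call = "gain"
                elif mean_l2 <= -call_cutoff:
                    call = "loss"
                rows.append(
                    (
                        sid,
                        chrom,
                        bin_meta[seg_bins[0]][1],
                        bin_meta[seg_bins[-1]][2],
                        len(seg_bins),
                        mean_l2,
                        call,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "n_bins",
                 "mean_log2_ratio", "call"],
    )


def genome_fraction_cnv(
    segments: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.Series:
    """Fraction of the genome covered by gain/loss segments, per sample."""
    genome = float(sum(chrom_lengths.values()))
    out = {}
    for sid, sub in segments.groupby("sample_id"):
        for _chrom, c in sub.groupby("chrom"):
            c = c.sort_values("start")
            if (c["start"].to_numpy()[1:] < c["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments for sample {sid}")
        called = sub[sub["call"].isin(["gain", "loss"])]
        out[sid] = float((called["end"] - called["start"]).sum() / genome)
    return pd.Series(out, name="genome_fraction_cnv")
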
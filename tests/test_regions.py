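"""Context geometry, HMR segmentation and CNV calling contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methgroup.regions import (
    annotate_hmrs,
    build_context_track,
    call_cnvs,
    call_hmrs,
    call_hmrs_cohort,
    genome_fraction_cnv,
    hmr_summary,
)
from methgroup.synthetic import generate_gene_track, generate_methylomes
from tests.conftest import make_cohort


def islands_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def total_bases(track, chrom, label):
    iv = track.intervals[chrom][label]
    return int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0


class TestContextTrack:
    def test_flanks_are_exactly_2kb_per_side(self):
        track = build_context_track(
            islands_df([("chr1", 10_000, 11_000)]), {"chr1": 1_000_000}
        )
        assert total_bases(track, "chr1", "island") == 1_000
        assert total_bases(track, "chr1", "shore") == 4_000
        assert total_bases(track, "chr1", "shelf") == 4_000
        iv = track.intervals["chr1"]
        assert iv["shore"].tolist() == [[8_000, 10_000], [11_000, 13_000]]
        assert iv["shelf"].tolist() == [[6_000, 8_000], [13_000, 15_000]]

    def test_close_islands_gap_is_entirely_shore(self):
        # 1,000 bp gap: shore zones from both sides cover it; island > shore
        # precedence keeps the islands themselves intact
        track = build_context_track(
            islands_df([("chr1", 10_000, 11_000), ("chr1", 12_000, 13_000)]),
            {"chr1": 1_000_000},
        )
        ov = track.overlap_bases("chr1", 11_000, 12_000)
        assert ov == {"island": 0, "shore": 1_000, "shelf": 0, "open_sea": 0}

    def test_island_at_chromosome_start_clips_left_flanks(self):
        track = build_context_track(
            islands_df([("chr1", 0, 500)]), {"chr1": 1_000_000}
        )
        assert track.intervals["chr1"]["shore"].tolist() == [[500, 2_500]]
        assert total_bases(track, "chr1", "shelf") == 2_000

    def test_island_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome bounds"):
            build_context_track(islands_df([("chr1", 500, 2_000)]),
                                {"chr1": 1_000})

    @given(st.lists(st.tuples(st.integers(0, 90), st.integers(1, 8)),
                    min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_is_disjoint_and_complete(self, raw):
        length = 100_000
        rows = [("chr1", s * 1_000, min((s + w) * 1_000, length))
                for s, w in raw]
        track = build_context_track(islands_df(rows), {"chr1": length})
        pieces = []
        for lab in ("island", "shore", "shelf", "open_sea"):
            pieces.extend(map(tuple, track.intervals["chr1"][lab]))
        pieces.sort()
        assert pieces[0][0] == 0 and pieces[-1][1] == length
        for (s0, e0), (s1, e1) in zip(pieces, pieces[1:]):
            assert e0 == s1  # no gap, no overlap


def sites_table(positions, betas, n_total=30, chrom="chr1"):
    return pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "start": positions,
            "end": [p + 1 for p in positions],
            "beta": betas,
            "n_meth": [0] * len(positions),
            "n_total": [n_total] * len(positions),
        }
    )


class TestCallHmrs:
    def test_dense_hypo_run_is_one_segment(self):
        df = sites_table([100, 200, 300, 400, 500], [0.1] * 5)
        out = call_hmrs(df)
        assert len(out) == 1
        seg = out.iloc[0]
        assert (seg.start, seg.end, seg.n_cpgs) == (100, 501, 5)
        assert seg.mean_beta == pytest.approx(0.1)

    def test_large_gap_splits_and_min_cpgs_drops_candidates(self):
        pos = [100, 200, 300, 900, 1000, 1100]  # 600 bp gap in the middle
        df = sites_table(pos, [0.05] * 6)
        assert len(call_hmrs(df, max_gap=500, min_cpgs=4)) == 0
        # lowering min_cpgs recovers both 3-site candidates
        assert len(call_hmrs(df, max_gap=500, min_cpgs=3)) == 2

    def test_methylated_sites_give_no_hmr(self):
        df = sites_table([100, 200, 300, 400], [0.9] * 4)
        assert len(call_hmrs(df)) == 0

    def test_low_coverage_sites_cannot_seed_hmrs(self):
        df = sites_table([100, 200, 300, 400], [0.1] * 4, n_total=3)
        assert len(call_hmrs(df, min_cov=5)) == 0

    def test_unsorted_input_rejected(self):
        df = sites_table([400, 100, 200, 300], [0.1] * 4)
        with pytest.raises(ValueError, match="sorted"):
            call_hmrs(df)

    def test_intervening_methylated_site_does_not_break_merge(self):
        # hypo sites 100..500 with a methylated site at 250: the run is over
        # hypo sites only and their mutual gaps stay <= max_gap
        df = sites_table([100, 200, 250, 300, 400, 500],
                         [0.1, 0.1, 0.9, 0.1, 0.1, 0.1])
        out = call_hmrs(df, min_cpgs=5)
        assert len(out) == 1 and out.iloc[0].n_cpgs == 5


class TestAnnotate:
    def _track(self):
        return build_context_track(
            islands_df([("chr1", 10_000, 11_000)]), {"chr1": 1_000_000}
        )

    def _hmrs(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["n_cpgs"] = 5
        df["mean_beta"] = 0.1
        df["sample_id"] = "S1"
        return df

    def test_island_coincident_hmr(self):
        ann = annotate_hmrs(self._hmrs([("chr1", 10_000, 11_000)]), self._track())
        assert ann.iloc[0]["context"] == "island"
        assert bool(ann.iloc[0]["island_or_shore_any"])

    def test_half_shore_half_open_sea_resolves_to_shore(self):
        # [12,500, 13,500): 500 bp shore, 500 bp shelf -> tie broken by
        # precedence toward shore
        ann = annotate_hmrs(self._hmrs([("chr1", 12_500, 13_500)]), self._track())
        assert ann.iloc[0]["context"] == "shore"

    def test_empty_hmr_list_gives_empty_summary(self):
        ann = annotate_hmrs(self._hmrs([]).iloc[0:0], self._track())
        assert len(hmr_summary(ann)) == 0

    def test_promoter_precedence_respects_strand(self):
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [50_000], "end": [60_000],
             "name": ["g"], "strand": ["-"]}
        )
        # promoter of a minus-strand gene sits at its end coordinate
        ann = annotate_hmrs(self._hmrs([("chr1", 60_500, 61_000)]),
                            self._track(), genes=genes)
        assert ann.iloc[0]["element"] == "promoter"
        ann2 = annotate_hmrs(self._hmrs([("chr1", 52_000, 53_000)]),
                             self._track(), genes=genes)
        assert ann2.iloc[0]["element"] == "intron"
        ann3 = annotate_hmrs(self._hmrs([("chr1", 200_000, 201_000)]),
                             self._track(), genes=genes)
        assert ann3.iloc[0]["element"] == "intergenic"

    def test_hmr_group_enrichment_on_synthetic_cohort(self, small_config):
        cohort, truth, islands = generate_methylomes(small_config, seed=6)
        hmrs = call_hmrs_cohort(cohort)
        track = build_context_track(islands, cohort.chrom_lengths)
        genes, exons = generate_gene_track(small_config, seed=6)
        summary = hmr_summary(annotate_hmrs(hmrs, track, genes, exons))
        summary["group"] = truth.labels[
            [cohort.sample_ids.index(s) for s in summary["sample_id"]]
        ]
        means = summary.groupby("group")["n_hmrs"].mean()
        assert means[2] > means[1] and means[2] > means[3]


class TestCallCnvs:
    @staticmethod
    def _flat_cohort(n=6, bins=20, per_bin=5, bin_size=100_000, depth=30):
        m = bins * per_bin
        spacing = bin_size // per_bin
        beta = np.full((n, m), 0.8)
        return make_cohort(beta, n_total=depth, spacing=spacing,
                           chrom_length=bins * bin_size)

    def test_identical_coverage_one_neutral_segment(self):
        cohort = self._flat_cohort()
        segs = call_cnvs(cohort, bin_size=100_000)
        assert len(segs) == cohort.n_samples
        assert (segs["call"] == "neutral").all()
        assert np.allclose(segs["mean_log2_ratio"], 0.0)

    def test_infinite_threshold_single_segment_per_chromosome(self, small_config):
        cohort, _, _ = generate_methylomes(small_config, seed=3)
        segs = call_cnvs(cohort, bin_size=100_000, t_threshold=np.inf)
        per = segs.groupby(["sample_id", "chrom"]).size()
        assert (per == 1).all()

    def test_planted_gain_recovered_with_accurate_log_ratio(self):
        # 10 elevated bins out of 40 so the sample median stays anchored on
        # neutral bins, as in a real genome-wide profile
        cohort = self._flat_cohort(n=10, bins=40)
        rng = np.random.default_rng(0)
        n_total = rng.poisson(30, size=cohort.n_total.shape)
        gain_sites = (cohort.sites["start"] >= 500_000) & \
            (cohort.sites["start"] < 1_500_000)  # bins 5..14
        n_total[0, gain_sites.to_numpy()] = rng.poisson(
            45, size=int(gain_sites.sum()))
        cohort.n_total = n_total
        segs = call_cnvs(cohort, bin_size=100_000)
        gains = segs[(segs["sample_id"] == "S00") & (segs["call"] == "gain")]
        assert len(gains) == 1
        seg = gains.iloc[0]
        covered = (min(seg.end, 1_500_000) - max(seg.start, 500_000)) / 100_000
        assert covered >= 8
        assert abs(seg.mean_log2_ratio - np.log2(1.5)) < 0.15
        others = segs[segs["sample_id"] != "S00"]
        assert (others["call"] == "neutral").all()

    def test_lower_call_cutoff_never_decreases_cnv_fraction(self):
        cohort = self._flat_cohort(n=8)
        rng = np.random.default_rng(1)
        cohort.n_total = rng.poisson(30, size=cohort.n_total.shape)
        cohort.n_total[1, :50] = rng.poisson(40, size=50)
        prev = None
        for cutoff in (0.5, 0.3, 0.1, 0.0):
            segs = call_cnvs(cohort, bin_size=100_000, call_cutoff=cutoff)
            frac = genome_fraction_cnv(segs, cohort.chrom_lengths).sum()
            if prev is not None:
                assert frac >= prev - 1e-12
            prev = frac

    def test_too_few_samples_rejected(self):
        cohort = self._flat_cohort(n=2)
        with pytest.raises(ValueError, match=">= 3 samples"):
            call_cnvs(cohort)


class TestGenomeFraction:
    def _segs(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "chrom", "start", "end", "n_bins",
                           "mean_log2_ratio", "call"]
        )

    def test_no_calls_zero(self):
        segs = self._segs([("S1", "chr1", 0, 10_000_000, 20, 0.0, "neutral")])
        frac = genome_fraction_cnv(segs, {"chr1": 10_000_000, "chr2": 10_000_000})
        assert frac["S1"] == 0.0

    def test_two_megabase_gain_on_twenty_megabase_genome(self):
        segs = self._segs([
            ("S1", "chr1", 0, 2_000_000, 4, 0.6, "gain"),
            ("S1", "chr1", 2_000_000, 10_000_000, 16, 0.0, "neutral"),
        ])
        frac = genome_fraction_cnv(segs, {"chr1": 10_000_000, "chr2": 10_000_000})
        assert frac["S1"] == pytest.approx(0.1)

    def test_invariant_to_chromosome_ordering(self):
        rows = [("S1", "chr2", 0, 1_000_000, 2, 0.7, "gain"),
                ("S1", "chr1", 0, 2_000_000, 4, -0.8, "loss")]
        a = genome_fraction_cnv(self._segs(rows),
                                {"chr1": 10_000_000, "chr2": 10_000_000})
        b = genome_fraction_cnv(self._segs(rows[::-1]),
                                {"chr2": 10_000_000, "chr1": 10_000_000})
        assert a["S1"] == b["S1"]

    def test_overlapping_segments_rejected(self):
        segs = self._segs([
            ("S1", "chr1", 0, 2_000_000, 4, 0.6, "gain"),
            ("S1", "chr1", 1_000_000, 3_000_000, 4, 0.6, "gain"),
        ])
        with pytest.raises(ValueError, match="overlapping"):
            genome_fraction_cnv(segs, {"chr1": 10_000_000})
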
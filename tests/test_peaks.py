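import numpy as np
import pandas as pd
import pytest

from conftest import random_intervals
from epimemo.genome import GeneModel, GenomicInterval
from epimemo.peaks import (
    annotate_peaks,
    bin_genome,
    consensus_peaks,
    count_fragments,
    cpm_normalize,
    links_to_frame,
    peak_categories,
)
from oracles import annotate_oracle, consensus_oracle, count_oracle


class TestConsensusPeaks:
    def test_peak_in_six_of_28_retained_five_discarded(self):
        peak = GenomicInterval("chr1", 100, 300)
        for present, kept in [(6, True), (5, False)]:
            samples = [[peak] for _ in range(present)] + [[] for _ in range(28 - present)]
            result = consensus_peaks(samples, min_support=6)
            assert (len(result) == 1) is kept
            assert result.n_samples == 28

    def test_overlapping_peaks_merge_with_support(self):
        samples = [
            [GenomicInterval("chr1", 100, 300)],
            [GenomicInterval("chr1", 250, 400)],
        ]
        result = consensus_peaks(samples, min_support=1)
        assert [(p.start, p.end) for p in result.peaks] == [(100, 400)]
        assert result.support.tolist() == [2]

    def test_two_peaks_same_sample_count_once(self):
        samples = [
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 300)],
            [GenomicInterval("chr1", 180, 250)],
        ]
        result = consensus_peaks(samples, min_support=1)
        assert result.support.tolist() == [2]

    def test_min_support_exceeding_samples_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks([[GenomicInterval("chr1", 0, 10)]], min_support=2)

    def test_invariant_to_sample_and_peak_order(self, rng):
        genome = {"chrA": 5000, "chrB": 3000}
        samples = [random_intervals(rng, 15, genome) for _ in range(4)]
        base = consensus_peaks(samples, min_support=2)
        shuffled = [list(s) for s in samples[::-1]]
        for s in shuffled:
            rng.shuffle(s)
        alt = consensus_peaks(shuffled, min_support=2)
        key = lambda r: [(p.chrom, p.start, p.end) for p in r.peaks]
        assert key(base) == key(alt)
        assert base.support.tolist() == alt.support.tolist()

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        genome = {"chr1": 4000, "chr2": 2500}
        for _ in range(40):
            n_samples = int(rng.integers(1, 6))
            samples = [
                random_intervals(rng, int(rng.integers(0, 12)), genome)
                for _ in range(n_samples)
            ]
            min_support = int(rng.integers(1, n_samples + 1))
            got = consensus_peaks(samples, min_support)
            tuples = [[(iv.chrom, iv.start, iv.end) for iv in s] for s in samples]
            expected = consensus_oracle(tuples, min_support, genome)
            assert [
                (p.chrom, p.start, p.end, int(s))
                for p, s in zip(got.peaks, got.support)
            ] == expected


class TestBinGenome:
    @pytest.mark.parametrize(
        "sizes,width,expected_n",
        [
            ([("chr1", 10_000)], 4000, 3),
            ([("chr1", 4000)], 4000, 1),
            ([("chr1", 10_000), ("chr2", 7000)], 4000, 5),
        ],
    )
    def test_bin_counts_are_ceil(self, sizes, width, expected_n):
        bins = bin_genome(sizes, width)
        assert len(bins) == expected_n

    def test_last_bin_truncated(self):
        bins = bin_genome([("chr1", 10_000)], 4000)
        assert (bins[-1].start, bins[-1].end) == (8000, 10_000)

    def test_bins_tile_exactly(self, rng):
        sizes = [("c1", int(rng.integers(1, 30_000))), ("c2", int(rng.integers(1, 30_000)))]
        bins = bin_genome(sizes, 1234)
        for chrom, length in sizes:
            mine = [b for b in bins if b.chrom == chrom]
            assert mine[0].start == 0
            assert mine[-1].end == length
            for prev, nxt in zip(mine, mine[1:]):
                assert prev.end == nxt.start

    def test_empty_sizes_rejected(self):
        with pytest.raises(ValueError):
            bin_genome([], 4000)


class TestCountFragments:
    def test_any_overlap_and_half_open_boundary(self):
        features = [GenomicInterval("chr1", 200, 400, "f1")]
        frags = {
            "s1": [GenomicInterval("chr1", 100, 250)],  # overlaps
            "s2": [GenomicInterval("chr1", 100, 200)],  # abuts: no overlap
        }
        m = count_fragments(frags, features)
        assert m.loc["f1", "s1"] == 1
        assert m.loc["f1", "s2"] == 0

    def test_fragment_spanning_two_features_counts_in_both(self):
        features = [
            GenomicInterval("chr1", 0, 100, "a"),
            GenomicInterval("chr1", 100, 200, "b"),
        ]
        m = count_fragments({"s": [GenomicInterval("chr1", 50, 150)]}, features)
        assert m["s"].tolist() == [1, 1]

    def test_overlapping_features_rejected(self):
        features = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 50, 150),
        ]
        with pytest.raises(ValueError, match="overlap"):
            count_fragments({"s": []}, features)

    def test_matches_all_pairs_oracle(self, rng):
        genome = {"chr1": 3000, "chr2": 2000}
        for _ in range(20):
            feats = sorted(random_intervals(rng, 8, genome, max_len=150))
            feats = [
                f
                for i, f in enumerate(feats)
                if all(not f.overlaps(g) for g in feats[:i])
            ]
            feats = [
                GenomicInterval(f.chrom, f.start, f.end, f"f{i}")
                for i, f in enumerate(feats)
            ]
            frags = {
                "s1": random_intervals(rng, 30, genome, max_len=250),
                "s2": random_intervals(rng, 10, genome, max_len=250),
            }
            got = count_fragments(frags, feats)
            for sample, fr in frags.items():
                expected = count_oracle(
                    [(x.chrom, x.start, x.end) for x in fr],
                    [(f.chrom, f.start, f.end) for f in feats],
                )
                assert got[sample].tolist() == expected

    def test_midpoint_mode_assigns_single_feature(self):
        features = [
            GenomicInterval("chr1", 0, 100, "a"),
            GenomicInterval("chr1", 100, 200, "b"),
        ]
        m = count_fragments(
            {"s": [GenomicInterval("chr1", 50, 150)]}, features, midpoint=True
        )
        assert m["s"].tolist() == [0, 1]  # midpoint 100 is in [100, 200)


class TestAnnotatePeaks:
    def test_tss_within_window_is_promoter(self, tiny_genes):
        # gA TSS at 6800, peak end 5400 -> distance 1400
        links = annotate_peaks([GenomicInterval("chr1", 5000, 5400, "p")], tiny_genes[:1])
        assert links[0].link_type == "tss_proximal"
        assert links[0].category == "promoter"

    def test_overlap_fallback_is_enhancer(self):
        genes = [GeneModel("g", GenomicInterval("chr1", 3000, 9000), "+")]
        # TSS 3000 is 2001+ away only if peak far enough; use peak at 5500
        links = annotate_peaks([GenomicInterval("chr1", 5500, 5900, "p")], genes)
        assert [(l.link_type, l.category) for l in links] == [("gene_overlap", "enhancer")]

    def test_two_tss_yield_two_promoter_links(self):
        genes = [
            GeneModel("g1", GenomicInterval("chr1", 6000, 9000), "+"),
            GeneModel("g2", GenomicInterval("chr1", 1000, 4500), "-"),
        ]
        links = annotate_peaks([GenomicInterval("chr1", 5000, 5400, "p")], genes)
        assert {l.gene_id for l in links} == {"g1", "g2"}
        assert all(l.category == "promoter" for l in links)

    def test_isolated_peak_has_no_links(self):
        links = annotate_peaks([GenomicInterval("chr9", 10, 20, "p")], [])
        assert links[0].gene_id is None
        assert links[0].category == "enhancer"

    def test_matches_all_pairs_oracle(self, rng):
        genome = {"chr1": 50_000}
        for _ in range(15):
            peaks = [
                GenomicInterval(p.chrom, p.start, p.end, f"p{i}")
                for i, p in enumerate(random_intervals(rng, 10, genome, max_len=900))
            ]
            genes = []
            for i in range(8):
                start = int(rng.integers(0, 45_000))
                genes.append(
                    GeneModel(
                        f"g{i}",
                        GenomicInterval("chr1", start, start + int(rng.integers(500, 4000))),
                        "+" if rng.random() < 0.5 else "-",
                    )
                )
            links = annotate_peaks(peaks, genes, tss_window=2000)
            frame = links_to_frame(links)
            expected = annotate_oracle(
                [(p.chrom, p.start, p.end) for p in peaks],
                [(g.gene_id, g.chrom, g.span.start, g.span.end, g.strand) for g in genes],
                2000,
            )
            for peak, (prox, over, cat) in zip(peaks, expected):
                mine = frame[frame.peak_id == peak.id]
                assert set(mine.category) == {cat}
                got_genes = set(mine.gene_id.dropna())
                assert got_genes == (prox or over)


class TestCpmNormalize:
    def test_direct_values(self):
        counts = pd.DataFrame({"s": [5, 15]}, index=["a", "b"])
        cpm = cpm_normalize(counts)
        assert cpm["s"].tolist() == [250_000.0, 750_000.0]

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(10, 3)))
        doubled = counts.copy()
        doubled[0] = doubled[0] * 2
        pd.testing.assert_frame_equal(cpm_normalize(counts), cpm_normalize(doubled))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            cpm_normalize(pd.DataFrame({"s": [0, 0]}))
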
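import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from epimemo.peaks import annotate_peaks, peak_categories
from epimemo.simulate import (
    SimConfig,
    simulate_counts,
    simulate_experiment,
    simulate_genome,
    simulate_peak_calls,
    simulate_tracks,
)

SMALL = dict(
    n_genes=60,
    n_peaks=120,
    chrom_sizes=[("chr1", 600_000), ("chr2", 400_000)],
    replicates={"RNA": (3, 3, 3, 3), "ATAC": (3, 3, 3, 3), "K27ac": (3, 3, 3, 3)},
)


class TestConfig:
    def test_class_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(class_fractions={"null": 0.5, "persistent": 0.4})

    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            SimConfig(peak_dropout=1.2)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=10, n_peaks=20)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SimConfig.from_yaml(p) == cfg


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=5, **SMALL)
        a = simulate_genome(cfg)
        b = simulate_genome(cfg)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_peaks_nonoverlapping_and_sized(self):
        genes, peaks, _ = simulate_genome(SimConfig(seed=1, **SMALL))
        assert all(200 <= p.length <= 1000 for p in peaks)
        for a, b in zip(peaks, peaks[1:]):
            assert not a.overlaps(b)

    def test_promoter_fraction_zero_means_no_tss_proximal_peak(self):
        cfg = SimConfig(seed=2, promoter_fraction=0.0, **SMALL)
        genes, peaks, assignment = simulate_genome(cfg)
        cats = peak_categories(annotate_peaks(peaks, genes))
        assert (cats == "promoter").sum() == 0
        assert not assignment["is_promoter"].any()

    def test_promoter_peaks_annotate_to_their_gene(self):
        cfg = SimConfig(seed=3, **SMALL)
        genes, peaks, assignment = simulate_genome(cfg)
        from epimemo.peaks import links_to_frame

        frame = links_to_frame(annotate_peaks(peaks, genes))
        prom = assignment[assignment["is_promoter"]]
        merged = frame[frame.link_type == "tss_proximal"].merge(
            prom, on="peak_id", suffixes=("_ann", "_true")
        )
        assert len(merged) >= len(prom)
        own = merged[merged.gene_id_ann == merged.gene_id_true]
        assert set(own.peak_id) == set(prom.peak_id)

    def test_zero_peaks_is_valid(self):
        cfg = SimConfig(seed=1, n_peaks=0, **{k: v for k, v in SMALL.items() if k != "n_peaks"})
        genes, peaks, assignment = simulate_genome(cfg)
        assert peaks == [] and assignment.empty

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(SimConfig(n_genes=1000, chrom_sizes=[("c", 10_000)]))


class TestSimulateCounts:
    def test_deterministic_and_shapes(self):
        cfg = SimConfig(seed=4, **SMALL)
        genes, peaks, assign = simulate_genome(cfg)
        c1, sheets, truth, libs = simulate_counts(cfg, peaks, assign)
        c2, _, truth2, _ = simulate_counts(cfg, peaks, assign)
        for assay in c1:
            pd.testing.assert_frame_equal(c1[assay], c2[assay])
        pd.testing.assert_frame_equal(truth, truth2)
        assert c1["ATAC"].shape == (120, 12)
        assert c1["RNA"].shape == (60, 12)

    def test_zero_effect_lfc_behaves_as_null(self):
        cfg = SimConfig(seed=4, effect_lfc=0.0, dispersion=0.0, **SMALL)
        genes, peaks, assign = simulate_genome(cfg)
        counts, sheets, truth, libs = simulate_counts(cfg, peaks, assign)
        m = counts["ATAC"]
        hfd = sheets["ATAC"].sample_ids(group="HFD")
        nc = sheets["ATAC"].sample_ids(group="NC")
        ratio = (m[hfd].to_numpy() / libs["ATAC"][hfd].to_numpy()).mean() / (
            m[nc].to_numpy() / libs["ATAC"][nc].to_numpy()
        ).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_nb_moments_match_parameterization(self):
        # one null feature, many samples: var ~ mu + alpha mu^2
        cfg = SimConfig(
            seed=8,
            n_genes=2,
            n_peaks=2,
            chrom_sizes=[("chr1", 100_000)],
            replicates={"ATAC": (2500, 2500, 2500, 2500)},
            class_fractions={"null": 1.0, "reversible": 0, "persistent": 0, "late_only": 0, "inversed": 0},
            libsize_range=(1.0, 1.0),
            baseline_mean=200.0,
            dispersion=0.05,
        )
        genes, peaks, assign = simulate_genome(cfg)
        counts, _, _, _ = simulate_counts(cfg, peaks, assign)
        x = counts["ATAC"].to_numpy()[0]
        mu, alpha = 200.0, 0.05
        assert x.mean() == pytest.approx(mu, rel=0.02)
        assert x.var(ddof=1) == pytest.approx(mu + alpha * mu**2, rel=0.10)

    def test_class_proportions_converge(self):
        cfg = SimConfig(
            seed=6,
            n_genes=1500,
            n_peaks=3000,
            chrom_sizes=[("chr1", 45_000_000)],
            replicates={"ATAC": (2, 2, 2, 2)},
        )
        genes, peaks, assign = simulate_genome(cfg)
        _, _, truth, _ = simulate_counts(cfg, peaks, assign)
        fractions = truth["class"].value_counts(normalize=True)
        for cls, frac in cfg.class_fractions.items():
            assert fractions.get(cls, 0.0) == pytest.approx(frac, abs=0.03)


class TestSimulatePeakCalls:
    def test_no_dropout_no_jitter_reproduces_truth(self):
        cfg = SimConfig(seed=1, peak_dropout=0.0, boundary_jitter=0, **SMALL)
        genes, peaks, _ = simulate_genome(cfg)
        calls = simulate_peak_calls(peaks, cfg, n_samples=4)
        for sample in calls:
            assert [(p.chrom, p.start, p.end) for p in sample] == [
                (p.chrom, p.start, p.end) for p in peaks
            ]

    def test_mean_support_matches_binomial_expectation(self):
        cfg = SimConfig(
            seed=2,
            peak_dropout=0.2,
            n_genes=500,
            n_peaks=1000,
            chrom_sizes=[("chr1", 8_000_000)],
        )
        genes, peaks, _ = simulate_genome(cfg)
        calls = simulate_peak_calls(peaks, cfg, n_samples=28)
        support = sum(len(s) for s in calls) / len(peaks)
        assert support == pytest.approx(28 * 0.8, rel=0.02)

    def test_extreme_dropout_leaves_no_consensus(self):
        from epimemo.peaks import consensus_peaks

        cfg = SimConfig(seed=3, peak_dropout=0.99, **SMALL)
        genes, peaks, _ = simulate_genome(cfg)
        calls = simulate_peak_calls(peaks, cfg, n_samples=28)
        result = consensus_peaks(calls, min_support=6)
        assert len(result) <= len(peaks) * 0.05


class TestSimulateTracks:
    def test_noiseless_tracks_are_exact_multiples(self):
        cfg = SimConfig(seed=5, n_track_regions=200)
        regions, tracks = simulate_tracks(cfg, {"a": 1.0, "b": 2.0}, sigma=0.0)
        va = tracks["a"].data["chrSim"][2]
        vb = tracks["b"].data["chrSim"][2]
        assert np.allclose(vb, 2 * va)

    def test_base_signal_spans_two_decades(self):
        cfg = SimConfig(seed=5, n_track_regions=2000)
        _, tracks = simulate_tracks(cfg, {"a": 1.0}, sigma=0.0)
        v = tracks["a"].data["chrSim"][2]
        assert v.max() / v.min() > 100

    def test_nonpositive_scale_rejected(self):
        cfg = SimConfig(seed=5)
        with pytest.raises(ValueError):
            simulate_tracks(cfg, {"a": 0.0})


class TestSimulateExperiment:
    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        cfg = SimConfig(seed=11, n_track_regions=2000, **SMALL)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_experiment(cfg, d1)
        simulate_experiment(cfg, d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel
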
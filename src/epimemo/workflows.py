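"""High-level convenience pipelines tying the modules together.

These are the same call sequences a user would write by hand: simulate an
experiment, run the two per-timepoint differential contrasts per assay,
classify trajectories, attach cross-assay support, and score recovery
against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffstats, peaks as peaks_mod, persistence
from .genome import GenomicInterval
from .simulate import SimConfig, simulate_counts, simulate_genome

CONTRASTS = {"T1": "HFD:NC", "T2": "HFD-NC:NC-NC"}


@dataclass
class SyntheticAnalysis:
    """Everything produced by one simulated experiment and its analysis."""

    config: SimConfig
    genes: list
    peaks: list[GenomicInterval]
    truth: pd.DataFrame  # indexed by feature_id
    counts: dict[str, pd.DataFrame]
    results: dict[str, dict[str, pd.DataFrame]]  # assay -> timepoint -> table
    calls: pd.DataFrame
    evidence: pd.DataFrame
    links: list
    categories: pd.Series


def differential_by_timepoint(
    counts: pd.DataFrame, sheet, assay: str
) -> dict[str, pd.DataFrame]:
    out = {}
    for tp, contrast in CONTRASTS.items():
        a, b = diffstats.contrast_samples(sheet, assay, contrast)
        out[tp] = diffstats.run_differential(counts, a, b)
    return out


def run_synthetic_analysis(
    config: SimConfig, alpha: float = 0.01, with_support: bool = True
) -> SyntheticAnalysis:
    """Simulate one experiment and run the full downstream analysis."""
    genes, peaks, assignment = simulate_genome(config)
    counts, sheets, truth, _ = simulate_counts(config, peaks, assignment)
    results = {
        assay: differential_by_timepoint(counts[assay], sheets[assay], assay)
        for assay in counts
    }
    calls = persistence.classify_features(
        results["ATAC"]["T1"], results["ATAC"]["T2"], alpha=alpha
    )
    links = peaks_mod.annotate_peaks(peaks, genes)
    categories = peaks_mod.peak_categories(links)
    evidence = pd.DataFrame()
    if with_support and "RNA" in results and "K27ac" in results:
        k27_peaks = [
            GenomicInterval(p.chrom, p.start, p.end, id=f"k27_{p.id}") for p in peaks
        ]
        k27_links = peaks_mod.annotate_peaks(k27_peaks, genes)
        calls, evidence = persistence.cross_assay_support(
            calls,
            links,
            results["RNA"],
            k27ac_results=results["K27ac"],
            k27ac_links=k27_links,
            atac_peaks=peaks,
            k27ac_peaks=k27_peaks,
            alpha=alpha,
        )
    return SyntheticAnalysis(
        config=config,
        genes=genes,
        peaks=peaks,
        truth=truth.set_index("feature_id"),
        counts=counts,
        results=results,
        calls=calls,
        evidence=evidence,
        links=links,
        categories=categories,
    )


def class_recovery(analysis: SyntheticAnalysis) -> dict[str, float]:
    """Sensitivity / confusion of the trajectory classification against the
    planted truth (direction-agnostic for the directional classes)."""
    j = analysis.calls.join(analysis.truth, rsuffix="_true")
    planted = j["class_true"]
    called = j["class"]

    def rate(true_cls: str, called_prefix: str) -> float:
        sub = called[planted == true_cls]
        if len(sub) == 0:
            return float("nan")
        return float(sub.str.startswith(called_prefix).mean())

    return {
        "persistent_sensitivity": rate("persistent", "persistent"),
        "reversible_sensitivity": rate("reversible", "reversible"),
        "late_only_sensitivity": rate("late_only", "late_only"),
        "inversed_sensitivity": rate("inversed", "inversed"),
        "reversible_to_persistent": rate("reversible", "persistent"),
        "null_unchanged_rate": rate("null", "unchanged"),
        "n_features": float(len(j)),
    }


def support_rate_of_true_persistent(analysis: SyntheticAnalysis) -> tuple[float, int]:
    """Fraction of planted-persistent peaks flagged as cross-assay supported."""
    j = analysis.calls.join(analysis.truth, rsuffix="_true")
    pers = j[j["class_true"] == "persistent"]
    if len(pers) == 0:
        return float("nan"), 0
    return float(pers["supported"].mean()), int(len(pers))


def rescaled_to_geometric_mean(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rescale positive values to geometric mean 1 (the gauge in which
    planted and estimated scale factors are comparable)."""
    v = np.asarray(values, dtype=float)
    return v / np.exp(np.log(v).mean())
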
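"""Consensus peak construction, genome binning, fragment counting and
peak-to-gene annotation.

The consensus rule mirrors the replicate-supported peak selection used for
ATAC-seq: peak calls from all samples are merged into maximal union
intervals, each union interval's support is the number of distinct samples
contributing at least 1 bp of overlap, and intervals below a minimum support
are discarded ("at least" is inclusive, so ties at the threshold are kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomicInterval

__all__ = [
    "ConsensusPeakSet",
    "PeakGeneLink",
    "consensus_peaks",
    "bin_genome",
    "count_fragments",
    "annotate_peaks",
    "links_to_frame",
    "peak_categories",
    "cpm_normalize",
]


@dataclass
class ConsensusPeakSet:
    """Merged peaks with per-peak sample support."""

    peaks: list[GenomicInterval]
    support: np.ndarray  # int, parallel to peaks
    n_samples: int

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.int64)
        if len(self.support) != len(self.peaks):
            raise ValueError("support length must match peaks")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class PeakGeneLink:
    """One peak–gene association.

    ``tss_proximal`` links (TSS within the window of either peak end, or
    inside the peak) take priority: ``gene_overlap`` links exist only for
    peaks with no proximal TSS. A peak with at least one proximal link is a
    promoter peak; every other peak is an enhancer peak.
    """

    peak_id: str
    gene_id: str | None
    link_type: str  # "tss_proximal" | "gene_overlap" | "none"
    category: str  # "promoter" | "enhancer"


def consensus_peaks(
    sample_peaks: Sequence[Sequence[GenomicInterval]],
    min_support: int,
) -> ConsensusPeakSet:
    """Merge per-sample peak calls and keep union intervals supported by at
    least ``min_support`` distinct samples.

    Support counts samples, not peaks: several peaks from one sample falling
    in the same union interval contribute 1. Output peaks are sorted,
    non-overlapping, and get ids ``peak_000001`` onward.
    """
    n_samples = len(sample_peaks)
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if min_support > n_samples:
        raise ValueError(
            f"min_support={min_support} exceeds number of samples ({n_samples})"
        )

    tagged = [
        (iv.chrom, iv.start, iv.end, si)
        for si, ivs in enumerate(sample_peaks)
        for iv in ivs
    ]
    merged: list[tuple[str, int, int, int]] = []  # chrom, start, end, support
    if tagged:
        tagged.sort(key=lambda t: (t[0], t[1], t[2]))
        cur_chrom, cur_start, cur_end, _ = tagged[0]
        cur_samples = {tagged[0][3]}
        for chrom, start, end, si in tagged[1:]:
            # book-ended peaks merge too: coverage is contiguous
            if chrom == cur_chrom and start <= cur_end:
                cur_end = max(cur_end, end)
                cur_samples.add(si)
            else:
                merged.append((cur_chrom, cur_start, cur_end, len(cur_samples)))
                cur_chrom, cur_start, cur_end = chrom, start, end
                cur_samples = {si}
        merged.append((cur_chrom, cur_start, cur_end, len(cur_samples)))

    kept = [m for m in merged if m[3] >= min_support]
    peaks = [
        GenomicInterval(c, s, e, id=f"peak_{i + 1:06d}")
        for i, (c, s, e, _) in enumerate(kept)
    ]
    support = np.array([m[3] for m in kept], dtype=np.int64)
    return ConsensusPeakSet(peaks, support, n_samples)


def bin_genome(
    chrom_sizes: Sequence[tuple[str, int]], width: int = 4000
) -> list[GenomicInterval]:
    """Tile each chromosome with fixed-width bins; the last bin is truncated
    at the chromosome end. Bin ids are ``<chrom>:<start>-<end>``."""
    if width < 1:
        raise ValueError("bin width must be >= 1")
    if not chrom_sizes:
        raise ValueError("empty chromosome sizes")
    bins: list[GenomicInterval] = []
    for chrom, length in chrom_sizes:
        if length <= 0:
            raise ValueError(f"chromosome {chrom}: non-positive length")
        for start in range(0, length, width):
            end = min(start + width, length)
            bins.append(GenomicInterval(chrom, start, end, id=f"{chrom}:{start}-{end}"))
    return bins


def _feature_arrays(
    features: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group sorted non-overlapping features by chromosome; validate."""
    order = sorted(range(len(features)), key=lambda i: features[i])
    by_chrom: dict[str, list[int]] = {}
    for i in order:
        by_chrom.setdefault(features[i].chrom, []).append(i)
    out = {}
    for chrom, idx in by_chrom.items():
        starts = np.array([features[i].start for i in idx])
        ends = np.array([features[i].end for i in idx])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping features (ambiguous counting)")
        out[chrom] = (starts, ends, np.array(idx))
    return out


def count_fragments(
    fragments_by_sample: Mapping[str, Sequence[GenomicInterval]],
    features: Sequence[GenomicInterval],
    midpoint: bool = False,
) -> pd.DataFrame:
    """Count fragments per feature per sample (features × samples).

    A fragment is counted in every feature it overlaps by >= 1 bp
    (half-open, so a fragment abutting a feature end does not count). With
    ``midpoint=True`` a fragment is instead assigned to the single feature
    containing its midpoint. Features must be non-overlapping.
    """
    feat = _feature_arrays(features)
    ids = [iv.id or f"feature_{i + 1:06d}" for i, iv in enumerate(features)]
    counts = np.zeros((len(features), len(fragments_by_sample)), dtype=np.int64)
    for j, frags in enumerate(fragments_by_sample.values()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for fr in frags:
            by_chrom.setdefault(fr.chrom, []).append((fr.start, fr.end))
        for chrom, pairs in by_chrom.items():
            if chrom not in feat:
                continue
            starts, ends, idx = feat[chrom]
            fs = np.array([p[0] for p in pairs])
            fe = np.array([p[1] for p in pairs])
            if midpoint:
                mid = (fs + fe) // 2
                pos = np.searchsorted(ends, mid, side="right")
                ok = pos < len(starts)
                ok[ok] &= starts[pos[ok]] <= mid[ok]
                np.add.at(counts[:, j], idx[pos[ok]], 1)
            else:
                # overlapping features form a contiguous run in the sorted
                # per-chromosome block: [lo, hi)
                lo = np.searchsorted(ends, fs, side="right")
                hi = np.searchsorted(starts, fe, side="left")
                keep = hi > lo
                local = np.zeros(len(starts) + 1, dtype=np.int64)
                np.add.at(local, lo[keep], 1)
                np.add.at(local, hi[keep], -1)
                counts[idx, j] += np.cumsum(local[:-1])
    return pd.DataFrame(counts, index=ids, columns=list(fragments_by_sample))


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    tss_window: int = 2000,
) -> list[PeakGeneLink]:
    """Annotate peaks with nearby genes.

    Rule: a peak is linked to every gene whose TSS lies within ``tss_window``
    of either peak end (TSS inside the peak counts); such peaks are
    promoters. A peak with no proximal TSS is linked to every gene whose span
    overlaps it; with or without overlap links it is an enhancer. Peaks with
    no links at all get a single record with ``gene_id=None``.
    """
    if tss_window < 0:
        raise ValueError("tss_window must be >= 0")
    by_chrom: dict[str, dict] = {}
    for gi, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(gi)
    for chrom, idx in by_chrom.items():
        tss = np.array([genes[i].tss for i in idx])
        order = np.argsort(tss, kind="stable")
        by_chrom[chrom] = {
            "tss_sorted": tss[order],
            "tss_idx": np.array(idx)[order],
            "span_start": np.array([genes[i].span.start for i in idx]),
            "span_end": np.array([genes[i].span.end for i in idx]),
            "idx": np.array(idx),
        }
    links: list[PeakGeneLink] = []
    for pi, peak in enumerate(peaks):
        pid = peak.id or f"peak_{pi + 1:06d}"
        g = by_chrom.get(peak.chrom)
        if g is not None:
            lo = np.searchsorted(g["tss_sorted"], peak.start - tss_window, side="left")
            hi = np.searchsorted(
                g["tss_sorted"], (peak.end - 1) + tss_window, side="right"
            )
            proximal = g["tss_idx"][lo:hi]
            if len(proximal):
                links.extend(
                    PeakGeneLink(pid, genes[i].gene_id, "tss_proximal", "promoter")
                    for i in sorted(proximal)
                )
                continue
            hit = (g["span_start"] < peak.end) & (g["span_end"] > peak.start)
            overlapping = g["idx"][hit]
            if len(overlapping):
                links.extend(
                    PeakGeneLink(pid, genes[i].gene_id, "gene_overlap", "enhancer")
                    for i in overlapping
                )
                continue
        links.append(PeakGeneLink(pid, None, "none", "enhancer"))
    return links


def links_to_frame(links: Sequence[PeakGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [l.peak_id for l in links],
            "gene_id": [l.gene_id for l in links],
            "link_type": [l.link_type for l in links],
            "category": [l.category for l in links],
        }
    )


def peak_categories(links: Sequence[PeakGeneLink]) -> pd.Series:
    """Per-peak promoter/enhancer category (one row per peak)."""
    frame = links_to_frame(links)
    return frame.groupby("peak_id", sort=False)["category"].first()


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million by sample (column) totals."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total count for sample(s) {bad}")
    return counts / totals * 1e6
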
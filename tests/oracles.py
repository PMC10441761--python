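"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is deliberately naive: per-base occupancy scans, all-pairs
overlap checks and full hypergeometric enumeration, kept free of any code
from the package's optimized implementations.
"""

from __future__ import annotations

from math import comb
from typing import Sequence

import numpy as np


def consensus_oracle(
    sample_peaks: Sequence[Sequence[tuple[str, int, int]]],
    min_support: int,
    genome: dict[str, int],
) -> list[tuple[str, int, int, int]]:
    """Per-base union + support scan. Returns (chrom, start, end, support)."""
    out = []
    for chrom in sorted(genome):
        length = genome[chrom]
        covered = np.zeros((len(sample_peaks), length), dtype=bool)
        for si, peaks in enumerate(sample_peaks):
            for c, s, e in peaks:
                if c == chrom:
                    covered[si, s:e] = True
        any_cov = covered.any(axis=0)
        pos = 0
        while pos < length:
            if not any_cov[pos]:
                pos += 1
                continue
            start = pos
            while pos < length and any_cov[pos]:
                pos += 1
            support = int(covered[:, start:pos].any(axis=1).sum())
            if support >= min_support:
                out.append((chrom, start, pos, support))
    return out


def count_oracle(
    fragments: Sequence[tuple[str, int, int]],
    features: Sequence[tuple[str, int, int]],
) -> list[int]:
    """All-pairs >=1 bp overlap count per feature."""
    counts = [0] * len(features)
    for fc, fs, fe in fragments:
        for i, (c, s, e) in enumerate(features):
            if fc == c and fs < e and s < fe:
                counts[i] += 1
    return counts


def annotate_oracle(
    peaks: Sequence[tuple[str, int, int]],
    genes: Sequence[tuple[str, str, int, int, str]],  # id, chrom, start, end, strand
    window: int,
) -> list[tuple[set[str], set[str], str]]:
    """Per peak: (proximal gene ids, overlap gene ids, category) by direct
    distance computation."""
    out = []
    for pc, ps, pe in peaks:
        proximal, overlapping = set(), set()
        for gid, gc, gs, ge, strand in genes:
            if gc != pc:
                continue
            tss = gs if strand == "+" else ge - 1
            if ps <= tss < pe:
                dist = 0
            else:
                dist = min(abs(tss - ps), abs(tss - (pe - 1)))
            if dist <= window:
                proximal.add(gid)
            if ps < ge and gs < pe:
                overlapping.add(gid)
        if proximal:
            out.append((proximal, set(), "promoter"))
        else:
            out.append((set(), overlapping, "enhancer"))
    return out


def fisher_p_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x: int) -> float:
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-7))


def bh_oracle(pvals: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg by the textbook formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, pvals[i] * m / rank)
        adj[i] = running_min
    return adj
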
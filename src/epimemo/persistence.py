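"""Trajectory classification across the two timepoints, cross-assay support,
and promoter/enhancer enrichment of differential peaks.

A feature tested at T1 (end of the high-fat diet phase) and T2 (after the
reversal phase) falls into exactly one class:

* significant at both timepoints, same sign  -> ``persistent_{up,down}``
* significant at both, opposite signs        -> ``inversed``
* significant at T1 only                     -> ``reversible_{up,down}``
* significant at T2 only                     -> ``late_only_{up,down}``
* significant at neither                     -> ``unchanged``

A persistent chromatin change is *supported* when a linked gene's expression
or a matched H3K27ac region shows a significant, sign-consistent change at
either timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomicInterval
from .peaks import PeakGeneLink

__all__ = [
    "CLASSES",
    "PersistenceCall",
    "EnrichmentResult",
    "classify",
    "classify_features",
    "cross_assay_support",
    "venn_summary",
    "fisher_category_enrichment",
    "fisher_exact_table",
]

CLASSES = (
    "reversible_up",
    "reversible_down",
    "persistent_up",
    "persistent_down",
    "late_only_up",
    "late_only_down",
    "inversed",
    "unchanged",
)


@dataclass
class PersistenceCall:
    feature_id: str
    cls: str
    t1_log2fc: float
    t1_p: float
    t2_log2fc: float
    t2_p: float
    supported: bool = False
    support_evidence: list[tuple[str, str, str, str]] = field(default_factory=list)
    # evidence tuples: (assay, timepoint, partner id, direction)


@dataclass
class EnrichmentResult:
    """2x2 Fisher test of category composition: rows (differential,
    background), columns (enhancer, promoter)."""

    table: np.ndarray
    odds_ratio: float
    p_two_sided: float


def classify(
    t1: tuple[float, float], t2: tuple[float, float], alpha: float = 0.01
) -> str:
    """Classify one feature from (log2fc, p) at each timepoint."""
    (lfc1, p1), (lfc2, p2) = t1, t2
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
    sig1, sig2 = p1 < alpha, p2 < alpha
    if sig1 and lfc1 == 0 or sig2 and lfc2 == 0:
        raise ValueError("significant feature with log2fc == 0: direction undefined")
    if sig1 and sig2:
        if np.sign(lfc1) != np.sign(lfc2):
            return "inversed"
        return "persistent_up" if lfc1 > 0 else "persistent_down"
    if sig1:
        return "reversible_up" if lfc1 > 0 else "reversible_down"
    if sig2:
        return "late_only_up" if lfc2 > 0 else "late_only_down"
    return "unchanged"


def classify_features(
    res_t1: pd.DataFrame,
    res_t2: pd.DataFrame,
    alpha: float = 0.01,
    mode: str = "rawp",
) -> pd.DataFrame:
    """Classify every shared feature of two differential tables.

    ``mode`` selects the significance column: ``rawp`` (``wald_p``, the
    default matching the p < 0.01 usage for RNA/ATAC/K27ac calls) or ``fdr``
    (``padj``, for broad-mark bins at FDR < 0.1).
    """
    if mode not in ("rawp", "fdr"):
        raise ValueError("mode must be 'rawp' or 'fdr'")
    col = "wald_p" if mode == "rawp" else "padj"
    common = res_t1.index.intersection(res_t2.index)
    if len(common) == 0:
        raise ValueError("no shared features between timepoints")
    t1 = res_t1.loc[common]
    t2 = res_t2.loc[common]
    classes = [
        classify((l1, p1), (l2, p2), alpha=alpha)
        for l1, p1, l2, p2 in zip(
            t1["log2fc"], t1[col], t2["log2fc"], t2[col]
        )
    ]
    return pd.DataFrame(
        {
            "class": classes,
            "t1_log2fc": t1["log2fc"].to_numpy(),
            "t1_p": t1[col].to_numpy(),
            "t2_log2fc": t2["log2fc"].to_numpy(),
            "t2_p": t2[col].to_numpy(),
            "supported": False,
        },
        index=common,
    )


def _direction(cls: str) -> str | None:
    if cls.endswith("_up"):
        return "up"
    if cls.endswith("_down"):
        return "down"
    return None


def _sign_consistent(direction: str, lfc: float) -> bool:
    return (direction == "up" and lfc > 0) or (direction == "down" and lfc < 0)


def cross_assay_support(
    calls: pd.DataFrame,
    links: Sequence[PeakGeneLink],
    rna_results: Mapping[str, pd.DataFrame],
    k27ac_results: Mapping[str, pd.DataFrame] | None = None,
    k27ac_links: Sequence[PeakGeneLink] | None = None,
    atac_peaks: Sequence[GenomicInterval] | None = None,
    k27ac_peaks: Sequence[GenomicInterval] | None = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag directional calls corroborated by RNA and/or H3K27ac evidence.

    A call with direction *d* is supported when, at either timepoint:

    * a gene linked to the peak is significant in RNA with sign matching *d*, or
    * a H3K27ac region sharing a linked gene — or directly overlapping the
      peak by >= 1 bp — is significant with sign matching *d*.

    ``rna_results`` / ``k27ac_results`` map timepoint labels ("T1", "T2") to
    differential tables indexed by gene / K27ac feature id. Returns the calls
    table with the ``supported`` column filled, plus a tidy evidence table
    (peak_id, assay, timepoint, partner, direction, channel).
    """
    gene_links: dict[str, set[str]] = {}
    for l in links:
        if l.gene_id is not None:
            gene_links.setdefault(l.peak_id, set()).add(l.gene_id)

    k27_by_gene: dict[str, set[str]] = {}
    if k27ac_links is not None:
        for l in k27ac_links:
            if l.gene_id is not None:
                k27_by_gene.setdefault(l.gene_id, set()).add(l.peak_id)

    overlap_k27: dict[str, set[str]] = {}
    if atac_peaks is not None and k27ac_peaks is not None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for kp in k27ac_peaks:
            by_chrom.setdefault(kp.chrom, []).append(kp)
        for ap in atac_peaks:
            if ap.id is None:
                continue
            hits = {
                kp.id
                for kp in by_chrom.get(ap.chrom, ())
                if kp.id is not None and kp.overlaps(ap)
            }
            if hits:
                overlap_k27[ap.id] = hits

    evidence_rows: list[dict] = []
    supported = np.zeros(len(calls), dtype=bool)
    for i, (peak_id, row) in enumerate(calls.iterrows()):
        direction = _direction(row["class"])
        if direction is None:
            continue
        genes = gene_links.get(peak_id, set())
        for tp, table in rna_results.items():
            for gene in genes & set(table.index):
                rec = table.loc[gene]
                if rec["wald_p"] < alpha and _sign_consistent(direction, rec["log2fc"]):
                    supported[i] = True
                    evidence_rows.append(
                        dict(
                            peak_id=peak_id,
                            assay="RNA",
                            timepoint=tp,
                            partner=gene,
                            direction=direction,
                            channel="linked_gene",
                        )
                    )
        if k27ac_results is None:
            continue
        candidates: dict[str, str] = {}  # k27 id -> channel
        for gene in genes:
            for kid in k27_by_gene.get(gene, ()):
                candidates.setdefault(kid, "shared_gene")
        for kid in overlap_k27.get(peak_id, ()):
            candidates[kid] = "direct_overlap"
        for tp, table in k27ac_results.items():
            for kid, channel in candidates.items():
                if kid not in table.index:
                    continue
                rec = table.loc[kid]
                if rec["wald_p"] < alpha and _sign_consistent(direction, rec["log2fc"]):
                    supported[i] = True
                    evidence_rows.append(
                        dict(
                            peak_id=peak_id,
                            assay="K27ac",
                            timepoint=tp,
                            partner=kid,
                            direction=direction,
                            channel=channel,
                        )
                    )
    out = calls.copy()
    out["supported"] = supported
    evidence = pd.DataFrame(
        evidence_rows,
        columns=["peak_id", "assay", "timepoint", "partner", "direction", "channel"],
    )
    return out, evidence


def venn_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Tidy count table of calls per class (all classes listed, zeros kept)."""
    counts = calls["class"].value_counts()
    rows = []
    for cls in CLASSES:
        rows.append(
            {
                "class": cls,
                "direction": _direction(cls) or "both",
                "n": int(counts.get(cls, 0)),
            }
        )
    out = pd.DataFrame(rows)
    assert out["n"].sum() == len(calls)
    return out


def fisher_category_enrichment(
    differential_ids: Sequence[str],
    categories: pd.Series,
    background: str = "all",
) -> EnrichmentResult:
    """Fisher's exact test for enhancer enrichment among differential peaks.

    ``categories`` maps every peak id to ``promoter``/``enhancer``.
    ``background`` is ``all`` peaks (default) or ``non_differential``.
    The 2x2 table is rows (differential, background) × columns
    (enhancer, promoter); a zero cross-product cell gives an infinite odds
    ratio by convention.
    """
    diff_ids = set(differential_ids)
    if not diff_ids:
        raise ValueError("empty differential peak set")
    unknown = diff_ids - set(categories.index)
    if unknown:
        raise ValueError(f"differential peaks missing categories: {sorted(unknown)[:5]}")
    if background not in ("all", "non_differential"):
        raise ValueError("background must be 'all' or 'non_differential'")
    is_diff = categories.index.isin(diff_ids)
    is_enh = (categories == "enhancer").to_numpy()
    bg = np.ones(len(categories), dtype=bool) if background == "all" else ~is_diff
    table = np.array(
        [
            [int((is_diff & is_enh).sum()), int((is_diff & ~is_enh).sum())],
            [int((bg & is_enh).sum()), int((bg & ~is_enh).sum())],
        ]
    )
    odds_ratio, p = fisher_exact_table(table)
    return EnrichmentResult(table=table, odds_ratio=odds_ratio, p_two_sided=p)


def fisher_exact_table(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (sample odds ratio, p); a zero cross-product denominator maps to
    an infinite odds ratio.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p)
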
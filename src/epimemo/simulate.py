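"""Synthetic multi-omic experiments with planted ground truth.

The generator emulates the two-condition, two-timepoint diet-reversal
design: four groups (NC and HFD at the end of the diet phase; NC-NC and
HFD-NC after the reversal phase) with unbalanced replicate numbers per
assay, negative-binomial counts with per-library size factors, per-sample
peak calls with dropout and boundary jitter, and signal tracks with known
library scale factors. Every feature carries a planted trajectory class
(null / reversible / persistent / late-only / inversed) that downstream
modules are expected to recover.

Everything is driven by one integer seed; a fixed seed yields byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genome import (
    GeneModel,
    GenomicInterval,
    SampleSheet,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_count_matrix,
    write_gene_table,
    write_sample_sheet,
)

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_counts",
    "simulate_peak_calls",
    "simulate_tracks",
    "simulate_experiment",
]

CLASS_NAMES = ("null", "reversible", "persistent", "late_only", "inversed")
GROUP_ORDER = ("NC", "HFD", "NC-NC", "HFD-NC")

# geometry of one simulated gene locus (bp)
_TSS_OFFSET = 6001  # room for a minus-strand gene body left of its TSS
_DISTAL_OFFSET = 2500  # first distal peak slot, > 2 kb from the TSS
_SLOT_SPACING = 1600  # distal slots never collide (peak <= 1000 bp)
_MIN_PEAK, _MAX_PEAK = 200, 1000
_MIN_GENE, _MAX_GENE = 2000, 6000
_BLOCK_SLACK = 3000


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study-design defaults."""

    seed: int = 0
    chrom_sizes: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 2_000_000),
            ("chr2", 1_600_000),
            ("chr3", 1_200_000),
        ]
    )
    n_genes: int = 300
    n_peaks: int = 600
    # replicates per (NC, HFD, NC-NC, HFD-NC)
    replicates: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: {
            "RNA": (8, 7, 15, 16),
            "ATAC": (7, 6, 9, 6),
            "K27ac": (3, 3, 3, 3),
        }
    )
    baseline_mean: float = 200.0
    dispersion: float = 0.05
    effect_lfc: float = 1.5
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "null": 0.6,
            "reversible": 0.1,
            "persistent": 0.1,
            "late_only": 0.1,
            "inversed": 0.1,
        }
    )
    libsize_range: tuple[float, float] = (0.5, 2.0)
    peak_dropout: float = 0.2
    boundary_jitter: int = 50
    promoter_fraction: float = 0.45
    concordance: float = 0.8
    n_track_regions: int = 5000
    track_sigma: float = 0.1
    track_region_width: int = 200

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}")
        for name, rate in [
            ("peak_dropout", self.peak_dropout),
            ("promoter_fraction", self.promoter_fraction),
            ("concordance", self.concordance),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name}={rate} outside [0, 1]")
        if self.peak_dropout >= 1:
            raise ValueError("peak_dropout must be < 1")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        lo, hi = self.libsize_range
        if not 0 < lo <= hi:
            raise ValueError("libsize_range must be positive and ordered")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chrom_sizes" in raw:
            raw["chrom_sizes"] = [(str(c), int(l)) for c, l in raw["chrom_sizes"]]
        if "replicates" in raw:
            raw["replicates"] = {
                k: tuple(int(x) for x in v) for k, v in raw["replicates"].items()
            }
        if "libsize_range" in raw:
            raw["libsize_range"] = tuple(raw["libsize_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "chrom_sizes": [[c, l] for c, l in self.chrom_sizes],
            "n_genes": self.n_genes,
            "n_peaks": self.n_peaks,
            "replicates": {k: list(v) for k, v in self.replicates.items()},
            "baseline_mean": self.baseline_mean,
            "dispersion": self.dispersion,
            "effect_lfc": self.effect_lfc,
            "class_fractions": dict(self.class_fractions),
            "libsize_range": list(self.libsize_range),
            "peak_dropout": self.peak_dropout,
            "boundary_jitter": self.boundary_jitter,
            "promoter_fraction": self.promoter_fraction,
            "concordance": self.concordance,
            "n_track_regions": self.n_track_regions,
            "track_sigma": self.track_sigma,
            "track_region_width": self.track_region_width,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _block_length(peaks_per_gene: int) -> int:
    return (
        _TSS_OFFSET
        + _DISTAL_OFFSET
        + (peaks_per_gene - 1) * _SLOT_SPACING
        + _MAX_PEAK
        + _BLOCK_SLACK
    )


def simulate_genome(
    config: SimConfig,
) -> tuple[list[GeneModel], list[GenomicInterval], pd.DataFrame]:
    """Place genes and non-overlapping peaks on the configured chromosomes.

    Each peak belongs to one gene locus by construction: promoter peaks
    straddle their gene's TSS (both ends well within 2 kb), distal peaks sit
    > 2 kb from every TSS. Returns (genes, peaks, assignment table) where the
    assignment table has columns (peak_id, gene_id, is_promoter).
    """
    rng = _rngs(config.seed, 6)[0]
    n_genes, n_peaks = config.n_genes, config.n_peaks
    if n_genes < 1:
        raise ValueError("need at least one gene")
    peaks_per_gene = max(1, math.ceil(n_peaks / n_genes)) if n_peaks else 1
    block = _block_length(peaks_per_gene)

    blocks: list[tuple[str, int]] = []  # (chrom, block_start)
    for chrom, length in config.chrom_sizes:
        for b in range(length // block):
            if len(blocks) >= n_genes:
                break
            blocks.append((chrom, b * block))
    if len(blocks) < n_genes:
        raise ValueError(
            f"genome too small: fits {len(blocks)} gene loci of {block} bp, "
            f"need {n_genes}"
        )

    genes: list[GeneModel] = []
    tss_positions: list[int] = []
    for gi, (chrom, bstart) in enumerate(blocks):
        tss = bstart + _TSS_OFFSET
        gene_len = int(rng.integers(_MIN_GENE, _MAX_GENE + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            span = GenomicInterval(chrom, tss, tss + gene_len)
        else:
            span = GenomicInterval(chrom, tss + 1 - gene_len, tss + 1)
        genes.append(GeneModel(f"gene_{gi + 1:05d}", span, strand))
        tss_positions.append(tss)

    n_prom = int(round(config.promoter_fraction * n_peaks))
    slot0_genes = min(n_peaks, n_genes)
    if n_prom > slot0_genes:
        raise ValueError(
            f"promoter_fraction asks for {n_prom} promoter peaks but only "
            f"{slot0_genes} genes have a first peak slot"
        )
    promoter_owner = set(
        rng.choice(slot0_genes, size=n_prom, replace=False).tolist()
    )

    raw: list[tuple[GenomicInterval, int, bool]] = []  # interval, gene idx, promoter?
    for pi in range(n_peaks):
        gi = pi % n_genes
        slot = pi // n_genes
        chrom = genes[gi].chrom
        tss = tss_positions[gi]
        length = int(rng.integers(_MIN_PEAK, _MAX_PEAK + 1))
        if slot == 0 and gi in promoter_owner:
            length = min(length, 1000)
            start = tss - length // 2
            raw.append((GenomicInterval(chrom, start, start + length), gi, True))
        else:
            start = tss + _DISTAL_OFFSET + slot * _SLOT_SPACING
            raw.append((GenomicInterval(chrom, start, start + length), gi, False))

    raw.sort(key=lambda t: t[0])
    peaks: list[GenomicInterval] = []
    rows = []
    for i, (iv, gi, prom) in enumerate(raw):
        pid = f"peak_{i + 1:06d}"
        peaks.append(GenomicInterval(iv.chrom, iv.start, iv.end, id=pid))
        rows.append(
            {"peak_id": pid, "gene_id": genes[gi].gene_id, "is_promoter": prom}
        )
    assignment = pd.DataFrame(rows, columns=["peak_id", "gene_id", "is_promoter"])
    return genes, peaks, assignment


def _plant_classes(config: SimConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    fractions = np.array([config.class_fractions.get(c, 0.0) for c in CLASS_NAMES])
    cls = rng.choice(len(CLASS_NAMES), size=n, p=fractions)
    direction = np.where(rng.random(n) < 0.5, "up", "down")
    return pd.DataFrame(
        {
            "class": [CLASS_NAMES[c] for c in cls],
            "direction": direction,
        }
    )


def _effect_multipliers(
    classes: pd.DataFrame, effect_lfc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature multiplicative effect at T1 and T2 (applied to the
    HFD / HFD-NC group respectively)."""
    sign = np.where(classes["direction"].to_numpy() == "up", 1.0, -1.0)
    cls = classes["class"].to_numpy()
    t1 = np.ones(len(classes))
    t2 = np.ones(len(classes))
    at_t1 = np.isin(cls, ("reversible", "persistent", "inversed"))
    t1[at_t1] = 2.0 ** (sign[at_t1] * effect_lfc)
    at_t2_same = np.isin(cls, ("persistent", "late_only"))
    t2[at_t2_same] = 2.0 ** (sign[at_t2_same] * effect_lfc)
    inv = cls == "inversed"
    t2[inv] = 2.0 ** (-sign[inv] * effect_lfc)
    return t1, t2


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = 1.0 / (1.0 + dispersion * mean)
    return rng.negative_binomial(n, p)


def _assay_sheet(assay: str, reps: tuple[int, int, int, int]) -> SampleSheet:
    rows = []
    for group, n in zip(GROUP_ORDER, reps):
        tp = "T1" if group in ("NC", "HFD") else "T2"
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"{assay}_{group}_{r}",
                    "assay": assay,
                    "group": group,
                    "timepoint": tp,
                    "replicate": r,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def _simulate_matrix(
    feature_ids: Sequence[str],
    classes: pd.DataFrame,
    sheet: SampleSheet,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB counts for one assay given planted per-feature classes."""
    t1_mult, t2_mult = _effect_multipliers(classes, config.effect_lfc)
    lo, hi = config.libsize_range
    sample_ids = sheet.sample_ids()
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_ids)))
    counts = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        row = sheet.frame.loc[sheet.frame["sample_id"] == sid].iloc[0]
        if row["group"] == "HFD":
            eff = t1_mult
        elif row["group"] == "HFD-NC":
            eff = t2_mult
        else:
            eff = 1.0
        mean = config.baseline_mean * libsize[j] * eff
        counts[:, j] = _nb_draw(rng, np.broadcast_to(mean, (len(feature_ids),)), config.dispersion)
    frame = pd.DataFrame(counts, index=list(feature_ids), columns=sample_ids)
    return frame, pd.Series(libsize, index=sample_ids, name="libsize_factor")


def simulate_counts(
    config: SimConfig,
    peaks: Sequence[GenomicInterval],
    assignment: pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], dict[str, SampleSheet], pd.DataFrame, dict[str, pd.Series]]:
    """Simulate count matrices for every configured assay.

    ATAC features are the peaks; K27ac features are co-located regions (one
    per peak, id ``k27_<peak_id>``); RNA features are the genes. A peak's
    planted effect is mirrored on its linked gene's RNA feature and its
    K27ac partner with probability ``config.concordance`` (independently per
    assay); discordant partners stay null.

    Returns (counts per assay, sample sheet per assay, truth table,
    per-assay library size factors).
    """
    rng_cls, rng_counts, rng_conc = _rngs(config.seed, 6)[1:4]
    peak_ids = [p.id for p in peaks]
    classes = _plant_classes(config, len(peaks), rng_cls)
    classes.index = peak_ids

    nonnull = classes["class"].to_numpy() != "null"
    rna_conc = (rng_conc.random(len(peaks)) < config.concordance) & nonnull
    k27_conc = (rng_conc.random(len(peaks)) < config.concordance) & nonnull

    gene_of_peak = assignment.set_index("peak_id")["gene_id"]
    truth = pd.DataFrame(
        {
            "feature_id": peak_ids,
            "class": classes["class"].to_numpy(),
            "direction": classes["direction"].to_numpy(),
            "gene_id": gene_of_peak.loc[peak_ids].to_numpy(),
            "rna_concordant": rna_conc,
            "k27ac_concordant": k27_conc,
        }
    )

    # gene-level classes: first concordant non-null peak wins, others null
    gene_ids = sorted(set(assignment["gene_id"]))
    gene_cls = pd.DataFrame(
        {"class": "null", "direction": "up"}, index=gene_ids
    )
    for pid, conc in zip(peak_ids, rna_conc):
        if conc:
            g = gene_of_peak[pid]
            if gene_cls.loc[g, "class"] == "null":
                gene_cls.loc[g, "class"] = classes.loc[pid, "class"]
                gene_cls.loc[g, "direction"] = classes.loc[pid, "direction"]

    k27_classes = classes.copy()
    k27_classes.loc[~k27_conc, "class"] = "null"
    k27_classes.index = [f"k27_{pid}" for pid in peak_ids]

    counts: dict[str, pd.DataFrame] = {}
    sheets: dict[str, SampleSheet] = {}
    libsizes: dict[str, pd.Series] = {}
    for assay, reps in config.replicates.items():
        sheet = _assay_sheet(assay, reps)
        if assay == "RNA":
            feats, cls_table = gene_ids, gene_cls
        elif assay == "K27ac":
            feats, cls_table = list(k27_classes.index), k27_classes
        else:
            feats, cls_table = peak_ids, classes
        counts[assay], libsizes[assay] = _simulate_matrix(
            feats, cls_table, sheet, config, rng_counts
        )
        sheets[assay] = sheet
    return counts, sheets, truth, libsizes


def simulate_peak_calls(
    peaks: Sequence[GenomicInterval],
    config: SimConfig,
    n_samples: int | None = None,
) -> list[list[GenomicInterval]]:
    """Per-sample peak-call lists: the true peaks with independent dropout
    and uniform boundary jitter of up to ``boundary_jitter`` bp per end."""
    rng = _rngs(config.seed, 6)[4]
    if n_samples is None:
        n_samples = sum(config.replicates.get("ATAC", (7, 6, 9, 6)))
    j = config.boundary_jitter
    out: list[list[GenomicInterval]] = []
    for _ in range(n_samples):
        sample: list[GenomicInterval] = []
        for peak in peaks:
            if rng.random() < config.peak_dropout:
                continue
            if j > 0:
                start = peak.start + int(rng.integers(-j, j + 1))
                end = peak.end + int(rng.integers(-j, j + 1))
            else:
                start, end = peak.start, peak.end
            start = max(0, start)
            if end <= start:
                end = start + 1
            sample.append(GenomicInterval(peak.chrom, start, end, id=peak.id))
        out.append(sample)
    return out


def simulate_tracks(
    config: SimConfig,
    true_scale: Mapping[str, float],
    sigma: float | None = None,
) -> tuple[list[GenomicInterval], dict[str, SignalTrack]]:
    """Signal tracks over tiled regions with known per-library scale factors.

    Region *r* of library *l* gets value ``base_r * true_scale_l * exp(eps)``
    with ``eps ~ Normal(0, sigma^2)``; the per-region base level is
    log-uniform over 2.5 decades so the stability filters have work to do.
    """
    if any(s <= 0 for s in true_scale.values()):
        raise ValueError("true_scale factors must be positive")
    rng = _rngs(config.seed, 6)[5]
    if sigma is None:
        sigma = config.track_sigma
    w = config.track_region_width
    n = config.n_track_regions
    regions = [
        GenomicInterval("chrSim", i * w, (i + 1) * w, id=f"region_{i + 1:06d}")
        for i in range(n)
    ]
    base = 10.0 ** rng.uniform(0.0, 2.5, size=n)
    tracks = {}
    for lib, scale in true_scale.items():
        noise = np.exp(rng.normal(0.0, sigma, size=n)) if sigma > 0 else 1.0
        values = base * scale * noise
        starts = np.arange(n, dtype=np.int64) * w
        tracks[lib] = SignalTrack({"chrSim": (starts, starts + w, values)})
    return regions, tracks


def simulate_experiment(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every artifact under ``outdir``.

    Writes chrom.sizes, genes.tsv, true_peaks.bed, per-sample ATAC peak-call
    BEDs, one count TSV per assay, a combined sample sheet, the truth table,
    per-library bedGraphs with their true scale factors, and the config as
    YAML. Returns the path of each artifact by name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes, peaks, assignment = simulate_genome(config)
    counts, sheets, truth, libsizes = simulate_counts(config, peaks, assignment)
    atac_n = sum(config.replicates.get("ATAC", (7, 6, 9, 6)))
    calls = simulate_peak_calls(peaks, config, n_samples=atac_n)

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(config.chrom_sizes, paths["chrom_sizes"])
    paths["genes"] = outdir / "genes.tsv"
    write_gene_table(genes, paths["genes"])
    paths["true_peaks"] = outdir / "true_peaks.bed"
    write_bed(peaks, paths["true_peaks"])
    paths["assignment"] = outdir / "peak_gene_assignment.tsv"
    assignment.to_csv(paths["assignment"], sep="\t", index=False)

    call_dir = outdir / "peak_calls"
    call_dir.mkdir(exist_ok=True)
    atac_ids = sheets["ATAC"].sample_ids() if "ATAC" in sheets else [
        f"ATAC_sample_{i + 1}" for i in range(atac_n)
    ]
    for sid, sample_peaks in zip(atac_ids, calls):
        write_bed(sample_peaks, call_dir / f"{sid}.bed")
    paths["peak_calls"] = call_dir

    all_sheets = pd.concat([s.frame for s in sheets.values()], ignore_index=True)
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    write_sample_sheet(SampleSheet(all_sheets), paths["sample_sheet"])

    for assay, frame in counts.items():
        p = outdir / f"counts_{assay}.tsv"
        write_count_matrix(frame, p)
        paths[f"counts_{assay}"] = p
    lib_frame = pd.concat(libsizes.values()).rename_axis("sample_id").reset_index()
    paths["libsize_factors"] = outdir / "libsize_factors.tsv"
    lib_frame.to_csv(paths["libsize_factors"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)

    true_scale = {"lib1": 0.5, "lib2": 1.0, "lib3": 2.0}
    regions, tracks = simulate_tracks(config, true_scale)
    track_dir = outdir / "tracks"
    track_dir.mkdir(exist_ok=True)
    for lib, track in tracks.items():
        write_bedgraph(track, track_dir / f"{lib}.bedgraph")
    paths["tracks"] = track_dir
    paths["track_regions"] = outdir / "track_regions.bed"
    write_bed(regions, paths["track_regions"])
    pd.Series(true_scale, name="true_scale").rename_axis("library").reset_index().to_csv(
        outdir / "true_track_scale.tsv", sep="\t", index=False
    )
    paths["true_track_scale"] = outdir / "true_track_scale.tsv"

    paths["config"] = outdir / "config.yaml"
    config.to_yaml(paths["config"])
    return paths
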
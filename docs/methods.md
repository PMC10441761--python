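# Methods

## Study design and data model

The package analyses a two-condition, two-timepoint design. Group labels are
coupled to timepoints: NC and HFD exist only at T1 (end of the diet phase),
NC-NC and HFD-NC only at T2 (after the reversal phase). The two contrasts of
interest are HFD vs NC at T1 and HFD-NC vs NC-NC at T2; every downstream
classification is a function of a feature's (log2 fold change, p) pair at
each timepoint.

All coordinates are 0-based half-open throughout; GFF3 input is converted at
the file boundary. Chromosome names are never normalized — a mismatch
between input files surfaces as missing overlap/zero signal with a warning
rather than being silently patched.

## Consensus peaks

Per-sample peak calls are pooled and merged into maximal union intervals;
book-ended intervals merge (coverage is contiguous). Each union interval's
support is the number of distinct samples contributing at least 1 bp, and
intervals with support below `min_support` (default 6, "at least" being
inclusive) are dropped. Support counts samples, not peaks: two calls from
one sample falling in the same union interval contribute once. The
implementation is a sort-and-sweep and is property-tested against a
per-base occupancy oracle.

## Counting and annotation

Fragment counting is any-overlap (≥ 1 bp, half-open, so abutting intervals
do not count); a fragment spanning two features increments both. A
`midpoint` mode assigns each fragment to the single feature containing its
midpoint. Features must be non-overlapping — overlapping features are an
error, not a silent double count. Broad marks are quantified in fixed-width
bins (default 4 kb, last bin truncated at the chromosome end).

Peak-to-gene annotation: a peak is linked (`tss_proximal`) to every gene
whose TSS lies within the window (default 2 kb) of either peak end, with TSS
positions inside the peak included; the TSS of a minus-strand gene is the
last base of its span, so the rule is strand-aware but symmetric around a
single base. Only when a peak has no proximal TSS is it linked to genes
whose spans overlap it (`gene_overlap`). Peaks with at least one proximal
link are promoters; all others are enhancers. Window edges are inclusive,
with distance measured to the nearest end base.

## Differential testing

The differential stage is a deliberately transparent two-group NB pipeline:

- **Size factors** — median-of-ratios: the reference for feature *i* is its
  geometric mean across samples (features containing any zero are excluded
  from the reference set); sample *j*'s factor is the median ratio to the
  reference.
- **Dispersion** — NB parameterized as var = μ + αμ². Per feature, a
  method-of-moments estimate α = (s² − m)/m² is computed *within* each
  group on normalized counts (pooling across groups would absorb a real
  group effect into the dispersion) and combined by degrees of freedom. The
  combined estimate is then shrunk toward the cross-feature median with 10
  pseudo degrees of freedom. The shrinkage matters: with three replicates
  per group the raw per-feature estimate has four degrees of freedom, and
  its downward outliers make the Wald test badly anticonservative (measured
  null fraction of p < 0.01 ≈ 0.057 at n = 3/3 without shrinkage, ≈ 0.020
  with it). The standalone `estimate_dispersion` function keeps the pure
  method-of-moments contract; the shrinkage is applied by
  `run_differential`.
- **Wald test** — group means μ̂ are means of size-factor-normalized counts;
  log2fc = log2(μ̂_B/μ̂_A) with a pseudo-mean guard c = 0.5 added to both
  means only when either falls below c (so the common case is unbiased and
  an all-zero group still yields finite, flagged output). Delta-method
  variance Var(log2 μ̂_g) = (1/ln2)² (1/μ̂_g + α̂)/n_g summed over groups;
  p is the two-sided normal tail. Residual anticonservatism (normal rather
  than t tails; the Poisson term ignores the spread of size factors) leaves
  the null fraction of p < 0.01 near 0.016 at the 7-vs-6 design rather than
  0.01 exactly.
- **Multiple testing** — Benjamini–Hochberg step-up (delegated to
  statsmodels), no independent filtering.
- **Thresholds** — classification defaults to raw p < 0.01 per timepoint
  (the convention for the peak-level assays in this design); an `fdr` mode
  switches to adjusted p (e.g. < 0.1 for binned broad marks).

This is not a reimplementation of DESeq2: Cox–Reid-adjusted likelihood
dispersion, trend fitting, LFC shrinkage, Cook's-distance outlier handling
and independent filtering are intentionally absent, and numerical agreement
with DESeq2 on real data is not expected or chased.

## Trajectory classification and cross-assay support

Given (lfc, p) at T1 and T2 and a level α, each feature receives exactly one
class: significant at both timepoints and same sign → `persistent_{up,down}`;
both and opposite signs → `inversed`; T1 only → `reversible_{up,down}`;
T2 only → `late_only_{up,down}`; neither → `unchanged`. A significant result
with lfc = 0 has no direction and is an error rather than an arbitrary
tie-break.

A directional call is *supported* when, at either timepoint, (a) a gene
linked to the peak is significant in RNA with matching sign, or (b) an
H3K27ac region that shares a linked gene with the peak or directly overlaps
it (≥ 1 bp) is significant with matching sign. "Consistent" is read as sign
match of the log2 fold changes — the minimal reading; the evidence table
records every match with its channel (`linked_gene`, `shared_gene`,
`direct_overlap`), so stricter definitions can be applied downstream.
Evidence from either timepoint counts (the any-timepoint reading).

Category enrichment of differential peaks uses a two-sided Fisher's exact
test on the 2×2 table (differential vs background) × (enhancer vs promoter).
The default background is *all* peaks, including the differential ones —
matching the "differential proportion vs overall proportion" comparison this
analysis style reports; `background="non_differential"` gives the disjoint
table.

## Track scaling

Browser tracks are rescaled by a per-library factor fitted on stable
regions. Candidate region signals are length-weighted sums of bedGraph
values (a mean-per-bp view differs only by a constant for equal-width
regions). Filters run in order: (1) drop regions whose cross-library average
ranks in the top 100 — with fewer than 100 regions this degenerates to
dropping the single maximum, with a warning; (2) drop regions whose average
falls below the global average over all regions × libraries; (3) among
survivors, drop the top 10% by cross-library variation, measured by default
as the coefficient of variation (scale-free, hence robust to the very
scale differences being corrected; `sd` and `var` modes exist). Every input
region gets exactly one recorded fate.

Each library's retained signals are regressed through the origin against the
cross-library average; the slope is the scaling factor and the track is
divided by it. Through-origin is the default because a pure scaling must map
zero to zero; an intercept mode exists. Note the regression identifies
factors only up to one global constant (the library equal to the average
gets slope 1), so comparisons against planted truth are made after rescaling
both sets to geometric mean 1.

## Synthetic data generator

The generator emulates the study: four groups with the design's unbalanced
replicate counts (RNA 8/7/15/16, ATAC 7/6/9/6, ChIP 3/3/3/3), NB counts with
per-library size factors drawn log-uniformly from [0.5, 2], and planted
trajectory classes {null, reversible, persistent, late-only, inversed} with
a single effect magnitude |log2 fold change| = 1.5 applied to the HFD group
at T1 and/or the HFD-NC group at T2 according to the class. Defaults:
baseline mean 200 and dispersion 0.05 (typical of a well-covered peak in a
moderately deep library), 60% null features, promoter fraction 0.45,
per-sample peak-call dropout 0.2 with ±50 bp boundary jitter, and
cross-assay concordance 0.8 (the probability that a peak's effect is
mirrored on its linked gene's RNA feature and on a co-located H3K27ac
feature, drawn independently per partner assay).

Gene loci are laid out in disjoint blocks so that promoter peaks straddle
their own gene's TSS and distal peaks sit > 2 kb from every TSS — peak–gene
assignment is unambiguous by construction, which is what makes annotation
and support logic testable against planted truth. Signal tracks place a
log-uniform base level spanning 2.5 decades over tiled regions and multiply
by the library's planted factor and log-normal noise.

What the generator does *not* emulate: read-level artifacts (GC and
mappability bias, duplicates), batch effects, dispersion heterogeneity
across features, correlated features, partial-overlap peak structure across
assays, and gene-dense regions where nearest-gene assignment is ambiguous.
Passing recovery tests therefore demonstrates the correctness and
calibration of the implementation under the stated model, not performance on
real sequencing data.

Everything derives from a single integer seed through independent
sub-streams; a fixed seed reproduces every output file byte for byte.

## Problem sizes and tolerances

The test-suite and acceptance-script experiments use: 100 random toy
instances for the interval oracles (≤ 5 samples, ≤ 50 peaks, ≤ 100 kb
genome); exhaustive 2×2 tables to total 30 for Fisher (tolerance 1e-10);
2,000 null features × 10 seeds for size-factor recovery (5% bound); 20,000
null features at the 7/6 design for type-I calibration (band 0.003–0.03 at
p < 0.01, acknowledging the small-sample anticonservatism discussed above);
2,500 features split evenly over the five classes for classification
recovery; 2,000 peaks (half persistent) for the support-rate checks; and
5,000 regions × 10 seeds for track-factor recovery (exact at σ = 0, 10% at
σ = 0.1). These sizes give the binomial standard errors needed for the
stated bounds while keeping a full run on one CPU in well under a minute
per experiment.

## Known limitations

- The Wald test is mildly anticonservative at small n; raw-p thresholds are
  conventions of the analysis style, not calibrated FDR guarantees.
- The size-factor estimator needs at least one feature with no zero counts;
  very sparse matrices require a pseudo-reference upstream.
- Cross-assay support treats evidence tests as independent channels; it does
  not correct for the number of candidate partners per peak.
- The consensus rule counts sample presence as ≥ 1 bp overlap with the
  merged interval; deeply nested or chained peaks can therefore link distant
  calls into one supported interval.
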
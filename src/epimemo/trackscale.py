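"""Stable-region scaling of browser tracks.

Depth (CPM) normalization alone leaves visible library-to-library height
differences in ATAC/ChIP tracks, largely from differing signal-to-noise
ratios. This module implements the regression fix: pick candidate regions
(e.g. 2-kb TSS windows), discard unstable ones, regress each library's
region signals against the cross-library average through the origin, and
divide the library's track by the fitted slope.

Region filters, applied in order:

1. drop regions whose cross-library average signal ranks in the top 100
   (with fewer than 100 regions, only the single maximum is dropped, with a
   warning);
2. drop regions whose cross-library average is below the global average over
   all regions x libraries;
3. among survivors, drop regions whose cross-library variation (coefficient
   of variation by default) ranks in the top 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomicInterval, SignalTrack

__all__ = [
    "StableRegionSet",
    "region_signals",
    "select_stable_regions",
    "fit_scaling_factors",
    "rescale_track",
    "normalize_tracks",
]

EXCLUSION_REASONS = (
    "top100_average",
    "below_global_average",
    "top10pct_variation",
    "retained",
)


@dataclass
class StableRegionSet:
    """Region x library signal matrix plus the per-region filter outcome."""

    signals: pd.DataFrame  # all input regions x libraries
    reasons: pd.Series  # per region, one of EXCLUSION_REASONS

    @property
    def retained(self) -> pd.DataFrame:
        return self.signals.loc[self.reasons == "retained"]


def region_signals(
    tracks: Mapping[str, SignalTrack],
    regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Length-weighted signal sum per region per library.

    ``signal(r, l) = sum over track intervals of value x overlapping bp``;
    uncovered bases contribute 0. Regions must be non-overlapping. A region
    on a chromosome absent from a track scores 0 with a warning.
    """
    ids = [r.id or f"region_{i + 1:06d}" for i, r in enumerate(regions)]
    out = np.zeros((len(regions), len(tracks)))
    warned: set[tuple[str, str]] = set()
    for j, (lib, track) in enumerate(tracks.items()):
        for i, region in enumerate(regions):
            if region.chrom not in track.data:
                if (lib, region.chrom) not in warned:
                    warnings.warn(
                        f"library {lib}: chromosome {region.chrom} absent from track"
                    )
                    warned.add((lib, region.chrom))
                continue
            starts, ends, values = track.data[region.chrom]
            lo = np.searchsorted(ends, region.start, side="right")
            hi = np.searchsorted(starts, region.end, side="left")
            if hi <= lo:
                continue
            covered = np.minimum(ends[lo:hi], region.end) - np.maximum(
                starts[lo:hi], region.start
            )
            out[i, j] = float(np.dot(values[lo:hi], covered))
    return pd.DataFrame(out, index=ids, columns=list(tracks))


def select_stable_regions(
    signals: pd.DataFrame,
    top_n: int = 100,
    variation_quantile: float = 0.10,
    variation: str = "cv",
) -> StableRegionSet:
    """Apply the three stability filters and record each region's fate."""
    if signals.shape[1] < 2:
        raise ValueError("need >= 2 libraries")
    if variation not in ("cv", "sd", "var"):
        raise ValueError("variation must be 'cv', 'sd' or 'var'")
    x = signals.to_numpy(dtype=float)
    n_regions = len(signals)
    reasons = pd.Series("retained", index=signals.index, dtype=object)

    region_avg = x.mean(axis=1)
    if n_regions < top_n:
        warnings.warn(
            f"only {n_regions} regions; top-{top_n} filter degenerates to "
            "dropping the single maximum"
        )
        n_top = 1
    else:
        n_top = top_n
    top_idx = np.argsort(region_avg)[::-1][:n_top]
    reasons.iloc[top_idx] = "top100_average"

    global_avg = x.mean()
    low = (region_avg < global_avg) & (reasons == "retained").to_numpy()
    reasons.iloc[np.flatnonzero(low)] = "below_global_average"

    survivors = np.flatnonzero((reasons == "retained").to_numpy())
    if survivors.size:
        sub = x[survivors]
        sd = sub.std(axis=1, ddof=1)
        mean = sub.mean(axis=1)
        if variation == "cv":
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(mean > 0, sd / mean, np.inf)
        elif variation == "sd":
            v = sd
        else:
            v = sd**2
        cutoff = np.quantile(v, 1.0 - variation_quantile)
        noisy = survivors[v > cutoff]
        reasons.iloc[noisy] = "top10pct_variation"

    if not (reasons == "retained").any():
        raise ValueError("no region survived the stability filters")
    return StableRegionSet(signals=signals, reasons=reasons)


def fit_scaling_factors(
    stable: StableRegionSet, intercept: bool = False
) -> pd.DataFrame:
    """Per-library scaling factor from regression against the cross-library
    average over retained regions.

    Through the origin (default): ``factor = sum(x*y) / sum(x**2)`` where x
    is the average signal and y the library's signal. With ``intercept`` the
    slope of an ordinary least squares fit is used instead. Returns a table
    (factor, n_regions, residual_variance) indexed by library.
    """
    y = stable.retained.to_numpy(dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need >= 2 retained regions")
    x = y.mean(axis=1)
    if not np.any(x > 0):
        raise ValueError("all retained-region averages are zero")
    rows = []
    for j, lib in enumerate(stable.retained.columns):
        if intercept:
            slope, _ = np.polyfit(x, y[:, j], 1)
        else:
            slope = float(np.dot(x, y[:, j]) / np.dot(x, x))
        resid = y[:, j] - slope * x
        rows.append(
            {
                "library": lib,
                "factor": float(slope),
                "n_regions": int(len(x)),
                "residual_variance": float(np.var(resid, ddof=1)),
            }
        )
    out = pd.DataFrame(rows).set_index("library")
    if (out["factor"] <= 0).any():
        bad = list(out.index[out["factor"] <= 0])
        raise ValueError(f"non-positive scaling factor for {bad}")
    return out


def rescale_track(track: SignalTrack, factor: float) -> SignalTrack:
    """Divide every track value by ``factor`` (> 0); intervals unchanged."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return track.scale(1.0 / factor)


def normalize_tracks(
    tracks: Mapping[str, SignalTrack],
    regions: Sequence[GenomicInterval],
    variation: str = "cv",
    intercept: bool = False,
) -> tuple[pd.DataFrame, dict[str, SignalTrack], StableRegionSet]:
    """End-to-end stable-region normalization.

    Returns (factor table, rescaled tracks, stable-region record).
    """
    signals = region_signals(tracks, regions)
    stable = select_stable_regions(signals, variation=variation)
    factors = fit_scaling_factors(stable, intercept=intercept)
    rescaled = {
        lib: rescale_track(tracks[lib], factors.loc[lib, "factor"]) for lib in tracks
    }
    return factors, rescaled, stable
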
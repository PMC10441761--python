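"""Two-group negative-binomial differential testing.

A deliberately transparent re-implementation of the standard count-based
differential pipeline: median-of-ratios size factors, method-of-moments
NB dispersion, a delta-method Wald test on the log2 fold change of group
means, and Benjamini–Hochberg adjustment. It trades the shrinkage machinery
of full GLM-based tools (dispersion trend fitting, Cox–Reid adjustment,
independent filtering) for auditability; divergences from those tools are
expected and documented in the methods note.

The NB parameterization throughout is mean/dispersion with
``var = mu + alpha * mu**2``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import SampleSheet

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "log2_z_transform",
    "run_differential",
]

ALPHA_FLOOR = 1e-8
LOW_MEAN_GUARD = 0.5
LN2 = np.log(2.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference for feature *i* is its geometric mean across samples,
    computed over features with no zero count; sample *j*'s factor is the
    median over those features of ``count_ij / reference_i``.
    """
    x = counts.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; size factors "
            "need at least one such feature (use more features or a "
            "pseudo-reference)"
        )
    logx = np.log(x[all_positive])
    log_ref = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(normalized: pd.DataFrame | np.ndarray) -> pd.Series:
    """Per-feature method-of-moments NB dispersion from normalized counts.

    ``alpha = max(alpha_floor, (s2 - m) / m**2)`` with ``m`` the mean and
    ``s2`` the unbiased variance across samples. Features with zero mean are
    floored (low-count flag is the floor itself).
    """
    x = np.asarray(normalized, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    m = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m) / np.square(m)
    alpha = np.where(m > 0, alpha, ALPHA_FLOOR)
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    index = normalized.index if isinstance(normalized, pd.DataFrame) else None
    return pd.Series(alpha, index=index, name="dispersion")


DISPERSION_PRIOR_DF = 10.0


def _pooled_group_dispersion(
    norm_a: np.ndarray, norm_b: np.ndarray, prior_df: float = DISPERSION_PRIOR_DF
) -> np.ndarray:
    """Within-group MoM dispersions, df-combined and shrunk across features.

    Pooling the two groups directly would fold a real group effect into the
    dispersion and destroy power; estimating within groups keeps the
    estimator unbiased under planted effects. The raw per-feature estimate is
    then shrunk toward the cross-feature median with ``prior_df`` pseudo
    degrees of freedom: with a handful of replicates the per-feature
    method-of-moments estimate is so noisy that downward outliers make the
    Wald test badly anticonservative, and borrowing strength across features
    restores calibration (the same motivation as the empirical-Bayes
    machinery in mainstream count-model tools).
    """
    total_df = 0
    acc = None
    for g in (norm_a, norm_b):
        m = g.mean(axis=1)
        s2 = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - m) / np.square(m)
        a = np.where(m > 0, a, 0.0)
        a = np.maximum(a, 0.0)
        df = g.shape[1] - 1
        acc = a * df if acc is None else acc + a * df
        total_df += df
    raw = acc / max(total_df, 1)
    prior = float(np.median(raw))
    shrunk = (total_df * raw + prior_df * prior) / (total_df + prior_df)
    return np.maximum(shrunk, ALPHA_FLOOR)


def nb_wald_test(
    counts_a: np.ndarray | pd.DataFrame,
    counts_b: np.ndarray | pd.DataFrame,
    size_factors_a: np.ndarray | pd.Series,
    size_factors_b: np.ndarray | pd.Series,
    dispersion: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Wald test of log2 fold change (B vs A) for each feature.

    Group means are means of size-factor-normalized counts. A pseudo-mean
    guard ``c = 0.5`` enters both the fold change and the variance, but only
    for features where either group mean falls below ``c`` — so the common
    case stays unbiased while all-zero groups give finite, flagged output.

    Delta-method variance: ``Var(log2 mu_g) = (1/ln2)^2 (1/mu_g + alpha)/n_g``
    summed over the two groups; the Wald p is the two-sided normal tail of
    ``log2fc / se``.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    sa = np.asarray(size_factors_a, dtype=float)
    sb = np.asarray(size_factors_b, dtype=float)
    alpha = np.atleast_1d(np.asarray(dispersion, dtype=float))

    na, nb_ = a.shape[1], b.shape[1]
    mu_a = (a / sa).mean(axis=1)
    mu_b = (b / sb).mean(axis=1)

    guard = (mu_a < LOW_MEAN_GUARD) | (mu_b < LOW_MEAN_GUARD)
    c = np.where(guard, LOW_MEAN_GUARD, 0.0)
    ga, gb = mu_a + c, mu_b + c
    log2fc = np.log2(gb / ga)
    var = (1.0 / LN2) ** 2 * ((1.0 / ga + alpha) / na + (1.0 / gb + alpha) / nb_)
    se = np.sqrt(var)
    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    index = counts_a.index if isinstance(counts_a, pd.DataFrame) else None
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "wald_p": np.minimum(wald_p, 1.0),
            "low_count_guard": guard,
        },
        index=index,
    )


def bh_adjust(pvalues: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_z_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """``log2(x + 1)`` then per-feature z-scaling (sample sd, n-1); constant
    features map to all-zero rows. Used for heatmap display."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("normalized counts must be non-negative")
    logged = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    mean = logged.mean(axis=1, keepdims=True)
    if logged.shape[1] > 1:
        sd = logged.std(axis=1, ddof=1, keepdims=True)
    else:
        sd = np.zeros_like(mean)
    z = np.where(sd > 0, (logged - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=normalized.index, columns=normalized.columns)


def run_differential(
    counts: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
) -> pd.DataFrame:
    """Full two-group differential analysis (B vs A).

    Size factors are estimated on the combined two-group submatrix;
    dispersion is estimated within groups. Returns a per-feature table with
    base_mean, log2fc, se, wald_p, padj and dispersion.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    overlap = set(samples_a) & set(samples_b)
    if overlap:
        raise ValueError(f"samples in both groups: {sorted(overlap)}")
    sub = counts.loc[:, samples_a + samples_b]
    sf = size_factors(sub)
    norm = sub / sf
    norm_a = norm[samples_a].to_numpy()
    norm_b = norm[samples_b].to_numpy()
    alpha = _pooled_group_dispersion(norm_a, norm_b)
    res = nb_wald_test(
        counts.loc[:, samples_a],
        counts.loc[:, samples_b],
        sf[samples_a].to_numpy(),
        sf[samples_b].to_numpy(),
        alpha,
    )
    res.index = counts.index
    res.insert(0, "base_mean", norm.mean(axis=1).to_numpy())
    res["padj"] = bh_adjust(res["wald_p"].to_numpy())
    res["dispersion"] = alpha
    return res[
        ["base_mean", "log2fc", "se", "wald_p", "padj", "dispersion", "low_count_guard"]
    ]


def contrast_samples(
    sheet: SampleSheet, assay: str, contrast: str
) -> tuple[list[str], list[str]]:
    """Resolve a ``B:A`` contrast string (e.g. ``HFD:NC``) to sample id lists
    ``(A, B)`` for one assay."""
    try:
        group_b, group_a = contrast.split(":")
    except ValueError as exc:
        raise ValueError("contrast must look like 'HFD:NC' (B:A)") from exc
    a = sheet.sample_ids(assay=assay, group=group_a)
    b = sheet.sample_ids(assay=assay, group=group_b)
    if not a or not b:
        raise ValueError(f"contrast {contrast!r}: empty group for assay {assay}")
    return a, b
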
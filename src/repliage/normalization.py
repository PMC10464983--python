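"""Size-factor normalisation, log transformation and MA-plot statistics.

Counts are normalised with the median-of-ratios size-factor estimator
(the DESeq-family estimator): per gene, a geometric-mean reference over
samples (genes containing any zero are excluded from the reference); per
sample, the median of count/reference ratios.  Display values are
log2(x + 1) of normalised counts; condition-level expression is the mean
of per-replicate normalised counts, log-transformed afterwards.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class NormalizationError(ValueError):
    pass


def size_factors(counts: pd.DataFrame, rescale_geomean: bool = False) -> pd.Series:
    """Median-of-ratios size factors, one per sample (column).

    Genes with any zero count are excluded from the geometric-mean
    reference.  Raises if no gene is nonzero in every sample, suggesting
    the total-count fallback (:func:`total_count_factors`).

    With ``rescale_geomean`` the factors are rescaled to geometric mean 1;
    ratios between samples are invariant either way.
    """
    if (counts.values < 0).any():
        raise NormalizationError("counts must be non-negative")
    positive = (counts.values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "is undefined — consider total_count_factors() as a fallback")
    sub = counts.values[positive].astype(float)
    log_ref = np.log(sub).mean(axis=1)  # log geometric mean per gene
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    if rescale_geomean:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def total_count_factors(counts: pd.DataFrame) -> pd.Series:
    """Fallback estimator: library totals scaled to geometric mean 1."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise NormalizationError("a sample has zero total counts")
    factors = totals / np.exp(np.mean(np.log(totals)))
    factors.name = "size_factor"
    return factors


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor (linear scale)."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise NormalizationError("size factors missing for some samples")
    if (factors <= 0).any():
        raise NormalizationError("size factors must be positive")
    return counts / factors


def to_log2(norm: pd.DataFrame | pd.Series):
    """log2(x + 1) of linear-scale normalised values."""
    return np.log2(norm + 1.0)


def condition_mean(norm: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Mean of per-replicate normalised counts (linear scale)."""
    missing = [s for s in samples if s not in norm.columns]
    if missing:
        raise NormalizationError(f"samples not in matrix: {missing}")
    return norm[samples].mean(axis=1)


def ma_stats(
    ref: pd.Series,
    test: pd.Series,
    min_ref: float = 2.0,
    filter_both: bool = False,
) -> tuple[pd.DataFrame, float]:
    """MA-plot coordinates and regression slope for two conditions.

    *ref* and *test* are per-gene normalised counts on the linear scale
    (typically condition means).  Genes with reference count below
    *min_ref* (default 2, applied pre-log) are excluded; with
    ``filter_both`` the threshold is applied to both conditions.

    Returns a DataFrame with per-gene ``mean`` (average of the two log2
    values) and ``diff`` (test - ref, log2), plus the ordinary
    least-squares slope of diff on mean.
    """
    ref, test = ref.align(test, join="inner")
    keep = ref >= min_ref
    if filter_both:
        keep &= test >= min_ref
    ref, test = ref[keep], test[keep]
    if len(ref) < 2:
        raise NormalizationError(
            f"only {len(ref)} genes survive the min_ref={min_ref} filter; "
            "regression slope undefined")
    log_ref = np.log2(ref + 1.0)
    log_test = np.log2(test + 1.0)
    mean = (log_ref + log_test) / 2.0
    diff = log_test - log_ref
    x = mean - mean.mean()
    denom = float((x ** 2).sum())
    slope = float((x * (diff - diff.mean())).sum() / denom) if denom > 0 else 0.0
    stats = pd.DataFrame({"mean": mean, "diff": diff})
    return stats, slope
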
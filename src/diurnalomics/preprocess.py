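"""Count filtering and variance-stabilising transforms.

The preprocessing mirrors the standard RNA-seq recipe: drop features whose
total read count across every sample of both groups falls below a threshold
(default 100), estimate per-sample size factors by the median-of-ratios
method, and move to log2 scale with a pseudocount.  The log2(x/sf + 1)
transform is an approximation to a full variance-stabilising transform: it
removes depth differences and compresses the mean-variance relationship
enough for harmonic regression downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import TimedSampleMatrix

NORMALIZE_METHODS = ("median-ratio+log2", "log2+pseudocount")


def filter_low_counts(m: TimedSampleMatrix, min_total: int = 100) -> TimedSampleMatrix:
    """Drop features whose summed count over all samples is below ``min_total``.

    The sum runs across every sample of both groups combined; a feature with
    total exactly ``min_total`` is retained.  Feature order is preserved and
    the operation is idempotent.
    """
    if m.value_kind != "counts":
        raise ValueError("filter_low_counts applies to count matrices only")
    totals = m.values.sum(axis=1)
    keep = totals >= min_total
    return TimedSampleMatrix(
        values=m.values.loc[keep.to_numpy()],
        samples=m.samples,
        value_kind="counts",
    )


def size_factors_median_ratio(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalisation).

    For each feature with a strictly positive geometric mean across samples,
    compute count / geometric-mean; the size factor of a sample is the median
    of those ratios over features.  Features containing a zero in any sample
    are excluded from the reference, not an error.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    usable = np.isfinite(logs).all(axis=1)
    if not usable.any():
        raise ValueError("no feature has all-positive counts; cannot form reference")
    log_geo = logs[usable].mean(axis=1)
    ratios = logs[usable] - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_and_log(
    m: TimedSampleMatrix, method: str = "median-ratio+log2"
) -> TimedSampleMatrix:
    """Depth-normalise counts and transform to log2 scale.

    ``median-ratio+log2``: log2(count / size_factor + 1) with median-of-ratios
    size factors.  ``log2+pseudocount``: plain log2(count + 1), no depth
    correction.
    """
    if m.value_kind != "counts":
        raise ValueError("normalize_and_log applies to count matrices only")
    if method not in NORMALIZE_METHODS:
        raise ValueError(f"method must be one of {NORMALIZE_METHODS}")
    arr = m.values.to_numpy(dtype=float)
    if method == "median-ratio+log2":
        sf = size_factors_median_ratio(m.values).to_numpy()
        out = np.log2(arr / sf[None, :] + 1.0)
    else:
        out = np.log2(arr + 1.0)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return TimedSampleMatrix(values=values, samples=m.samples, value_kind="continuous")
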
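"""Simplified negative-binomial differential expression.

Two modes mirror the standard time-course design:

* **global** — NB GLM with a group factor only, pooling all sampling times;
  Wald test on the group coefficient.
* **time-adjusted** — NB GLM with categorical time plus group, compared by a
  likelihood-ratio test against the time-only model, so that a genotype
  effect is assessed on top of the shared diurnal profile.

Library depth enters as a log size-factor offset (median-of-ratios).  The
per-feature dispersion is a method-of-moments estimate shrunk in log space
toward a fitted mean-dispersion trend alpha(mu) = a0 + a1/mu.  This is a
deliberate simplification of the DESeq2 machinery: there is no Cox-Reid
adjusted-profile likelihood, no LFC shrinkage and no independent filtering,
so discovery counts on real data will differ from a DESeq2 run.  P-values
are Benjamini-Hochberg adjusted across features.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import TimedSampleMatrix
from .preprocess import size_factors_median_ratio

_MIN_ALPHA = 1e-8
_MAX_ALPHA = 10.0


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


def estimate_dispersions(
    counts: np.ndarray, size_factors: np.ndarray, groups: np.ndarray,
    shrink_weight: float = 0.5,
) -> np.ndarray:
    """Per-feature NB dispersions: method-of-moments shrunk to a trend.

    On the normalised scale q = K/s, Var(q) ~= mu * mean(1/s) + alpha*mu^2;
    the within-group pooled variance gives a raw moment estimate of alpha,
    which is shrunk (geometric interpolation, weight ``shrink_weight`` on
    the trend) toward a fitted trend alpha(mu) = a0 + a1/mu.
    """
    counts = np.asarray(counts, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    q = counts / sf[None, :]
    labels = pd.unique(groups)
    n = counts.shape[1]
    resid_ss = np.zeros(counts.shape[0])
    for lab in labels:
        mask = groups == lab
        sub = q[:, mask]
        resid_ss += np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1)
    pooled_var = resid_ss / max(n - len(labels), 1)
    mu = q.mean(axis=1)
    inv_sf = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - mu * inv_sf) / mu**2
    raw = np.clip(np.where(np.isfinite(raw), raw, _MIN_ALPHA), _MIN_ALPHA, _MAX_ALPHA)

    usable = mu > 0
    if usable.sum() >= 10:
        A = np.column_stack([np.ones(usable.sum()), 1.0 / mu[usable]])
        coef, *_ = np.linalg.lstsq(A, raw[usable], rcond=None)
        a0, a1 = np.maximum(coef, 0.0)
        with np.errstate(divide="ignore"):
            trend = np.clip(a0 + a1 / np.where(mu > 0, mu, np.inf),
                            _MIN_ALPHA, _MAX_ALPHA)
    else:
        trend = np.full_like(raw, np.median(raw))
    shrunk = np.exp(
        (1.0 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )
    return np.clip(shrunk, _MIN_ALPHA, _MAX_ALPHA)


def _fit_nb(y, X, offset, alpha):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        )
        return model.fit(maxiter=100, tol=1e-8)


def _prepare(m: TimedSampleMatrix):
    if m.value_kind != "counts":
        raise ValueError("differential expression requires a counts matrix")
    groups = m.samples["group"].astype(str).to_numpy()
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, found {list(labels)}")
    sf = size_factors_median_ratio(m.values).to_numpy()
    return groups, labels, sf


def _assemble(features, lfc, pvals, flags, alpha_sig: float) -> pd.DataFrame:
    pvals = np.asarray(pvals, dtype=float)
    ok = np.isfinite(pvals)
    fdr = np.full_like(pvals, np.nan)
    if ok.any():
        fdr[ok] = benjamini_hochberg(pvals[ok])
    direction = np.where(
        ok & (fdr < alpha_sig) & (np.asarray(lfc) > 0), "up",
        np.where(ok & (fdr < alpha_sig) & (np.asarray(lfc) < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature": features,
            "log2_fold_change": lfc,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
            "flag": flags,
        }
    )


def nb_global_test(m: TimedSampleMatrix, alpha_sig: float = 0.05) -> pd.DataFrame:
    """Group-only NB GLM Wald test, pooling all sampling times.

    Returns feature, log2_fold_change (group2 vs group1), p, BH fdr and a
    direction call; all-zero features are excluded with a flag.
    """
    groups, labels, sf = _prepare(m)
    g = (groups == labels[1]).astype(float)
    X = np.column_stack([np.ones_like(g), g])
    offset = np.log(sf)
    counts = m.values.to_numpy(dtype=float)
    n_feat = counts.shape[0]
    lfc = np.full(n_feat, np.nan)
    pvals = np.full(n_feat, np.nan)
    flags = np.array([""] * n_feat, dtype=object)
    disp = estimate_dispersions(counts, sf, groups)
    for i in range(n_feat):
        y = counts[i]
        if y.sum() == 0:
            flags[i] = "all_zero"
            continue
        try:
            fit = _fit_nb(y, X, offset, disp[i])
            lfc[i] = fit.params[1] / np.log(2.0)
            pvals[i] = fit.pvalues[1]
        except Exception as exc:
            flags[i] = f"fit_failed: {exc}"
    return _assemble(m.feature_ids, lfc, pvals, flags, alpha_sig)


def nb_time_adjusted_test(m: TimedSampleMatrix, alpha_sig: float = 0.05) -> pd.DataFrame:
    """Likelihood-ratio test of the group effect adjusting for time.

    Full model: categorical time + group; reduced model: time only; LRT on
    1 df.  Every timepoint must be observed in both groups.
    """
    groups, labels, sf = _prepare(m)
    times = m.samples["time"].to_numpy(dtype=float)
    for tp in np.unique(times):
        present = {labels[0]: False, labels[1]: False}
        for g_lab in labels:
            present[g_lab] = np.any((times == tp) & (groups == g_lab))
        missing = [g_lab for g_lab, ok in present.items() if not ok]
        if missing:
            raise ValueError(
                f"timepoint {tp} missing in group(s) {missing}"
            )
    g = (groups == labels[1]).astype(float)
    time_levels = np.unique(times)
    time_dummies = np.column_stack(
        [(times == tp).astype(float) for tp in time_levels[1:]]
    )
    X_red = np.column_stack([np.ones_like(g), time_dummies])
    X_full = np.column_stack([X_red, g])
    offset = np.log(sf)
    counts = m.values.to_numpy(dtype=float)
    n_feat = counts.shape[0]
    lfc = np.full(n_feat, np.nan)
    pvals = np.full(n_feat, np.nan)
    flags = np.array([""] * n_feat, dtype=object)
    disp = estimate_dispersions(counts, sf, groups)
    for i in range(n_feat):
        y = counts[i]
        if y.sum() == 0:
            flags[i] = "all_zero"
            continue
        try:
            full = _fit_nb(y, X_full, offset, disp[i])
            red = _fit_nb(y, X_red, offset, disp[i])
            lr = max(0.0, 2.0 * (full.llf - red.llf))
            pvals[i] = stats.chi2.sf(lr, df=1)
            lfc[i] = full.params[-1] / np.log(2.0)
        except Exception as exc:
            flags[i] = f"fit_failed: {exc}"
    return _assemble(m.feature_ids, lfc, pvals, flags, alpha_sig)


def responsive_insensitive_sets(
    up_in_high: set[str], down_in_low: set[str], unchanged_in_ko: set[str]
) -> tuple[set[str], dict[str, int]]:
    """Set algebra for hormone-responsive, receptor-insensitive genes.

    The core set is (up under high-hormone) ∩ (down under low-hormone) ∩
    (unchanged in the receptor knockout).  Also returns the full UpSet
    partition of the three input sets keyed by membership pattern, e.g.
    ``"up_in_high+down_in_low"``.
    """
    up_in_high = set(up_in_high)
    down_in_low = set(down_in_low)
    unchanged_in_ko = set(unchanged_in_ko)
    core = up_in_high & down_in_low & unchanged_in_ko
    names = ("up_in_high", "down_in_low", "unchanged_in_ko")
    sets = (up_in_high, down_in_low, unchanged_in_ko)
    partition: dict[str, int] = {}
    universe = up_in_high | down_in_low | unchanged_in_ko
    for item in universe:
        key = "+".join(n for n, s in zip(names, sets) if item in s)
        partition[key] = partition.get(key, 0) + 1
    return core, partition
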
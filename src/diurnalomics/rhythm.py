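"""Per-feature 24-h rhythmicity testing.

Three detector families are run at a fixed 24-h period and combined by a
consensus rule:

* **cosinor** — linear harmonic regression
  ``y = M + b_s sin(2*pi*t/24) + b_c cos(2*pi*t/24)`` with an F-test of the
  two harmonic terms against the intercept-only model.  The fit yields the
  rhythm parameters: mesor M (baseline), amplitude A = sqrt(b_s^2 + b_c^2)
  (half peak-to-trough) and acrophase phi = (24/2pi)*atan2(b_s, b_c) mod 24
  (clock time of the model peak).
* **jtk** — a nonparametric template test in the JTK_CYCLE style: Kendall's
  tau between the series and cosine references peaking at each candidate
  lag, with a Bonferroni correction over lags.
* **ls** — the single-frequency floating-mean Lomb-Scargle periodogram at
  1/24 h^-1, with its exact Gaussian-null tail.

A feature is called rhythmic by the default "any" consensus when at least
one detector is significant at the common alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TimedSampleMatrix
from .phase import wrap_phase

DEFAULT_PERIOD = 24.0
DEFAULT_METHODS = ("cosinor", "jtk", "ls")
CONSENSUS_RULES = ("any", "majority", "all")

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class CosinorFit:
    """Rhythm parameters of a single-feature cosinor fit."""

    mesor: float
    amplitude: float
    acrophase: float  # hours in [0, 24)
    p_rhythm: float
    r2: float
    residual_df: int
    zero_residual: bool = False  # perfect fit: p_rhythm floored at tiny

    def __post_init__(self) -> None:
        assert self.amplitude >= 0
        assert 0 <= self.acrophase < DEFAULT_PERIOD or np.isnan(self.acrophase)


@dataclass
class RhythmCallTable:
    """Per-feature, per-group detector p-values and consensus flags.

    ``table`` columns: feature, group, p_cosinor, p_jtk, p_ls (subset per
    ``methods``), mesor, amplitude, acrophase, r2, consensus, error.
    """

    table: pd.DataFrame
    alpha: float = 0.01
    rule: str = "any"
    methods: tuple[str, ...] = DEFAULT_METHODS

    def rhythmic_features(self, group: str) -> set[str]:
        sub = self.table[(self.table["group"] == group) & self.table["consensus"]]
        return set(sub["feature"])

    def rhythmic_in_all_groups(self) -> set[str]:
        groups = self.table["group"].unique()
        sets = [self.rhythmic_features(g) for g in groups]
        return set.intersection(*sets) if sets else set()

    def rhythmic_in_any_group(self) -> set[str]:
        groups = self.table["group"].unique()
        sets = [self.rhythmic_features(g) for g in groups]
        return set.union(*sets) if sets else set()


def _harmonic_design(t: np.ndarray, period: float) -> np.ndarray:
    w = 2 * np.pi / period
    return np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])


def _check_design(t: np.ndarray, min_obs: int) -> None:
    if t.size < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {t.size}")
    if np.unique(t).size < 2:
        raise ValueError("degenerate design: all observations at the same time")


def fit_cosinor(y, t, period: float = DEFAULT_PERIOD) -> CosinorFit:
    """Least-squares cosinor fit of one series at a fixed period.

    ``p_rhythm`` is the F-test of the sin/cos pair against the intercept-only
    model.  A perfect harmonic fit (zero residual variance with a nonzero
    amplitude) reports the smallest representable p and is flagged.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("non-finite values in series")
    _check_design(t, min_obs=4)
    X = _harmonic_design(t, period)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss1 = float(np.sum((y - fitted) ** 2))
    ss0 = float(np.sum((y - y.mean()) ** 2))
    df_resid = y.size - 3
    mesor, b_sin, b_cos = beta
    amp = float(np.hypot(b_sin, b_cos))
    phi = float(wrap_phase(np.arctan2(b_sin, b_cos) * period / (2 * np.pi)))
    scale = max(ss0, 1.0e-300)
    zero_resid = ss1 <= 1e-12 * scale
    if ss0 <= 0:  # constant series
        return CosinorFit(float(mesor), 0.0, 0.0, 1.0, 0.0, df_resid)
    if zero_resid and amp > 0:
        return CosinorFit(float(mesor), amp, phi, _TINY_P, 1.0, df_resid, True)
    f_stat = ((ss0 - ss1) / 2.0) / (ss1 / df_resid)
    p = float(stats.f.sf(f_stat, 2, df_resid))
    return CosinorFit(float(mesor), amp, phi, p, 1.0 - ss1 / ss0, df_resid)


def fit_cosinor_matrix(
    Y: np.ndarray, t: np.ndarray, period: float = DEFAULT_PERIOD
) -> pd.DataFrame:
    """Vectorised cosinor over a features-by-samples array.

    Returns a DataFrame with columns mesor, amplitude, acrophase, p_cosinor,
    r2 (one row per feature, positional index).
    """
    Y = np.asarray(Y, dtype=float)
    t = np.asarray(t, dtype=float)
    _check_design(t, min_obs=4)
    X = _harmonic_design(t, period)
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T  # (features, 3)
    fitted = beta @ X.T
    ss1 = np.sum((Y - fitted) ** 2, axis=1)
    ss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df_resid = t.size - 3
    amp = np.hypot(beta[:, 1], beta[:, 2])
    phi = wrap_phase(np.arctan2(beta[:, 1], beta[:, 2]) * period / (2 * np.pi))
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((ss0 - ss1) / 2.0) / (ss1 / df_resid)
        p = stats.f.sf(f_stat, 2, df_resid)
        r2 = np.where(ss0 > 0, 1.0 - ss1 / ss0, 0.0)
    constant = ss0 <= 0
    perfect = (~constant) & (ss1 <= 1e-12 * np.maximum(ss0, 1e-300)) & (amp > 0)
    p = np.where(perfect, _TINY_P, p)
    p = np.where(constant, 1.0, p)
    amp = np.where(constant, 0.0, amp)
    phi = np.where(constant, 0.0, phi)
    return pd.DataFrame(
        {
            "mesor": beta[:, 0],
            "amplitude": amp,
            "acrophase": phi,
            "p_cosinor": np.clip(p, 0.0, 1.0),
            "r2": np.clip(r2, 0.0, 1.0),
        }
    )


def jtk_test(y, t, period: float = DEFAULT_PERIOD, lag_grid=None) -> float:
    """JTK-style nonparametric rhythm test.

    Kendall's tau is computed between the series and a cosine reference
    peaking at each candidate lag (default: the distinct sampling times);
    the smallest one-sided tail probability is Bonferroni-adjusted by the
    number of lags and capped at 1.  Constant series return p = 1.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    _check_design(t, min_obs=6)
    if np.ptp(y) == 0:
        return 1.0
    lags = np.unique(t) if lag_grid is None else np.asarray(lag_grid, dtype=float)
    w = 2 * np.pi / period
    best = 1.0
    for lag in lags:
        # round the template so symmetric sampling yields exact ties
        ref = np.round(np.cos(w * (t - lag)), 9)
        res = stats.kendalltau(ref, y, alternative="greater")
        if res.pvalue < best:
            best = float(res.pvalue)
    return min(1.0, best * lags.size)


def lomb_scargle_test(y, t, period: float = DEFAULT_PERIOD) -> float:
    """Single-frequency floating-mean Lomb-Scargle test at 1/period.

    The standardised power is a monotone function of the harmonic-regression
    R^2, whose Gaussian-null tail is exact: p = (1 - R^2)^((n-3)/2).  The
    result is invariant to adding a constant to the series; constant series
    return p = 1.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    _check_design(t, min_obs=6)
    if np.ptp(y) == 0:
        return 1.0
    X = _harmonic_design(t, period)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss1 = float(np.sum((y - X @ beta) ** 2))
    ss0 = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, min(1.0, 1.0 - ss1 / ss0))
    p = (1.0 - r2) ** ((y.size - 3) / 2.0)
    return float(max(p, _TINY_P))


def _lomb_scargle_matrix(Y: np.ndarray, t: np.ndarray, period: float) -> np.ndarray:
    X = _harmonic_design(t, period)
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    ss1 = np.sum((Y - beta @ X.T) ** 2, axis=1)
    ss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss0 > 0, 1.0 - ss1 / ss0, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    p = (1.0 - r2) ** ((t.size - 3) / 2.0)
    return np.clip(np.where(ss0 <= 0, 1.0, p), _TINY_P, 1.0)


def consensus_rhythmicity(
    pvals: pd.DataFrame, alpha: float = 0.01, rule: str = "any"
) -> pd.Series:
    """Combine per-method p-value columns into a rhythmicity flag.

    ``rule="any"`` (the default) calls a feature rhythmic if at least one
    method falls below alpha; ``"majority"`` needs more than half and
    ``"all"`` every method.  Missing p-values (NaN) are treated as
    non-significant and drop out of the method count.
    """
    if rule not in CONSENSUS_RULES:
        raise ValueError(f"rule must be one of {CONSENSUS_RULES}")
    pcols = [c for c in pvals.columns if c.startswith("p_")]
    if not pcols:
        raise ValueError("no p-value columns (p_*) found")
    hits = (pvals[pcols] < alpha).sum(axis=1)
    n_avail = pvals[pcols].notna().sum(axis=1)
    if (n_avail == 0).any():
        raise ValueError("some rows have no available method p-value")
    if rule == "any":
        return hits >= 1
    if rule == "majority":
        return hits > n_avail / 2
    return hits == n_avail


def detect_all(
    m: TimedSampleMatrix,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    alpha: float = 0.01,
    rule: str = "any",
    period: float = DEFAULT_PERIOD,
) -> RhythmCallTable:
    """Run the detector battery per group and assemble the consensus table.

    Each group is analysed independently (replicates at a timepoint count as
    independent observations).  Per-feature failures are recorded in the
    ``error`` column rather than aborting the scan.
    """
    unknown = set(methods) - set(DEFAULT_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not methods:
        raise ValueError("at least one method required")
    frames = []
    for group in m.groups:
        sub = m.subset_group(group)
        t = sub.times()
        Y = sub.values.to_numpy(dtype=float)
        if Y.shape[0] == 0:
            continue
        cos = fit_cosinor_matrix(Y, t, period)
        frame = pd.DataFrame(
            {
                "feature": sub.feature_ids,
                "group": group,
                "mesor": cos["mesor"].to_numpy(),
                "amplitude": cos["amplitude"].to_numpy(),
                "acrophase": cos["acrophase"].to_numpy(),
                "r2": cos["r2"].to_numpy(),
            }
        )
        if "cosinor" in methods:
            frame["p_cosinor"] = cos["p_cosinor"].to_numpy()
        if "ls" in methods:
            frame["p_ls"] = _lomb_scargle_matrix(Y, t, period)
        errors = [""] * Y.shape[0]
        if "jtk" in methods:
            lags = np.unique(t)
            pj = np.empty(Y.shape[0])
            for i in range(Y.shape[0]):
                try:
                    pj[i] = jtk_test(Y[i], t, period, lag_grid=lags)
                except Exception as exc:  # pragma: no cover - defensive
                    pj[i] = np.nan
                    errors[i] = f"jtk: {exc}"
            frame["p_jtk"] = pj
        frame["error"] = errors
        frames.append(frame)
    if not frames:
        cols = ["feature", "group", "mesor", "amplitude", "acrophase", "r2",
                *[f"p_{m_}" for m_ in methods], "consensus", "error"]
        empty = pd.DataFrame(columns=cols)
        return RhythmCallTable(empty, alpha=alpha, rule=rule, methods=tuple(methods))
    table = pd.concat(frames, ignore_index=True)
    pcols = [c for c in table.columns if c.startswith("p_") and c != "p_rhythm"]
    table["consensus"] = consensus_rhythmicity(table[pcols], alpha=alpha, rule=rule)
    return RhythmCallTable(table, alpha=alpha, rule=rule, methods=tuple(methods))
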
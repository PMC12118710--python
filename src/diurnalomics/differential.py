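"""Between-group comparison of rhythm parameters.

A single joint nonlinear least-squares fit per feature,

    y = (M + dM*G) + (A + dA*G) * cos(2*pi*(t - (phi + dphi*G))/24),

with group indicator G in {0, 1}, estimates the group differences in mesor
(dM), amplitude (dA) and acrophase (dphi, hours) simultaneously; Wald tests
on the converged fit give one p-value per contrast.  Gating follows the
rhythm-call table: mesor and amplitude differences are assessed for
features rhythmic in at least one group, the phase difference only for
features rhythmic in both ("robustly rhythmic") — phase is unidentifiable
without a rhythm on both sides.

Sign convention: positive dphi means group 2 peaks later (a phase delay);
differences are wrapped to (-12, 12].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import TimedSampleMatrix
from .phase import wrap_phase, wrap_phase_difference
from .rhythm import DEFAULT_PERIOD, RhythmCallTable, fit_cosinor

DRG_CLASSES = (
    "mesor_up",
    "mesor_down",
    "amp_up",
    "amp_down",
    "phase_advance",
    "phase_delay",
)


@dataclass
class DiffRhythmResult:
    """Joint-fit rhythm comparison for one feature (group2 minus group1)."""

    mesor_g1: float
    amplitude_g1: float
    acrophase_g1: float
    mesor_g2: float
    amplitude_g2: float
    acrophase_g2: float
    delta_mesor: float
    delta_amplitude: float
    delta_phase: float  # hours in (-12, 12]; positive = group2 delayed
    p_mesor: float
    p_amplitude: float
    p_phase: float  # NaN when phase is unidentifiable or gated out
    converged: bool = True


def _model(theta: np.ndarray, t: np.ndarray, g: np.ndarray, period: float):
    mesor, d_mesor, amp, d_amp, phi, d_phi = theta
    w = 2 * np.pi / period
    return (mesor + d_mesor * g) + (amp + d_amp * g) * np.cos(
        w * (t - (phi + d_phi * g))
    )


def fit_differential_cosinor(
    y1, t1, y2, t2, period: float = DEFAULT_PERIOD
) -> DiffRhythmResult:
    """Joint nonlinear cosinor fit of two groups with difference parameters.

    Initialised from the per-group linear cosinor fits; a bounded number of
    phase-shifted restarts guards against local minima.  On persistent
    non-convergence the per-group linear estimates and their differences are
    returned with the p-values withheld.  ``p_phase`` is suppressed (NaN)
    when either fitted amplitude is numerically zero.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    fit1 = fit_cosinor(y1, t1, period)
    fit2 = fit_cosinor(y2, t2, period)

    y = np.concatenate([y1, y2])
    t = np.concatenate([t1, t2])
    g = np.concatenate([np.zeros(y1.size), np.ones(y2.size)])
    scale = max(float(np.ptp(y)), 1.0)

    phi0 = fit1.acrophase if fit1.amplitude > 1e-8 * scale else fit2.acrophase
    dphi0 = (
        wrap_phase_difference(fit2.acrophase - fit1.acrophase)
        if min(fit1.amplitude, fit2.amplitude) > 1e-8 * scale
        else 0.0
    )
    base = np.array(
        [
            fit1.mesor,
            fit2.mesor - fit1.mesor,
            fit1.amplitude,
            fit2.amplitude - fit1.amplitude,
            phi0,
            dphi0,
        ]
    )

    def residuals(theta):
        return y - _model(theta, t, g, period)

    solution = None
    for phase_jitter in (0.0, 6.0, -6.0):
        theta0 = base.copy()
        theta0[4] = wrap_phase(theta0[4] + phase_jitter)
        res = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
        if res.success and (solution is None or res.cost < solution.cost - 1e-12):
            solution = res
        if solution is not None and phase_jitter == 0.0 and res.success:
            break  # base start converged; restarts only on failure

    linear = DiffRhythmResult(
        fit1.mesor, fit1.amplitude, fit1.acrophase,
        fit2.mesor, fit2.amplitude, fit2.acrophase,
        fit2.mesor - fit1.mesor,
        fit2.amplitude - fit1.amplitude,
        wrap_phase_difference(fit2.acrophase - fit1.acrophase),
        np.nan, np.nan, np.nan, converged=False,
    )
    if solution is None:
        return linear

    theta = solution.x
    mesor, d_mesor, amp, d_amp, phi, d_phi = theta
    # canonicalise negative amplitudes (A, phi) -> (-A, phi + 12)
    if amp < 0 and amp + d_amp < 0:
        amp, d_amp, phi = -amp, -d_amp - 2 * amp, wrap_phase(phi + period / 2)
        theta = np.array([mesor, d_mesor, amp, d_amp, phi, d_phi])
    amp1, amp2 = amp, amp + d_amp
    if amp1 < 0 or amp2 < 0:
        # sign-flip of a single group: fall back to per-group linear estimates
        return linear

    n = y.size
    dof = n - 6
    if dof <= 0:
        return linear
    ssr = 2.0 * solution.cost
    s2 = ssr / dof
    s2 = max(s2, 1e-24 * (1.0 + scale**2))  # floor for (near-)perfect fits
    jac = solution.jac
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return linear
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    def wald(idx: int) -> float:
        if se[idx] == 0:
            return 1.0 if abs(theta[idx]) < 1e-12 * scale else 0.0
        t_stat = theta[idx] / se[idx]
        return float(2.0 * stats.t.sf(abs(t_stat), dof))

    amp_tol = 1e-8 * scale
    p_phase = wald(5) if (amp1 > amp_tol and amp2 > amp_tol) else np.nan
    d_phi_w = wrap_phase_difference(d_phi)
    return DiffRhythmResult(
        mesor_g1=float(mesor),
        amplitude_g1=float(amp1),
        acrophase_g1=float(wrap_phase(phi)),
        mesor_g2=float(mesor + d_mesor),
        amplitude_g2=float(amp2),
        acrophase_g2=float(wrap_phase(phi + d_phi)),
        delta_mesor=float(d_mesor),
        delta_amplitude=float(d_amp),
        delta_phase=float(d_phi_w),
        p_mesor=wald(1),
        p_amplitude=wald(3),
        p_phase=p_phase,
    )


def _classes(row: pd.Series, alpha: float) -> str:
    labels: list[str] = []
    if np.isfinite(row["p_mesor"]) and row["p_mesor"] < alpha and row["delta_mesor"] != 0:
        labels.append("mesor_up" if row["delta_mesor"] > 0 else "mesor_down")
    if (
        np.isfinite(row["p_amplitude"])
        and row["p_amplitude"] < alpha
        and row["delta_amplitude"] != 0
    ):
        labels.append("amp_up" if row["delta_amplitude"] > 0 else "amp_down")
    if np.isfinite(row["p_phase"]) and row["p_phase"] < alpha and row["delta_phase"] != 0:
        labels.append("phase_delay" if row["delta_phase"] > 0 else "phase_advance")
    return ";".join(labels)


def compare_all(
    m: TimedSampleMatrix,
    calls: RhythmCallTable,
    alpha: float = 0.05,
    period: float = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """Rhythm-parameter comparison for every feature rhythmic in >= 1 group.

    Requires exactly two groups in the matrix (first = reference).  The
    comparison is fitted irrespective of per-group significance, but rows
    are restricted to features consensus-rhythmic in at least one group, and
    ``p_phase`` is kept only for features rhythmic in both.  Swapping the
    group labels negates every difference and permutes the up/down and
    advance/delay classes.
    """
    groups = m.groups
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    g1, g2 = groups
    r1 = calls.rhythmic_features(g1)
    r2 = calls.rhythmic_features(g2)
    eligible = [f for f in m.feature_ids if f in r1 or f in r2]

    m1 = m.subset_group(g1)
    m2 = m.subset_group(g2)
    t1, t2 = m1.times(), m2.times()

    rows = []
    for feat in eligible:
        fit = fit_differential_cosinor(
            m1.values.loc[feat].to_numpy(dtype=float), t1,
            m2.values.loc[feat].to_numpy(dtype=float), t2,
            period,
        )
        row = {
            "feature": feat,
            "mesor_g1": fit.mesor_g1,
            "amplitude_g1": fit.amplitude_g1,
            "acrophase_g1": fit.acrophase_g1,
            "mesor_g2": fit.mesor_g2,
            "amplitude_g2": fit.amplitude_g2,
            "acrophase_g2": fit.acrophase_g2,
            "delta_mesor": fit.delta_mesor,
            "delta_amplitude": fit.delta_amplitude,
            "delta_phase": fit.delta_phase,
            "p_mesor": fit.p_mesor,
            "p_amplitude": fit.p_amplitude,
            "p_phase": fit.p_phase if (feat in r1 and feat in r2) else np.nan,
            "rhythmic_g1": feat in r1,
            "rhythmic_g2": feat in r2,
            "converged": fit.converged,
        }
        rows.append(row)
    cols = [
        "feature", "mesor_g1", "amplitude_g1", "acrophase_g1",
        "mesor_g2", "amplitude_g2", "acrophase_g2",
        "delta_mesor", "delta_amplitude", "delta_phase",
        "p_mesor", "p_amplitude", "p_phase",
        "rhythmic_g1", "rhythmic_g2", "converged",
    ]
    table = pd.DataFrame(rows, columns=cols)
    table["classes"] = (
        table.apply(_classes, axis=1, args=(alpha,)) if len(table) else ""
    )
    table.attrs["alpha"] = alpha
    table.attrs["groups"] = (g1, g2)
    return table


def summarize_drg(table: pd.DataFrame) -> pd.DataFrame:
    """Count features per non-empty combination of rhythm-change classes.

    The UpSet-style summary: one row per observed class combination (classes
    joined by '+', sorted), with its feature count.  The total for any single
    class equals the sum over combinations containing it.
    """
    if len(table) == 0:
        return pd.DataFrame(columns=["combination", "count"])
    combos: dict[str, int] = {}
    for classes in table["classes"]:
        if not classes:
            continue
        key = "+".join(sorted(classes.split(";")))
        combos[key] = combos.get(key, 0) + 1
    out = pd.DataFrame(
        sorted(combos.items()), columns=["combination", "count"]
    )
    return out


def class_totals(table: pd.DataFrame) -> pd.Series:
    """Total feature count per individual rhythm-change class."""
    totals = {c: 0 for c in DRG_CLASSES}
    for classes in table.get("classes", []):
        if not classes:
            continue
        for c in classes.split(";"):
            totals[c] += 1
    return pd.Series(totals, name="count")


def mean_phase_shift(table: pd.DataFrame, test: str = "t") -> tuple[float, float]:
    """Mean acrophase difference over robustly rhythmic features, with a
    one-sample test against zero.

    Operates on the wrapped differences of rows where ``p_phase`` is present
    (the robustly rhythmic set).  ``test`` is ``"t"`` (one-sample t-test) or
    ``"wilcoxon"`` (signed-rank).  With fewer than two values only the mean
    is returned (p = NaN).
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    deltas = table.loc[table["p_phase"].notna(), "delta_phase"].to_numpy(dtype=float)
    if deltas.size == 0:
        raise ValueError("no robustly rhythmic features with a phase difference")
    mean = float(deltas.mean())
    if deltas.size < 2:
        return mean, float("nan")
    if test == "t":
        if np.ptp(deltas) == 0:
            return mean, 0.0 if mean != 0 else 1.0
        return mean, float(stats.ttest_1samp(deltas, 0.0).pvalue)
    if np.all(deltas == 0):
        return mean, 1.0
    return mean, float(stats.wilcoxon(deltas).pvalue)
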
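"""Circular statistics on acrophases (hours modulo 24).

Acrophases live on a 24-h circle; every helper here is wrap-aware.  Phase
values are reported in [0, 24) and phase differences in (-12, 12], the
convention being that a positive difference means the second group peaks
later (a phase delay).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PERIOD = 24.0

__all__ = [
    "wrap_phase",
    "wrap_phase_difference",
    "phase_histogram",
    "circular_mean_hours",
    "circular_median_hours",
    "kuiper_two_sample",
]


def wrap_phase(hours):
    """Map hour values onto [0, 24)."""
    return np.mod(hours, PERIOD)


def wrap_phase_difference(delta):
    """Wrap an hour difference onto (-12, 12].

    ``wrap_phase_difference(0.1 - 23.9)`` is ``+0.2`` (a 0.2-h delay), not
    -23.8.
    """
    d = np.mod(np.asarray(delta, dtype=float), PERIOD)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    d[d > PERIOD / 2] -= PERIOD
    return float(d[0]) if scalar else d


def phase_histogram(phases, bin_hours: float = 4.0) -> pd.Series:
    """Count acrophases in fixed-width bins partitioning [0, 24).

    ``bin_hours`` must divide 24 exactly.  Returns a Series indexed by bin
    start hour; the counts sum to the number of phases.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases to bin")
    n_bins = PERIOD / bin_hours
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_hours} h does not divide 24 h")
    n_bins = int(round(n_bins))
    edges = np.linspace(0.0, PERIOD, n_bins + 1)
    counts, _ = np.histogram(wrap_phase(phases), bins=edges)
    idx = pd.Index(edges[:-1], name="bin_start_h")
    return pd.Series(counts, index=idx, name="count")


def circular_mean_hours(phases) -> float:
    """Circular mean of hour values, reported in [0, 24)."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("circular mean of empty set")
    ang = phases * (2 * np.pi / PERIOD)
    mean_angle = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    hours = float(np.mod(mean_angle * PERIOD / (2 * np.pi), PERIOD))
    return 0.0 if PERIOD - hours < 1e-9 else hours


def circular_median_hours(phases) -> float:
    """Circular median: the member value minimising summed circular absolute
    deviations, ties broken toward the smaller hour.

    {23, 0, 1} gives 0 (wrap-aware), not the arithmetic 8.
    """
    phases = wrap_phase(np.asarray(phases, dtype=float))
    if phases.size == 0:
        raise ValueError("circular median of empty set")
    candidates = np.unique(phases)
    dev = np.abs(wrap_phase_difference(phases[None, :] - candidates[:, None]))
    costs = dev.sum(axis=1)
    best = costs.min()
    # candidates are sorted ascending, so the first minimiser is the smallest hour
    return float(candidates[np.flatnonzero(np.isclose(costs, best, atol=1e-12))[0]])


def _kuiper_fpp(V: float, n_eff: float) -> float:
    """Tail probability of the Kuiper statistic at effective sample size n.

    Stephens' asymptotic series with the O(1/sqrt(n)) correction term,
    which keeps the tail accurate down to effective sizes of a few tens.
    """
    if V <= 0 or n_eff <= 0:
        return 1.0
    z = np.sqrt(n_eff) * V
    if z < 0.4:  # series converges to 1 from below; avoid cancellation
        return 1.0
    j = np.arange(1, 201, dtype=float)
    e = np.exp(-2.0 * j**2 * z**2)
    leading = 2.0 * np.sum((4.0 * j**2 * z**2 - 1.0) * e)
    correction = (8.0 * z / (3.0 * np.sqrt(n_eff))) * np.sum(
        j**2 * (4.0 * j**2 * z**2 - 3.0) * e
    )
    return float(np.clip(leading - correction, 0.0, 1.0))


def kuiper_two_sample(phases_a, phases_b) -> tuple[float, float]:
    """Two-sample Kuiper test between circular phase samples.

    Returns ``(V, p)`` where ``V = D+ + D-`` is the Kuiper statistic between
    the two empirical distributions on the circle and ``p`` comes from the
    asymptotic Kuiper series at effective sample size n_a·n_b/(n_a+n_b).
    V is invariant under a common rotation of all phases and under swapping
    the two samples.
    """
    a = np.sort(wrap_phase(np.asarray(phases_a, dtype=float)))
    b = np.sort(wrap_phase(np.asarray(phases_b, dtype=float)))
    if a.size == 0 or b.size == 0:
        raise ValueError("kuiper_two_sample needs non-empty samples")
    support = np.concatenate([a, b])
    support.sort()
    d_right = (
        np.searchsorted(a, support, side="right") / a.size
        - np.searchsorted(b, support, side="right") / b.size
    )
    d_left = (
        np.searchsorted(a, support, side="left") / a.size
        - np.searchsorted(b, support, side="left") / b.size
    )
    v = float(max(d_right.max(), d_left.max()) - min(d_right.min(), d_left.min()))
    n_eff = a.size * b.size / (a.size + b.size)
    return v, _kuiper_fpp(v, n_eff)
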
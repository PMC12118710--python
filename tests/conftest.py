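"""Shared fixtures and independent oracles used across the suite."""

import numpy as np
import pandas as pd
import pytest

from diurnalomics.datamodel import SampleMeta, matrix_from_arrays

#: the emulated sampling design: 6 timepoints every 4 h, 3 replicates
TIMES_4H = np.repeat([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 3)


def cosine_series(t, mesor, amplitude, acrophase, period=24.0):
    return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / period)


def grid_search_cosinor(y, t, period=24.0, phi_step=1e-3):
    """Independent cosinor oracle: scan acrophase on a fine grid and solve
    mesor/amplitude in closed form per candidate phase.

    Returns (mesor, amplitude, acrophase) at the SSE minimum with the
    amplitude constrained non-negative (both sign representations are on
    the grid, 12 h apart).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    phis = np.arange(0.0, period, phi_step)
    C = np.cos(2 * np.pi / period * (t[None, :] - phis[:, None]))
    c_mean = C.mean(axis=1)
    c_var = (C**2).mean(axis=1) - c_mean**2
    y_mean = y.mean()
    cov = (C * y[None, :]).mean(axis=1) - c_mean * y_mean
    a = cov / c_var
    m = y_mean - a * c_mean
    sse = ((y[None, :] - (m[:, None] + a[:, None] * C)) ** 2).sum(axis=1)
    sse[a < 0] = np.inf  # keep the A >= 0 representation
    best = int(np.argmin(sse))
    return float(m[best]), float(a[best]), float(phis[best])


@pytest.fixture
def toy_count_matrix():
    """3 features x 4 samples (2 groups x 2 times x 1 replicate)."""
    meta = [
        SampleMeta("a1", "WT", 2.0, 1),
        SampleMeta("a2", "WT", 14.0, 1),
        SampleMeta("b1", "KO", 2.0, 1),
        SampleMeta("b2", "KO", 14.0, 1),
    ]
    values = np.array([[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 0, 2]])
    return matrix_from_arrays(values, ["f1", "f2", "f3"], meta, "counts")


@pytest.fixture
def design_meta():
    """SampleMeta list for the full 2-group, 6x4-h, 3-replicate design."""
    meta = []
    for group in ("WT", "KO"):
        for tp in (2.0, 6.0, 10.0, 14.0, 18.0, 22.0):
            for rep in (1, 2, 3):
                meta.append(SampleMeta(f"{group}_{tp:g}_{rep}", group, tp, rep))
    return meta
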
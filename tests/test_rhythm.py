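"""Rhythm detectors: cosinor exactness and oracle equivalence, JTK null,
Lomb-Scargle calibration, consensus semantics, shared invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diurnalomics.datamodel import matrix_from_arrays
from diurnalomics.rhythm import (
    consensus_rhythmicity,
    detect_all,
    fit_cosinor,
    fit_cosinor_matrix,
    jtk_test,
    lomb_scargle_test,
)
from conftest import TIMES_4H, cosine_series, grid_search_cosinor

T6 = np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0])


class TestCosinor:
    def test_noiseless_cosine_recovered_exactly(self):
        y = cosine_series(T6, mesor=3.0, amplitude=2.0, acrophase=8.0)
        fit = fit_cosinor(y, T6)
        assert fit.mesor == pytest.approx(3.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase == pytest.approx(8.0, abs=1e-9)
        assert fit.zero_residual
        assert fit.p_rhythm <= np.finfo(float).tiny

    def test_constant_series_flat_fit(self):
        fit = fit_cosinor(np.full(12, 5.0), TIMES_4H[:12])
        assert fit.mesor == pytest.approx(5.0)
        assert fit.amplitude == 0.0
        assert fit.p_rhythm == 1.0

    def test_matches_grid_search_oracle_on_noisy_series(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            y = cosine_series(
                TIMES_4H, rng.uniform(2, 6), rng.uniform(0.5, 2), rng.uniform(0, 24)
            ) + rng.standard_normal(TIMES_4H.size) * 0.4
            fit = fit_cosinor(y, TIMES_4H)
            m, a, phi = grid_search_cosinor(y, TIMES_4H, phi_step=1e-3)
            assert fit.mesor == pytest.approx(m, abs=1e-3)
            assert fit.amplitude == pytest.approx(a, abs=1e-3)
            assert abs((fit.acrophase - phi + 12) % 24 - 12) < 1e-3

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="same time"):
            fit_cosinor(np.arange(6.0), np.full(6, 4.0))

    def test_matrix_fit_agrees_with_scalar_fit(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((20, TIMES_4H.size)) + 3.0
        table = fit_cosinor_matrix(Y, TIMES_4H)
        for i in (0, 7, 19):
            fit = fit_cosinor(Y[i], TIMES_4H)
            assert table.loc[i, "mesor"] == pytest.approx(fit.mesor, rel=1e-9)
            assert table.loc[i, "amplitude"] == pytest.approx(fit.amplitude, rel=1e-9)
            assert table.loc[i, "p_cosinor"] == pytest.approx(fit.p_rhythm, rel=1e-9)


class TestDetectorInvariances:
    """Time-shift and scale equivariance shared by every detector."""

    @pytest.fixture
    def noisy_series(self):
        rng = np.random.default_rng(23)
        y = cosine_series(TIMES_4H, 4.0, 1.0, 7.0) + 0.5 * rng.standard_normal(
            TIMES_4H.size
        )
        return y

    def test_time_shift_moves_acrophase_only(self, noisy_series):
        delta = 5.0
        fit0 = fit_cosinor(noisy_series, TIMES_4H)
        fit1 = fit_cosinor(noisy_series, (TIMES_4H + delta) % 24)
        assert fit1.mesor == pytest.approx(fit0.mesor, rel=1e-9)
        assert fit1.amplitude == pytest.approx(fit0.amplitude, rel=1e-9)
        assert fit1.p_rhythm == pytest.approx(fit0.p_rhythm, rel=1e-9)
        assert fit1.acrophase == pytest.approx((fit0.acrophase + delta) % 24, abs=1e-9)
        assert lomb_scargle_test(noisy_series, (TIMES_4H + delta) % 24) == pytest.approx(
            lomb_scargle_test(noisy_series, TIMES_4H), rel=1e-9
        )

    def test_scale_equivariance(self, noisy_series):
        c = 3.7
        fit0 = fit_cosinor(noisy_series, TIMES_4H)
        fit1 = fit_cosinor(c * noisy_series, TIMES_4H)
        assert fit1.mesor == pytest.approx(c * fit0.mesor, rel=1e-9)
        assert fit1.amplitude == pytest.approx(c * fit0.amplitude, rel=1e-9)
        assert fit1.p_rhythm == pytest.approx(fit0.p_rhythm, rel=1e-9)
        for test in (jtk_test, lomb_scargle_test):
            assert test(c * noisy_series, TIMES_4H) == pytest.approx(
                test(noisy_series, TIMES_4H), rel=1e-9
            )

    def test_ls_invariant_to_additive_constant(self, noisy_series):
        assert lomb_scargle_test(noisy_series + 100.0, TIMES_4H) == pytest.approx(
            lomb_scargle_test(noisy_series, TIMES_4H), rel=1e-6
        )


class TestJTK:
    def test_noiseless_cosine_hits_minimal_p(self):
        y = cosine_series(TIMES_4H, 0.0, 1.0, 10.0)
        p_aligned = jtk_test(y, TIMES_4H)
        # perfect concordance at the matching lag: smallest attainable
        # Bonferroni-adjusted p for this design
        others = [
            jtk_test(
                cosine_series(TIMES_4H, 0.0, 1.0, 10.0)
                + 0.8 * np.random.default_rng(1).standard_normal(TIMES_4H.size),
                TIMES_4H,
            )
            for _ in range(1)
        ]
        assert p_aligned <= min(others)
        assert p_aligned < 0.01

    def test_antiphase_matches_in_phase(self):
        # round so the symmetric tie structure is exact in floating point
        y = np.round(cosine_series(TIMES_4H, 0.0, 1.0, 10.0), 9)
        anti = np.round(cosine_series(TIMES_4H, 0.0, 1.0, 22.0), 9)
        assert jtk_test(y, TIMES_4H) == pytest.approx(
            jtk_test(anti, TIMES_4H), rel=1e-12
        )

    def test_constant_series_p_one(self):
        assert jtk_test(np.full(18, 2.0), TIMES_4H) == 1.0

    def test_exact_tau_null_matches_full_enumeration(self):
        """scipy's exact one-sided Kendall tail equals brute-force
        enumeration over all orderings for n = 6 distinct values."""
        t = T6
        # acrophase 7 h gives six distinct template values (no ties), so the
        # exact permutation null applies
        ref = np.cos(2 * np.pi * (t - 7.0) / 24)
        y = np.array([2.0, 5.0, 3.0, 1.0, 4.0, 0.0])
        observed = stats.kendalltau(ref, y, alternative="greater")
        taus = []
        for perm in itertools.permutations(y):
            taus.append(stats.kendalltau(ref, np.array(perm)).statistic)
        taus = np.array(taus)
        enumerated = np.mean(taus >= observed.statistic - 1e-12)
        assert observed.pvalue == pytest.approx(enumerated, abs=1e-12)


class TestLombScargle:
    def test_pure_cosine_significant(self):
        y = cosine_series(TIMES_4H, 1.0, 1.0, 3.0)
        assert lomb_scargle_test(y, TIMES_4H) < 1e-10

    def test_constant_p_one(self):
        assert lomb_scargle_test(np.zeros(18), TIMES_4H) == 1.0

    def test_null_calibration_monte_carlo(self):
        """Under Gaussian white noise the exact Beta tail is uniform:
        rejection rate at alpha = 0.01 within the binomial 99% CI."""
        rng = np.random.default_rng(77)
        n_sim = 4000
        Y = rng.standard_normal((n_sim, TIMES_4H.size))
        from diurnalomics.rhythm import _lomb_scargle_matrix

        p = _lomb_scargle_matrix(Y, TIMES_4H, 24.0)
        rate = np.mean(p < 0.01)
        ci = 2.576 * np.sqrt(0.01 * 0.99 / n_sim)
        assert abs(rate - 0.01) < ci


class TestConsensus:
    def test_any_rule_single_hit(self):
        table = pd.DataFrame({"p_a": [0.005], "p_b": [0.5], "p_c": [0.5]})
        assert consensus_rhythmicity(table, alpha=0.01, rule="any").iloc[0]

    def test_any_rule_no_hit(self):
        table = pd.DataFrame({"p_a": [0.02], "p_b": [0.02], "p_c": [0.02]})
        assert not consensus_rhythmicity(table, alpha=0.01, rule="any").iloc[0]

    def test_any_rule_monotone_in_methods(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.random((50, 3)), columns=["p_a", "p_b", "p_c"])
        with2 = consensus_rhythmicity(table[["p_a", "p_b"]], alpha=0.05)
        with3 = consensus_rhythmicity(table, alpha=0.05)
        assert (with3 | ~with2).all()  # adding a method never shrinks the set

    @pytest.mark.parametrize(
        "rule,expected", [("any", True), ("majority", False), ("all", False)]
    )
    def test_rules(self, rule, expected):
        table = pd.DataFrame({"p_a": [0.001], "p_b": [0.5], "p_c": [0.5]})
        assert consensus_rhythmicity(table, alpha=0.01, rule=rule).iloc[0] == expected


class TestDetectAll:
    def test_strong_rhythms_all_detected(self, design_meta):
        rng = np.random.default_rng(9)
        t = np.array([m.time for m in design_meta])
        Y = np.stack(
            [
                cosine_series(t, 8.0, 2.0, rng.uniform(0, 24))
                + 0.2 * rng.standard_normal(t.size)
                for _ in range(20)
            ]
        )
        m = matrix_from_arrays(Y, [f"f{i}" for i in range(20)], design_meta,
                               "continuous")
        calls = detect_all(m, alpha=0.01)
        assert calls.table["consensus"].all()

    def test_lipid_mode_method_subset(self, design_meta):
        rng = np.random.default_rng(10)
        Y = rng.standard_normal((5, len(design_meta))) + 5
        m = matrix_from_arrays(Y, list("abcde"), design_meta, "continuous")
        calls = detect_all(m, methods=("cosinor", "jtk"))
        assert "p_ls" not in calls.table.columns
        assert {"p_cosinor", "p_jtk"} <= set(calls.table.columns)

    def test_empty_matrix_gives_empty_table(self, design_meta):
        m = matrix_from_arrays(
            np.zeros((0, len(design_meta))), [], design_meta, "continuous"
        )
        calls = detect_all(m)
        assert len(calls.table) == 0

    def test_deterministic(self, design_meta):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((8, len(design_meta)))
        m = matrix_from_arrays(Y, [f"f{i}" for i in range(8)], design_meta,
                               "continuous")
        t1 = detect_all(m).table
        t2 = detect_all(m).table
        pd.testing.assert_frame_equal(t1, t2)
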
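"""Circular phase statistics, Kuiper PSEA, category merging, Fisher ORA."""

import math

import numpy as np
import pandas as pd
import pytest

from diurnalomics.enrichment import (
    category_phase_difference,
    merge_categories,
    ora_fisher,
    psea_analysis,
    psea_kuiper,
    read_gmt,
    round_phases_half_up,
    set_phase_median,
    write_gmt,
)
from diurnalomics.phase import (
    circular_mean_hours,
    circular_median_hours,
    kuiper_two_sample,
    phase_histogram,
    wrap_phase_difference,
)


class TestWrapping:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (23.9, 0.1, 0.2),   # crosses midnight: +0.2 h delay, not -23.8
            (0.0, 12.0, 12.0),  # boundary maps to +12, not -12
            (10.0, 13.5, 3.5),
            (0.0, 6.0, 6.0),
            (6.0, 0.0, -6.0),
            (8.0, 8.0, 0.0),
        ],
    )
    def test_wrapped_differences(self, a, b, expected):
        assert wrap_phase_difference(b - a) == pytest.approx(expected)

    def test_exhaustive_unit_grid_in_range(self):
        grid = np.arange(0.0, 24.0, 1.0)
        diffs = wrap_phase_difference(
            (grid[None, :] - grid[:, None]).ravel()
        )
        assert (diffs > -12.0).all() and (diffs <= 12.0).all()


class TestPhaseHistogram:
    def test_basic_bin(self):
        counts = phase_histogram([1.0, 2.0, 3.0], bin_hours=4)
        assert counts.loc[0.0] == 3
        assert counts.sum() == 3

    def test_uniform_hours(self):
        counts = phase_histogram(np.arange(24.0), bin_hours=4)
        assert (counts == 4).all()

    def test_bad_bin_width(self):
        with pytest.raises(ValueError, match="divide"):
            phase_histogram([1.0], bin_hours=5)


class TestCircularCentres:
    @pytest.mark.parametrize(
        "phases,expected",
        [([2.0, 4.0, 6.0], 4.0), ([23.0, 0.0, 1.0], 0.0), ([5.0], 5.0)],
    )
    def test_median_known_cases(self, phases, expected):
        assert circular_median_hours(phases) == pytest.approx(expected)

    def test_median_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            phases = rng.uniform(0, 24, size=rng.integers(3, 12))
            got = circular_median_hours(phases)
            # independent oracle: brute-force cost at each member phase
            def cost(c):
                d = np.abs((phases - c + 12) % 24 - 12)
                return d.sum()
            best = min(sorted(phases), key=lambda c: (round(cost(c), 12), c))
            assert got == pytest.approx(best)

    @pytest.mark.parametrize(
        "phases,expected", [([4.0, 6.0], 5.0), ([23.0, 1.0], 0.0)]
    )
    def test_circular_mean(self, phases, expected):
        assert circular_mean_hours(phases) == pytest.approx(expected)


class TestKuiper:
    def test_concentrated_set_highly_significant(self):
        rng = np.random.default_rng(0)
        background = rng.uniform(0, 24, 5000)
        concentrated = rng.uniform(7.0, 9.0, 50)
        p = psea_kuiper(concentrated, background)
        assert p < 1e-6

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 24, 40)
        b = rng.uniform(0, 24, 300)
        v0, p0 = kuiper_two_sample(a, b)
        for delta in (3.0, 11.5, 17.0):
            v, p = kuiper_two_sample((a + delta) % 24, (b + delta) % 24)
            assert v == pytest.approx(v0, abs=1e-12)
            assert p == pytest.approx(p0, rel=1e-9)

    def test_sample_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 24, 30)
        b = rng.uniform(0, 24, 60)
        assert kuiper_two_sample(a, b)[0] == pytest.approx(
            kuiper_two_sample(b, a)[0], abs=1e-12
        )


class TestPSEA:
    def _phases(self, rng, n=200):
        return {f"g{i}": float(p) for i, p in enumerate(rng.uniform(0, 24, n))}

    def test_small_sets_skipped_with_reason(self):
        rng = np.random.default_rng(3)
        phases = self._phases(rng)
        sets = {"tiny": ("small set", ["g0", "g1"])}
        out = psea_analysis(phases, sets, min_genes=10)
        assert out.loc[0, "skip_reason"].startswith("fewer than 10")
        assert np.isnan(out.loc[0, "p_enrichment"])

    def test_concentrated_set_detected_with_its_phase(self):
        rng = np.random.default_rng(4)
        phases = self._phases(rng, 500)
        for i in range(30):
            phases[f"g{i}"] = float(8.0 + 0.5 * rng.standard_normal())
        sets = {"peak8": ("morning set", [f"g{i}" for i in range(30)])}
        out = psea_analysis(phases, sets, min_genes=10, alpha=0.01)
        assert out.loc[0, "significant"]
        assert out.loc[0, "set_phase"] == pytest.approx(8.0, abs=1.0)

    def test_rounding_half_up(self):
        assert round_phases_half_up({"a": 7.5, "b": 23.6, "c": 0.2}) == {
            "a": 8.0, "b": 0.0, "c": 0.0,
        }

    def test_set_phase_median_delegates_to_circular_median(self):
        assert set_phase_median([23.0, 0.0, 1.0]) == pytest.approx(
            circular_median_hours([23.0, 0.0, 1.0])
        )


class TestCategories:
    def test_merge_and_difference(self):
        results = pd.DataFrame(
            {
                "set": ["a", "b", "c", "d"],
                "set_phase": [4.0, 6.0, 23.0, 1.0],
            }
        )
        mapping = {"a": "metabolism", "b": "metabolism", "c": "immune", "d": "immune"}
        merged = merge_categories(results, mapping)
        assert merged["metabolism"] == pytest.approx(5.0)
        assert merged["immune"] == pytest.approx(0.0)

    def test_missing_set_warns_and_skips(self):
        results = pd.DataFrame({"set": ["a"], "set_phase": [4.0]})
        with pytest.warns(UserWarning, match="ghost"):
            merged = merge_categories(results, {"a": "x", "ghost": "y"})
        assert merged == {"x": pytest.approx(4.0)}

    def test_empty_mapping(self):
        results = pd.DataFrame({"set": ["a"], "set_phase": [4.0]})
        assert merge_categories(results, {}) == {}

    def test_category_phase_difference_wraps_and_warns(self):
        g1 = {"metabolism": 10.0, "immune": 6.0, "only1": 3.0}
        g2 = {"metabolism": 13.5, "immune": 0.0}
        with pytest.warns(UserWarning, match="only1"):
            diffs = category_phase_difference(g1, g2)
        assert diffs["metabolism"] == pytest.approx(3.5)  # delay
        assert diffs["immune"] == pytest.approx(-6.0)  # advance
        assert "only1" not in diffs


class TestORA:
    def test_exact_hypergeometric_tail(self):
        """Universe 20, set 5, hits 4, overlap 3: tail = 155/4845."""
        background = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        hits = {"g0", "g1", "g2", "g10"}
        out = ora_fisher(hits, background, {"s": ("", sorted(gene_set))})
        expected = (
            math.comb(5, 3) * math.comb(15, 1) + math.comb(5, 4) * math.comb(15, 0)
        ) / math.comb(20, 4)
        assert out.loc[0, "p_enrichment"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(155 / 4845)

    def test_matches_enumeration_on_small_universes(self):
        """Exact combinatorial enumeration oracle, universe <= 30."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            n_bg = int(rng.integers(10, 31))
            background = {f"g{i}" for i in range(n_bg)}
            k_set = int(rng.integers(3, n_bg))
            gene_set = set(rng.choice(sorted(background), k_set, replace=False))
            n_hits = int(rng.integers(3, n_bg))
            hits = set(rng.choice(sorted(background), n_hits, replace=False))
            overlap = len(hits & gene_set)
            if overlap < 3:
                continue
            out = ora_fisher(hits, background, {"s": ("", sorted(gene_set))})
            tail = sum(
                math.comb(k_set, j) * math.comb(n_bg - k_set, n_hits - j)
                for j in range(overlap, min(k_set, n_hits) + 1)
            ) / math.comb(n_bg, n_hits)
            assert out.loc[0, "p_enrichment"] == pytest.approx(tail, rel=1e-10)

    def test_below_min_overlap_not_reported(self):
        background = {f"g{i}" for i in range(20)}
        out = ora_fisher({"g19"}, background, {"s": ("", ["g0", "g1", "g2"])})
        assert out.empty

    def test_hits_equal_background_saturates(self):
        background = {f"g{i}" for i in range(10)}
        out = ora_fisher(
            background, background, {"s": ("", ["g0", "g1", "g2", "g3"])}
        )
        assert out.loc[0, "p_enrichment"] == pytest.approx(1.0)

    def test_hits_outside_background_rejected(self):
        with pytest.raises(ValueError, match="alien"):
            ora_fisher({"alien"}, {"g0"}, {})


class TestGMT:
    def test_roundtrip(self, tmp_path):
        sets = {"s1": ("desc one", ["a", "b", "c"]), "s2": ("", ["x", "y"])}
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert back == sets

    def test_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="3 columns"):
            read_gmt(path)
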
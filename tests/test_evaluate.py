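"""Metric definitions, DM comparison test, stratification and repeat summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkmt import evaluate as ev


class TestMseLog:
    def test_perfect(self):
        assert ev.mse_log([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_offset_on_log_scale(self):
        obs = np.array([1.0, 5.0, 20.0])
        pred = np.expm1(np.log1p(obs) + 1.0)
        assert ev.mse_log(pred, obs) == pytest.approx(1.0)

    def test_hand_computed(self):
        pred, obs = np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 1.0])
        expected = np.mean((np.log1p(pred) - np.log1p(obs)) ** 2)
        assert ev.mse_log(pred, obs) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ev.mse_log([], [])


class TestGmfe:
    def test_perfect_is_exactly_one(self):
        assert ev.gmfe([3.0, 0.5], [3.0, 0.5]) == 1.0

    def test_uniform_twofold_is_exactly_two(self):
        obs = np.array([1.0, 4.0, 10.0])
        assert ev.gmfe(2 * obs, obs) == pytest.approx(2.0, abs=1e-12)

    def test_symmetry_of_fold_direction(self):
        obs = np.array([1.0, 4.0])
        pred = np.array([2.0, 2.0])  # 2x over and 2x under
        assert ev.gmfe(pred, obs) == pytest.approx(2.0, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.floats(min_value=0.01, max_value=100.0))
    def test_symmetric_and_scale_invariant(self, seed, c):
        gen = np.random.default_rng(seed)
        pred = gen.lognormal(0, 1, 20)
        obs = gen.lognormal(0, 1, 20)
        assert ev.gmfe(pred, obs) == pytest.approx(ev.gmfe(obs, pred), rel=1e-9)
        assert ev.gmfe(c * pred, c * obs) == pytest.approx(ev.gmfe(pred, obs),
                                                           rel=1e-9)
        assert ev.gmfe(pred, obs) >= 1.0

    def test_nonpositive_pred_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            v = ev.gmfe([-1.0, 2.0], [2.0, 2.0])
        assert v > 1.0


class TestRSquared:
    def test_perfect_and_mean_baseline(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert ev.r_squared(obs, obs) == pytest.approx(1.0)
        mean_pred = np.full(3, np.expm1(np.log1p(obs).mean()))
        assert ev.r_squared(mean_pred, obs) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_negative(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = obs[::-1].copy()
        lo, lp = np.log1p(obs), np.log1p(pred)
        expected = 1 - np.sum((lo - lp) ** 2) / np.sum((lo - lo.mean()) ** 2)
        assert ev.r_squared(pred, obs) == pytest.approx(expected)
        assert expected < 0

    def test_constant_obs_flagged(self):
        with pytest.raises(ValueError):
            ev.r_squared([1.0, 2.0], [3.0, 3.0])


class TestDMTest:
    def test_identical_errors_degenerate(self):
        r = ev.dm_test([1.0, -1.0, 2.0], [1.0, -1.0, 2.0])
        assert r.degenerate
        assert r.p_value == 1.0
        assert r.statistic == 0.0

    def test_constant_nonzero_differential_flagged(self):
        r = ev.dm_test([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0])
        assert r.degenerate

    def test_statistic_formula(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        d = a**2 - b**2
        stat = d.mean() / np.sqrt(np.mean((d - d.mean()) ** 2) / 50)
        r = ev.dm_test(a, b)
        assert r.statistic == pytest.approx(stat)
        assert 0 <= r.p_value <= 1

    def test_type_one_error_calibration(self):
        gen = np.random.default_rng(2024)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = gen.normal(size=200)
            b = gen.normal(size=200)
            if ev.dm_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestStratifiedGmfe:
    def test_boundary_routing(self):
        rep = ev.stratified_gmfe([1.0] * 3, [1.0] * 3, [0.4, 1.0, 3.0])
        assert [rep.bins[b]["n"] for b in ("low", "mid", "high")] == [1, 1, 1]

    def test_exact_boundary_in_mid(self):
        rep = ev.stratified_gmfe([1.0], [1.0], [0.5])
        assert rep.bins["mid"]["n"] == 1
        rep2 = ev.stratified_gmfe([1.0], [1.0], [2.0])
        assert rep2.bins["mid"]["n"] == 1

    def test_per_bin_values_match_hand_computation(self):
        obs = np.array([0.2, 0.4, 1.0, 1.5, 3.0, 4.0])
        pred_a = obs * np.array([2, 2, 2, 2, 4, 4.0])
        pred_b = obs.copy()
        rep = ev.stratified_gmfe(pred_a, pred_b, obs)
        assert rep.bins["low"]["gmfe_a"] == pytest.approx(2.0)
        assert rep.bins["mid"]["gmfe_a"] == pytest.approx(2.0)
        assert rep.bins["high"]["gmfe_a"] == pytest.approx(4.0)
        for b in ("low", "mid", "high"):
            assert rep.bins[b]["gmfe_b"] == pytest.approx(1.0)

    def test_missing_counted_and_bins_sum(self):
        obs = np.array([0.2, np.nan, 1.0, np.nan, 3.0])
        rep = ev.stratified_gmfe(np.ones(5), np.ones(5), obs)
        assert rep.n_missing == 2
        assert sum(rep.bins[b]["n"] for b in rep.bins) == rep.n_total == 3

    def test_empty_bin_reported_na(self):
        rep = ev.stratified_gmfe([1.0], [1.0], [1.0])
        assert rep.bins["low"]["gmfe_a"] is None


class TestSummarizeRepeats:
    def test_all_wins(self):
        s = ev.summarize_repeats(np.ones(10), np.full(10, 2.0))
        assert s.win_rate == 1.0
        assert s.win_count == 10
        assert s.mean_delta_wins == pytest.approx(-1.0)
        assert s.mean_delta_losses is None

    def test_identical_runs(self):
        s = ev.summarize_repeats([1.0, 1.0], [1.0, 1.0])
        assert s.win_rate == 0.0
        assert s.mean_delta_losses == 0.0

    def test_hand_computed_table(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 4.0])
        s = ev.summarize_repeats(a, b)
        assert s.win_count == 2
        assert s.win_rate == 0.5
        assert s.mean_a == pytest.approx(2.5)
        assert s.sd_a == pytest.approx(np.std(a, ddof=1))
        assert s.mean_delta_wins == pytest.approx(-1.0)
        assert s.mean_delta_losses == pytest.approx(0.5)

    def test_single_run_no_sd(self):
        s = ev.summarize_repeats([1.0], [2.0])
        assert s.sd_a is None
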
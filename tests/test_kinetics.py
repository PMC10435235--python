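"""Trace conditioning, half-rise interpolation, and nonparametric summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from adhesionlag.kinetics import (
    cell_summary,
    condition_trace,
    group_compare,
    half_rise_result,
    half_rise_time,
    mann_whitney_u,
    median_ci,
    population_summary,
)


class TestConditionTrace:
    def test_min_max_rescale(self):
        out, valid, _ = condition_trace(np.array([10.0, 20.0, 30.0]), window_frames=1)
        assert valid
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_window_one_is_identity_after_rescale(self):
        trace = np.array([0.0, 3.0, 1.0, 4.0])
        out, _, _ = condition_trace(trace, window_frames=1)
        np.testing.assert_allclose(out, (trace - 0) / 4)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(8)
        trace = rng.uniform(0, 100, 25)
        out, _, _ = condition_trace(trace, window_frames=3)
        rescaled = (trace - trace.min()) / (trace.max() - trace.min())
        oracle = np.empty_like(rescaled)
        for i in range(len(rescaled)):
            lo, hi = max(0, i - 1), min(len(rescaled), i + 2)
            oracle[i] = rescaled[lo:hi].mean()
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_constant_trace_flagged_not_raised(self):
        _, valid, reason = condition_trace(np.full(10, 5.0), window_frames=3)
        assert not valid and "constant" in reason

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            condition_trace(np.arange(10.0), window_frames=4)


class TestHalfRiseTime:
    def test_linear_interpolation_example(self):
        t, valid, _ = half_rise_time(
            np.array([0.0, 0.2, 0.8, 1.0]), np.array([0.0, 20.0, 40.0, 60.0])
        )
        assert valid
        assert t == pytest.approx(30.0)  # 20 + (0.5-0.2)/(0.8-0.2)*20

    def test_starts_above_half_invalid(self):
        t, valid, reason = half_rise_time(
            np.array([0.6, 0.9, 1.0]), np.array([0.0, 20.0, 40.0])
        )
        assert not valid and reason == "starts above 0.5"
        assert np.isnan(t)

    def test_never_reaches_half_invalid(self):
        _, valid, reason = half_rise_time(
            np.array([0.0, 0.1, 0.2]), np.array([0.0, 20.0, 40.0])
        )
        assert not valid and reason == "never reaches 0.5"

    def test_logistic_midpoint_recovered_within_one_second(self):
        """Logistic rise with analytic midpoint 95 s sampled every 20 s."""
        times = np.arange(0.0, 300.0, 20.0)
        trace = 1.0 / (1.0 + np.exp(-(times - 95.0) / 12.0))
        t, valid, _ = half_rise_time(trace, times)
        assert valid
        assert abs(t - 95.0) < 1.0

    def test_first_upward_crossing_selected(self):
        trace = np.array([0.0, 0.6, 0.3, 0.9, 1.0])
        times = np.arange(5) * 10.0
        t, valid, _ = half_rise_time(trace, times)
        assert valid
        assert t < 10.0  # first crossing, between samples 0 and 1


class TestDelta:
    def test_subtraction(self):
        hr = half_rise_result(
            1,
            trace_red=np.array([0.0, 10.0, 20.0, 20.0, 20.0]),
            trace_green=np.array([0.0, 0.0, 0.0, 10.0, 20.0]),
            times_s=np.arange(5) * 20.0,
            window_frames=1,
        )
        assert hr.valid
        assert hr.delta_t_half_s == pytest.approx(hr.t_half_green_s - hr.t_half_red_s)
        assert hr.delta_t_half_s > 0  # green lags red

    def test_identical_traces_zero_delta(self):
        trace = np.array([0.0, 5.0, 10.0, 10.0])
        hr = half_rise_result(1, trace, trace, np.arange(4) * 20.0, window_frames=1)
        assert hr.delta_t_half_s == pytest.approx(0.0)

    def test_invalid_channel_excludes_delta(self):
        hr = half_rise_result(
            1,
            trace_red=np.full(5, 7.0),  # constant -> invalid
            trace_green=np.array([0.0, 0.0, 5.0, 10.0, 10.0]),
            times_s=np.arange(5) * 20.0,
            window_frames=1,
        )
        assert not hr.valid
        assert np.isnan(hr.delta_t_half_s)

    def test_channel_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        red = np.sort(rng.uniform(0, 1, 12))
        green = np.sort(rng.uniform(0, 1, 12))
        times = np.arange(12) * 20.0
        fwd = half_rise_result(1, red, green, times, window_frames=3)
        rev = half_rise_result(1, green, red, times, window_frames=3)
        assert fwd.delta_t_half_s == pytest.approx(-rev.delta_t_half_s, abs=1e-9)


class TestMedianCI:
    def test_n9_uses_second_and_eighth_order_statistics(self):
        """Exact Binomial(9, 1/2) tail enumeration puts the smallest >=95%
        symmetric interval at (x_(2), x_(8))."""
        x = np.arange(1.0, 10.0)  # 1..9 sorted
        # oracle: enumerate coverages 1 - 2*sum_{i<j} C(9,i)/2^9
        coverages = {}
        for j in range(1, 5):
            tail = sum(math.comb(9, i) for i in range(j)) / 2**9
            coverages[j] = 1 - 2 * tail
        best = max(j for j, c in coverages.items() if c >= 0.95)
        assert best == 2
        lo, hi, degenerate = median_ci(x)
        assert (lo, hi) == (2.0, 8.0)
        assert not degenerate

    def test_small_n_degenerates_to_full_range(self):
        lo, hi, degenerate = median_ci([3.0, 1.0, 2.0, 5.0, 4.0])
        assert degenerate
        assert (lo, hi) == (1.0, 5.0)

    def test_coverage_monotone_in_n(self):
        # n=6 is the smallest n with a valid 95% interval (full range)
        _, _, degenerate6 = median_ci(np.arange(6.0))
        assert not degenerate6


class TestCellSummary:
    def test_symmetric_deltas_median_zero(self):
        s = cell_summary([-1.0, 0.0, 1.0])
        assert s.median_delta_s == 0.0

    def test_all_positive_n10_signed_rank_p(self):
        """All-positive deltas, n=10: one-sided exact signed-rank p = 2^-10
        (every sign flip except the observed one gives a smaller statistic)."""
        deltas = np.arange(1.0, 11.0)
        s = cell_summary(deltas)
        assert s.p_one_sided == pytest.approx(2.0**-10)

    def test_sign_test_option(self):
        deltas = np.arange(1.0, 11.0)
        s = cell_summary(deltas, test="sign")
        assert s.p_one_sided == pytest.approx(2.0**-10)

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(50, 20, 25)
        s = cell_summary(deltas)
        assert s.ci95_low_s <= s.median_delta_s <= s.ci95_high_s


class TestPopulationSummary:
    def test_two_point_arithmetic(self):
        s = population_summary([40.0, 60.0])
        assert s.mean_of_medians_s == pytest.approx(50.0)
        assert s.sem_s == pytest.approx(10.0)  # sd = sqrt(200), sem = sd/sqrt(2)

    def test_equal_medians_zero_sem(self):
        s = population_summary([55.0] * 7)
        assert s.sem_s == 0.0

    def test_single_cell_has_no_sem(self):
        s = population_summary([55.0])
        assert np.isnan(s.sem_s)


class TestGroupCompare:
    def test_complete_separation_u_zero(self):
        result = group_compare([[1.0, 2.0], [3.0, 4.0]])
        assert result.test == "mann-whitney"
        assert result.statistic == 0.0

    def test_identical_groups_p_one(self):
        g = [5.0, 5.0, 5.0, 5.0]
        result = group_compare([g, list(g)])
        assert result.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_equals_permutation_enumeration(self, seed):
        """4 vs 4 samples: exact p equals exhaustive enumeration over
        C(8,4)=70 group assignments, counting pairwise wins directly."""
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 10, 4), rng.uniform(0, 10, 4)
        u_obs, p = mann_whitney_u(x, y)
        pooled = np.concatenate([x, y])

        def u_of(idx):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(8) if i not in idx]]
            return sum(
                1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
            )

        mu = 4 * 4 / 2.0
        all_u = [u_of(idx) for idx in itertools.combinations(range(8), 4)]
        oracle_p = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in all_u])
        assert p == pytest.approx(oracle_p)
        assert u_obs == pytest.approx(u_of(tuple(range(4))))

    def test_matches_scipy_exact_when_untied(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 7)
        _, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_three_groups_kruskal_dunn(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.0, 2.0)]
        result = group_compare(groups)
        assert result.test == "kruskal-wallis+dunn"
        assert result.p_value < 0.01
        pairs = {(i, j): p for i, j, _, p in result.pairwise}
        assert pairs[(0, 2)] < 0.05
        assert pairs[(0, 1)] > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([[1.0], []])
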
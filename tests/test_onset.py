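"""Time-to-onset: durations, order strata, Weibull MLE, incidence, Gehan test."""

from __future__ import annotations

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from triplewhammy.errors import FitError, ImplausibleSequenceError
from triplewhammy.onset import (
    WeibullFit,
    classify_failure,
    compute_duration,
    fit_weibull,
    gehan_wilcoxon,
    incidence_curve,
    median_onset,
    order_strata,
    pairwise_onset_comparison,
    _profile_score,
)

D = dt.date


class TestComputeDuration:
    def test_same_day_is_zero_under_day0(self):
        assert compute_duration(D(2020, 5, 1), D(2020, 5, 1), "day0") == 0

    def test_week_later_is_seven(self):
        assert compute_duration(D(2020, 5, 1), D(2020, 5, 8), "day0") == 7

    def test_same_day_is_one_under_day1(self):
        assert compute_duration(D(2020, 5, 1), D(2020, 5, 1), "day1") == 1

    def test_onset_before_start_is_implausible(self):
        with pytest.raises(ImplausibleSequenceError):
            compute_duration(D(2020, 5, 2), D(2020, 5, 1))


class TestOrderStrata:
    def test_two_distinct_starts(self):
        result = order_strata({"R": D(2020, 1, 1), "N": D(2020, 1, 10)})
        assert result.labels == {"R": "1st", "N": "2nd"}
        assert result.last_class == "N" and not result.simultaneous
        assert result.order_key == "R->N"

    def test_tied_starts_are_simultaneous(self):
        result = order_strata({"R": D(2020, 1, 1), "D": D(2020, 1, 1)})
        assert result.simultaneous and result.last_class is None

    def test_triple_with_nsaid_last(self):
        result = order_strata(
            {"R": D(2020, 1, 1), "D": D(2020, 2, 1), "N": D(2020, 3, 1)}
        )
        assert result.last_class == "N"
        assert result.labels == {"R": "1st", "D": "2nd", "N": "3rd"}

    def test_partial_tie_also_excluded_from_order(self):
        result = order_strata(
            {"R": D(2020, 1, 1), "D": D(2020, 1, 1), "N": D(2020, 3, 1)}
        )
        assert result.simultaneous


class TestWeibullFit:
    def test_parameter_recovery_early_failure(self):
        rng = np.random.default_rng(42)
        sample = rng.weibull(0.5, 5000) * 30.0
        fit = fit_weibull(sample)
        assert 0.47 <= fit.shape_beta <= 0.53
        assert fit.beta_ci_low < 0.5 < fit.beta_ci_high
        assert fit.failure_type == "early"

    def test_exponential_recovers_shape_one_and_mean_scale(self):
        rng = np.random.default_rng(7)
        sample = rng.exponential(20.0, 5000)
        fit = fit_weibull(sample)
        assert fit.shape_beta == pytest.approx(1.0, rel=0.05)
        assert fit.scale == pytest.approx(sample.mean(), rel=0.05)

    def test_degenerate_samples_raise(self):
        with pytest.raises(FitError):
            fit_weibull([5.0, 5.0, 5.0, 5.0])
        with pytest.raises(FitError):
            fit_weibull([1.0, 2.0])

    def test_score_is_zero_at_the_fit(self):
        rng = np.random.default_rng(3)
        sample = rng.weibull(1.7, 400) * 12.0
        fit = fit_weibull(sample)
        assert abs(_profile_score(fit.shape_beta, np.log(sample))) < 1e-6

    def test_likelihood_beats_a_grid_around_the_fit(self):
        from triplewhammy.onset import _weibull_loglik

        rng = np.random.default_rng(5)
        sample = rng.weibull(0.8, 300) * 25.0
        fit = fit_weibull(sample)
        ll_hat = _weibull_loglik(fit.shape_beta, fit.scale, sample)
        for ks in np.linspace(0.5, 2.0, 50):
            assert _weibull_loglik(fit.shape_beta * ks, fit.scale, sample) <= ll_hat + 1e-9

    def test_agrees_with_scipy_mle(self):
        rng = np.random.default_rng(11)
        sample = rng.weibull(0.6, 1000) * 40.0
        fit = fit_weibull(sample)
        shape_sp, _, scale_sp = stats.weibull_min.fit(sample, floc=0)
        assert fit.shape_beta == pytest.approx(shape_sp, rel=1e-4)
        assert fit.scale == pytest.approx(scale_sp, rel=1e-4)

    def test_zero_policies(self):
        sample = [0.0, 0.0, 2.0, 5.0, 9.0, 14.0]
        half = fit_weibull(sample, zero_policy="offset_half")
        excl = fit_weibull(sample, zero_policy="exclude")
        shift = fit_weibull(sample, zero_policy="shift_all_plus1")
        assert half.n == 6 and excl.n == 4 and shift.n == 6
        assert len({half.shape_beta, excl.shape_beta, shift.shape_beta}) == 3

    def test_recovery_sweep_bias_and_coverage(self):
        """For true shape in {0.5, 1, 2} at n=2000 over 20 seeds: median bias
        within 5% and CI coverage at least 17/20."""
        for beta_true in (0.5, 1.0, 2.0):
            estimates, covered = [], 0
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                sample = rng.weibull(beta_true, 2000) * 30.0
                fit = fit_weibull(sample)
                estimates.append(fit.shape_beta)
                covered += fit.beta_ci_low <= beta_true <= fit.beta_ci_high
            median_bias = abs(np.median(estimates) - beta_true) / beta_true
            assert median_bias <= 0.05, f"beta={beta_true}: bias {median_bias}"
            assert covered >= 17, f"beta={beta_true}: coverage {covered}/20"


class TestClassifyFailure:
    def test_ci_entirely_below_one_is_early(self):
        fit = WeibullFit(0.47, 30, 0.46, 0.49, 2047, 0.0, "early")
        assert classify_failure(fit) == "early"

    def test_ci_straddling_one_is_random_not_excluded(self):
        fit = WeibullFit(1.74, 30, 0.63, 3.67, 6, 0.0, "random")
        assert classify_failure(fit) == "random"

    def test_strict_mode_boundary(self):
        fit = WeibullFit(1.0, 30, 0.9, 1.1, 100, 0.0, "random")
        assert classify_failure(fit, mode="strict") == "random"
        assert classify_failure(WeibullFit(1.2, 30, 0.9, 1.5, 100, 0.0, ""),
                                mode="strict") == "wear_out"


class TestIncidenceCurve:
    def test_hand_computed_steps_with_ties(self):
        curve = incidence_curve([6, 6, 6, 10, 12])
        assert curve.times == (6.0, 10.0, 12.0)
        assert curve.incidence == pytest.approx((0.6, 0.8, 1.0))

    def test_single_observation(self):
        curve = incidence_curve([7])
        assert curve.times == (7.0,) and curve.incidence == (1.0,)

    def test_final_incidence_is_one(self):
        rng = np.random.default_rng(0)
        curve = incidence_curve(rng.integers(0, 50, 40))
        assert curve.incidence[-1] == pytest.approx(1.0)

    def test_matches_lifelines_kaplan_meier(self):
        """With no censoring the curve equals 1 - KM survival."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        sample = np.round(rng.weibull(0.7, 200) * 15.0, 1)
        curve = incidence_curve(sample)
        km = KaplanMeierFitter().fit(sample)
        for t, c in zip(curve.times, curve.incidence):
            assert c == pytest.approx(
                1.0 - km.survival_function_at_times(t).iloc[0], abs=1e-9
            )


class TestMedianOnset:
    @pytest.mark.parametrize(
        "sample, expected",
        [([6, 6, 6, 10, 12], 6.0), ([1, 2, 3, 4], 2.0), ([7], 7.0)],
    )
    def test_first_time_reaching_half(self, sample, expected):
        assert median_onset(incidence_curve(sample)) == expected

    @settings(max_examples=50, deadline=None)
    @given(sample=st.lists(st.integers(0, 400), min_size=1, max_size=30))
    def test_invariant_under_sample_duplication(self, sample):
        once = median_onset(incidence_curve(sample))
        twice = median_onset(incidence_curve(sample + sample))
        assert once == twice


class TestGehan:
    def test_identical_groups_score_zero(self):
        res = gehan_wilcoxon([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0

    def test_fully_separated_groups(self):
        res = gehan_wilcoxon([1, 2, 3], [10, 11, 12], method="normal_approx")
        assert res.statistic == 9.0  # all 9 cross-pairs favor b

    def test_statistic_equals_cross_pair_enumeration(self):
        rng = np.random.default_rng(8)
        a, b = rng.integers(0, 20, 9), rng.integers(0, 20, 7)
        res = gehan_wilcoxon(a, b, method="normal_approx")
        brute = sum(np.sign(bj - ai) for ai in a for bj in b)
        assert res.statistic == brute

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.integers(0, 30), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 30), min_size=1, max_size=8),
    )
    def test_antisymmetry(self, a, b):
        assert gehan_wilcoxon(a, b).statistic == -gehan_wilcoxon(b, a).statistic

    def test_exact_permutation_matches_brute_force(self):
        a, b = [1, 5, 9], [2, 3, 12]
        res = gehan_wilcoxon(a, b, method="exact_permutation")
        pooled = np.array(a + b, dtype=float)
        count = total = 0
        for subset in itertools.combinations(range(6), 3):
            sb = pooled[list(subset)]
            sa = pooled[[i for i in range(6) if i not in subset]]
            w = sum(np.sign(x - y) for y in sa for x in sb)
            total += 1
            count += abs(w) >= abs(res.statistic)
        assert res.p_value == pytest.approx(count / total)

    def test_agrees_with_lifelines_gehan_wilcoxon(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(13)
        a = rng.weibull(0.8, 120) * 18.0
        b = rng.weibull(0.8, 90) * 30.0
        ours = gehan_wilcoxon(a, b, method="normal_approx")
        theirs = logrank_test(a, b, weightings="wilcoxon")
        assert ours.z**2 == pytest.approx(theirs.test_statistic, rel=0.05)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=0.01)


class TestPairwise:
    def test_three_groups_give_three_pairs(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [5, 6, 7]}
        frame = pairwise_onset_comparison(groups)
        assert len(frame) == 3

    def test_self_comparison_is_null(self):
        res = gehan_wilcoxon([3, 1, 4, 1, 5], [3, 1, 4, 1, 5])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_separated_scales_are_significant(self):
        rng = np.random.default_rng(17)
        groups = {
            "fast": rng.weibull(1.0, 200) * 5.0,
            "slow": rng.weibull(1.0, 200) * 100.0,
        }
        frame = pairwise_onset_comparison(groups)
        assert bool(frame["significant"].iloc[0])

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(19)
        groups = {k: rng.weibull(1.0, 50) * s for k, s in
                  [("a", 5.0), ("b", 8.0), ("c", 50.0)]}
        frame = pairwise_onset_comparison(groups, adjust="holm")
        assert (frame["p_adjusted"] >= frame["p_value"] - 1e-12).all()
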
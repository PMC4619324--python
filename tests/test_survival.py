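import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from dnamesig import (
    cox_fit,
    interaction_lrt,
    km_estimate,
    logrank_test,
    select_covariates,
)
from dnamesig.cohort_io import ValidationError
from dnamesig.survival import FitError


def _km_oracle(times, events):
    """Hand product-limit: S(t) = prod over event times <= t of (1 - d/n)."""
    out = {}
    s = 1.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        n = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e)
        s *= 1 - d / n
        out[t] = s
    return out


def _logrank_oracle(times_a, events_a, times_b, events_b):
    """Observed-minus-expected log-rank with hypergeometric variance."""
    entries = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(t for t, e, _ in entries if e)):
        n = sum(1 for x, _, _ in entries if x >= t)
        n1 = sum(1 for x, _, g in entries if x >= t and g == 0)
        d = sum(1 for x, e, _ in entries if x == t and e)
        d1 = sum(1 for x, e, g in entries if x == t and e and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def _cox_1d_oracle(times, events, group):
    """Maximize the tie-free Cox partial likelihood for one binary covariate."""

    def neg_ll(beta):
        ll = 0.0
        for t, e, g in zip(times, events, group):
            if not e:
                continue
            risk = [gg for tt, _, gg in zip(times, events, group) if tt >= t]
            ll += beta * g - math.log(sum(math.exp(beta * gg) for gg in risk))
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-8, 8), method="bounded",
                          options={"xatol": 1e-8})
    return res.x


class TestKaplanMeier:
    def test_worked_product_limit_example(self):
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 1])
        got = dict(zip(km.event_times, km.survival))
        assert got[1.0] == pytest.approx(3 / 4)
        assert got[3.0] == pytest.approx(3 / 8)
        assert got[4.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(2.0, size=40) + 0.01
        km = km_estimate(times, np.ones(40, dtype=int))
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx((times > t).mean())

    def test_all_censored_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.event_times.size == 0 and km.survival_at(10.0) == 1.0

    def test_matches_hand_oracle_with_ties(self, rng):
        times = rng.integers(1, 8, size=30).astype(float)
        events = rng.integers(0, 2, size=30)
        km = km_estimate(times, events)
        oracle = _km_oracle(list(times), list(events))
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(oracle[t], abs=1e-10)

    def test_permutation_invariant(self, rng):
        times = rng.exponential(1.0, 20) + 0.01
        events = rng.integers(0, 2, 20)
        perm = rng.permutation(20)
        a, b = km_estimate(times, events), km_estimate(times[perm], events[perm])
        np.testing.assert_allclose(a.survival, b.survival)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])

    def test_monotone_in_unit_interval(self, rng):
        km = km_estimate(rng.exponential(1, 50) + 0.01, rng.integers(0, 2, 50))
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all((km.survival >= 0) & (km.survival <= 1))


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t, e = [1.0, 2.0, 3.0], [1, 1, 0]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_hypergeometric_oracle(self):
        stat, _ = logrank_test([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert stat == pytest.approx(
            _logrank_oracle([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1]), abs=1e-8
        )

    def test_matches_oracle_on_random_tiefree_data(self, rng):
        # also exercises the identity with the Cox score test's ingredients
        for _ in range(5):
            ta = np.sort(rng.choice(1000, 12, replace=False)).astype(float) / 10
            tb = np.sort(rng.choice(1000, 15, replace=False)).astype(float) / 10 + 0.05
            ea, eb = rng.integers(0, 2, 12), rng.integers(0, 2, 15)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            stat, _ = logrank_test(ta, ea, tb, eb)
            assert stat == pytest.approx(_logrank_oracle(ta, ea, tb, eb), abs=1e-6)

    def test_symmetric_in_group_labels(self):
        a = logrank_test([1, 3, 5], [1, 1, 0], [2, 4, 6], [1, 0, 1])
        b = logrank_test([2, 4, 6], [1, 0, 1], [1, 3, 5], [1, 1, 0])
        assert a[0] == pytest.approx(b[0])

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError, match="events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


class TestCoxFit:
    def test_binary_covariate_matches_grid_oracle(self):
        # interleaved event times so the partial likelihood has a finite
        # maximizer (all-group-1-first would be complete separation)
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 1]
        group = [1, 0, 1, 0, 0, 1]
        fit = cox_fit(times, events, pd.DataFrame({"g": group}))
        beta_hat = _cox_1d_oracle(times, events, group)
        assert fit.table.loc["g", "coef"] == pytest.approx(beta_hat, abs=1e-4)

    def test_oracle_agreement_on_random_tiefree_data(self, rng):
        times = rng.exponential(1.0, 30) + 0.001
        events = rng.integers(0, 2, 30)
        events[0] = 1
        group = rng.integers(0, 2, 30)
        fit = cox_fit(times, events, pd.DataFrame({"g": group}))
        assert fit.table.loc["g", "coef"] == pytest.approx(
            _cox_1d_oracle(times, events, group), abs=1e-4
        )

    def test_hazard_ratio_inside_ci(self, rng):
        times = rng.exponential(1.0, 50) + 0.001
        events = np.ones(50, dtype=int)
        x = rng.normal(size=50)
        fit = cox_fit(times, events, pd.DataFrame({"x": x}))
        row = fit.table.loc["x"]
        assert row["ci_lower"] < row["hazard_ratio"] < row["ci_upper"]
        assert row["hazard_ratio"] > 0

    def test_constant_covariate_named_in_error(self):
        with pytest.raises(FitError, match="'flat'"):
            cox_fit([1, 2, 3], [1, 1, 0], pd.DataFrame({"flat": [1, 1, 1]}))

    def test_collinear_covariates_rejected(self):
        x = [0, 1, 0, 1, 1]
        with pytest.raises(FitError, match="rank-deficient"):
            cox_fit(
                [1, 2, 3, 4, 5], [1, 1, 1, 0, 1],
                pd.DataFrame({"a": x, "b": [2 * v for v in x]}),
            )

    def test_time_scaling_leaves_coefficients_unchanged(self, rng):
        times = rng.exponential(1.0, 40) + 0.001
        events = rng.integers(0, 2, 40)
        events[:5] = 1
        x = rng.normal(size=40)
        a = cox_fit(times, events, pd.DataFrame({"x": x}))
        b = cox_fit(times * 10, events, pd.DataFrame({"x": x}))
        assert a.table.loc["x", "coef"] == pytest.approx(b.table.loc["x", "coef"], abs=1e-8)


class TestSelectCovariates:
    def _survival_with_effect(self, rng, n, hr):
        x = rng.integers(0, 2, n)
        times = rng.exponential(1.0 / (0.3 * hr**x))
        return times + 1e-6, np.ones(n, dtype=int), x

    def test_strong_planted_effect_included(self, rng):
        times, events, x = self._survival_with_effect(rng, 500, hr=4.0)
        noise = rng.normal(size=500)
        kept = select_covariates(times, events, pd.DataFrame({"planted": x, "noise": noise}))
        assert "planted" in kept

    def test_independent_candidate_usually_excluded(self):
        excluded = 0
        reps = 30
        for i in range(reps):
            rng = np.random.default_rng(900 + i)
            times = rng.exponential(1.0, 500) + 1e-6
            events = np.ones(500, dtype=int)
            noise = rng.normal(size=500)
            kept = select_covariates(times, events, pd.DataFrame({"noise": noise}))
            excluded += "noise" not in kept
        assert excluded / reps >= 0.9

    def test_empty_candidates_give_empty_subset(self):
        assert select_covariates([1, 2], [1, 0], pd.DataFrame(index=[0, 1])) == []

    def test_sparse_candidate_dropped(self, rng):
        times, events, x = self._survival_with_effect(rng, 100, hr=4.0)
        sparse = pd.Series([np.nan] * 60 + list(x[60:]), dtype=float)
        kept = select_covariates(times, events, pd.DataFrame({"sparse": sparse}))
        assert kept == []


class TestInteractionLRT:
    def _two_arm_data(self, rng, n, hr_carbo, hr_cis):
        marker = rng.integers(0, 2, n)
        arm = np.where(rng.random(n) < 0.5, "carboplatin", "cisplatin")
        hr = np.where(arm == "carboplatin", hr_carbo, hr_cis) ** marker
        times = rng.exponential(1.0 / (0.3 * hr)) + 1e-6
        events = np.ones(n, dtype=int)
        return times, events, marker, arm

    def test_two_binary_factors_have_one_df(self, rng):
        times, events, marker, arm = self._two_arm_data(rng, 200, 3.0, 1.0)
        res = interaction_lrt(times, events, marker, arm)
        assert res.df == 1
        assert res.lrt_statistic >= 0 and 0 < res.p <= 1

    def test_statistic_is_twice_loglik_gap(self, rng):
        times, events, marker, arm = self._two_arm_data(rng, 200, 3.0, 1.0)
        res = interaction_lrt(times, events, marker, arm)
        assert res.lrt_statistic == pytest.approx(
            2 * (res.full.log_likelihood - res.null.log_likelihood)
        )

    def test_planted_interaction_detected(self, rng):
        times, events, marker, arm = self._two_arm_data(rng, 400, 3.5, 1.0)
        assert interaction_lrt(times, events, marker, arm).p < 0.05

    def test_empty_event_cell_rejected(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 0]  # marker=1 & cisplatin cell has no event
        marker = [0, 0, 1, 1]
        arm = ["carboplatin", "cisplatin", "carboplatin", "cisplatin"]
        with pytest.raises(FitError, match="cisplatin"):
            interaction_lrt(times, events, marker, arm)

    def test_single_arm_rejected(self, rng):
        times, events, marker, _ = self._two_arm_data(rng, 50, 2.0, 2.0)
        with pytest.raises(ValidationError, match="treatment"):
            interaction_lrt(times, events, marker, ["carboplatin"] * 50)
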
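"""Kaplan-Meier estimation, log-rank, summaries and dose-response fits."""

import math

import numpy as np
import pytest

from wormarena.survival import (
    DoseResponseFit,
    SurvivalDataset,
    equivalent_dose,
    fit_power_law,
    km_curve,
    log_rank,
    relative_sensitivity,
    summarize,
)


def product_limit_oracle(times, events):
    """Hand product-limit loop: S at each distinct event time."""
    order = np.argsort(times)
    times, events = np.asarray(times, float)[order], np.asarray(events)[order]
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


def ds(times, events=None, group=""):
    times = np.asarray(times, float)
    if events is None:
        events = np.ones_like(times, int)
    return SurvivalDataset(times, events, group=group)


class TestKaplanMeier:
    def test_three_uncensored_deaths(self):
        curve = km_curve(ds([1, 2, 3]))
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])
        assert curve.median == 2.0

    def test_censoring_removes_from_risk_set(self):
        # deaths at 1 and 3, censored at 2: S(1) = 2/3, S(3) = (2/3)*(1-1/1) = 0
        curve = km_curve(ds([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(curve.times, [1.0, 3.0])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])

    def test_single_censored_subject(self):
        curve = km_curve(ds([5], [0]))
        assert len(curve.times) == 0
        assert math.isnan(curve.median)
        assert curve.survival_at(5.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        times = rng.integers(1, 30, size=60).astype(float)
        curve = km_curve(ds(times))
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_hand_product_limit_on_random_censored_data(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(2, 25))
            times = rng.integers(1, 15, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                events[0] = 1
            curve = km_curve(ds(times, events))
            oracle = product_limit_oracle(times, events)
            assert len(curve.times) == len(oracle)
            for t, s in zip(curve.times, curve.survival):
                assert s == pytest.approx(oracle[t], abs=1e-12)

    def test_quartiles_from_curve(self):
        curve = km_curve(ds(np.arange(1.0, 101.0)))
        assert curve.q25 == 25.0
        assert curve.median == 50.0
        assert curve.q75 == 75.0

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            ds([0.0, 1.0])
        with pytest.raises(ValueError):
            SurvivalDataset(np.array([1.0]), np.array([2]))
        with pytest.raises(ValueError):
            SurvivalDataset(np.array([]), np.array([]))


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        a = ds([2, 4, 6, 8], [1, 1, 0, 1])
        res = log_rank(a, ds([2, 4, 6, 8], [1, 1, 0, 1]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # A deaths {1,2}, B deaths {3,4}: O_A=2, E_A=1/2+1/3,
        # V=1/4+2/9 -> chi2 = (7/6)^2 / (17/36) = 49/17
        res = log_rank(ds([1, 2]), ds([3, 4]))
        assert res.statistic == pytest.approx(49 / 17, rel=1e-12)
        assert res.df == 1

    def test_symmetric_in_group_order(self):
        a, b = ds([5, 8, 12, 20], [1, 1, 1, 0]), ds([3, 4, 9], [1, 1, 1])
        assert log_rank(a, b).statistic == pytest.approx(log_rank(b, a).statistic)

    def test_separated_exponentials_detected(self):
        # means 20 vs 40 h at n=200: the test should essentially always fire
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = ds(rng.exponential(20, 200))
            b = ds(rng.exponential(40, 200))
            if log_rank(a, b).p_value < 0.001:
                hits += 1
        assert hits >= 99


class TestSummarize:
    def test_uncensored_closed_forms(self):
        s = summarize(ds([10, 20, 30]))
        assert s["mean_h"] == pytest.approx(20.0)
        assert s["sem_h"] == pytest.approx(10 / math.sqrt(3))
        assert s["median_h"] == 20.0
        assert not s["mean_over_events_only"]

    def test_lethality_at_time(self):
        s = summarize(ds([10, 10, 40, 40]), lethality_at=[24.0])
        assert s["lethality"][24.0] == pytest.approx(50.0)

    def test_censored_excluded_from_mean_and_flagged(self):
        s = summarize(ds([10, 20, 60], [1, 1, 0]))
        assert s["mean_h"] == pytest.approx(15.0)
        assert s["n_events"] == 2 and s["n_censored"] == 1
        assert s["mean_over_events_only"]

    def test_matches_direct_formula_on_random_data(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            times = rng.uniform(1, 50, n)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            s = summarize(ds(times, events))
            ev = times[events == 1]
            assert s["mean_h"] == pytest.approx(ev.mean())
            if len(ev) > 1:
                assert s["sem_h"] == pytest.approx(ev.std(ddof=1) / math.sqrt(len(ev)))


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        a, b = 10.503, -1.394
        doses = [0.25, 0.5, 0.75, 1.0]
        medians = [a * x**b for x in doses]
        fit = fit_power_law(doses, medians)
        assert fit.a == pytest.approx(a, abs=1e-9)
        assert fit.b == pytest.approx(b, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_flat_response(self):
        fit = fit_power_law([1, 2, 4], [36.0, 36.0, 36.0])
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.a == pytest.approx(36.0)
        assert fit.r_squared == 1.0

    def test_two_points_interpolate_exactly(self):
        fit = fit_power_law([1.0, 4.0], [100.0, 25.0])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.predict(2.0) == pytest.approx(50.0)

    def test_recovery_grid(self):
        # noiseless inputs over a broad (a, b) grid recover within 1e-6
        doses = np.array([0.2, 0.6, 1.3, 2.8, 5.0])
        for a in (0.15, 1.0, 7.3, 95.0):
            for b in (-2.9, -1.0, -0.1, 0.4, 2.9):
                fit = fit_power_law(doses, a * doses**b)
                assert fit.a == pytest.approx(a, rel=1e-6)
                assert fit.b == pytest.approx(b, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_power_law([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0], [-1.0, 2.0])


class TestEquivalentDose:
    FIT = DoseResponseFit(a=10.503, b=-1.394, r_squared=0.9976)

    def test_printed_worked_example(self):
        # mutant median 36 h at 0.25 mM corresponds to 0.413 mM for controls
        x = equivalent_dose(self.FIT, 36.0)
        assert round(x, 3) == 0.413

    def test_unit_dose_fixed_point(self):
        assert equivalent_dose(self.FIT, self.FIT.a) == pytest.approx(1.0)

    def test_roundtrip_inversion(self):
        for x0 in (0.1, 0.5, 2.0):
            assert equivalent_dose(self.FIT, self.FIT.predict(x0)) == pytest.approx(x0)

    def test_flat_fit_rejected(self):
        with pytest.raises(ValueError):
            equivalent_dose(DoseResponseFit(a=10.0, b=0.0, r_squared=1.0), 5.0)

    def test_relative_sensitivity_printed_value(self):
        s = relative_sensitivity(self.FIT, actual_dose=0.25, observed_median=36.0)
        assert abs(s - 65.0) <= 1.0

    def test_zero_when_median_matches_model(self):
        s = relative_sensitivity(self.FIT, 0.5, self.FIT.predict(0.5))
        assert s == pytest.approx(0.0, abs=1e-9)

    def test_doubling_equivalent_dose_is_100_percent(self):
        median_at_double = self.FIT.predict(1.0)
        assert relative_sensitivity(self.FIT, 0.5, median_at_double) == pytest.approx(100.0)
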
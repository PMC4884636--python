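"""Kaplan–Meier, Greenwood, relative-survival corrections, Z and log-rank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nodestrat import (
    DegenerateTestError,
    GridAlignmentError,
    UndefinedRatioError,
    km_estimate,
    logrank_test,
    relative_survival,
    rs_z_test,
)
from nodestrat.life_tables import ExpectedSurvivalCurve
from nodestrat.survival import RelativeSurvivalCurve, SurvivalCurve

from conftest import make_record


def brute_force_km(times, dead, max_months):
    """Independent product-limit oracle: loop over distinct death times."""
    times = np.maximum(np.asarray(times), 1)
    dead = np.asarray(dead, dtype=bool)
    death_times = sorted(set(times[dead]))
    surv = np.ones(max_months + 1)
    for m in range(1, max_months + 1):
        s = 1.0
        for e in death_times:
            if e <= m:
                n = np.sum(times >= e)
                d = np.sum((times == e) & dead)
                s *= 1.0 - d / n
        surv[m] = s
    return surv


def _cohort(times_status):
    return [
        make_record(patient_id=str(i), follow_up_months=t,
                    vital_status="dead" if dead else "censored")
        for i, (t, dead) in enumerate(times_status)
    ]


def _rs_from_values(raw):
    """Relative survival computed from a prescribed observed/expected ratio
    sequence (expected survival identically 1)."""
    m = len(raw) - 1
    grid = np.arange(m + 1)
    obs = SurvivalCurve(grid, np.array(raw, float), np.zeros(m + 1),
                        np.ones(m + 1, dtype=int))
    exp = ExpectedSurvivalCurve(grid, np.ones(m + 1))
    return relative_survival(obs, exp)


class TestKaplanMeier:
    def test_single_death(self):
        curve = km_estimate(_cohort([(5, True)]), 10)
        assert list(curve.survival[:5]) == [1.0] * 5
        assert list(curve.survival[5:]) == [0.0] * 6

    def test_five_subject_worked_example(self):
        cohort = _cohort([(3, True), (5, False), (7, True), (9, True), (10, False)])
        curve = km_estimate(cohort, 12)
        assert curve.survival[2] == 1.0
        assert curve.survival[3] == pytest.approx(0.8)
        assert curve.survival[7] == pytest.approx(0.8 * 2 / 3)
        assert curve.survival[9] == pytest.approx(0.8 * 2 / 3 * 0.5)
        # Greenwood SE at month >= 9
        se = 0.8 * 2 / 3 * 0.5 * np.sqrt(1 / 20 + 1 / 6 + 1 / 2)
        assert curve.std_err[9] == pytest.approx(se)
        assert curve.std_err[9] == pytest.approx(0.2257, abs=5e-4)

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(1, 21)
            times = rng.integers(0, 30, size=n)
            dead = rng.random(n) < 0.6
            cohort = _cohort(list(zip(times.tolist(), dead.tolist())))
            curve = km_estimate(cohort, 30)
            np.testing.assert_allclose(
                curve.survival, brute_force_km(times, dead, 30), atol=1e-12
            )

    def test_matches_lifelines(self):
        """Cross-check against an independent KM implementation."""
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        times = rng.integers(1, 60, size=80)
        dead = rng.random(80) < 0.5
        cohort = _cohort(list(zip(times.tolist(), dead.tolist())))
        curve = km_estimate(cohort, 60)
        kmf = KaplanMeierFitter().fit(times, event_observed=dead)
        grid = np.arange(61)
        expected = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(curve.survival, expected, atol=1e-10)

    def test_n_at_risk_non_increasing(self, small_cohort):
        curve = km_estimate(small_cohort, 120)
        assert np.all(np.diff(curve.n_at_risk) <= 0)
        assert curve.survival[0] == 1.0


class TestRelativeSurvival:
    def test_identity_when_observed_equals_expected(self):
        rs = _rs_from_values([1.0, 0.95, 0.90])
        obs = SurvivalCurve(np.arange(3), np.array([1.0, 0.95, 0.90]),
                            np.zeros(3), np.ones(3, int))
        exp = ExpectedSurvivalCurve(np.arange(3), np.array([1.0, 0.95, 0.90]))
        rs = relative_survival(obs, exp)
        np.testing.assert_allclose(rs.rs, 1.0)
        assert all(f == "none" for f in rs.corrections_applied)

    def test_capping_worked_example(self):
        rs = _rs_from_values([1.0, 1.02, 0.95])
        np.testing.assert_allclose(rs.rs, [1.0, 1.0, 0.95])
        assert list(rs.corrections_applied) == ["none", "capped", "none"]

    def test_carry_back_worked_example(self):
        rs = _rs_from_values([1.0, 0.90, 0.93, 0.88])
        np.testing.assert_allclose(rs.rs, [1.0, 0.90, 0.90, 0.88])
        assert list(rs.corrections_applied) == ["none", "none", "carried_back", "none"]

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.01, 1.3), min_size=1, max_size=40))
    def test_output_always_non_increasing(self, tail):
        rs = _rs_from_values([1.0] + tail)
        assert np.all(np.diff(rs.rs) <= 0)
        assert np.all((rs.rs >= 0) & (rs.rs <= 1))

    def test_flat_table_equals_observed(self, flat_table, small_cohort):
        from nodestrat import ederer2_expected

        obs = km_estimate(small_cohort, 120)
        exp = ederer2_expected(small_cohort, flat_table, 120)
        rs = relative_survival(obs, exp)
        np.testing.assert_allclose(rs.rs, obs.survival, atol=1e-12)

    def test_zero_expected_with_positive_observed_raises(self):
        obs = SurvivalCurve(np.arange(2), np.array([1.0, 0.5]), np.zeros(2),
                            np.ones(2, int))
        exp = ExpectedSurvivalCurve(np.arange(2), np.array([1.0, 0.0]))
        with pytest.raises(UndefinedRatioError):
            relative_survival(obs, exp)

    def test_grid_mismatch_raises(self):
        obs = SurvivalCurve(np.arange(3), np.ones(3), np.zeros(3), np.ones(3, int))
        exp = ExpectedSurvivalCurve(np.array([0, 2, 4]), np.ones(3))
        with pytest.raises(GridAlignmentError):
            relative_survival(obs, exp)


def _curve_with(month, rs, se):
    grid = np.arange(month + 1)
    vals = np.linspace(1.0, rs, month + 1)
    ses = np.linspace(0.0, se, month + 1)
    return RelativeSurvivalCurve(grid, vals, ses,
                                 np.array(["none"] * (month + 1), dtype=object))


class TestZTest:
    def test_identical_curves(self):
        c = _curve_with(120, 0.8, 0.02)
        res = rs_z_test(c, c, 120)
        assert res.z == 0.0 and res.p == 1.0

    def test_worked_example(self):
        a = _curve_with(120, 0.97, 0.01)
        b = _curve_with(120, 0.71, 0.03)
        res = rs_z_test(a, b, 120)
        assert res.z == pytest.approx(0.26 / np.sqrt(0.001), rel=1e-9)
        assert res.z == pytest.approx(8.222, abs=5e-3)
        assert res.p < 0.001

    def test_antisymmetric(self):
        a = _curve_with(60, 0.9, 0.02)
        b = _curve_with(60, 0.8, 0.01)
        r1, r2 = rs_z_test(a, b, 60), rs_z_test(b, a, 60)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate(self):
        a = _curve_with(10, 0.9, 0.0)
        b = _curve_with(10, 0.8, 0.0)
        with pytest.raises(DegenerateTestError):
            rs_z_test(a, b, 10)


class TestLogRank:
    def test_self_comparison_is_null(self, small_cohort):
        res = logrank_test(small_cohort[:100], small_cohort[:100])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_event_time_hand_value(self):
        """Group A: 10 deaths at month 1; group B: 10 censored at month 24.
        O-E = 5 and hypergeometric variance 100*100/(400*19) per death."""
        a = _cohort([(1, True)] * 10)
        b = _cohort([(24, False)] * 10)
        res = logrank_test(a, b)
        v = (10 * 10 * 10 * (20 - 10)) / (20**2 * (20 - 1))  # = 1.3158
        assert res.statistic == pytest.approx(5**2 / v, rel=1e-9)

    def test_symmetric_and_order_invariant(self, small_cohort):
        a, b = small_cohort[:150], small_cohort[150:300]
        r1 = logrank_test(a, b)
        r2 = logrank_test(b, a[::-1])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_no_events_raises(self):
        a = _cohort([(10, False)] * 3)
        b = _cohort([(20, False)] * 3)
        with pytest.raises(DegenerateTestError):
            logrank_test(a, b)
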
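"""Product-limit estimation, Greenwood variance and the yearly Z comparison.

The estimator is checked against an independent exact-rational oracle
(`fractions.Fraction` arithmetic over the risk-set recursion) and against
lifelines' Kaplan-Meier fit on random instances.
"""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from vcarm.km import (
    DegenerateComparisonError,
    KMError,
    compare_arms_by_year,
    format_comparison,
    format_p,
    km_curve,
    two_sample_z,
)


def oracle_km(times, events, t):
    """Exact product-limit estimate and Greenwood variance at time t.

    Independent oracle in rational arithmetic: walks distinct death times
    <= t, counting the risk set by brute force (censored subjects at a death
    time still at risk).
    """
    death_times = sorted({ti for ti, ei in zip(times, events) if ei == 1 and ti <= t})
    s = Fraction(1)
    gw = Fraction(0)
    undefined = False
    for dt in death_times:
        n = sum(1 for ti in times if ti >= dt)
        d = sum(1 for ti, ei in zip(times, events) if ti == dt and ei == 1)
        s *= Fraction(n - d, n)
        if n == d:
            undefined = True
        elif not undefined:
            gw += Fraction(d, n * (n - d))
    var = float(s) ** 2 * float(gw) if not undefined else 0.0
    return float(s), var


def random_instance(rng, n):
    times = rng.integers(1, 8, size=n).astype(float)
    events = rng.integers(0, 2, size=n)
    return times, events


class TestKMCurve:
    def test_hand_worked_three_subjects(self):
        # death at 1 (risk 3), censored at 2, death at 3 (risk 1)
        curve = km_curve([1, 2, 3], [1, 0, 1], eval_times=[0, 1, 2, 3])
        assert curve.estimates == pytest.approx([1, 2 / 3, 2 / 3, 0])
        # Greenwood at t=1: (2/3)^2 * 1/(3*2)
        assert curve.se[1] == pytest.approx(np.sqrt((2 / 3) ** 2 / 6), abs=1e-12)
        assert curve.se[1] == pytest.approx(0.272, abs=5e-4)
        assert curve.se[3] == 0.0  # estimate reached 0

    def test_no_events_curve_stays_at_one(self):
        curve = km_curve([3, 5, 9], [0, 0, 0], eval_times=np.arange(10.0))
        assert np.all(curve.estimates == 1.0)
        assert np.all(curve.se == 0.0)

    def test_empty_input_raises(self):
        with pytest.raises(KMError):
            km_curve([], [])

    def test_start_of_followup_has_zero_se(self):
        curve = km_curve([1, 2], [1, 1], eval_times=[0, 1, 2])
        assert curve.estimates[0] == 1.0
        assert curve.se[0] == 0.0

    def test_matches_exact_rational_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 31))
            times, events = random_instance(rng, n)
            grid = np.arange(0.0, 9.0)
            curve = km_curve(times, events, eval_times=grid)
            for i, t in enumerate(grid):
                s, var = oracle_km(list(times), list(events), t)
                assert curve.estimates[i] == pytest.approx(s, abs=1e-12)
                assert curve.se[i] ** 2 == pytest.approx(var, abs=1e-12)

    def test_matches_lifelines_estimates(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(10):
            n = int(rng.integers(5, 40))
            times, events = random_instance(rng, n)
            grid = np.arange(0.0, 9.0)
            curve = km_curve(times, events, eval_times=grid)
            kmf = lifelines.KaplanMeierFitter().fit(times, events)
            expected = kmf.survival_function_at_times(grid).to_numpy()
            np.testing.assert_allclose(curve.estimates, expected, atol=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(1, 10), st.booleans()), min_size=1, max_size=25
        )
    )
    def test_curve_nonincreasing_and_ci_ordered(self, subjects):
        times = [t for t, _ in subjects]
        events = [int(e) for _, e in subjects]
        curve = km_curve(times, events, eval_times=np.arange(0.0, 12.0))
        assert np.all(np.diff(curve.estimates) <= 1e-15)
        assert np.all(curve.ci_low <= curve.estimates + 1e-15)
        assert np.all(curve.estimates <= curve.ci_high + 1e-15)
        assert np.all((curve.ci_low >= 0) & (curve.ci_high <= 1))
        # cumulative Greenwood sum (relative variance) nondecreasing while
        # the curve is positive; the SE itself need not be monotone since
        # the S(t) factor shrinks
        positive = curve.estimates > 0
        rel_var = (curve.se[positive] / curve.estimates[positive]) ** 2
        assert np.all(np.diff(rel_var) >= -1e-12)

    @given(
        st.lists(st.integers(1, 10), min_size=1, max_size=25)
    )
    def test_no_censoring_equals_empirical_fraction(self, death_years):
        times = np.array(death_years, dtype=float)
        events = np.ones_like(times, dtype=int)
        grid = np.arange(0.0, 12.0)
        curve = km_curve(times, events, eval_times=grid)
        empirical = np.array([(times > t).mean() for t in grid])
        np.testing.assert_allclose(curve.estimates, empirical, atol=1e-12)

    def test_yearly_grid_carries_last_step_forward(self):
        curve = km_curve([2.5, 6.0], [1, 0], eval_times=[0, 1, 2, 3, 4, 5])
        assert curve.estimates[2] == 1.0      # before the death at 2.5
        assert curve.estimates[3] == pytest.approx(0.5)
        assert curve.estimates[5] == pytest.approx(0.5)  # plateau

    def test_n_at_risk_counts_subjects_still_observed(self):
        curve = km_curve([1, 2, 3, 15], [1, 0, 1, 0], eval_times=[0, 1, 2, 3, 4])
        np.testing.assert_array_equal(curve.n_at_risk, [4, 4, 3, 2, 1])


class TestTwoSampleZ:
    def test_equal_estimates_give_p_one(self):
        z, p = two_sample_z(0.5, 0.02, 0.5, 0.03)
        assert z == 0.0 and p == 1.0

    def test_symmetric_in_arm_order(self):
        z1, p1 = two_sample_z(0.7, 0.02, 0.6, 0.03)
        z2, p2 = two_sample_z(0.6, 0.03, 0.7, 0.02)
        assert z1 == -z2
        assert p1 == pytest.approx(p2, abs=0)

    def test_published_year5_comparison(self):
        # estimates and CI-derived SEs from the validation trial's year-5 row
        se_a = (0.747 - 0.681) / 3.92
        se_b = (0.693 - 0.623) / 3.92
        z, p = two_sample_z(0.714, se_a, 0.658, se_b)
        assert p == pytest.approx(0.023, abs=0.002)  # printed as 0.024
        assert p < 0.05

    def test_published_year15_comparison(self):
        se_a = (0.587 - 0.509) / 3.92
        se_b = (0.492 - 0.418) / 3.92
        z, p = two_sample_z(0.548, se_a, 0.455, se_b)
        assert p < 0.001

    def test_degenerate_cases(self):
        z, p = two_sample_z(0.5, 0.0, 0.5, 0.0)
        assert p == 1.0
        with pytest.raises(DegenerateComparisonError):
            two_sample_z(0.5, 0.0, 0.6, 0.0)

    @given(
        st.floats(0, 1), st.floats(1e-4, 0.2),
        st.floats(0, 1), st.floats(1e-4, 0.2),
    )
    def test_matches_normal_sf(self, sa, sea, sb, seb):
        z, p = two_sample_z(sa, sea, sb, seb)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)
        assert 0.0 <= p <= 1.0


class TestCompareArmsByYear:
    def test_identical_curves_all_p_one(self):
        curve = km_curve([3, 7, 12, 15], [1, 1, 0, 0], eval_times=np.arange(16.0))
        result = compare_arms_by_year(curve, curve, horizon=15)
        assert len(result) == 15
        assert (result["p_value"] == 1.0).all()

    def test_horizon_beyond_support_raises(self):
        curve = km_curve([3, 7], [1, 1], eval_times=np.arange(6.0))
        with pytest.raises(KMError):
            compare_arms_by_year(curve, curve, horizon=15)

    def test_formatting(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.024) == "0.024"
        curve = km_curve([3, 7, 12, 15], [1, 1, 0, 0], eval_times=np.arange(16.0))
        report = format_comparison(compare_arms_by_year(curve, curve, horizon=15))
        assert list(report.columns) == [
            "year", "n_at_risk", "observed (95% CI)", "predicted (95% CI)", "p",
        ]
        assert report["p"].iloc[0] == "1.000"
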
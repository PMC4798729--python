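"""Unit and property tests for the well-mixed lineage models."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineagemorph import core
from lineagemorph.core import (
    FeedbackForm,
    FeedbackParams,
    LineageState,
    PulseSchedule,
    RegimeLabel,
    ThreeStageParams,
    TwoStageParams,
)


def two_stage(p, phi, gamma, delta=0.0, **kw):
    return TwoStageParams(FeedbackParams(p=p, phi=phi, gamma=gamma, **kw),
                          delta=delta)


class TestRenewalProbability:
    def test_vanishes_without_positive_source(self):
        fb = FeedbackParams(p=1.0, phi=5.0, gamma=1.0)
        assert core.renewal_probability(np.array([1.0, 0.0]), fb) == 0.0

    def test_negative_feedback_dominates_at_large_td(self):
        fb = FeedbackParams(p=1.0, phi=5.0, gamma=1.0)
        assert core.renewal_probability(np.array([1.0, 1e9]), fb) < 1e-8

    def test_analytic_maximum(self):
        # max of chi/((1+gamma chi)(1+phi chi)) sits at chi* = 1/sqrt(gamma phi)
        fb = FeedbackParams(p=1.0, phi=9.0, gamma=1.0)
        chi_star = 1.0 / math.sqrt(9.0)
        p_star = core.renewal_probability(np.array([0.0, chi_star]), fb)
        assert p_star == pytest.approx(9.0 / 16.0, abs=1e-12)
        grid = np.linspace(0, 10, 20001)
        vals = [core.renewal_probability(np.array([0.0, c]), fb) for c in grid]
        assert max(vals) <= p_star + 1e-9

    def test_rejects_negative_populations(self):
        fb = FeedbackParams(p=0.9, phi=1.0, gamma=1.0)
        with pytest.raises(ValueError):
            core.renewal_probability(np.array([-0.1, 1.0]), fb)

    def test_exogenous_terms_enter_hill_arguments(self):
        fb = FeedbackParams(p=1.0, phi=1.0, gamma=1.0, phi_ex=9.0)
        # chi1 = 0 but phi_ex drives the positive term: P = (9/10)
        assert core.renewal_probability(np.array([1.0, 0.0]), fb) \
            == pytest.approx(0.9)

    @given(st.floats(0.51, 1.0), st.floats(0.01, 50.0), st.floats(0.01, 50.0),
           st.floats(0.0, 1e4))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounded_by_p(self, p, phi, gamma, chi1):
        fb = FeedbackParams(p=p, phi=phi, gamma=gamma)
        P = core.renewal_probability(np.array([1.0, chi1]), fb)
        assert 0.0 <= P <= p + 1e-12


class TestRightHandSides:
    def test_two_stage_no_stem_cells(self):
        params = two_stage(0.9, 1.0, 1.0, delta=0.5)
        d = core.two_stage_rhs(np.array([0.0, 4.0]), params)
        assert d == pytest.approx([0.0, -2.0])

    def test_renewal_balance_freezes_chi0(self):
        params = two_stage(1.0, 10.0, 1.0, delta=1.0)
        eq = core.equilibria_two_stage(params)
        high = eq.chi1_roots[2]
        d = core.two_stage_rhs(np.array([high, high]), params)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_final_state_td_never_decreases(self):
        params = two_stage(0.8, 0.05, 0.002, delta=0.0)
        d = core.two_stage_rhs(np.array([2.0, 30.0]), params)
        assert d[1] >= 0.0

    def test_three_stage_sc_constant_and_td_decay(self):
        params = ThreeStageParams(
            FeedbackParams(p=0.75, phi=1.0, gamma=0.02,
                           positive_source="CP"),
            zeta=0.0, delta=0.2)
        d = core.three_stage_rhs(np.array([1.0, 0.0, 5.0]), params)
        assert d[0] == 0.0
        assert d[1] == 0.0
        assert d[2] == pytest.approx(-1.0)

    def test_three_stage_stationary_conditions(self):
        # published three-stage parameter set: the stationary state solves
        # zeta chi0 = (1 - 2P) chi1 and 2 (1 - P) chi1 = delta chi2
        from scipy.optimize import fsolve

        params = ThreeStageParams(
            FeedbackParams(p=0.75, phi=1.0, gamma=0.02,
                           positive_source="CP"),
            zeta=0.09, delta=0.2)
        traj = core.integrate_lineage(
            params, LineageState(chi=np.array([1.0, 4.0, 10.0])), 2000.0)

        def resid(v):
            chi = np.array([1.0, max(v[0], 1e-12), max(v[1], 1e-12)])
            return core.three_stage_rhs(chi, params)[1:]

        sol = fsolve(resid, traj.states[-1, 1:], full_output=False)
        chi = np.array([1.0, sol[0], sol[1]])
        assert np.max(np.abs(core.three_stage_rhs(chi, params)[1:])) < 1e-10


class TestIntegration:
    def test_fig1f_threshold_sides(self):
        # just below / above the phi/gamma ~ 5.8 threshold
        for phi, survives in ((5.0, False), (7.0, True)):
            params = two_stage(1.0, phi, 1.0, delta=1.0)
            traj = core.integrate_lineage(
                params, LineageState(chi=np.array([0.3, 0.0])), 300.0)
            assert bool(traj.states[-1, 1] > 0.1) is survives

    def test_converges_to_closed_form_high_root(self):
        params = two_stage(1.0, 10.0, 1.0, delta=1.0)
        high = (9.0 + math.sqrt(41.0)) / 20.0
        traj = core.integrate_lineage(
            params, LineageState(chi=np.array([0.7, 0.7])), 400.0)
        assert traj.states[-1, 1] == pytest.approx(high, rel=1e-6)
        assert traj.states[-1, 0] == pytest.approx(high, rel=1e-6)

    def test_no_positive_feedback_means_extinction(self):
        params = two_stage(1.0, 0.0, 1.0, delta=1.0)
        traj = core.integrate_lineage(
            params, LineageState(chi=np.array([5.0, 5.0])), 100.0)
        assert traj.states[-1].max() < 1e-6

    def test_nonnegative_and_td_monotone_without_turnover(self):
        params = two_stage(0.8, 0.05, 0.002, delta=0.0)
        traj = core.integrate_lineage(
            params, LineageState(chi=np.array([1.0, 120.0])), 100.0,
            t_eval=np.linspace(0, 100, 400))
        assert np.all(traj.states >= 0.0)
        assert np.all(np.diff(traj.states[:, 1]) >= -1e-9)

    def test_matches_fixed_step_reference(self):
        # adaptive integration vs 10x-refined RK4 on the threshold setup
        params = two_stage(1.0, 7.0, 1.0, delta=1.0)
        t_eval = np.linspace(0.0, 50.0, 101)
        adaptive = core.integrate_lineage(
            params, LineageState(chi=np.array([0.3, 0.0])), 50.0,
            t_eval=t_eval)
        reference = core.integrate_lineage(
            params, LineageState(chi=np.array([0.3, 0.0])), 50.0,
            method="rk4", dt=1e-3, t_eval=t_eval)
        scale = np.max(np.abs(reference.states))
        assert np.max(np.abs(adaptive.states - reference.states)) < 1e-6 * scale


class TestEquilibria:
    def test_closed_form_roots(self):
        eq = core.equilibria_two_stage(two_stage(1.0, 10.0, 1.0, delta=1.0))
        lo, hi = (9.0 - math.sqrt(41)) / 20.0, (9.0 + math.sqrt(41)) / 20.0
        assert eq.chi1_roots == pytest.approx((0.0, lo, hi))
        assert eq.chi0_values == pytest.approx((0.0, lo, hi))  # delta = 1
        assert eq.stability == (True, False, True)
        assert eq.bistable

    def test_renewal_is_half_at_nonzero_equilibria(self):
        params = two_stage(0.8, 0.05, 0.002, delta=0.2)
        eq = core.equilibria_two_stage(params)
        for chi1 in eq.chi1_roots[1:]:
            P = core.renewal_probability(np.array([0.2 * chi1, chi1]),
                                         params.feedback)
            assert abs(P - 0.5) < 1e-9

    def test_below_threshold_only_zero_root(self):
        eq = core.equilibria_two_stage(two_stage(1.0, 4.0, 1.0, delta=1.0))
        assert eq.chi1_roots == (0.0,)
        assert not eq.bistable

    def test_half_renewal_ceiling_never_bistable(self):
        for phi, gamma in ((10.0, 0.1), (100.0, 1.0), (1000.0, 0.01)):
            eq = core.equilibria_two_stage(
                two_stage(0.5, phi, gamma, delta=1.0))
            assert not eq.bistable

    def test_degenerate_gamma_zero_unbounded(self):
        eq = core.equilibria_two_stage(two_stage(0.9, 1.0, 0.0, delta=1.0))
        assert eq.unbounded and eq.chi1_roots == (0.0,)

    def test_degenerate_phi_zero(self):
        eq = core.equilibria_two_stage(two_stage(0.9, 0.0, 1.0, delta=1.0))
        assert eq.chi1_roots == (0.0,) and not eq.unbounded

    def test_numeric_cross_check_against_rhs_roots(self):
        from scipy.optimize import brentq

        params = two_stage(0.85, 2.0, 0.05, delta=0.7)
        eq = core.equilibria_two_stage(params)

        def chi0_growth(chi1):
            P = core.renewal_probability(np.array([0.0, chi1]),
                                         params.feedback)
            return 2.0 * P - 1.0

        lo = brentq(chi0_growth, 1e-6, 1.0)
        hi = brentq(chi0_growth, 1.0, 1e4)
        assert eq.chi1_roots[1] == pytest.approx(lo, rel=1e-9)
        assert eq.chi1_roots[2] == pytest.approx(hi, rel=1e-9)


class TestBistabilityThreshold:
    def test_printed_value_at_p_one(self):
        r = core.bistability_threshold(1.0)
        assert r == pytest.approx(3.0 + 2.0 * math.sqrt(2.0), abs=1e-12)
        assert round(r, 1) == 5.8

    def test_derived_value_at_p_08(self):
        # larger root of 0.36 r^2 - 5.2 r + 1 = 0
        r = core.bistability_threshold(0.8)
        quad = 0.36 * r * r - 5.2 * r + 1.0
        assert abs(quad) < 1e-9
        assert r == pytest.approx(14.25, abs=0.005)

    def test_no_threshold_at_or_below_half(self):
        assert core.bistability_threshold(0.5) is None
        assert core.bistability_threshold(0.3) is None

    @pytest.mark.parametrize("p", np.round(np.arange(0.55, 1.0001, 0.05), 2))
    def test_agrees_with_existence_bisection(self, p):
        # independent oracle: bisect the phi/gamma ratio at which two real
        # positive equilibria appear
        def exists(r):
            eq = core.equilibria_two_stage(
                two_stage(float(p), r * 1.0, 1.0, delta=1.0))
            return len(eq.chi1_roots) == 3

        lo, hi = 1.0, 1e5
        assert not exists(lo) and exists(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if exists(mid):
                hi = mid
            else:
                lo = mid
        assert core.bistability_threshold(float(p)) == pytest.approx(
            hi, abs=1e-6 * max(1.0, hi))


class TestCriticalValues:
    def test_published_growth_leap_bounds(self):
        cv = core.critical_values(two_stage(0.8, 0.05, 0.002, delta=0.0))
        assert cv.chi1_critlow == pytest.approx(42.0, abs=0.05)
        assert cv.chi1_crithigh == pytest.approx(238.0, abs=0.05)

    def test_equal_to_nonzero_equilibria(self):
        params = two_stage(0.9, 0.3, 0.01)
        cv = core.critical_values(params)
        eq = core.equilibria_two_stage(
            TwoStageParams(params.feedback, delta=0.5))
        assert cv.chi1_critlow == eq.chi1_roots[1]
        assert cv.chi1_crithigh == eq.chi1_roots[2]

    def test_sign_change_scan_confirms_bounds(self):
        params = two_stage(0.8, 0.05, 0.002)
        cv = core.critical_values(params)
        grid = np.linspace(1.0, 400.0, 8000)
        growth = np.array([
            2 * core.renewal_probability(np.array([0.0, c]), params.feedback)
            - 1 for c in grid])
        crossings = grid[np.where(np.diff(np.sign(growth)) != 0)[0]]
        assert crossings[0] == pytest.approx(cv.chi1_critlow, abs=0.1)
        assert crossings[-1] == pytest.approx(cv.chi1_crithigh, abs=0.1)

    def test_no_region_below_threshold(self):
        assert core.critical_values(two_stage(0.6, 0.1, 0.1)) is None


class TestRegimeClassification:
    @pytest.mark.parametrize("chi1_0,expected", [
        (20.0, RegimeLabel.REGIME2_TOO_FEW_TD),
        (120.0, RegimeLabel.REGIME3_GROWTH_LEAP),
        (260.0, RegimeLabel.REGIME1_TOO_MANY_TD),
    ])
    def test_published_initial_conditions(self, chi1_0, expected):
        params = two_stage(0.8, 0.05, 0.002)
        lab = core.classify_final_state_regime(
            LineageState(chi=np.array([1.0, chi1_0])), params)
        assert lab is expected

    def test_no_stem_cells_no_dynamics(self):
        params = two_stage(0.8, 0.05, 0.002)
        lab = core.classify_final_state_regime(
            LineageState(chi=np.array([0.0, 20.0])), params)
        assert lab is RegimeLabel.REGIME2_TOO_FEW_TD

    def test_large_sc_pool_leaps_from_below_critlow(self):
        params = two_stage(0.8, 0.05, 0.002)
        small = core.classify_final_state_regime(
            LineageState(chi=np.array([1.0, 0.0])), params)
        assert small is RegimeLabel.REGIME2_TOO_FEW_TD
        big = core.classify_final_state_regime(
            LineageState(chi=np.array([150.0, 0.0])), params)
        assert big is RegimeLabel.REGIME3_GROWTH_LEAP


class TestPulseExperiments:
    PARAMS = two_stage(0.8, 0.25, 0.015, delta=0.2)

    def test_toggle_on_then_off(self):
        sched = PulseSchedule(windows=((0.0, 2.0, 200.0, 0.0),
                                       (100.0, 102.0, 0.0, 200.0)))
        traj = core.apply_pulse_experiment(
            self.PARAMS, LineageState(chi=np.array([2.0, 0.0])), sched, 160.0)
        eq = core.equilibria_two_stage(self.PARAMS)
        i = np.searchsorted(traj.times, 99.0)
        assert traj.states[i, 1] == pytest.approx(eq.chi1_roots[2], rel=1e-3)
        assert traj.states[-1, 1] < 1e-2

    def test_empty_schedule_matches_plain_integration(self):
        a = core.apply_pulse_experiment(
            self.PARAMS, LineageState(chi=np.array([2.0, 1.0])),
            PulseSchedule(), 30.0)
        b = core.integrate_lineage(
            self.PARAMS, LineageState(chi=np.array([2.0, 1.0])), 30.0,
            t_eval=a.times)
        assert np.allclose(a.states, b.states, rtol=1e-6, atol=1e-9)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError):
            PulseSchedule(windows=((0.0, 3.0, 10.0, 0.0),
                                   (2.0, 4.0, 10.0, 0.0)))

    def test_final_state_insensitive_to_triggering_pulse(self):
        # grid over pulse duration x magnitude: among pulses that trigger
        # the growth leap, the final TD count barely varies
        params = two_stage(0.8, 0.05, 0.002, delta=0.0)
        crithigh = core.critical_values(params).chi1_crithigh

        def final_chi1(level, cycles):
            sched = PulseSchedule(windows=((0.0, cycles, level, 0.0),))
            traj = core.apply_pulse_experiment(
                params, LineageState(chi=np.array([5.0, 0.0])), sched, 400.0)
            return float(traj.states[-1, 1])

        finals = []
        for cycles in (1.0, 2.0, 4.0):
            lo, hi = 0.05, 5000.0  # bisect the minimal triggering level
            for _ in range(30):
                mid = math.sqrt(lo * hi)
                if final_chi1(mid, cycles) > crithigh:
                    hi = mid
                else:
                    lo = mid
            finals += [final_chi1(hi * m, cycles) for m in (1.05, 1.5)]
        finals = np.asarray(finals)
        assert finals.min() > crithigh
        assert finals.std() / finals.mean() < 0.05


@pytest.fixture(scope="module")
def product_table():
    return core.behavior_census(FeedbackForm.PRODUCT_HILL,
                                p_values=(0.6, 0.9), t_end=1000.0)


class TestBehaviorCensus:
    def test_no_feedback_always_unbounded(self, product_table):
        for regime in ("steady", "final"):
            assert product_table[regime]["none"]["unbounded"] == "Always"
            assert product_table[regime]["none"]["nonzero"] == "Never"

    def test_negative_feedback_always_stabilizes(self, product_table):
        for regime in ("steady", "final"):
            row = product_table[regime]["neg"]
            assert row["nonzero"] == "Always"
            assert row["unbounded"] == "Never"
            assert row["bi"] == "Never"

    def test_mixed_feedback_bounded_and_switchable(self, product_table):
        assert product_table["steady"]["both"]["unbounded"] == "Never"
        assert product_table["steady"]["both"]["bi"] == "Sometimes"
        assert product_table["final"]["both"]["nonzero"] == "Always"

    def test_positive_only_final_always_bimodal(self, product_table):
        assert product_table["final"]["pos"]["bi"] == "Always"
        assert product_table["final"]["pos"]["zero"] == "Never"

    def test_shared_denominator_eliminates_bistability(self):
        table = core.behavior_census(FeedbackForm.SHARED_DENOMINATOR,
                                     p_values=(0.75,), t_end=600.0)
        assert table["steady"]["both"]["nonzero"] == "Never"
        assert table["steady"]["both"]["bi"] == "Never"


class TestInvariantProperties:
    @given(st.floats(0.55, 1.0), st.floats(0.05, 5.0), st.floats(30.0, 300.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equilibrium_identities(self, p, gamma, ratio):
        params = two_stage(p, ratio * gamma, gamma, delta=0.7)
        eq = core.equilibria_two_stage(params)
        for chi1, chi0 in zip(eq.chi1_roots[1:], eq.chi0_values[1:]):
            P = core.renewal_probability(np.array([chi0, chi1]),
                                         params.feedback)
            assert abs(P - 0.5) < 1e-9
            assert abs(chi0 - params.delta * chi1) < 1e-9 * chi1

    @given(st.floats(0.55, 1.0), st.floats(0.05, 5.0), st.floats(30.0, 300.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_critical_values_match_equilibria(self, p, gamma, ratio):
        params = two_stage(p, ratio * gamma, gamma, delta=0.0)
        cv = core.critical_values(params)
        eq = core.equilibria_two_stage(
            TwoStageParams(params.feedback, delta=1.0))
        if cv is None:
            assert len(eq.chi1_roots) == 1
        else:
            assert cv.chi1_critlow == eq.chi1_roots[1]
            assert cv.chi1_crithigh == eq.chi1_roots[2]

    def test_chi0_vanishes_in_final_state_with_negative_feedback(self):
        params = two_stage(0.9, 0.3, 0.05, delta=0.0)
        traj = core.integrate_to_final_state(
            params, LineageState(chi=np.array([3.0, 1.0])))
        assert traj.states[-1, 0] < 1e-7
        assert np.all(traj.states.min(axis=0) >= 0.0)
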
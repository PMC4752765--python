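import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neoblast as nb
from neoblast import DegenerateStateError, FullState
from neoblast.feedback import f_N
from neoblast.fixed_points import newton_fixed_point
from neoblast.full_model import (
    diagnose,
    mortality_partition,
    mortality_rates,
    progeny_production,
    relative_need_allocation,
    simulate,
    step,
)
from neoblast.steady_state import Calibration


def _toy_calibration(D_bar, N_c=100.0, sigma_N=15.0, c=0.15, alpha_times_D=0.5):
    D_bar = np.asarray(D_bar, dtype=float)
    rho = D_bar / D_bar.sum()
    return Calibration(
        D_bar=D_bar, rho_bar=rho, alpha=alpha_times_D / D_bar,
        N_c=N_c, sigma_N=sigma_N,
        sigma_D=c * D_bar, sigma_rho=c * rho, Y_e=450.0,
    )


class TestMortality:
    def test_homeostasis_gives_baseline_rates(self, homeostatic_state, full_calib, params):
        M = mortality_rates(homeostatic_state, full_calib, params)
        assert M == pytest.approx(np.array(params.mu_i), rel=1e-12)

    def test_saturated_excess_doubles_baseline(self, full_calib, params):
        # class 1 far above both its level and its proportion target:
        # both logistics saturate and M_1 -> 2 mu_1
        d = full_calib.D_bar * np.array([10.0, 0.05, 0.05])
        M = mortality_rates(FullState(0, 1.0, d, 0.0), full_calib, params)
        assert M[0] == pytest.approx(2.0 * params.mu_i[0], rel=1e-3)

    def test_deep_deficit_suppresses_mortality(self, full_calib, params):
        # class 1 far below both targets: both logistics -> 0 and M_1 -> 0
        d = full_calib.D_bar * np.array([1e-3, 1.0, 1.0])
        M = mortality_rates(FullState(0, 1.0, d, 0.0), full_calib, params)
        assert M[0] < 1e-2 * params.mu_i[0]

    def test_empty_tissue_is_degenerate(self, full_calib, params):
        with pytest.raises(DegenerateStateError):
            mortality_rates(FullState(0, 10.0, np.zeros(3), 0.0),
                            full_calib, params)


class TestMortalityPartition:
    def test_equal_shares_at_homeostasis(self, homeostatic_state, full_calib, params):
        shares = mortality_partition(homeostatic_state, full_calib, params)
        assert shares == pytest.approx(np.full((3, 2), 0.5), rel=1e-9)

    def test_shares_normalize(self, full_calib, params):
        state = FullState(0, 1.0, full_calib.D_bar * [0.4, 1.7, 0.9], 0.0)
        shares = mortality_partition(state, full_calib, params)
        assert shares.sum(axis=1) == pytest.approx(np.ones(3))

    def test_proportion_excess_dominates_when_level_on_target(self, full_calib, params):
        # class 1 at its target level but over-represented in the mix
        d = full_calib.D_bar.copy()
        d[1:] *= 0.5
        state = FullState(0, 1.0, d, 0.0)
        shares = mortality_partition(state, full_calib, params)
        assert shares[0, 0] < shares[0, 1]

    def test_known_term_ratio(self):
        from neoblast.full_model import _partition
        shares = _partition(np.array([0.9]), np.array([0.3]))
        assert shares[0] == pytest.approx([0.75, 0.25])


class TestRelativeNeed:
    def test_balanced_classes_share_equally(self):
        w = relative_need_allocation([30.0, 30.0, 30.0], [30.0, 30.0, 30.0])
        assert w == pytest.approx([1 / 3] * 3)

    @pytest.mark.parametrize(
        "d, expected",
        [([20.0, 30.0, 30.0], [0.5, 0.25, 0.25]),
         ([40.0, 15.0, 30.0], [0.25, 0.5, 0.25])],
    )
    def test_scarce_classes_receive_more(self, d, expected):
        w = relative_need_allocation(d, [40.0, 30.0, 30.0])
        assert w == pytest.approx(expected)
        assert w.sum() == pytest.approx(1.0)

    def test_empty_class_is_degenerate(self):
        with pytest.raises(DegenerateStateError):
            relative_need_allocation([0.0, 30.0, 30.0], [40.0, 30.0, 30.0])

    def test_floor_rescues_empty_class(self):
        w = relative_need_allocation([0.0, 30.0, 30.0], [40.0, 30.0, 30.0],
                                     floor=1e-9)
        assert w[0] == pytest.approx(1.0)  # the empty class takes ~all progeny


class TestProgenyProduction:
    def test_no_neoblasts_no_progeny(self, full_calib, params):
        state = FullState(0, 0.0, full_calib.D_bar.copy(), 0.0)
        fb = diagnose(state, full_calib, params).feedback
        assert progeny_production(state, full_calib, params, fb) == 0.0

    def test_half_feedback_case(self, params):
        # N=100 with f_D = f_N = 0.5 and open gates:
        # P = 100 * 0.5 * (p2 + 2 p3 * 0.5) = 0.0325
        calib = _toy_calibration([100.0, 100.0, 100.0], N_c=100.0,
                                 sigma_N=15.0, alpha_times_D=1.0)
        state = FullState(0, 100.0, np.array([100.0, 100.0, 100.0]), 0.0)
        fb = diagnose(state, calib, params).feedback
        assert fb.fD == pytest.approx(0.5)
        assert fb.fN == pytest.approx(0.5)
        P = progeny_production(state, calib, params, fb)
        assert P == pytest.approx(0.0325, rel=1e-9)


class TestStep:
    def test_half_feedback_neoblast_update(self, params):
        # N' = 100 (1 + p1 - p3*0.5*0.5) = 100.00625 under open gates
        calib = _toy_calibration([100.0] * 3, N_c=100.0, sigma_N=15.0,
                                 alpha_times_D=1.0)
        state = FullState(0, 100.0, np.array([100.0] * 3), 0.0)
        nxt, _ = step(state, calib, params)
        assert nxt.N == pytest.approx(100.00625, rel=1e-12)

    def test_closed_form_is_near_fixed_point(self, homeostatic_state, full_ss,
                                             full_calib, params):
        """Per-step relative drift at the closed form is bounded by the
        self-feedback shortfall p1 (1 - f_N(N_bar))."""
        nxt, _ = step(homeostatic_state, full_calib, params)
        bound = params.p1 * (1.0 - f_N(full_ss.N_bar, full_calib.N_c,
                                       full_calib.sigma_N)) + 1e-12
        assert abs(nxt.N / homeostatic_state.N - 1.0) <= bound
        assert np.all(np.abs(nxt.D / homeostatic_state.D - 1.0) <= bound)

    def test_exact_fixed_point_when_self_feedback_saturates(self, full_ss, params):
        """With N_c pushed far below N_bar the logistic saturates to
        exactly 1 in floating point and the closed form is an exact
        fixed point: a 1,000-step run does not move."""
        calib = nb.make_calibration(full_ss, params.replace(c_N=1e-3))
        state = FullState(0, full_ss.N_bar, full_ss.D_bar.copy(), 0.0)
        traj = simulate(state, calib, params, 1000, record_stride=1000)
        final = traj.final_state
        assert final.N == pytest.approx(state.N, rel=1e-6)
        assert final.D == pytest.approx(state.D, rel=1e-6)

    def test_step_map_fixed_point_near_closed_form(self, full_ss, full_calib, params):
        """The exact fixed point of the step map adjacent to the closed
        form: differentiated cells within 2 %, neoblasts within 4 %
        (the gap comes from f_N(N_bar) < 1; the point is a saddle —
        see the fixed_points module)."""
        seed = np.concatenate([[full_ss.N_bar], full_ss.D_bar])
        z = newton_fixed_point(seed, full_calib, params, model="full")
        assert np.all(np.abs(z[1:] / full_ss.D_bar - 1.0) < 0.02)
        assert abs(z[0] / full_ss.N_bar - 1.0) < 0.04

    def test_single_step_simulate_matches_step(self, homeostatic_state,
                                               full_calib, params):
        traj = simulate(homeostatic_state, full_calib, params, 1, record_stride=1)
        nxt, _ = step(homeostatic_state, full_calib, params)
        assert traj.final_state.N == nxt.N
        assert traj.final_state.D == pytest.approx(nxt.D, rel=0)


count = st.floats(min_value=1.0, max_value=1e6)


class TestStateInvariants:
    @given(
        n=count,
        d=st.lists(count, min_size=3, max_size=3),
        q=st.floats(min_value=0.0, max_value=1e8),
        scale=st.floats(min_value=1e2, max_value=1e6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_states_stay_non_negative(self, n, d, q, scale):
        params = nb.default_parameters().replace(
            sufficient_resources=False, mu_Q_max=0.05)
        calib = _toy_calibration([scale, scale, scale],
                                 N_c=scale, sigma_N=0.15 * scale)
        nxt, _ = step(FullState(0, n, np.array(d), q), calib, params)
        assert nxt.N >= 0.0 and nxt.Q >= 0.0
        assert np.all(nxt.D >= 0.0)

    @given(
        n=count,
        d=st.lists(count, min_size=3, max_size=3),
        q=st.floats(min_value=0.0, max_value=1e8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_resource_bookkeeping_identity(self, n, d, q):
        """Q(t+1) - Q(t) decomposes exactly into the four reported
        fluxes (plus the clamp adjustment when the pool empties)."""
        params = nb.default_parameters().replace(
            sufficient_resources=False, mu_Q_max=0.05)
        calib = _toy_calibration([1e4, 1e4, 1e4], N_c=1e4, sigma_N=1.5e3)
        state = FullState(0, n, np.array(d), q)
        nxt, diag = step(state, calib, params)
        fluxes = sum((diag.flux_food, diag.flux_recycle,
                      diag.flux_maintenance, diag.flux_division))
        # compare without reassociating the floating-point sum
        assert nxt.Q == state.Q + fluxes + diag.q_clamp

    def test_sufficient_mode_leaves_pool_untouched(self, homeostatic_state,
                                                   full_calib, params):
        nxt, diag = step(homeostatic_state, full_calib, params)
        assert nxt.Q == homeostatic_state.Q
        assert (diag.flux_food, diag.flux_recycle,
                diag.flux_maintenance, diag.flux_division) == (0, 0, 0, 0)


class TestGrowthTrajectory:
    def test_neoblast_fraction_nearly_constant(self, growth_result):
        """Along the growth/degrowth protocol the neoblast fraction
        stays within 20 % of the value the trajectory settles at,
        once the initial transient (first tenth of the run) passes."""
        f = growth_result.frame()
        frac = f.neoblast_fraction.to_numpy()
        settled = frac[len(frac) // 10:]
        assert np.all(np.abs(settled / frac[-1] - 1.0) < 0.20)

    def test_degenerate_state_error_carries_step_index(self, full_calib, params):
        state = FullState(t=0, N=10.0, D=np.zeros(3), Q=0.0)
        with pytest.raises(DegenerateStateError, match="at step 0"):
            simulate(state, full_calib, params, 5)
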
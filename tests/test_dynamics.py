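"""Assembled dynamics and the fixed-step integrator.

The independent oracle for trajectories is an adaptive high-accuracy
integration (DOP853, rtol 1e-11) of the same right-hand side, run
piecewise between meal on/off boundaries so the adaptive stepper never
crosses an input discontinuity.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import glucofilt as gf
from glucofilt.model import _rk4_step
from glucofilt.parameters import NONNEGATIVE_STATES, STATE_NAMES


def adaptive_oracle(params, x0, schedule, horizon):
    """Reference trajectory on the 1-min grid via piecewise DOP853."""
    cuts = sorted({0.0, float(horizon)}
                  | {e.start for e in schedule.events}
                  | {e.end for e in schedule.events})
    times = [0.0]
    states = [np.asarray(x0, dtype=float)]
    x = states[0]
    for a, b in zip(cuts, cuts[1:]):
        mid = 0.5 * (a + b)
        def rhs(t, xx):
            return gf.state_derivative(t, xx, schedule, params, meal_time=mid)[0]
        t_eval = np.arange(np.floor(a) + 1.0, b + 1e-9, 1.0)
        sol = solve_ivp(rhs, (a, b), x, t_eval=t_eval, rtol=1e-11, atol=1e-11,
                        method="DOP853")
        assert sol.success
        times.extend(sol.t)
        states.extend(sol.y.T)
        end = solve_ivp(rhs, (a, b), x, rtol=1e-11, atol=1e-11, method="DOP853")
        x = end.y[:, -1]
        if times[-1] == b:
            states[-1] = x
    return np.asarray(times), np.asarray(states)


class TestStateDerivative:
    def test_consistent_basal_is_near_equilibrium(self, cohort_params, no_meal):
        """All net fluxes vanish at the steady-state-consistent basal point.

        The only structural residual is the K*dG/dt secretion coupling on
        portal insulin, driven by the small glucose-side imbalance of the
        rounded published parameters; it is asserted to be exactly that
        coupling term.
        """
        x = gf.consistent_basal_state(cohort_params)
        dx, sig = gf.state_derivative(0.0, x, no_meal, cohort_params)
        tol = np.maximum(0.01 * np.abs(x), 0.05)
        ipo = STATE_NAMES.index("Ipo")
        for i in range(12):
            if i == ipo:
                leak = cohort_params.K * max(sig.Gdot, 0.0)
                assert abs(dx[i] - leak) <= tol[i]
            else:
                assert abs(dx[i]) <= tol[i], STATE_NAMES[i]

    def test_zero_state_plug_in(self, normal_params, no_meal):
        dx, sig = gf.state_derivative(0.0, np.zeros(12), no_meal, normal_params)
        assert dx[0] == dx[1] == dx[2] == 0.0
        assert dx[3] == pytest.approx(2.7 - 1.0)       # EGP=kp1, Uii=Fcns
        assert dx[10] == 0.0
        # beta-cell target floored at -Sb when glucose is far below basal
        assert dx[4] == pytest.approx(-0.05 * 1.549)
        assert sig.Gdot > 0 and dx[5] == pytest.approx(sig.Spo)

    def test_meal_rate_feeds_solid_stomach(self, normal_params, meal_schedule):
        x = np.zeros(12)
        dx, _ = gf.state_derivative(125.0, x, meal_schedule, normal_params)
        assert dx[0] == pytest.approx(3_700.0)

    def test_rejects_non_finite_state(self, normal_params, no_meal):
        x = np.zeros(12)
        x[3] = np.nan
        with pytest.raises(ValueError):
            gf.state_derivative(0.0, x, no_meal, normal_params)


class TestMealSchedule:
    def test_windows_and_bookkeeping(self, meal_schedule):
        s = meal_schedule
        assert s.input_rate(119.9) == 0.0
        assert s.input_rate(120.0) == 3_700.0
        assert s.input_rate(129.9) == 3_700.0
        assert s.input_rate(130.0) == 0.0
        assert s.current_dose(60.0) == 0.0
        assert s.current_dose(125.0) == 37_000.0
        assert s.current_dose(500.0) == 74_000.0
        assert s.total_ingested(1440.0) == 185_000.0
        assert s.total_ingested(125.0) == pytest.approx(5 * 3_700.0)

    def test_overlapping_meals_rejected(self):
        with pytest.raises(ValueError):
            gf.MealSchedule((
                gf.MealEvent(dose=37_000, start=0.0, rate=3_700),
                gf.MealEvent(dose=37_000, start=5.0, rate=3_700),
            ))


class TestSimulate:
    def test_shape_and_step_validation(self, normal_params, no_meal):
        x0 = gf.table_initial_state(normal_params)
        traj = gf.simulate(x0, no_meal, normal_params, horizon=30, step=5)
        assert traj.states.shape == (7, 12)
        assert traj.times[-1] == 30
        with pytest.raises(ValueError):
            gf.simulate(x0, no_meal, normal_params, horizon=10, step=3)

    def test_no_meal_stays_near_basal(self, cohort_params, no_meal):
        """24 h without food drifts less than 5% from the basal glycaemia."""
        x0 = gf.table_initial_state(cohort_params)
        traj = gf.simulate(x0, no_meal, cohort_params, horizon=1440, step=1)
        g = traj.glucose_concentration
        assert np.all(np.abs(g / cohort_params.Gb - 1.0) < 0.05)

    def test_total_meal_input_is_185_g(self, normal_params, meal_schedule):
        x0 = gf.table_initial_state(normal_params)
        traj = gf.simulate(x0, meal_schedule, normal_params, horizon=1440, step=1)
        assert traj.cumulative_ingested[-1] == pytest.approx(185_000.0, rel=1e-9)

    def test_gut_mass_balance(self, cohort_params, meal_schedule):
        """Stomach+gut content plus BW/f * integral(Ra) equals intake."""
        p = cohort_params
        x0 = gf.table_initial_state(p)
        traj = gf.simulate(x0, meal_schedule, p, horizon=1440, step=1)
        gut = traj.states[:, :3].sum(axis=1)
        balance = gut + p.BW / p.f * traj.cumulative_ra - traj.cumulative_ingested
        assert np.abs(balance).max() <= 1e-6 * 185_000.0

    def test_signals_nonnegative_along_trajectory(self, cohort_params, meal_schedule):
        x0 = gf.table_initial_state(cohort_params)
        traj = gf.simulate(x0, meal_schedule, cohort_params, horizon=1440, step=1)
        for col in ("EGP", "E", "Uid", "S", "Spo", "Ra"):
            assert (traj.signals[col] >= 0).all(), col
        assert (traj.states[:, list(NONNEGATIVE_STATES)] >= 0).all()

    def test_t2dm_post_meal_peaks_exceed_normal(self, meal_schedule):
        gn = gf.simulate(
            gf.table_initial_state(gf.ModelParameters.normal()), meal_schedule,
            gf.ModelParameters.normal(), horizon=1440, step=1,
        ).glucose_concentration
        gd = gf.simulate(
            gf.table_initial_state(gf.ModelParameters.t2dm()), meal_schedule,
            gf.ModelParameters.t2dm(), horizon=1440, step=1,
        ).glucose_concentration
        for start in (120, 420, 960):
            window = slice(start, start + 180)
            assert gd[window].max() > gn[window].max()

    def test_matches_adaptive_oracle(self, cohort_params, meal_schedule):
        """RK4 at 0.1-min substeps agrees with DOP853 to < 1e-4 relative."""
        x0 = gf.table_initial_state(cohort_params)
        traj = gf.simulate(x0, meal_schedule, cohort_params, horizon=1440, step=1)
        times, ref = adaptive_oracle(cohort_params, x0, meal_schedule, 1440)
        assert np.allclose(times, traj.times)
        rel = np.abs(traj.states - ref) / np.maximum(np.abs(ref), 1.0)
        assert rel.max() < 1e-4

    def test_substep_halving_converges(self, normal_params, no_meal, meal_schedule):
        x0 = gf.table_initial_state(normal_params)
        smooth = [
            gf.simulate(x0, no_meal, normal_params, 720, 1, substep=h).states
            for h in (0.1, 0.05)
        ]
        rel = np.abs(smooth[0] - smooth[1]) / np.maximum(np.abs(smooth[1]), 1.0)
        assert rel.max() < 1e-5
        # with meals the sharp gastric-emptying transition limits the order
        # locally; successive halvings must still contract strongly
        meal = [
            gf.simulate(x0, meal_schedule, normal_params, 360, 1, substep=h).states
            for h in (0.1, 0.05, 0.025)
        ]
        d1 = np.abs(meal[0] - meal[1]).max()
        d2 = np.abs(meal[1] - meal[2]).max()
        assert d2 < d1 / 8.0


class TestKernelAgreement:
    def test_compiled_flow_matches_reference_rk4(self, cohort_params, meal_schedule):
        """The numba kernel reproduces the pure-python RK4 across a meal
        boundary, including the nonnegativity clipping."""
        dyn = gf.GlucoseDynamics(cohort_params, meal_schedule)
        rng = np.random.default_rng(7)
        pts = gf.table_initial_state(cohort_params) + 0.05 * rng.standard_normal((6, 12))
        got = dyn(pts, 119.0, 2.0)
        nonneg = list(NONNEGATIVE_STATES)
        for row, expected_start in zip(got, pts):
            x = expected_start.copy()
            for j in range(20):
                x, _ = _rk4_step(119.0 + 0.1 * j, x, 0.1, meal_schedule, cohort_params)
                x[nonneg] = np.maximum(x[nonneg], 0.0)
            assert np.allclose(row, x, rtol=1e-12, atol=1e-12)
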
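"""Filter recursions, checked against closed-form linear-Gaussian results.

On a linear system both sigma-point constructions are exact, so the UKF
and CQKF must reproduce the analytic Kalman filter to numerical precision;
that recursion (written out here independently) is the oracle.
"""

import numpy as np
import pytest
from scipy.linalg import expm

import glucofilt as gf
from glucofilt.filters import (
    FilterSpec,
    GaussianBelief,
    _sqrt_psd,
    measurement_update,
    time_update,
)

from conftest import random_psd


def kalman_recursion(F, Q, H, R, mean0, P0, ys):
    """Textbook linear Kalman filter; returns per-step means and covs."""
    m, P = np.asarray(mean0, float), np.asarray(P0, float)
    means, covs = [], []
    for y in ys:
        m = F @ m
        P = F @ P @ F.T + Q
        S = float((H @ P @ H.T).item()) + R
        K = (P @ H.T) / S
        m = m + K[:, 0] * (y - float((H @ m).item()))
        P = P - K @ (H @ P)
        means.append(m.copy())
        covs.append(0.5 * (P + P.T))
    return np.array(means), np.array(covs)


@pytest.fixture
def linear_system():
    A = np.array([[0.0, 1.0], [-0.3, -0.4]])
    dt = 1.0
    F = expm(A * dt)
    Q = np.diag([0.02, 0.05])
    H = np.array([[1.0, 0.0]])
    R = 0.5
    return F, Q, H, R, dt


class TestMeasurementUpdate:
    def test_scalar_hand_kalman_algebra(self):
        pred = GaussianBelief([0.0], [[4.0]])
        spec = FilterSpec(R=16.0, H=[[1.0]], Q=[[0.0]])
        post, innov, s = measurement_update(pred, 5.0, spec)
        assert post.mean[0] == pytest.approx(1.0)
        assert post.cov[0, 0] == pytest.approx(3.2)
        assert innov == 5.0 and s == 20.0

    def test_uninformative_measurement_keeps_prior(self, rng):
        pred = GaussianBelief(rng.standard_normal(4), random_psd(rng, 4))
        spec = FilterSpec(R=1e15, H=[[1.0, 0, 0, 0]], Q=np.zeros((4, 4)))
        post, _, _ = measurement_update(pred, 1e3, spec)
        assert np.allclose(post.mean, pred.mean, atol=1e-9)
        assert np.allclose(post.cov, pred.cov, rtol=1e-10)

    def test_perfect_prior_ignores_measurement(self):
        pred = GaussianBelief(np.ones(3), np.zeros((3, 3)))
        spec = FilterSpec(R=1.0, H=[[0, 1.0, 0]], Q=np.zeros((3, 3)))
        post, _, _ = measurement_update(pred, 99.0, spec)
        assert np.allclose(post.mean, pred.mean)

    def test_posterior_trace_never_exceeds_prior(self, rng):
        for _ in range(20):
            pred = GaussianBelief(rng.standard_normal(5), random_psd(rng, 5))
            spec = FilterSpec(R=0.3, H=[[0, 0, 1.0, 0, 0]], Q=np.zeros((5, 5)))
            post, _, _ = measurement_update(pred, rng.standard_normal(), spec)
            assert np.trace(post.cov) <= np.trace(pred.cov) + 1e-10

    def test_non_finite_measurement_rejected(self):
        pred = GaussianBelief([0.0], [[1.0]])
        with pytest.raises(ValueError):
            measurement_update(pred, np.nan, FilterSpec(H=[[1.0]], Q=[[0.0]]))


class TestTimeUpdate:
    @pytest.mark.parametrize("flavour", ["ukf", "cqkf"])
    def test_dirac_limit(self, flavour, normal_params, meal_schedule):
        """Zero covariance, zero Q: the prediction is the deterministic flow."""
        dyn = gf.GlucoseDynamics(normal_params, meal_schedule)
        x = gf.table_initial_state(normal_params)
        belief = GaussianBelief(x, np.zeros((12, 12)))
        spec = FilterSpec(flavour=flavour, Q=np.zeros((12, 12)), dt=1.0)
        pred = time_update(belief, spec, dyn, t=0.0)
        assert np.allclose(pred.mean, dyn.flow(x, 0.0, 1.0), atol=1e-12)
        assert np.allclose(pred.cov, 0.0, atol=1e-12)

    @pytest.mark.parametrize("flavour", ["ukf", "cqkf"])
    def test_linear_prediction_matches_closed_form(self, flavour, linear_system, rng):
        F, Q, H, R, dt = linear_system
        belief = GaussianBelief(rng.standard_normal(2), random_psd(rng, 2))
        spec = FilterSpec(flavour=flavour, Q=Q, R=R, H=H, dt=dt)
        pred = time_update(belief, spec, lambda pts, t, d: pts @ F.T, t=0.0)
        assert np.allclose(pred.mean, F @ belief.mean, rtol=1e-10, atol=1e-10)
        want = F @ belief.cov @ F.T + Q
        assert np.allclose(pred.cov, want, rtol=1e-9, atol=1e-9)

    def test_output_covariance_dominates_q(self, normal_params, meal_schedule, rng):
        dyn = gf.GlucoseDynamics(normal_params, meal_schedule)
        Q = np.diag([1.0] + [0.1] * 11)
        belief = GaussianBelief(gf.table_initial_state(normal_params),
                                np.diag(rng.uniform(0.01, 1.0, 12)))
        pred = time_update(belief, FilterSpec(Q=Q, dt=1.0), dyn, t=0.0)
        assert np.linalg.eigvalsh(pred.cov - Q).min() >= -1e-9


class TestPsdRepair:
    def test_indefinite_matrix_is_floored(self):
        m = np.diag([1.0, -0.5])
        low = _sqrt_psd(m)
        repaired = low @ low.T
        w = np.linalg.eigvalsh(repaired)
        assert w.min() >= 0.0
        assert repaired[0, 0] == pytest.approx(1.0)


class TestRunFilter:
    @pytest.mark.parametrize("flavour", ["ukf", "cqkf"])
    def test_linear_gaussian_matches_kalman_oracle(self, flavour, linear_system, rng):
        F, Q, H, R, dt = linear_system
        # simulate a linear-Gaussian truth and measurements
        n_steps = 40
        x = np.array([1.0, 0.0])
        ys = []
        Lq = np.linalg.cholesky(Q)
        for _ in range(n_steps):
            x = F @ x + Lq @ rng.standard_normal(2)
            ys.append(float((H @ x).item()) + np.sqrt(R) * rng.standard_normal())
        mean0, P0 = np.zeros(2), np.eye(2)
        spec = FilterSpec(flavour=flavour, Q=Q, R=R, H=H, dt=dt)
        res = gf.run_filter(ys, GaussianBelief(mean0, P0), spec,
                            lambda pts, t, d: pts @ F.T)
        want_m, want_p = kalman_recursion(F, Q, H, R, mean0, P0, ys)
        assert np.abs(res.means - want_m).max() < 1e-8
        assert np.abs(res.covariances - want_p).max() < 1e-8

    def test_ukf_and_cqkf_coincide_on_linear_system(self, linear_system, rng):
        F, Q, H, R, dt = linear_system
        ys = list(rng.standard_normal(25))
        beliefs = []
        for flavour in ("ukf", "cqkf"):
            spec = FilterSpec(flavour=flavour, Q=Q, R=R, H=H, dt=dt)
            beliefs.append(gf.run_filter(ys, GaussianBelief(np.zeros(2), np.eye(2)),
                                         spec, lambda pts, t, d: pts @ F.T))
        assert np.abs(beliefs[0].means - beliefs[1].means).max() < 1e-8

    def test_degenerate_zero_noise_tracks_truth(self, normal_params, meal_schedule):
        """Exact init, no noise: the filter output equals the truth."""
        dyn = gf.GlucoseDynamics(normal_params, meal_schedule)
        x0 = gf.table_initial_state(normal_params)
        traj = gf.simulate(x0, meal_schedule, normal_params, horizon=180, step=1)
        ys = traj.states[1:, 3]           # noise-free Gp measurements
        spec = FilterSpec(flavour="ukf", Q=np.zeros((12, 12)), R=16.0, dt=1.0)
        res = gf.run_filter(ys, GaussianBelief(x0, np.zeros((12, 12))), spec, dyn)
        assert np.abs(res.means[:, 3] - traj.states[1:, 3]).max() < 1e-3

    def test_measurement_gaps_give_prediction_only_steps(self, normal_params,
                                                         meal_schedule):
        dyn = gf.GlucoseDynamics(normal_params, meal_schedule)
        x0 = gf.table_initial_state(normal_params)
        ys = np.full(10, np.nan)
        ys[4] = x0[3]
        spec = FilterSpec(Q=np.diag([1.0] + [0.1] * 11), R=16.0, dt=1.0)
        res = gf.run_filter(ys, GaussianBelief(x0, np.eye(12)), spec, dyn)
        assert np.isnan(res.innovations[0]) and np.isfinite(res.innovations[4])
        assert np.isfinite(res.means).all()

    def test_export_schema(self, normal_params, meal_schedule, tmp_path):
        dyn = gf.GlucoseDynamics(normal_params, meal_schedule)
        x0 = gf.table_initial_state(normal_params)
        spec = FilterSpec(Q=np.diag([1.0] + [0.1] * 11), R=16.0, dt=1.0)
        res = gf.run_filter([x0[3]] * 3, GaussianBelief(x0, np.eye(12)), spec, dyn)
        df = res.to_frame()
        assert list(df.columns[:2]) == ["t_min", "Qsto1_mean"]
        assert "Gp_std" in df.columns and "innovation_variance" in df.columns
        out = tmp_path / "est.csv"
        res.to_csv(out)
        assert out.read_text().startswith("t_min,")
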
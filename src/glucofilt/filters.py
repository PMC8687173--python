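"""Gaussian assumed-density filtering with sigma-point quadrature.

Two point-set constructions realise a Gaussian belief N(mean, P):

* the unscented transform — 2n+1 points at the mean and along the columns
  of the square root of (n+kappa)P, with weights kappa/(n+kappa) and
  1/(2(n+kappa));
* the cubature-quadrature rule — 2n axis points on the unit hypersphere
  scaled by the square roots of 2*chi', where chi' are the roots of the
  order-n' generalised (Chebyshev-)Laguerre polynomial with alpha = n/2-1,
  giving 2*n*n' points with Gauss-Laguerre-derived weights.

Both are exact for the mean and covariance of any Gaussian; the filters
propagate the points through the nonlinear model dynamics (time update)
and apply the exact linear Kalman correction for the scalar plasma-glucose
measurement (measurement update).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, roots_genlaguerre

from . import _kernels
from .model import MealSchedule, DEFAULT_SUBSTEP
from .parameters import GP_INDEX, STATE_NAMES, ModelParameters

__all__ = [
    "GaussianBelief",
    "QuadraturePointSet",
    "FilterSpec",
    "unscented_points",
    "chebyshev_laguerre_nodes",
    "cubature_quadrature_points",
    "generate_points",
    "time_update",
    "measurement_update",
    "run_filter",
    "FilterResult",
    "GlucoseDynamics",
    "default_measurement_matrix",
]

#: Eigenvalue floor used when repairing an indefinite covariance.
EIG_FLOOR = 1e-10

#: Tolerance below which a negative covariance eigenvalue is considered a
#: rounding artefact and silently repaired.
PSD_TOL = 1e-9

Propagator = Callable[[np.ndarray, float, float], np.ndarray]


def default_measurement_matrix(n: int = 12) -> np.ndarray:
    """Selector of the measured state (plasma glucose mass Gp)."""
    h = np.zeros((1, n))
    h[0, GP_INDEX if n == 12 else 0] = 1.0
    return h


@dataclass
class GaussianBelief:
    """Mean and covariance of the filter's state estimate."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape must match the mean dimension")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def symmetrized(self) -> "GaussianBelief":
        return GaussianBelief(self.mean, 0.5 * (self.cov + self.cov.T))


def _repair_psd(cov: np.ndarray) -> np.ndarray:
    """Symmetrise and, if indefinite, floor the spectrum at zero/EIG_FLOOR.

    Beliefs keep eigenvalues >= -PSD_TOL; anything below is repaired here
    (the negative-weight unscented prediction is the usual source).
    """
    sym = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(sym)
        return sym
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sym)
        floored = np.where(w < -PSD_TOL, EIG_FLOOR, np.maximum(w, 0.0))
        repaired = (v * floored) @ v.T
        return 0.5 * (repaired + repaired.T)


def _sqrt_psd(matrix: np.ndarray) -> np.ndarray:
    """Matrix square root S with S S' = P, repairing indefinite input.

    The fast path is the lower-triangular Cholesky factor.  When that fails
    (singular or indefinite input — the negative central weight of the
    unscented transform legitimately produces such predicted covariances)
    the symmetric eigendecomposition is used with negative eigenvalues
    floored: exactly-zero directions keep exactly zero spread, genuinely
    negative ones are clamped to EIG_FLOOR.
    """
    sym = 0.5 * (matrix + matrix.T)
    try:
        return np.linalg.cholesky(sym)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(sym)
        if not np.all(np.isfinite(w)):  # pragma: no cover
            raise np.linalg.LinAlgError(
                "covariance square root failed: non-finite spectrum"
            ) from None
        floored = np.where(w < -PSD_TOL, EIG_FLOOR, np.maximum(w, 0.0))
        return v * np.sqrt(floored)


@dataclass
class QuadraturePointSet:
    """Deterministic points and weights realising a Gaussian density."""

    flavour: str               # "unscented" | "cubature_quadrature"
    points: np.ndarray         # (N, n)
    weights: np.ndarray        # (N,)

    def mean(self) -> np.ndarray:
        return self.weights @ self.points

    def covariance(self) -> np.ndarray:
        dev = self.points - self.mean()
        return (dev * self.weights[:, None]).T @ dev

    def __len__(self) -> int:
        return self.points.shape[0]


def unscented_points(belief: GaussianBelief, kappa: float) -> QuadraturePointSet:
    """The 2n+1 unscented sigma points of a Gaussian belief.

    The central point carries weight kappa/(n+kappa) — negative for the
    recommended kappa = 3-n when n > 3 — and the 2n symmetric points
    1/(2(n+kappa)) each.
    """
    n = belief.dim
    if n + kappa <= 0:
        raise ValueError("n + kappa must be positive")
    sqrt = _sqrt_psd((n + kappa) * belief.cov)
    points = np.empty((2 * n + 1, n))
    points[0] = belief.mean
    points[1:n + 1] = belief.mean + sqrt.T
    points[n + 1:] = belief.mean - sqrt.T
    weights = np.full(2 * n + 1, 1.0 / (2.0 * (n + kappa)))
    weights[0] = kappa / (n + kappa)
    return QuadraturePointSet("unscented", points, weights)


def chebyshev_laguerre_nodes(order: int, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Roots and weights of the order-n' generalised Laguerre polynomial.

    The nodes chi' are the strictly positive, increasing roots of
    L^alpha_{n'}; the weights are the generalised Gauss-Laguerre quadrature
    factors for the weight function chi^alpha * exp(-chi) on (0, inf), so
    they sum to Gamma(alpha+1).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if alpha <= -1:
        raise ValueError("alpha must exceed -1")
    nodes, weights = roots_genlaguerre(order, alpha)
    return nodes, weights


def cubature_quadrature_points(
    belief: GaussianBelief, order: int
) -> QuadraturePointSet:
    """Cubature-quadrature points of a Gaussian belief (2*n*n' points).

    Third-degree spherical cubature (the 2n unit-axis intersections
    +/- e_i) combined with an order-n' radial Gauss-Laguerre rule at
    alpha = n/2 - 1: standard-Gaussian points sqrt(2*chi'_i) * (+/- e_j),
    mapped through the Cholesky factor of the covariance.  Weights are the
    Laguerre factors normalised over the 2n axes; with n' = 1 the rule
    reduces to the classic third-degree cubature (equal weights 1/(2n),
    radius sqrt(n)).
    """
    n = belief.dim
    alpha = n / 2.0 - 1.0
    nodes, lag_w = chebyshev_laguerre_nodes(order, alpha)
    sqrt = _sqrt_psd(belief.cov)
    radii = np.sqrt(2.0 * nodes)                       # (n',)
    # weights: A_i / (2 n Gamma(n/2)); sum of A_i = Gamma(n/2) so total 1.
    w_radial = lag_w * np.exp(-gammaln(n / 2.0)) / (2.0 * n)
    points = np.empty((2 * n * order, n))
    weights = np.empty(2 * n * order)
    cols = sqrt.T                                      # rows = L columns
    for i, (r, w) in enumerate(zip(radii, w_radial)):
        block = slice(2 * n * i, 2 * n * (i + 1))
        points[block] = np.vstack(
            [belief.mean + r * cols, belief.mean - r * cols]
        )
        weights[block] = w
    weights /= weights.sum()
    return QuadraturePointSet("cubature_quadrature", points, weights)


@dataclass
class FilterSpec:
    """Configuration of one sigma-point filter."""

    flavour: str = "ukf"                    # "ukf" | "cqkf"
    kappa: float | None = None              # unscented scaling; default 3-n
    cq_order: int = 2                       # Gauss-Laguerre order n'
    Q: np.ndarray = None                    # (n, n) process-noise covariance
    R: float = 16.0                         # scalar measurement variance
    H: np.ndarray = None                    # (1, n) measurement matrix
    dt: float = 1.0                         # sampling interval, min

    def __post_init__(self) -> None:
        if self.flavour not in ("ukf", "cqkf"):
            raise ValueError("flavour must be 'ukf' or 'cqkf'")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.Q is not None:
            self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
            if not np.allclose(self.Q, self.Q.T):
                raise ValueError("Q must be symmetric")
            if np.linalg.eigvalsh(self.Q).min() < -PSD_TOL:
                raise ValueError("Q must be positive semidefinite")
        if self.H is not None:
            self.H = np.atleast_2d(np.asarray(self.H, dtype=float))

    def resolved(self, n: int) -> "FilterSpec":
        """Fill dimension-dependent defaults (kappa=3-n, Gp selector, Q=0)."""
        spec = FilterSpec(
            flavour=self.flavour,
            kappa=self.kappa if self.kappa is not None else 3.0 - n,
            cq_order=self.cq_order,
            Q=self.Q if self.Q is not None else np.zeros((n, n)),
            R=self.R,
            H=self.H if self.H is not None else default_measurement_matrix(n),
            dt=self.dt,
        )
        return spec


def generate_points(belief: GaussianBelief, spec: FilterSpec) -> QuadraturePointSet:
    if spec.flavour == "ukf":
        kappa = spec.kappa if spec.kappa is not None else 3.0 - belief.dim
        return unscented_points(belief, kappa)
    return cubature_quadrature_points(belief, spec.cq_order)


def time_update(
    belief: GaussianBelief,
    spec: FilterSpec,
    propagate: Propagator,
    t: float,
) -> GaussianBelief:
    """Predict the belief one sampling interval ahead.

    Each quadrature point is pushed through the deterministic flow of the
    dynamics over [t, t+dt]; the predicted moments are the weighted point
    statistics plus the additive discrete process noise Q.
    """
    spec = spec.resolved(belief.dim)
    pts = generate_points(belief, spec)
    propagated = propagate(pts.points, t, spec.dt)
    w = pts.weights
    mean = w @ propagated
    dev = propagated - mean
    cov = (dev * w[:, None]).T @ dev + spec.Q
    return GaussianBelief(mean, _repair_psd(cov))


def measurement_update(
    pred: GaussianBelief, y: float, spec: FilterSpec
) -> tuple[GaussianBelief, float, float]:
    """Exact linear Kalman correction for y = H x + v, v ~ N(0, R).

    Returns the posterior belief, the innovation y - H x, and the
    innovation variance H P H' + R.
    """
    if not np.isfinite(y):
        raise ValueError("measurement must be finite")
    spec = spec.resolved(pred.dim)
    h = spec.H
    ph = pred.cov @ h.T                       # (n, 1)
    s = float((h @ ph).item()) + spec.R
    gain = ph / s                             # (n, 1)
    innovation = float(y - (h @ pred.mean).item())
    mean = pred.mean + gain[:, 0] * innovation
    cov = pred.cov - gain @ ph.T
    return GaussianBelief(mean, _repair_psd(cov)), innovation, s


@dataclass
class FilterResult:
    """Posterior beliefs over the measurement sequence."""

    times: np.ndarray                      # (K,) posterior timestamps, min
    means: np.ndarray                      # (K, n)
    covariances: np.ndarray                # (K, n, n)
    innovations: np.ndarray                # (K,), NaN at prediction-only steps
    innovation_variances: np.ndarray       # (K,)

    @property
    def stds(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diagonal(self.covariances, axis1=1, axis2=2), 0.0))

    def to_frame(self) -> pd.DataFrame:
        n = self.means.shape[1]
        names = STATE_NAMES if n == 12 else tuple(f"x{i}" for i in range(n))
        df = pd.DataFrame({"t_min": self.times})
        for i, name in enumerate(names):
            df[f"{name}_mean"] = self.means[:, i]
        stds = self.stds
        for i, name in enumerate(names):
            df[f"{name}_std"] = stds[:, i]
        df["innovation"] = self.innovations
        df["innovation_variance"] = self.innovation_variances
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_filter(
    y_series: Sequence[float],
    x0_belief: GaussianBelief,
    spec: FilterSpec,
    propagate: Propagator,
    t0: float = 0.0,
) -> FilterResult:
    """Alternate time and measurement updates over a measurement series.

    ``y_series[k]`` is the measurement at t0 + (k+1)*dt; a NaN entry marks
    a gap and produces a prediction-only step.
    """
    y_series = np.asarray(y_series, dtype=float)
    n = x0_belief.dim
    spec = spec.resolved(n)
    n_steps = y_series.shape[0]
    means = np.empty((n_steps, n))
    covs = np.empty((n_steps, n, n))
    innovations = np.full(n_steps, np.nan)
    innovation_vars = np.full(n_steps, np.nan)

    belief = x0_belief
    for k in range(n_steps):
        t = t0 + k * spec.dt
        try:
            belief = time_update(belief, spec, propagate, t)
            if np.isfinite(y_series[k]):
                belief, innovations[k], innovation_vars[k] = measurement_update(
                    belief, y_series[k], spec
                )
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance repair failed at step {k}: {exc}"
            ) from exc
        means[k] = belief.mean
        covs[k] = belief.cov
    times = t0 + spec.dt * np.arange(1, n_steps + 1)
    return FilterResult(times, means, covs, innovations, innovation_vars)


class GlucoseDynamics:
    """Deterministic one-interval flow of the glucose-insulin model.

    Callable with signature ``(points, t, dt) -> propagated points`` as the
    filters expect; backed by the compiled RK4 kernel with substeps bounded
    by ``substep`` and the physiological nonnegativity clipping applied.
    """

    def __init__(
        self,
        params: ModelParameters,
        schedule: MealSchedule,
        substep: float = DEFAULT_SUBSTEP,
        clip: bool = True,
    ) -> None:
        self.params = params
        self.schedule = schedule
        self.substep = substep
        self.clip = clip
        self._p = _kernels.pack_params(params)
        self._sched = _kernels.pack_schedule(schedule)

    def __call__(self, points: np.ndarray, t: float, dt: float) -> np.ndarray:
        pts = np.array(points, dtype=np.float64, copy=True)
        single = pts.ndim == 1
        if single:
            pts = pts[None, :]
        n_sub = max(1, math.ceil(dt / self.substep - 1e-12))
        _kernels.rk4_propagate(
            pts, float(t), float(dt), n_sub, self._p, *self._sched, self.clip
        )
        return pts[0] if single else pts

    def flow(self, x: np.ndarray, t: float, dt: float) -> np.ndarray:
        """Propagate a single state vector."""
        return self(np.asarray(x, dtype=float), t, dt)
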
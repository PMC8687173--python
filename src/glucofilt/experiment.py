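"""Monte-Carlo state-estimation study on virtual patients.

Noisy truth trajectories are produced by the meal model with additive
discrete Gaussian process noise; a noisy plasma-glucose measurement stream
drives the UKF and/or CQKF; performance is summarised by the per-state,
per-time-step RMSE across Monte-Carlo repetitions.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .filters import (
    FilterResult,
    FilterSpec,
    GaussianBelief,
    GlucoseDynamics,
    _sqrt_psd,
    run_filter,
)
from .model import (
    DEFAULT_SUBSTEP,
    MealSchedule,
    standard_meal_schedule,
    table_initial_state,
)
from .parameters import (
    GP_INDEX,
    NONNEGATIVE_STATES,
    STATE_NAMES,
    ModelParameters,
)

__all__ = [
    "ExperimentConfig",
    "TruthTrajectory",
    "RmseSeries",
    "ComparisonReport",
    "default_process_noise",
    "default_initial_covariance",
    "generate_truth",
    "generate_measurements",
    "run_single_trial",
    "monte_carlo_rmse",
    "compare_filters",
    "BURN_IN_MIN",
]

#: Minutes discarded before summary statistics; the first hour covers the
#: initial transient of the filters.
BURN_IN_MIN = 60.0


def default_process_noise() -> np.ndarray:
    """Q = diag(1, 0.1 x 11): variance 1 on Qsto1, 0.1 on the rest."""
    return np.diag([1.0] + [0.1] * 11)


def default_initial_covariance() -> np.ndarray:
    """P0 diagonal: large on the unobserved meal states Qsto1 and Y."""
    return np.diag(
        [400.0**2, 0.1, 0.1, 0.1, 200.0**2, 0.3, 100.0, 10.0, 10.0, 30.0, 0.1, 0.5]
    )


@dataclass
class ExperimentConfig:
    """Full description of one estimation study."""

    cohort: str = "normal"
    schedule: MealSchedule = field(default_factory=standard_meal_schedule)
    horizon: float = 1440.0            # min
    dt: float = 1.0                    # sampling interval, min
    Q: np.ndarray = field(default_factory=default_process_noise)
    R: float = 16.0
    P0: np.ndarray = field(default_factory=default_initial_covariance)
    mc_runs: int = 50
    base_seed: int = 0
    flavours: tuple[str, ...] = ("ukf", "cqkf")
    kappa: float | None = None         # default 3 - n
    cq_order: int = 2
    init_mode: str = "random"          # "random": mean ~ N(table, P0); "mean"
    noisy_truth: bool = True
    substep: float = DEFAULT_SUBSTEP
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
        if self.Q.shape != (12, 12):
            raise ValueError("Q must be 12x12")
        if self.P0.shape != (12, 12):
            raise ValueError("P0 must be 12x12")
        if self.mc_runs < 1:
            raise ValueError("mc_runs must be >= 1")
        if self.init_mode not in ("random", "mean"):
            raise ValueError("init_mode must be 'random' or 'mean'")
        for fl in self.flavours:
            if fl not in ("ukf", "cqkf"):
                raise ValueError(f"unknown filter flavour {fl!r}")

    @property
    def params(self) -> ModelParameters:
        return ModelParameters.from_profile(self.cohort, **self.param_overrides)

    @property
    def n_steps(self) -> int:
        n = round(self.horizon / self.dt)
        if abs(n * self.dt - self.horizon) > 1e-9:
            raise ValueError("dt must divide horizon")
        return n

    def filter_spec(self, flavour: str) -> FilterSpec:
        return FilterSpec(
            flavour=flavour, kappa=self.kappa, cq_order=self.cq_order,
            Q=self.Q, R=self.R, dt=self.dt,
        )


@dataclass
class TruthTrajectory:
    """Realised (possibly noise-driven) truth states on the sampling grid."""

    times: np.ndarray            # (K+1,)
    states: np.ndarray           # (K+1, 12)
    perturbations: np.ndarray    # (K, 12) process-noise draws (pre-clipping)
    seed: int | None = None

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]


def _rng_streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent generators for process noise, measurements, filter init."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def generate_truth(
    config: ExperimentConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TruthTrajectory:
    """Simulate the truth: RK4 flow per step plus additive N(0, Q) noise.

    Mass states are clipped at zero after the noise is added.  Fully
    reproducible from the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    params = config.params
    dyn = GlucoseDynamics(params, config.schedule, substep=config.substep)
    n_steps = config.n_steps
    noise_sqrt = _sqrt_psd(config.Q) if config.noisy_truth and config.Q.any() else None

    x = table_initial_state(params)
    states = np.empty((n_steps + 1, 12))
    perturbations = np.zeros((n_steps, 12))
    states[0] = x
    nonneg = list(NONNEGATIVE_STATES)
    for k in range(n_steps):
        x = dyn.flow(x, k * config.dt, config.dt)
        if noise_sqrt is not None:
            w = noise_sqrt @ rng.standard_normal(12)
            perturbations[k] = w
            x = x + w
            x[nonneg] = np.maximum(x[nonneg], 0.0)
        states[k + 1] = x
    times = np.arange(n_steps + 1) * config.dt
    return TruthTrajectory(times, states, perturbations, seed=seed)


def generate_measurements(
    truth: TruthTrajectory,
    R: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy plasma-glucose measurements y_k = Gp_k + v_k, k = 1..K."""
    if R < 0:
        raise ValueError("R must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(seed)
    gp = truth.states[1:, GP_INDEX]
    return gp + np.sqrt(R) * rng.standard_normal(gp.shape[0])


@dataclass
class TrialResult:
    """One truth/measurement realisation and its filtered estimate."""

    truth: TruthTrajectory
    measurements: np.ndarray
    estimate: FilterResult
    squared_errors: np.ndarray    # (K, 12)
    flavour: str
    seed: int


def run_single_trial(
    config: ExperimentConfig, flavour: str, seed: int
) -> TrialResult:
    """Generate truth and measurements, run one filter, record errors.

    The three noise sources (process, measurement, filter initialisation)
    draw from independent sub-streams of ``seed``, so trials with the same
    seed share the identical truth and measurements across filter flavours.
    """
    proc_rng, meas_rng, init_rng = _rng_streams(seed)
    params = config.params
    truth = generate_truth(config, seed=seed, rng=proc_rng)
    y = generate_measurements(truth, config.R, rng=meas_rng)

    mean0 = table_initial_state(params)
    if config.init_mode == "random":
        mean0 = mean0 + _sqrt_psd(config.P0) @ init_rng.standard_normal(12)
    belief0 = GaussianBelief(mean0, config.P0.copy())

    dyn = GlucoseDynamics(params, config.schedule, substep=config.substep)
    estimate = run_filter(y, belief0, config.filter_spec(flavour), dyn, t0=0.0)
    err = truth.states[1:] - estimate.means
    return TrialResult(truth, y, estimate, err**2, flavour, seed)


@dataclass
class RmseSeries:
    """Per-state RMSE over time, across M Monte-Carlo runs."""

    times: np.ndarray          # (K,)
    values: np.ndarray         # (K, 12)
    mc_runs: int
    flavour: str

    def state(self, name: str) -> np.ndarray:
        return self.values[:, STATE_NAMES.index(name)]

    def post_burn_in_mean(self, burn_in: float = BURN_IN_MIN) -> np.ndarray:
        """Time-averaged RMSE per state after the burn-in window.

        Falls back to the whole series when the horizon is shorter than
        the burn-in.
        """
        mask = self.times > burn_in
        if not mask.any():
            mask = np.ones_like(mask)
        return self.values[mask].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"{s}_rmse_{self.flavour}" for s in STATE_NAMES]
        )
        df.insert(0, "t_min", self.times)
        return df


def monte_carlo_rmse(config: ExperimentConfig, flavour: str) -> RmseSeries:
    """RMSE_k = sqrt(mean_j (x_jk - xhat_jk)^2) over mc_runs trials.

    Trial j uses seed base_seed + j.
    """
    total = None
    for j in range(config.mc_runs):
        seed = config.base_seed + j
        try:
            trial = run_single_trial(config, flavour, seed)
        except Exception as exc:
            raise RuntimeError(f"trial with seed {seed} failed: {exc}") from exc
        total = trial.squared_errors if total is None else total + trial.squared_errors
    rmse = np.sqrt(total / config.mc_runs)
    times = config.dt * np.arange(1, config.n_steps + 1)
    return RmseSeries(times, rmse, config.mc_runs, flavour)


@dataclass
class ComparisonReport:
    """UKF-vs-CQKF Monte-Carlo comparison."""

    rmse: dict[str, RmseSeries]
    post_burn_in: dict[str, np.ndarray]          # per-state time averages
    wall_clock_s: dict[str, float]
    wall_clock_ratio: float                      # cqkf / ukf (informational)
    config: ExperimentConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        frames = [series.to_frame().set_index("t_min")
                  for series in self.rmse.values()]
        return pd.concat(frames, axis=1).reset_index()

    def summary_frame(self) -> pd.DataFrame:
        rows = {fl: vals for fl, vals in self.post_burn_in.items()}
        df = pd.DataFrame(rows, index=list(STATE_NAMES))
        df.index.name = "state"
        return df


def compare_filters(config: ExperimentConfig) -> ComparisonReport:
    """Run the Monte-Carlo study for every configured filter flavour.

    The relative wall-clock time is reported for information only; it is
    hardware- and implementation-dependent.
    """
    rmse: dict[str, RmseSeries] = {}
    clocks: dict[str, float] = {}
    for flavour in config.flavours:
        start = _time.perf_counter()
        rmse[flavour] = monte_carlo_rmse(config, flavour)
        clocks[flavour] = _time.perf_counter() - start
    post = {fl: series.post_burn_in_mean() for fl, series in rmse.items()}
    if "ukf" in clocks and "cqkf" in clocks and clocks["ukf"] > 0:
        ratio = clocks["cqkf"] / clocks["ukf"]
    else:
        ratio = float("nan")
    return ComparisonReport(rmse, post, clocks, ratio, config)
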
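# Methods notes

## Model

The simulator is a 12-state compartmental model of oral glucose intake and
insulin response of the meal-simulation (UVA/Padova-type) lineage. Glucose ingested as a
solid enters the stomach (`Qsto1`), is ground into liquid chyme (`Qsto2`)
at rate `kgri`, empties into the gut (`Qgut`) at the state-dependent rate
`kempt(Qsto)` and appears in plasma at `Ra = f·kabs·Qgut/BW`. Plasma and
tissue glucose (`Gp`, `Gt`, mg/kg) exchange at `k1`, `k2`; the liver adds
`EGP`, the brain and erythrocytes remove the constant `Uii = Fcns`, muscle
and fat remove the Michaelis–Menten `Uid` accelerated by the remote
insulin action `X`, and the kidney removes `E` above the renal threshold.
The insulin side runs from beta-cell provision `Y` and portal release
`Spo` through portal-vein, liver and plasma insulin (`Ipo`, `Il`, `Ip`,
pmol/kg) with hepatic extraction `HE = m6 − m5·S`, plus the two-stage
delayed signal `I1 → Id` that suppresses `EGP`.

Assumptions inherited from the model class: a single well-mixed
compartment per pool, linear insulin kinetics apart from the
extraction/secretion couplings, additive meal input, and parameters
constant over the simulated day.

### Choices where the published description is incomplete or ambiguous

* **Meal input.** The dose is modelled as a finite rate into `Qsto1` over
  a window of length `D/rate` (37 g at 3.7 g/min → 10 min), not as an
  impulse. This matches the stated ingestion rate and keeps the input in
  the span of ordinary ODE forcing.
* **`kempt` before the first meal.** The shape parameters α, β divide by
  the dose `D`; with no meal yet ingested the empty-stomach limit `kmax`
  is used, and between meals `D` is the most recent dose.
* **`Uid` numerator.** `Gt` (mg/kg) is used in the numerator, consistent
  dimensionally with `Km0` (mg/kg) and with the source model; at the
  half-saturation point `Uid(Km0, 0) = Vm0/2`.
* **`Y` dynamics.** First-order beta-cell responsivity
  `Ẏ = −A·[Y − B·(G − h)]` with the target floored at `−Sb` and `h = Gb`,
  using the tabulated secretion block (`A`, `B`, `K`, `γ`).
* **Units.** `Gp`, `Gt` in mg/kg and `Ip`, `Il`, `Ipo` in pmol/kg; the
  tabulated initial values listed as concentrations (`Gp` in mg/dl, `Ip`
  in pmol/l) are converted through `VG` and `VI`. The renal threshold
  `ke2` (339/269) is compared against `Gp` in mg/kg. The measurement and
  `R = 16` are in the units of the `Gp` state.
* **Clamps.** `EGP`, `Uid`, `Spo` are floored at 0; `HE` is clipped to
  [0.01, 0.9] to guard the `m3` pole; mass states are clipped at 0 after
  every integration substep (only `Y` and `X` may go negative, and the
  `X` drive uses `max(I − Ib, 0)` so `X` stays nonnegative from a basal
  start).

### Basal state

The tabulated overnight-fasted initial values are not an exact fixed point
of the equations: the portal-insulin entry (6.04 / 6.38 pmol/kg) is
inconsistent with the secretion steady state `Ipo = Sb/γ` (3.10 / 8.05),
while the EGP calibration requires the tabulated value. Simulations and
filters therefore initialise from the tabulated state exactly
(`table_initial_state`), and a second constructor
(`consistent_basal_state`) solves the insulin chain for its steady state
(`Ipo = Sb/γ`, `Il = Sb/(m1+m3b − m1·m2/(m2+m4))`, `Ip` from the plasma
balance, `Gt` from the tissue balance by bisection) for model-consistency
checks. At that point all twelve derivatives vanish within 1% of the
basal scale except a small residual on `Ipo` equal to the `K·Ġ` secretion
coupling driven by the rounded glucose-side parameters; a fasting day
simulated from either start stays within ±5% of the basal glycaemia for
both cohorts.

## Integration

Fixed-step classical RK4 with substeps of at most 0.1 min (default), an
order of magnitude below the fastest time constants (`γ = 0.5/min`,
`m2 ≈ 0.5–0.7/min`). Switches in the right-hand side (the `Ġ > 0`
secretion branch, the renal threshold, the `Y` floor) are evaluated
pointwise; they are bounded discontinuities of the derivative only. The
piecewise-constant meal rate and the active dose are looked up once per
substep at the substep midpoint so that Runge–Kutta stages landing exactly
on a meal on/off boundary all see the rate holding inside the substep;
meal boundaries then align with the substep grid and the ingested mass is
integrated exactly (the gut mass balance closes to ~1e-15 relative). The
time-integral of `Ra` is carried as an augmented quadrature state using
the same RK4 stages, so mass-balance checks share the integrator's
accuracy.

Accuracy: against an adaptive DOP853 reference (rtol 1e-11, integrated
piecewise between meal boundaries) the 24-h trajectories agree to better
than 1e-4 relative. Self-convergence under substep halving is limited to
~1e-5–1e-4 near meal onsets, where the lower tanh transition of `kempt`
(width `c·D/2.5` ≈ 150 mg, traversed in a few hundredths of a minute at
3.7 g/min) is marginally resolved at 0.1 min; away from meals halving
changes the solution by < 1e-5 relative. The filtering study is
insensitive to this: the residual integration error is orders of
magnitude below the process noise.

A numba-compiled kernel (`_kernels.py`) evaluates the identical RHS and
RK4 over batches of sigma points; a test asserts bitwise agreement with
the pure-numpy reference implementation across a meal boundary.

## Filters

Both filters are Gaussian assumed-density filters differing only in how
the predictive moments are formed.

* **Unscented points**: `ξ0 = x̂`, `ξi = x̂ ± (√((n+κ)P))_i` with the
  lower Cholesky factor, `W0 = κ/(n+κ)`, `Wi = 1/(2(n+κ))`; default
  `κ = 3−n = −9`, exposed in the configuration.
* **Cubature-quadrature points**: radial nodes are the roots χ′ of the
  generalised Laguerre polynomial `L^α_{n′}` with `α = n/2−1`, obtained
  by the Golub–Welsch eigenvalue method (`scipy.special.roots_genlaguerre`,
  equivalent to the displayed Chebyshev–Laguerre recurrence — for
  `n′ = 2, α = 5` the monic polynomial is χ²−14χ+42 with roots 7±√7).
  Points are `√(2χ′_i)·(±e_j)` mapped through the Cholesky factor; the
  printed weight expression is typographically ambiguous, so weights are
  taken from the Gauss–Laguerre factors and normalised to sum to one,
  which is verified against the Gaussian moment identities (exact mean
  and covariance; exact fourth radial moment `n(n+2)` at `n′ = 2`). With
  `n′ = 1` the rule collapses to the classic third-degree cubature rule
  (radius √n, equal weights `1/2n`).
* **Time update**: each point is propagated through the deterministic
  flow over one sampling interval; the predicted covariance is the
  weighted scatter plus the discrete additive `Q` (truth generation uses
  the identical discretisation: exact flow per minute plus one `N(0, Q)`
  draw).
* **Measurement update**: the measurement model is linear
  (`H` selects `Gp`), so the exact linear Kalman correction is applied
  rather than a sigma-point transform of the measurement — for linear `H`
  the two coincide and this removes one approximation layer.
* **PSD repair**: with `W0 = −3` the predicted covariance can become
  indefinite (eigenvalues down to ≈ −0.16 are observed in the T2DM
  study). Beliefs are repaired at both updates by flooring genuinely
  negative eigenvalues at 1e-10 (exactly-zero directions keep zero
  spread, preserving the degenerate Dirac limit); covariances are
  symmetrised throughout.

## The study and the synthetic-data generator

The default configuration reproduces the benchmark study: 24 h at 1-min
sampling starting at 6 AM, meals of 37/74/74 g at 8 AM / 1 PM / 10 PM at
3.7 g/min, process noise `Q = diag(1, 0.1×11)` (variance 1 on `Qsto1`),
sensor noise `R = 16`, initial covariance
`P0 = diag(400², 0.1, 0.1, 0.1, 200², 0.3, 100, 10, 10, 30, 0.1, 0.5)`,
filters initialised from a Gaussian with the tabulated fasted means and
`P0` (a deterministic mean-start mode exists for tests), M = 50
Monte-Carlo runs. Trial j uses seed `base_seed + j`, split into three
independent sub-streams (process noise, sensor noise, filter
initialisation), so the same seed yields the identical truth and
measurements for both filters. The burn-in window for summary statistics
is 60 min; filter-comparison summaries report the time-averaged post-
burn-in RMSE per state, and the relative wall-clock time of the two
filters is reported but never asserted (hardware-dependent).

What the generator emulates: between-patient variability (additive
process noise on the dynamics), sensor error (white Gaussian), and the
two cohort parameterisations. What it does not emulate: real CGM artefacts
(drift, calibration error, correlated noise, dropouts), intra-day
parameter variation, exercise or stress effects, and model mismatch
between the truth and the filter — truth and filter share the same
equations, so passing tests demonstrate estimator correctness and
benchmark reproducibility on the virtual patient, not clinical accuracy
on real sensor data.

Problem sizes used by the test suite: the full study (both cohorts, both
filters, M = 50, 1 440 steps) runs in the acceptance tests; unit and
property tests use 1–2 h horizons and low-dimensional analytic systems
(the linear-Gaussian oracle is an independently coded textbook Kalman
recursion).

## Known limitations

* The published parameter tables are internally inconsistent at basal
  (see above); the package preserves the tables and documents the
  residual rather than re-fitting parameters.
* `Q` and `P0` mix units across states, as specified for the study; they
  are configuration values, not estimates.
* No smoothing, square-root filter variants, higher-degree spherical
  rules, exogenous insulin dosing or closed-loop control; the type-1
  variant (removing endogenous secretion) is not provided.
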
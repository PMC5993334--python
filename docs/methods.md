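# Methods

This note records the models implemented in `ratecal`, the parameters that
matter, the design choices made where the design was genuinely open, and what
the simulation-based tests do and do not establish.

## Encoding models and adaptive filters

Two observation families encode a 2-D intended velocity `v_t` through the
augmented regressor `ṽ_t = [1, v_t']'`:

* **Continuous channels** (LFP/ECoG band log-power): `y_t = ψ'ṽ_t + z_t`,
  `z_t ~ N(0, Z)`, with `ψ = [ξ, η_x, η_y]` (baseline, tuning coefficients).
  Ensembles draw `ξ ~ U[1,6]` dB, modulation depth `‖η‖ ~ U[7,10]`, preferred
  direction `~ U[0,2π)`, `Z ~ U[320,380]` dB², 30 channels by default.
* **Spiking neurons**: binary spike indicators per bin of width `Δ` with
  log-linear intensity `λ(v) = exp(β + α'v)`, equivalently cosine tuning
  `exp(β + ‖α‖‖v‖cos(θ_v − θ_pd))`. Ensembles draw baseline rate `U[4,10]` Hz
  and maximum rate `U[40,80]` Hz; `‖α‖ = ln(max/base)/v_max`, with `v_max` the
  peak speed of a noiseless reach of the configured task (the speed at which
  the maximum rate is attained is a modelling convention — the rate ranges
  alone do not determine it).

Both adaptive filters place the random-walk prior `rate · I` on the (fixed but
unknown) parameters and assimilate one observation per bin; channels are
conditionally independent, so each runs a 3-dimensional filter. Covariance
updates use the rank-one Sherman–Morrison form of the information update with
explicit re-symmetrization each step; the test suite verifies equality with
the explicit information-form solve to 1e-8 and SPD preservation over long
sessions. Conditional intensities cap the log-rate exponent at 50 to survive
transiently bad estimates.

**Bin widths.** Continuous features use `Δ = 0.1 s` (a typical power-feature
update interval). Spikes use the field-standard `Δ = 1 ms`. The 1-ms choice is
load-bearing: the point-process likelihood treats the innovation variance as
`λΔ`, while binary spikes have variance `λΔ(1 − λΔ)`. At 1 ms the worst case
`λ_maxΔ ≤ 0.08` keeps the approximation inside a few percent; at 5-ms bins
(`λ_maxΔ` up to 0.4) the measured steady-state error covariance sits ~20 %
below the analytic prediction at every rate — a bin-width artefact, not a
property of the calibration theory.

**Concurrent noise estimation.** When `Z` is unknown the filter estimates it
by covariance matching over a sliding window of `L` innovations (default
`L = 200`, a compromise between estimator variance ~`√(2/L)` ≈ 10 % and
responsiveness), applied right after the prediction step and floored at
`1e-6 ×` the initial guess.

## Calibration engine

`H_ave` (or `M_ave`) is computed from any realized session — periodicity is
not required, only the average. Eigenvalues below `1e-12 ×` the largest raise
a rank-deficiency error rather than extrapolating (e.g. a constant-velocity
session cannot calibrate tuning coefficients). `κ` is evaluated in the
rationalized form `2s/(√(h²s²+4hs) + hs)`, immune to cancellation at large
`h·s`; the two printed algebraic forms of the covariance eigenvalues and of
the time-bound inverse map are asserted equal to 1e-10 in tests. For spikes
with unknown true parameters, calibration evaluates the flat-intensity
information at the known firing-rate extremes and takes the conservative rate
(minimum for the error-bound objective, maximum for the time bound); this is
valid because `h₁` is monotone in the nuisance and each inverse map is
monotone in `h₁`.

## Subject model and task

The simulated subject follows discrete linear kinematics (position integrates
velocity; velocity persists with `α = exp(−Δ/τ)`, `τ = 0.2 s`; control and
white noise enter the velocity rows) and picks `u_t = −L(x_t − x*)` with `L`
the infinite-horizon LQR gain for cost `‖d−d*‖² + w_v‖v‖² + w_r‖u‖²`.
The task constants not determined by the task geometry were frozen once:
`w_v = 0.06`, `w_r = 0.012`, chosen so a noiseless 0.3-radius reach covers
95 % of the distance in ≈ 0.75–0.9 s at both shipped bin widths (so
out-and-back fits the 2-s trial); process-noise SD set so speed jitter is
≈ 5 % of the peak reach speed per velocity time constant. All are
configurable, and the acceptance tests re-run reduced sweeps under ±50 %
changes to `τ`, `W`, `w_v`, `w_r` to show the analytic-empirical agreement is
not a property of one tuned subject model.

A session is `n_trials` fixed-duration trials: out-reach to a peripheral
target for the first half, return to center for the second; targets in
counter-clockwise order or i.i.d. uniform.

**Closed loop.** In closed-loop simulations the subject acts on the *decoded*
cursor state; neural activity encodes the intended velocity; adaptation (when
enabled) consumes the intended velocity as the supervised encoded state. Two
practical elements make the loop well-posed:

* the kinematic decoder's prior velocity noise is *fitted to the realized
  kinematics* (SD of `v_{t+1} − αv_t`), because the decoder does not observe
  the control input; using the subject's raw process noise makes the decoder
  an order of magnitude too sluggish and reaches never complete;
* the intended speed is capped at 2× the peak reach speed — a physiological
  bound that keeps an unstable decoder loop (random parameters, oversized
  learning rates) from diverging exponentially while leaving normal operation
  untouched.

Decoders couple observations to the velocity components only (the encoding
models depend on velocity alone); position is obtained by integrating decoded
velocity inside the prediction step.

## Monte-Carlo validation design

The harness compares, per learning rate, the analytic predictions against
simulation:

* **Steady-state covariance**: per-channel sample covariance of the error
  over the final third of the session, averaged over channels and replicates
  in the parameter basis; compared through the spectral norm of the averaged
  matrix. Sessions run for ~6 predicted convergence times so the window is
  comfortably stationary.
* **Convergence time**: the expected error `E[g_t]` is estimated by averaging
  error *vectors* over replicates that share the truth and the initial
  estimates but not the noise; per-channel norms are normalized by the
  initial error and averaged over channels; the convergence time is the first
  5 %-crossing sustained for 10 recorded steps (the dwell suppresses
  noise-induced early crossings). The replicate count per rate follows a
  noise-floor rule (enough replicates that the steady-state floor of this
  estimator is ≲ 0.02, well under the 0.05 threshold), so cheap small-rate
  runs use 2 replicates and the largest rates tens.
* **Initial filter covariance**: sweep, coverage and decode-freeze
  experiments start the filter at its steady-state posterior covariance
  `U diag(κ_m) U'` for the rate under test. The analytic error dynamics
  describe the filter *after* its covariance has settled; starting from an
  arbitrary fixed covariance superimposes an RLS-like transient (fast early
  learning when `S₀ ≫ κ`, a sluggish start when `S₀ < κ`) that biases the
  measured crossing time by tens of percent with a sign that flips across the
  rate grid. The library filters themselves default to `diag(1)` (KF) /
  `diag(1e-2)` (PPF) for general use, where no particular rate is privileged.
* **Common random numbers**: all rates in a sweep share the session
  kinematics and the per-replicate noise seeds, reducing curve-to-curve
  Monte-Carlo variance.
* **Coverage**: fraction of steady-state (step, parameter) pairs within ±2
  analytic SDs, pooled over channels and rates.
* **Decode-freeze**: closed-loop adaptation snapshotted at increasing stop
  times; each snapshot decoder runs frozen on an evaluation block and is
  scored by the RMS perpendicular distance of the decoded position to the
  center-target line. The "very large" comparison rate is derived from the
  theory (the rate whose predicted error SD is 1.5× the mean modulation
  depth) so that "too large" is defined relative to the task's information
  scale rather than by an absolute number.

Default grids: 8 log-spaced rates over `5e-6 … 5e-4` (KF) and `1e-7 … 1e-4`
(PPF) — two to three decades bracketing each filter's calibrated operating
point, sized so every grid point's convergence is measurable within the
session budget on one CPU.

## Known limitations

* The analytic maps use the *time-averaged* information. For spikes the
  per-bin information `λ_tΔ ṽṽ'` swings over an order of magnitude within a
  trial, and at the large-rate end of the grid (where the filter's memory is
  short) the empirical covariance runs ~10–15 % below the prediction; the
  agreement is a few percent near the calibrated operating rates.
* The channel-averaged error-norm crossing is dominated by the least
  informative channels, so measured convergence times for heterogeneous
  spiking ensembles vary severalfold with the ensemble draw, while the
  analytic summary averages per-channel predictions. For the continuous
  ensembles (noise range only ±8 %) this effect is negligible.
* The generator emulates stationary, conditionally independent channels with
  exactly cosine-tuned mean responses and a single fixed OFC strategy. Real
  recordings drift, correlate across channels, and violate the tuning model;
  passing tests show the calibration theory predicts the behaviour of the
  matched filters under their own model class, not robustness to model
  mismatch beyond the noise-range and day-shift scenarios exercised here.
* No smoothing, no history/refractory terms in the point process, no
  adaptive rate scheduling within a session: the rate is fixed per run, which
  is exactly the regime the calibration targets.
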
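# ratecal

Analytic learning-rate calibration for adaptive Bayesian estimation of neural
encoding models, with a closed-loop brain–machine-interface (BMI) simulation
harness to validate the predictions by Monte Carlo.

## The problem

Closed-loop neurotechnologies (motor BMIs, adaptive DBS) must learn, online,
an *encoding model* relating neural activity to a brain state such as intended
cursor velocity. A standard approach places a random-walk prior
`ψ_t = ψ_{t−1} + s_t`, `Cov[s_t] = s·I`, on the unknown parameters and runs a
recursive Bayesian filter — a Kalman filter (KF) for continuous features such
as LFP/ECoG band log-powers, `y_t = ψ'ṽ_t + z_t` with `ṽ_t = [1, v_t']'` and
noise variance `Z`; or a point-process filter (PPF) for binary spike trains
with log-linear conditional intensity `λ(v) = exp(β + α'v)` in bins of width
`Δ`. The prior variance `s` (or `r` for spikes) is the **learning rate**: it
trades steady-state parameter error against convergence time, and it is
usually tuned by hand.

`ratecal` implements closed-form maps that make this trade-off explicit.
With the time-averaged regressor information

    H_ave = (1/T) Σ_t ṽ_t ṽ_t' / Z   =  U diag(h_1 … h_n) U',   h_1 ≤ … ≤ h_n
    (spikes: M_ave = (1/T) Σ_t ṽ_t ṽ_t' λ_t* Δ, same form)

and `κ_m = (√(h_m²s² + 4h_m s) − h_m s)/(2h_m)`, the steady-state error
covariance and the per-step decay factor of the expected error are

    S₊* = U diag( 1/√(h_m² + 4h_m/s) ) U'      (increasing in s)
    ρ   = κ_1/(κ_1 + s)                         (decreasing in s)

The inverse maps select the optimal rate for either objective:

    s = 4h₁ / (1/V_bd² − h₁²)                   bound ‖S₊*‖ ≤ V_bd, fastest convergence
    s = (1 − ρ)²/(h₁ρ),  ρ = E_rest^(Δ/C_bd)    bound the convergence time ≤ C_bd

plus conservative selection when the noise variance (or firing-rate scale) is
only known as a range, and concurrent covariance-matching estimation of `Z`.

The package also ships the full validation environment: an LQG
optimal-feedback-control model of the subject performing a 2-D
center-out-and-back cursor task (8 targets, radius 0.3, 2-s trials), ensembles
of simulated Gaussian channels and spiking neurons, velocity decoders for
closed-loop operation, and a Monte-Carlo harness that measures empirical
steady-state covariance, convergence time, confidence-bound coverage and
closed-loop decoding error against the analytic predictions.

## Worked example

Calibrate the KF learning rate for a periodic center-out training session,
requiring the steady-state error-covariance norm to stay below 0.4 dB² while
only knowing the noise variance lies in [320, 380] dB²:

```python
import numpy as np
from ratecal import LearningRateCalibrator
from ratecal.ofc import TaskConfig, default_cost, default_dynamics, generate_session

kin = generate_session(TaskConfig(n_trials=64), default_dynamics(0.1),
                       default_cost(), np.random.default_rng(0))
cal = LearningRateCalibrator(kind="gaussian", Z=(320.0, 380.0), delta=0.1,
                             v_bd=0.4).fit(kin.velocities)
res = cal.result_
print(res.learning_rate)                 # 0.00013657786189967634
print(np.diag(res.predicted_cov))        # [0.10931863 0.38190041 0.38364367]
print(res.predicted_convergence_time)    # 1684.0496891998857  (seconds)
```

The selected rate is `s ≈ 1.37e-4` (the conservative choice over the noise
range); at that rate the predicted steady-state error variances are ≈ 0.11 dB²
for the baseline and ≈ 0.38 dB² for each tuning coefficient (norm exactly at
the 0.4 bound), and the expected parameter error is predicted to fall to 5 %
of its initial value after ≈ 1680 s of adaptation. Asking instead for
convergence within 600 s (`c_bd=600.0`) returns the larger rate
`s ≈ 1.17e-3` with predicted convergence in ≈ 576 s — the two inverse maps
bracket the admissible interval for joint requirements.

The same interface runs from a shell:

```bash
ratecal calibrate --z 320 --z 380 --error-bound 0.4 --trials 64 --seed 0
ratecal sweep --preset kf_periodic --seed 1 --out sweep/
ratecal decode-freeze --preset kf_periodic --seed 1 --out df/
```

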
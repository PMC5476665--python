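# swayabc

Simulation of human body sway as an intermittently controlled
inverted pendulum, and likelihood-free Bayesian inference of the
physiological control parameters from posturographic signals.

## The problem

Quiet upright stance is unstable: the body behaves like a single-link
inverted pendulum pivoting at the ankle, continuously perturbed by
internal noise. It is stabilised by two controllers — instantaneous
passive muscle tone (stiffness `K`, damping `B`) and a delayed,
*intermittent* active PD controller mediated by the CNS (stiffness
`P`, damping `D`, delay `Δ`), which engages only in a sector of the
(θ, θ̇) phase plane whose area fraction is the level of control
`C_ON`. The resulting stochastic delay differential equation

    I θ̈ = mgh·θ − [K θ + B θ̇ + P θ(t−Δ)·𝟙_ON + D θ̇(t−Δ)·𝟙_ON] + σ ξ(t)

produces center-of-mass (COM) sway, `COM = h sin θ`. The five
subject-specific parameters (P, D, Δ, σ, C_ON) are physiologically
interpretable biomarkers, but the model's likelihood is intractable,
so they are inferred by sequential Monte Carlo approximate Bayesian
computation (SMC-ABC): candidate parameters are accepted when the
discrepancy

    ρ = (1/60) Σ |Φ_obs − Φ_sim| / |Φ_obs + Φ_sim|

between 60-element summary vectors (amplitude/velocity/acceleration
histograms + power spectrum of the COM signal) falls below an
adaptively tightening threshold.

The package is aimed at posturography and motor-control researchers:
it simulates sway, converts measured center-of-pressure (COP) to COM,
infers control parameters per subject, computes the standard linear
and nonlinear sway measures (MD, MV, MA, MF, fuzzy sample entropy,
DFA α, correlation dimension D₂, largest Lyapunov exponent λ_max),
and runs parameter-recovery and sensitivity studies on synthetic
cohorts. See `docs/methods.md` for the full model and the numerical
choices.

## Worked example

```python
import numpy as np
from swayabc import ControlParams, PendulumPlant, simulate_sway, infer_params

# a subject: 80 kg, COM height 0.78 m, known control parameters
plant = PendulumPlant(m=80.0, h=0.78)
truth = ControlParams(P=128.0, D=37.0, delta=0.16, sigma=0.16, c_on=0.75)

# three simulated 60-s "measurement" trials at 50 Hz
trials = simulate_sway(plant, truth, duration=60.0, seed=42, n_trials=3)

# likelihood-free inference (reduced budget: 500 particles, 4 iterations)
pops, posterior = infer_params(trials, plant, n_particles=500,
                               n_iterations=4, seed=7)
for name, mean, (lo, hi) in zip(posterior.names, posterior.mean,
                                posterior.ci95):
    print(f"{name:>6}: {mean:8.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
```

Output (exact numbers depend on the seeds):

```
     P:  131.628  95% CI [122.466, 146.714]
     D:   30.038  95% CI [2.442, 48.907]
 delta:    0.157  95% CI [0.058, 0.314]
 sigma:    0.169  95% CI [0.116, 0.235]
  c_on:    0.779  95% CI [0.568, 0.988]
```

The posterior mean of the active stiffness P (132 Nm/rad) lands
within a few percent of the true 128; Δ, σ and C_ON are likewise
recovered. The active damping D is weakly identified — its posterior
stays broad — because sway is slow: |θ̇| ≪ |θ|, so the stiffness
torque `P·θ(t−Δ)` exceeds the damping torque `D·θ̇(t−Δ)` roughly
50-fold at default parameters (`swayabc.torque_ratio()` measures
this directly).

A command line mirrors the library:

```sh
swayabc simulate --mass 80 --height 1.73 -p 128 -d 37 --delay 0.16 \
        --noise 0.16 --c-on 0.75 -o trials/
swayabc infer trials/*.csv --mass 80 --height 1.73 --com -o subject1
swayabc torque-ratio --damping 10
```

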
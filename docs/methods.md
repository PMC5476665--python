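# Methods

## The sway model

Quiet upright stance is modelled as a single-link inverted pendulum
pivoting at the ankle: a point mass `m` at the center-of-mass height
`h`, moment of inertia `I = m h²`, tilt angle `θ` (anterior–posterior).
The torque balance is a stochastic delay differential equation (SDDE)

    I θ̈(t) = m g h θ(t) − [K θ(t) + B θ̇(t)
              + f_P(θ(t−Δ)) + f_D(θ̇(t−Δ))] + σ ξ(t)

with two controllers. The *passive* controller (stiffness `K`, damping
`B`) models muscle tone and acts without delay; its default stiffness
`K = 0.8·mgh` is deliberately below the gravitational toppling
stiffness `mgh`, so passive control alone cannot stabilise the body.
The *active* controller models CNS action: a PD feedback on the state
delayed by `Δ` (neural conduction plus muscle activation), switched ON
intermittently,

    f_P = P θ(t−Δ),  f_D = D θ̇(t−Δ)
      iff θ_d (θ̇_d − a_s θ_d) > 0  and  θ_d² + θ̇_d² > r²,

and zero otherwise, where `θ_d, θ̇_d` are the delayed states. The ON
region is a double sector of the phase plane plus a quiet zone of
radius `r` around upright; the sector slope `a_s` is parameterised by
the *level of control* `C_ON = 0.5 + atan(−a_s)/π`, the fraction of
the phase plane where the controller engages. `ξ(t)` is unit white
noise scaled by the torque intensity `σ` (internal perturbations:
hemodynamics, respiration, sensorimotor noise). The observable is the
COM displacement `COM(t) = h·sin θ(t)` (exact, not small-angle),
reported in millimeters.

Five parameters are treated as subject-specific and inferable:
`P` (Nm/rad), `D` (Nms/rad), `Δ` (s), `σ` (Nm), `C_ON` (fraction).
Defaults (60-kg subject, h = 1 m): `P = 0.25·mgh ≈ 147`, `D = 10`,
`Δ = 0.2`, `σ = 0.2`, `C_ON = 0.62` (`a_s = −0.4`), `K ≈ 471`,
`B = 4`, `r = 0.004`.

### Discretization

The SDDE is integrated by Euler–Maruyama at `Δt = 1/f_s = 0.02 s`
(the sampling interval; a finer step is a config option, not the
default). The delay is `k = round(Δ/Δt)` steps, floored at 1 for
`Δ > 0`; exact zero delay is admitted for the linear-limit
diagnostics. Pre-history over the delay window is zero; the initial
tilt is drawn per trial from U(−0.01, 0.01) rad and no burn-in is
discarded. A trial whose |θ| exceeds 0.5 rad (or goes non-finite) is
flagged `fell` — the path holds its escape value so arrays stay
finite, and downstream the candidate receives infinite discrepancy.
The dt-refinement and linear-limit tests bound the discretization
error: halving the step changes the COM standard deviation by < 10%,
and with the controller forced ON at zero delay the empirical
stationary covariance matches the continuous Lyapunov-equation
solution within Monte-Carlo error.

## Signal processing

Measured center-of-pressure (COP) is converted to COM by convolution
with the two-sided exponential kernel of rate `sqrt(g/h)` — the
inverse of the mechanical relation `COP = (1 − (h/g) d²/dt²) COM`.
The discrete kernel is truncated where its weight drops below 1e−8 of
the peak and rescaled to unit sum so constants pass unchanged; edges
use reflective padding of one kernel half-width. All signals used for
summaries are zero-meaned and low-passed with a 51-tap Hamming
windowed-sinc FIR (10 Hz cutoff) applied forward and backward (zero
phase; the magnitude response is applied twice).

## Summary statistics and discrepancy

A trial set is summarised by 60 nonnegative numbers: 15-bin histograms
of the absolute COM amplitude, first difference × f_s (velocity) and
second difference × f_s² (acceleration), plus the first 15 Welch PSD
points, each block averaged over the trials. Bin edges are equal-width
from 0 to the per-subject maxima of the *observed* trials; simulated
values above the top edge are clipped into the last bin so
heavy-tailed candidates are penalised rather than dropped. Welch uses
a Hamming window, 8 segments with 50% overlap and a ≥1024-point FFT:
at 50 Hz the grid spacing is ≈ 0.049 Hz and points 1–15 (DC excluded;
a config switch includes it) span ≈ 0.049–0.73 Hz, giving the
spectrum the same weight as each histogram.

Two summaries are compared by

    ρ = (1/60) Σ |Φ_obs,i − Φ_sim,i| / |Φ_obs,i + Φ_sim,i| ∈ [0, 1],

with 0/0 terms defined as 0. ρ is symmetric and invariant to a common
positive rescaling; any other zero-denominator convention changes ρ
for empty bins and is deliberately not used.

## Inference (SMC-ABC)

The likelihood of the SDDE is intractable, so inference is by
approximate Bayesian computation with independent uniform priors:
P ∈ [50, 400], D ∈ [0.05, 50], Δ ∈ [0.05, 0.5], σ ∈ [0.05, 0.6],
C_ON ∈ [0.50, 1.00]. Candidate evaluation mirrors the measurement
protocol: three trials per candidate at the observed trial length,
filtered identically and summarised with the observed subject's bin
edges (required for comparability).

The sequential sampler tightens an acceptance threshold ε over
iterations. Iteration 1 draws prior candidates until `n/q` of them
have finite ρ and keeps the best fraction `q` (rejection at the pilot
q-quantile). Iteration t sets ε_t to the weighted q-quantile of the
previous population's discrepancies, resamples particles by weight,
perturbs with a multivariate Gaussian kernel whose covariance is
twice the weighted empirical covariance of the previous population —
so proposals respect the correlations between parameters (e.g. P
with C_ON), which markedly raises the acceptance rate over a
componentwise kernel — redraws proposals falling outside the prior
box, and weights acceptances by the standard
uniform-prior/Gaussian-mixture importance ratio. Candidate simulations
use independent streams keyed by (iteration, candidate counter), so
results are invariant to evaluation order.

The threshold quantile defaults to q = 0.25. This choice is driven by
the reduced-budget regime the package targets on a desk machine
(hundreds of particles, ~4 iterations): ρ has a strictly positive
stochastic floor (≈ 0.15–0.25 for 3 × 30–60-s trial sets, from
finite-sample noise in the histograms and PSD), and a median schedule
(q = 0.5) still sits far above that floor after four iterations,
leaving the posterior prior-dominated. q = 0.25 reaches the floor's
neighbourhood within four iterations at roughly 2–4× the simulation
cost; q ≤ 0.2 was rejected as disproportionately expensive. At
full-scale budgets (5000 particles × 7 iterations) the schedule is
simply a faster path to the same regime. A plain rejection-ABC
reference implementation is kept for validation; on a tractable toy
problem (1-D normal mean, wide uniform prior) both samplers reproduce
the analytic posterior within Monte-Carlo error.

Point estimates are weighted posterior means of the final population;
credible intervals are weighted quantiles, and marginal densities use
a Gaussian KDE with Silverman bandwidth on the weighted SD,
renormalised over the prior interval.

## Sway measures

Eight measures judge inferred-vs-measured signal similarity. Basic:
MD = mean |x|, MV = f_s·mean |Δx|, MA = f_s²·mean |Δ²x|,
MF = MV/(2π·MD) (an identity, tested as such). Nonlinear:

- **Fuzzy sample entropy.** Chebyshev distances between all template
  pairs of lengths L and L+1 (both with n−L start points) enter the
  membership μ(d) = exp(−d^q/c), q = ln(c·ln2)/ln r, so r is the
  distance of half-membership; FSE = −ln(A/B). Defaults L = 6,
  r = 0.03, c = 0.01 on the SD-normalised signal (tolerances of this
  magnitude presuppose unit variance). The printed membership form is
  implemented verbatim; a numba kernel is verified against a
  brute-force double loop to 1e−12.
- **DFA α.** Cumulative sum, first-order detrending in
  non-overlapping windows, 20 log-spaced scales in [5, 750], single
  slope over all scales. Calibrated on white noise (α ≈ 0.5) and its
  integral (α ≈ 1.5).
- **Correlation dimension.** Grassberger–Procaccia sums with a
  Theiler exclusion of twice the embedding lag J; the slope d_M is
  fitted where C_M lies in [1e−3, 1e−1] of its maximum (≥ 5 grid
  points); M grows from 1 until M > 2·d_M + 1. J is the first local
  minimum of a 16-bin histogram mutual information curve, lightly
  smoothed (3-point moving average) because raw histogram MI is
  jagged on near-periodic signals. The MI-based lag is
  estimator-dependent: finer binnings give systematically smaller J
  on slow sway signals. Calibrated on a limit cycle (D2 ≈ 1) and a
  two-torus (D2 ≈ 2); note that test periods must be incommensurate
  with the sampling grid, otherwise exactly repeating points create a
  spurious zero-distance floor.
- **Largest Lyapunov exponent.** Rosenstein-style: nearest neighbour
  outside the Theiler window, mean log divergence tracked forward,
  slope over steps 0…J. Reported per second when a sampling rate is
  given, per sample otherwise (the units are a convention; both are
  exposed).

Measured-vs-inferred comparisons use separate paired t-tests per
measure with p < 0.05, formatted as an 8-row table; identical groups
yield an undefined p, flagged not significant.

## Synthetic subjects

The generator emulates a simulated validation cohort, not real
posturography. Anthropometrics are drawn from normals
(66 ± 17 kg, 169 ± 12 cm) and screened by the filters weight
40–110 kg, height 145–200 cm, BMI 15–35; control parameters come from
normals (P 146 ± 50, D 23 ± 14, Δ 0.20 ± 0.06, σ 0.21 ± 0.10,
C_ON 0.65 ± 0.05) truncated to the prior box, so recovery is always
well-posed. Height and weight are independent (no correlation is
imposed); BMI screening culls implausible combinations. A draw is
accepted only if its three simulated trials do not fall, have maximum
zero-mean sway amplitude between 10 and 50 mm, and show a mean sway
frequency in [0.02, 1] Hz — the last two standing in for visual
realism screening, which is not reproducible. Screening is selective:
accepted-cohort parameter moments sit near, not at, the generating
means (e.g. the accepted mean of P runs ~15% above the generating
mean because low-stiffness draws fall or sway too widely).

What the generator does *not* emulate: nonstationarities of real
stance (voluntary movements, posture resets), multi-joint kinematics,
measurement noise of a force platform, and height–weight correlation.
Passing recovery tests therefore demonstrate the identifiability of
the model's parameters from its own output under realistic
anthropometrics — not that real sway obeys the model.

## Study problem sizes

The validation studies are sized for a single desk CPU: recovery uses
3 subjects × (3 × 30-s trials) with 500 particles × 4 iterations;
single-subject recovery uses 3 × 60-s trials at the same budget;
torque-ratio runs use the 6000-s protocol (they are cheap). Full-scale
budgets (10 subjects, 5000 particles × 7 iterations, 60-s trials) are
plain parameter changes to the same functions.

## Known limitations

- Active damping `D` is intrinsically weakly identified: sway is slow,
  so |θ̇| ≪ |θ| and the stiffness torque exceeds the damping torque
  ~50-fold at defaults (~3-fold even at D = 100). Recovery errors for
  D are large and positively biased; no test constrains them.
- σ recovery at 30-s trials is marginal for high-noise subjects: the
  discrepancy floor grows as trials shorten, and a ±30% σ change can
  sit inside the floor noise.
- The ON/OFF switching makes the process non-Gaussian and
  non-Markovian; all inference is simulation-based by design.
- The fuzzy-entropy membership exponent is implemented exactly as its
  defining formula states; other fuzzy-entropy variants in the
  literature differ and values are not interchangeable across
  conventions.
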
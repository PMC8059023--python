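# Methods

## Problem and model classes

During treadmill running, a change in belt speed produces a heart-rate
response with distinct components: a fast Phase I rise (of the order of
15 s, vagally mediated), a slower Phase II rise (15 s to ~3 min), and —
above the anaerobic threshold — a slow Phase III drift. For feedback
control of heart rate only the fast dynamics matter (an integrator in the
controller absorbs the drift), so the package works with small-signal
linear time-invariant models about an operating point:

- first order, `P1(s) = k1/(τ1 s + 1)`: Phases I and II lumped into one
  mean response time;
- second order, `P2(s) = k2/((τ21 s + 1)(τ22 s + 1))`: one time constant
  per phase, both real and stable.

Gains are in bpm per m/s, time constants in seconds; second-order time
constants are stored sorted ascending (the transfer function is symmetric
in them). No input delay is modelled.

## Excitation design

The input is a fifth-order maximal-length PRBS from a Fibonacci LFSR with
feedback polynomial x⁵ + x³ + 1, period 31 bits, 16 high / 15 low per
period. Defaults: 60 s bit clock, half-amplitude 0.25 m/s about the
operating speed `v_m`. The bit clock is a design choice, set so that a
360-sample (1800 s) window at the 5-s analysis period spans 30 of the 31
bit periods, and omitting one *high* bit period yields an exactly balanced
180/180 split of low/high samples. The default LFSR phase (initial state
1,1,0,0,0) is likewise chosen so that the canonical window starting at
290 s — the first 5 min being excluded as the initial transient — is the
earliest balanced window: with 12 samples per bit, the high-sample count
in the 290–2085 s window is `192 − 2·b3 − 10·b4` (bits indexed from 0),
so any phase with bits 3 and 4 high balances it exactly. The window search
itself is deterministic and exhaustive (earliest balanced start wins) and
reports the closest imbalance found when no balanced window exists.

## Operating point

The target heart rate is `HRref = f × (220 − age)` with f = 0.765 (the
moderate/vigorous transition; 0.7 is the conservative alternative for
subjects who would otherwise remain in the vigorous regime). A real test
finds `v_m` by servo-controlling the treadmill during warm-up until HR
settles at HRref; the synthetic pipeline replaces that controller with its
fixed point, `v_m = (HRref − HR0)/k`, where HR0 is the subject's affine
zero-speed HR intercept. Only `v_m` matters downstream, so the controller
itself is not simulated. Draws whose `v_m` falls outside the treadmill's
working range (0.5–6 m/s) are rejected and redrawn, mirroring recruitment
screening.

## Synthetic cohort

Each virtual participant has second-order truth with parameters drawn
independently from normal distributions with the cohort dispersion
(k2 24.70 ± 5.07 bpm/(m/s); τ21 18.60 ± 7.88 s; τ22 37.95 ± 16.01 s; age
32.5 ± 12.3 y), truncated below at 0.1× the mean to preserve positivity.
Note that storing time constants sorted makes the *component-wise* means
of a cohort slightly different from the generating means when the two
distributions overlap; tests account for this with a sorted-pair oracle.
An option generates first-order truth (gain k2, time constant τ21 + τ22)
for null-comparison experiments.

Free parameters the protocol does not determine, fixed a priori:

- baseline HR intercept: 80 ± 8 bpm (typical light-activity standing HR);
- HRV disturbance: AR(1) at 1 Hz with coefficient 0.8 and stationary SD
  2.2 bpm — a broad-spectrum, low-pass disturbance standing in for
  autonomic variability. Beat-to-beat RR structure is *not* modelled;
- white measurement noise: SD 1.0 bpm (telemetry quantisation/jitter);
- Phase III: linear drift of 0.05 bpm/min (a `creep` mode with a 15-min
  saturating exponential exists for robustness checks).

The noise calibration was computed from the AR(1) batch-averaging variance
(five-sample means of an AR(1) with a = 0.8 retain ≈ 0.85 of the
stationary SD) to put the true model's validation RMSE near 1.9 bpm, the
scale reported for real chest-strap data; the synthetic generator
reproduces the *structure* the analysis assumes (LTI truth, additive
stationary disturbance, linear drift), so passing tests demonstrate
correctness of the pipeline, not that real HR dynamics are LTI.

## Preprocessing

1-Hz HR → 0.2 Hz by averaging consecutive batches of five (trailing
remainder dropped and logged); window extraction is an inclusive slice on
the aligned 5-s grid; the output is detrended by removing the single
least-squares straight line over the window (mean + trend in one step —
this exactly cancels a linear Phase III drift); the input has its window
mean removed, which on a balanced window leaves levels at exactly
±0.25 m/s. Estimation and validation segments are detrended independently.
Gaps of up to 3 consecutive missing 1-Hz samples are linearly
interpolated; longer gaps raise.

## Estimation

Simulation-error (output-error) least squares: minimise
Σ (y(i) − y_sim(i))² where y_sim is the exact zero-order-hold response
from zero initial state. Discretization is exact, not Euler: distinct
time constants use the partial-fraction split into two first-order
recursions; (near-)repeated pairs (relative gap < 1e-7) take the
matrix-exponential state-space path, which handles the confluent case.

The gain enters the simulation linearly, so for fixed time constants the
optimal gain is `⟨y, ŷ₁⟩/⟨ŷ₁, ŷ₁⟩` (ŷ₁ the unit-gain response) and only
the time constants are searched — Nelder-Mead in log space (positivity by
construction), convergence tolerances 1e-8 on the log parameters and
1e-10 relative on the cost, at most 2000 evaluations per start. Starts are
deterministic: {10, 30, 60, 120} s for order 1; eight pairs spanning
5–120 s for order 2, plus two boundary-informed starts (τ̂1 from an
internal first-order fit, paired with 1e-2 s and 1e-4 s). The latter,
with a time-constant floor of 1e-6 s, guarantees numerically that the
order-2 residual never exceeds the order-1 residual on the same data (the
second-order class contains first-order behaviour in the vanishing-τ
limit). Degenerate all-zero outputs return gain 0 with a warning; constant
inputs are rejected as not persistently exciting.

## Validation and statistics

Validation simulates the estimated model from zero initial state on the
held-out session's detrended window — no initial-condition estimation —
and scores NRMSE fit (%) and RMSE (bpm) over exactly the N = 360 samples.
Negative fits (worse than the mean predictor) are reported, not clipped.

The paired analysis works on differences (order 2 − order 1) per
(participant, estimation-session) pair: Lilliefors-corrected KS normality
screen first (statsmodels, table-interpolated p-values); then one-sided
paired t-tests — alternative "less" for RMSE, "greater" for fit — and
one-sided 95% CIs `mean ∓ t₀.₉₅,ₙ₋₁·SE`, which are exactly dual to the
tests. If normality is rejected the report flags it and adds a Wilcoxon
signed-rank fallback, clearly labelled as beyond the primary analysis. No
multiple-testing correction is applied across the two outcomes, and the
report says so. Power for the one-sided paired t-test uses the noncentral
t distribution; `required_sample_size` inverts it by scan.

## Problem sizes and determinism

Default study: 11 participants × 2 sessions of 2160 s at 1 Hz, both model
orders, 44 estimations per run — about one second end to end. One master
seed (`StudyConfig.seed`) drives cohort draws and every noise realisation
through a single `numpy` Generator, so runs are bit-reproducible; the
estimator itself uses no randomness. Monte-Carlo checks in the test suite
(type-I error calibration, power cross-checks, truncated-normal draw
means) use fixed seeds and sizes of 10⁴–10⁵ replicates.

## Known limitations

- Real HR dynamics are nonlinear and intensity-dependent; the LTI model is
  a small-signal approximation valid near the operating point only.
- The synthetic HRV model is Gaussian AR(1); real HRV has respiratory and
  baroreflex spectral peaks and nonstationarity.
- No input/transport delay is estimated; short delays alias into the fast
  time constant.
- The operating-point computation assumes a globally affine steady-state
  HR-speed relation, which real subjects violate away from the set point.
- Reported cohort parameter dispersions are treated as independent
  marginals; correlations between gain and time constants are not modelled.
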
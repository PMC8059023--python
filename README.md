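# hrident

Identification of heart-rate dynamics during treadmill exercise, built to
answer one question: do **second-order** linear models, which give the fast
Phase I and slower Phase II components of the cardiac response their own
time constants, validate better than the usual **first-order** models that
lump both phases into a single mean response time?

The package is aimed at researchers in physiological systems modelling and
exercise science who design heart-rate feedback controllers and need
small-signal models of the speed→HR response about a moderate-to-vigorous
operating point.

## The models and the protocol

Treadmill speed deviation *u* (m/s) maps to heart-rate deviation *y* (bpm)
through one of two continuous-time transfer functions:

```
P1(s) = k1 / (τ1 s + 1)
P2(s) = k2 / ((τ21 s + 1)(τ22 s + 1))
```

Excitation is a fifth-order maximal-length PRBS (31 bits, 60 s per bit,
±0.25 m/s) about each subject's operating speed `v_m`, the speed at which
steady-state HR reaches `HRref = 0.765 × (220 − age)`. The 1-Hz HR stream
is downsampled to 0.2 Hz by 5-sample averaging; the evaluation window runs
from 290 s to 2085 s (N = 360 samples, exactly 180 at each speed level),
the output is linearly detrended (removing the slow Phase III drift) and
the input mean-centred. Each model is fitted by simulation-error least
squares (exact zero-order-hold simulation, gain concentrated analytically,
multi-start search over log time constants). Counterbalanced
cross-validation — estimate on session I, validate on II, then swap —
yields per-model validation outcomes

```
fit [%]   = (1 − ‖y − y_sim‖ / ‖y − ȳ‖) × 100      (NRMSE fit)
RMSE [bpm] = sqrt(mean((y_sim − y)²))
```

which are compared across orders by paired one-sided t-tests (α = 0.05)
after a Lilliefors normality screen, with matching one-sided 95%
confidence intervals for the mean difference.

Because the original chest-strap recordings are not deposited, the
pipeline ships a first-class synthetic-data module: virtual participants
with second-order truth drawn from the reported population dispersion
(k2 = 24.70 ± 5.07 bpm/(m/s), τ21 = 18.60 ± 7.88 s, τ22 = 37.95 ± 16.01 s),
AR(1) heart-rate-variability disturbance, white measurement noise, and a
linear Phase III drift.

## Worked example

```python
from hrident.pipeline import StudyConfig, run_study

run = run_study(StudyConfig(n_participants=11, seed=1))
print(run.report.to_markdown())
```

prints (abridged):

```
| outcome  | P1 mean ± SD | P2 mean ± SD | MD (95% CI)         | p-value  |
| rmse/bpm | 2.16 ± 0.22  | 2.04 ± 0.14  | -0.12 (-inf, -0.08) | 2.86e-05 |
| fit/%    | 54.01 ± 6.61 | 56.24 ± 7.38 | 2.24 (1.63, +inf)   | 1.35e-06 |
n = 22 model pairs
```

Reading: across the 22 counterbalanced model pairs, second-order models
(P2) validate with 0.12 bpm lower RMSE and 2.2 percentage points higher
fit than first-order models (P1); both one-sided CIs exclude zero, so the
improvement is significant at the 5% level. The same study can be run from
the shell:

```
hrident simulate --seed 1 --out records/
hrident identify --records records/ --out ident/
hrident report --validation ident/validation.csv --models ident/models.json --out report/
```

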
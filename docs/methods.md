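# Methods

## The model and what we had to decide

The virtual patient is the Bergman minimal model (BMM) with an appended
error-integral state, state order `(G, X, I, eps)`. Published versions
of this model family differ in small but consequential ways, and the
source material for this package is internally inconsistent in places;
the package therefore exposes explicit *readings* and documents which
one is the default and why.

**Glucose balance (`form`).** The default `deviation` reading,
`dG/dt = -(p1 + X)(G - Gss) + Gm/V1`, is the only one under which the
designated steady state `Gss = 80 mg/dL` is actually an equilibrium of
the glucose subsystem: the closed loop can regulate *to* 80 and stay
there. The verbatim `literal` reading (`-p1 G` instead of
`-p1 (G - Gss)`) has no equilibrium at the setpoint — under it the
closed loop settles tens of mg/dL below target and eventually at a
negative glucose level. It is retained as an option for comparison, not
for use.

**Plasma-insulin balance (`insulin`).** The default `basal` reading,
`dI/dt = -n (I - Ib) + v/V1`, lets plasma insulin decay toward the basal
concentration `Ib`, the standard minimal-model convention. The
alternative `printed` reading (`+Ib`) decays insulin toward `-Ib`; under
low infusion it drives the remote insulin action to
`X -> -(p3/p2) Ib`, and for the insulin-sensitive Patient 3
(`p3 = 99.4e-6`) that value is below `-p1`, which makes the glucose
dynamics exponentially unstable: BG diverges by six orders of magnitude
instead of settling. Because every published claim has all three
patients settling, `basal` is the default.

**Linearization affine term (`affine`).** The linear model
`dx/dt = Ax + Bu + Fd + H Gss` uses the fixed `A` layout with the
insulin-action column entry `-Gb` (`Gb = Gss`), `B = (0,0,1/V1,0)`,
`F = (1/V1,0,0,0)`. For the drift vector `H` the default `setpoint`
choice `H = (p1, 0, n*Ib/Gss, 1)` makes the model's drift vanish at the
regulated equilibrium — the property the sliding-surface construction
relies on, since the surface integrator replicates the *nominal* model
and `s` is meant to accumulate only unmodeled effects. The typeset
alternative `printed` (`H = (1,0,0,1)`) leaves a constant ~79 mg/dL/min
residual on the glucose row; the sliding variable then ramps at about
-0.7/min, the `tanh` limiter saturates within two minutes, and the
switching term degenerates into a constant insulin offset. Under the
default, `|s|` stays below ~15 across all presets and scenarios and the
adaptive law measurably reduces steady-state fluctuation relative to
the fixed-gain law in every paired seed.

## Controller parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `Q = diag(0.32, 0.25, 0.22, 0.61)`, `R = 1.05` | tuned set | — | LQIR state/input penalties |
| `K = (0.0038, 0.0021, 0.0024, 1.12e-4)` | published set | — | feedback gains used by the simulations |
| `g = (0.0088, 0.0051, 0.0052, 3.65e-4)` | tuned set | — | sliding-surface weights |
| `m` | 1.59 | — | SMC channel scaling; `strict()` recomputes `g1/g3 = 1.692` |
| `beta` | 4.48 | mU/min | switching gain; admissible range [4, 10], must exceed the disturbance bound (4 mU/min) |
| `Mo = m*beta` | 7.1232 | mU/min | fixed modulation gain (printed as 7.12) |
| `gamma` | 0.06 | per mg/dL | variation rate of the sech gain window |
| `u` clamp | [0, 100] | mU/min | pump limits (hypoglycemia guard) |
| sample period | 60 | s | controller rate, zero-order hold |
| noise variance | 0.2 | (mg/dL)^2 | i.i.d. Gaussian on the measurement only |

An important caveat, verified exhaustively during development: the
published feedback gain vector `K` is *not* the Riccati gain of the
published model and weights. Re-deriving `K` from the stated `A, B, Q,
R` gives `(-28.0, 4.6e4, 0.76, 0.76)` — the integral gain alone differs
by four orders of magnitude — and no sign/scaling/discretization variant
of the model reproduces the published numbers. The package therefore
keeps both: `solve_care`/`lqir_gain` perform honest synthesis (scalar
instances agree with closed forms to 1e-12, residuals < 1e-8), while
the closed-loop study uses the published gain set as its input, because
only those gains produce insulin-infusion magnitudes on the published
scale (peak ~0.6–7 mU/min rather than pump-saturating commands).

## The simulator

Between 60-s samples the plant is integrated with `scipy`'s adaptive
RK45 at `rtol = atol = 1e-8`. At each sample: measure (noise + optional
fault signal `5 + 2 sin(0.2 t)` mg/dL, `t` in minutes), update the
controller-side error integral (trapezoid on the measured error — no
anti-windup, the start-up phase depends on the windup), advance the
surface integrator `z` (trapezoid at the controller rate), evaluate the
control law, clamp, hold. `X` and `I` are fed back as true states (the
laws assume full state feedback); only glucose is measured through the
sensor model. States are not clamped; a flag records `G < 0` or
`I < -Ib`. Events fire exactly at `t = 500 min`: the meal is an
instantaneous +80 mg/dL jump of the glucose state (an alternative routes
a one-sample rectangular pulse through the `Gm/V1` channel, which only
adds ~6.7 mg/dL; the jump realization matches the reported excursion
scale), and stress switches the plant's `(p1, p2, p3)` to
`(8.0e-3, 25.0e-3, 2.5e-6)` while the controller keeps its pre-event
model.

Metrics use the plain mean over the recorded samples (the typeset
`1/N * sum_{n=0..N}` indexing is off by one sample, ≤0.1% here). When a
run never settles, the tuning cost replaces `T_set` with the run
duration so the cost stays finite and monotone. The t-test reports both
the exact Welch-df critical value and the large-sample 1.96 value; the
95% CI uses the normal approximation `mean ± 1.96 sd/sqrt(N)`. The
greedy tuning loop is cyclic coordinate descent (one parameter per
trial, sign flip on rejection), terminated by `n_max = 8`; the published
cost setpoint 1e7 would stop a minutes-based cost (~1e6) before the
first trial — it is consistent with a seconds-based integral — so the
default setpoint is unreachable and the loop runs to `n_max`, as the
published procedure describes happening in practice.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions: initial state
`(200, 0, 50, 0)`, 500-min regulation runs (300 min for tuning,
1000 min for meal/stress), sensor noise of variance 0.2, the three
patients, the event definitions above. It does not model meal-absorption
kinetics, subcutaneous insulin transport delays, circadian variation or
inter-day parameter drift — passing tests show correctness of the
control pipeline under the stated conditions, not clinical performance.

Two structural findings limit how much of the published result tables
can be reproduced, with any parameters:

1. **The stress scenario cannot raise BG above the setpoint.** In every
   self-consistent reading of the glucose balance, both the `p1` term
   and the insulin-action term vanish at `G = Gss`, so the pre-event
   equilibrium is invariant to the `(p1, p2, p3)` switch (and the
   post-event dynamics remain stable since `|X| <= (p3/p2) Ib << p1`).
   The recomputed stress overshoot is ~0.1 mg/dL against a published
   35.02. A stress-induced *rise* would require a basal
   endogenous-glucose-production term that the stated model does not
   contain.
2. **The published controller separation requires unavailable insulin
   authority.** With Patient 1's insulin sensitivity (`p3 = 5.3e-6`),
   halving the glucose fall time needs a sustained plasma-insulin level
   near 49 mU/L, i.e. an infusion of ~180 mU/min — two orders of
   magnitude above the published effort figures (`U_ms` ≈ 3–6
   (mU/min)^2). Under the published gain set the descent is governed by
   `p1` plus integral windup, all three controllers produce nearly
   identical BG trajectories (differences at the third decimal of
   `E_rms`), and the published orderings (LQ-ASMC < LQ-SMC < LQIR on
   error metrics; significant t-tests between controllers) do not
   emerge. The corresponding acceptance tests are left failing rather
   than tuned into agreement; the LQIR-level timing figures do land
   within ~15% of the published ones (e.g. `T_set` 250 vs 225 min,
   meal-recovery 216 vs 190 min).

Published `E_sa` values are additionally inconsistent with the published
`E_rms` on the same runs (Cauchy–Schwarz bounds the error sum below by
~9000 mg/dL when `E_rms ≈ 34` over 500 samples; 1367 is printed), so
absolute `E_sa` magnitudes are not meaningful comparison targets.

## Numerical choices and edge cases

* Riccati: `scipy.linalg.solve_continuous_are`; solutions symmetrized,
  validated for definiteness and a relative residual < 1e-8.
* Surface integrator: trapezoid at the 60-s step; the quadrature error
  against an exactly-model-consistent trajectory is ~2e-3 over 60 min.
* `sgn(0) = 0`; `sech` is evaluated in an overflow-free form; the
  adaptive gain saturates to `Mo` only beyond `gamma*|err| ≈ 37`
  (floating-point), far outside the physiological range.
* Degenerate metrics raise `MetricUndefinedError` (never-falling,
  never-settling or empty windows) rather than returning sentinels;
  `cpm_report` maps them to absent fields.
* Tuning trials that fail numerically are logged and rejected; the
  accepted-cost sequence is non-increasing by construction.

## Problem sizes

Default runs are 500 or 1000 controller samples; the full reproduction
grid is 3 patients x 3 controllers x 3 scenarios x 10 seeds (270 runs,
about a minute on one CPU). The acceptance script averages the stress
overshoot over 10 seeded runs and completes in a few seconds.
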
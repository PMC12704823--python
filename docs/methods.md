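# Methods

## The model

A participant's pre-surgery day is a 4-part composition
**x** = (sleep, SB, LPA, MVPA) of daily minutes closed to κ = 1440. All
analysis happens in Aitchison geometry: the composition is mapped to
z = V log **x** using pivot-coordinate ILR bases, where V is the 3×4
orthonormal contrast matrix of a sequential binary partition that isolates
the pivot behavior first and then splits off the remaining parts in
canonical order. The first contrast for pivot p is
√(3/4) · log( x_p / g(x_others) ) with g the geometric mean — the pivot's
log share against everything else. Rotating the pivot across the four
behaviors gives four bases; they are orthogonal rotations of one another,
so fitted values, residual sums of squares, the composition F-test and all
reallocation contrasts are identical across them. The suite asserts this
invariance to 1e-9, which is what makes the (unpublished) partition order
a testable non-choice rather than a consequential one.

The outcome model is ordinary least squares of %TWL on the three ILR
coordinates plus screened covariates. The overall composition is tested by
the nested F statistic ((RSS_r − RSS_f)/3)/(RSS_f/df_f) with (3, df_f)
degrees of freedom. p-values use exact t/F distributions because the
design targets n ≈ 45.

Isotemporal substitution is linear arithmetic in minute space: moving δ
minutes from behavior a to behavior b changes only those two parts and
keeps the day at 1440 min. The estimate is d'β̂ with
d = z(x_moved) − z(x_ref); covariate terms cancel in the difference, so
only the ILR block of the coefficient covariance enters the standard error
√(d'Σ̂d), and the 95% CI uses t(df_resid). The CI describes a difference
of conditional means, not a prediction interval, so residual noise is
excluded. A shift is infeasible when the displaced part would not stay
strictly positive; at the reference composition with 42.6 MVPA minutes,
displacing 45 or 60 min from MVPA is infeasible, which reproduces the
dashed cells of the published-style table. With a symmetric grid the
negative-delta cells into a behavior are the same contrasts as the
positive-delta cells out of it (estimate(a→b, −δ) = estimate(b→a, +δ)
exactly), so the 96-cell grid contains 12 infeasible cells, 6 of them in
the positive-delta view.

### Reference composition

The reference point is the cohort's compositional (geometric) mean,
equivalently the ILR-inverse of the mean ILR coordinates — the standard
prediction-at-the-mean for log-ratio models, and the choice that makes the
dual-route identity exact (asserted to 1e-9). Covariates are reported at
sample means/proportions but do not affect the differences.

### Covariate screening

"Adjust if significant" does not pin down a procedure. The default screens
each candidate (age, sex, race, pre-surgery BMI, surgery type) one at a
time with a partial F-test in a model already containing the ILR block,
retaining it at p < 0.05; `with_composition=False` switches to screening
against the intercept alone. Categoricals are reference-coded with the
most frequent level as reference; zero-variance candidates are skipped.
Complete cases are assumed throughout.

## Epoch processing

Wake wear minutes are classified by vector-magnitude counts/min with
half-open bands [0, 2000) SB, [2000, 7500) LPA, [7500, ∞) MVPA. The sleep
flag takes precedence over the bands: the sleep period is defined by the
upstream device-processing guider and its minutes are not re-classified,
mirroring sleep-period-first processing. Raw-signal sleep/non-wear
detection itself is out of scope; flags are consumed as input. A day is
valid at ≥ 16 h wear; a participant at ≥ 4 valid days. Non-wear minutes
are excluded from behavior totals and the person-level mean day is
proportionally rescaled to 1440 min at the averaging step (the source
design is silent on this; the rescale is the only choice consistent with
closure and is configurable). A person-level behavior mean of exactly zero
is replaced by a 0.5-min pseudo-minute before closure (configurable);
log-ratios are undefined at zero and the original cohort never needed the
rule.

## The synthetic generator

Person-level compositions are logistic-normal: z ~ N(μ_z, Σ) on the ILR
scale of a fixed generator basis, inverted to minutes. This matches the
analysis model's geometry, guarantees positivity, and makes the
reallocation ground truth analytic: the true effect of any shift is
β·(z(moved) − z(reference)), computed in closed form by
`true_reallocation_effect` and used as the oracle for the coverage checks.

The outcome is %TWL = β₀ + β'(z − μ_z) + surgery_effect·1[RYGB] + ε,
ε ~ N(0, σ²). Centring z at μ_z makes β₀ the expected %TWL of an SG
patient at the mean composition for every β, so the configured cohort mean
is honoured whether or not composition effects are present.

Defaults are calibration conveniences anchored to the published cohort
summaries, not acceptance claims:

- mean_minutes = (447.3, 583.7, 366.0, 42.6); β₀ = 23.8; σ = 5.1;
  p_rygb = 0.20; n = 45.
- Σ (between-person ILR covariance) is not reported anywhere; it is
  derived by assuming independent log-normal parts whose log-scale SDs
  equal each behavior's coefficient of variation (sd/mean of the printed
  minute summaries), projected into ILR space. Documented as assumed.
- β is a pure-MVPA clr direction scaled so the SB→MVPA +15 min true
  effect is +0.92 %TWL — the magnitude this literature reports — which
  also yields the characteristic asymmetry (MVPA→SB −1.31 at 15 min)
  arising from the convexity of log-ratios near a small MVPA part.
- surgery_effect = +3 %TWL for RYGB vs SG: the retained covariate in the
  motivating analysis, coefficient unreported, set to a clinically typical
  6-month difference. Age, sex, race and BMI are simulated with realistic
  marginals but zero true effect, exercising the screening step.
- The covariance validator accepts positive semi-definite matrices (the
  zero matrix is a useful degenerate case collapsing the cohort to the
  mean composition); only indefinite or asymmetric inputs are rejected.

The minute-stream generator emulates a 10-day, 24 h/day wrist protocol: a
fixed sleep window (default 447 min), wake minutes assigned SB/LPA/MVPA
with probabilities proportional to the mean minutes, counts/min drawn from
per-behavior log-normals constrained to put ≥ 95% of their mass inside the
behavior's cut-point band, and per-minute Bernoulli non-wear at rate/24.
It does not emulate circadian autocorrelation of counts, realistic
non-wear bout structure, day-of-week effects, or raw 30+ Hz signal;
passing the round-trip tests shows the classification/validity/averaging
logic is correct, not that the generator mimics real accelerometry.

## Simulation scale and numerical choices

Calibration checks run at the study's scale: type-I error of the F-test
from 2000 null cohorts of n = 45 (accepted in [0.035, 0.065]); per-cell
95%-CI coverage of the analytic truth from 500 cohorts (accepted in
[0.92, 0.98]); both sizes chosen so binomial noise is well inside the
acceptance bands. Large-sample moment checks use n = 10 000 with 3×SE
tolerances. Closure tolerance is 1e-9; least squares is solved by QR with
rank checked against a pivoted-QR tolerance of max(n,p)·eps·|R|max, and
rank-deficient designs are rejected naming the offending columns.
ILR-inverse rejects coordinates with |V'z| > 500 to avoid exp overflow.

## Limitations

- No multiplicity adjustment across the 96 reallocation cells (per-cell
  0.05, matching the motivating analysis); flag-level switch deliberately
  not provided, documented instead.
- The significance gate before reallocation is enforced by default and
  overridable (`force=True` / `--force`) for simulation studies.
- Single-timepoint, between-person design: reallocation estimates are
  model-based contrasts, not within-person change effects.
- One-for-remaining reallocations and mixed/robust models are out of
  scope.
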
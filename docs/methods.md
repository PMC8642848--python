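# Methods

## The problem

Waking and sleeping behaviours over a 24-h day — sitting, standing,
stepping, sleeping — are *compositional*: they compete for a fixed 1440
minutes, so only their relative sizes carry information, and increasing one
behaviour necessarily displaces the others. This package implements a
complete compositional data analysis (CoDA) of such device-measured
time-use against two glycaemic outcomes, fasting plasma glucose (FPG) and
2-h post-load glucose (2hPLG), in a cohort stratified into lower
(HbA1c < 39 mmol/mol) and higher (≥ 39 mmol/mol) diabetes-risk groups.

## Geometry (`composition`)

Compositions live in the Aitchison simplex: closure rescales positive parts
to 1440 min; perturbation (element-wise product + closure) is the group
operation; the compositional centre of a sample is the closed vector of
per-part geometric means. Analysis happens in isometric log-ratio (ilr)
*pivot* coordinates. For parts ordered (ref, o1, o2, o3):

    z1 = sqrt(3/4) ln( ref / (o1 o2 o3)^{1/3} )
    z2 = sqrt(2/3) ln( o1 / (o2 o3)^{1/2} )
    z3 = sqrt(1/2) ln( o2 / o3 )

z1 contrasts the reference behaviour against the geometric mean of the
rest; rotating the reference is an orthonormal change of basis, so any
least-squares fit is invariant and per-behaviour coefficients are read off
by refitting with each behaviour as reference. Only z1 is conventionally
reported; z2 and z3 use the remaining parts in canonical order (sit, stand,
step, sleep) with the reference moved to the front — the test suite asserts
the fit is invariant to this choice. Zero parts are a hard error, not
imputed: the modelled population spends ≥ 1 min/day in every behaviour, and
silent zero-replacement would change the model.

## Device processing (`processing`)

Day records come from a 7-day, 24 h/day thigh-worn inclinometer protocol
with a sleep/wake diary. Sleep is derived by subtraction: 1440 − sitting −
standing − stepping − non-wear. A day is invalid when monitor wear during
the diary waking window is below 80% of that window, or — if the diary has
no sleep/wake times — when total wear is under 10 h; both rules are strict
"less than", so boundary days are valid. Wear within the waking window is
interpreted as worn time, regardless of posture classification (the rule's
source does not specify; this is the documented assumption). Valid days
are averaged arithmetically per behaviour, then closed to 1440 to absorb
rounding and any non-wear remainder. Participants are excluded, in order:
fewer than 4 valid days, known diabetes, pregnancy, missing covariates;
missing FPG or 2hPLG only flags the participant out of that outcome's
analysis set. The cascade emits a ledger whose counts are conserved by
construction and tested.

## Group comparison (`groups`)

Per-behaviour group differences are expressed as the log-ratio of the two
groups' closed geometric-mean shares, converted to percent:
100·(exp(ln ḡ_higher − ln ḡ_lower) − 1). Confidence intervals are
percentile bootstrap (default 2000 resamples, participants resampled with
replacement within group, seeded). The overall test is a two-sample
Hotelling T² on the 3-d ilr coordinates with pooled covariance and the
exact F reference; it is invariant to the pivot reference, checked to
1e-9. A normal-theory alternative was not used for the CIs because the
percent-difference statistic is a smooth but non-linear functional of two
geometric means; the percentile bootstrap needs no delta-method
approximation.

## Regression (`regression`)

Ordinary least squares of ln(glucose) on (z1, z2, z3) plus covariates: age,
menopausal status (reference: male), education (reference: technical),
income (reference: highest band), smoking (reference: non-smoker),
depression flag, diet quality, energy intake, alcohol, calcium. Reference
levels are the majority categories, which keeps treatment-dummy variance
inflation low; with a rare reference level the dummies of one categorical
are strongly mutually correlated and per-column VIF is inflated for purely
coding-related reasons. Inference is Wald with t(residual-df) quantiles
(the z-vs-t choice is not dictated by the analysis being reproduced; t
matches standard OLS output). Stratified (per-group) models are separate
fits; the risk-group interaction is assessed in a pooled model with a group
main effect and group×(z1, z2, z3) terms, reading the Wald p of group×z1.
Backward elimination removes the candidate covariate with the largest Wald
p (joint F for a categorical's dummies) while that p exceeds 0.2, with
smoking and menopausal status forced back in. VIF is computed per design
column as 1/(1 − R²); perfect collinearity reports ∞ and rank-deficient
designs raise a collinearity error naming the dependent columns.

## Reallocation (`reallocation`)

From a base composition (a group geometric mean), t minutes move from one
behaviour to another, total fixed. The model's change in expected
ln(glucose) is the linear contrast Δ = (z_new − z_base)′β; covariate terms
cancel, so no representative covariate values are needed. SE = √(c′Σc)
from the coefficient covariance, treating the base composition as fixed
(the base's own sampling uncertainty is not propagated — a deliberate,
documented simplification). CIs are Δ ± t₀.₉₇₅·SE on the log scale,
transformed endpoint-wise by the exact back-transform 100·(exp(·) − 1) —
not the small-Δ approximation, which is visibly wrong for the ~10% changes
the grid reaches. Reallocation curves are asymmetric about zero (moving an
hour out of a 2-h behaviour is a much larger relative change than moving
an hour into an 8-h one); this is inherent to the log-ratio geometry and
is asserted in tests.

## Synthetic cohort (`cohort`)

The generator is the package's data source; its defaults are the study
conditions it emulates.

| parameter | default | rationale |
|---|---|---|
| group sizes | 376 / 272 | emulated cohort's risk-group sizes |
| centres (min/1440) | (526.4, 287.1, 120.6, 505.8) lower; (530.7, 288.5, 116.0, 504.8) higher | published group geometric means |
| β truths (pivot scale) | e.g. FPG-lower sit +0.04, 2hPLG higher step −0.13 | published adjusted per-behaviour coefficients |
| glucose means (mmol/L) | FPG 5.2/5.5; 2hPLG 5.2/6.0 | published group means |
| ln-glucose residual SD | FPG 0.09/0.15; 2hPLG 0.24/0.33 | ≈ sd/mean of the published values |
| ilr person SD | 0.25/coordinate | not published; plausible between-person spread (≈ ±65 min sitting at 1 SD) |
| ilr day SD | 0.15/coordinate | within-person day-to-day variation smaller than between-person |
| wear protocol | 7 recorded days | protocol length; valid-day failures create the 4–7 valid-day spread |
| exclusion rates | 21/741 low-wear, 37/741 diabetes, 2/741 pregnant, 33/741 missing covariates, 1/648 missing FPG, 8/648 missing 2hPLG | emulated exclusion cascade |

Compositions are logistic-normal: person ilr coordinates are multivariate
normal around ilr(centre); day records perturb the person composition with
ilr day noise. Because four per-behaviour coefficients share three free ilr
slopes, the configured per-behaviour truths are mapped to a zero-sum clr
vector a (a_P = √(3/4)·β₁ᴾ, then centred) and the realised truths are
β₁ᴾ = √(4/3)·a_P; configured tables that already sum to ~0 are reproduced
to rounding. Outcomes are exactly log-normal in the fitted model's form,
with a single generated covariate effect (standardised age), so Wald CI
coverage is exactly nominal by construction — which is what makes
parameter-recovery tests sharp. Covariates are drawn from simple
distributions matched to the published characteristics table (multinomial
categories, normal age/diet/energy/calcium, gamma alcohol); they carry no
effect on outcomes except age, so the adjusted model is correctly
specified.

What the generator does *not* emulate: accelerometer signal noise,
posture-classification error, bout patterning and behaviour intensity,
sleep-diary error, covariate–composition correlation (e.g. age–stepping),
and non-lognormal outcome tails. Passing recovery tests therefore shows the
*estimators* are correct under the stated model, not that the model is
correct for real cohorts.

## Pipeline and problem sizes

`pipeline.run` chains simulate → process → compare → fit → reallocate and
writes table2/3/4 CSVs, the dense reallocation-curve grid, the exclusion
ledger and a run log (package/library versions, config, max VIF, Hotelling
result). All randomness flows from one root seed via
`numpy.random.SeedSequence` spawning, making bundles byte-identical per
seed. Monte-Carlo test sizes were chosen to keep the whole suite under a
minute on one core while leaving binomial noise well inside the asserted
bands: 2000 replicates for the 5%-level calibration checks (SE ≈ 0.005)
and 500 replicates at full cohort size for CI coverage (SE ≈ 0.01 against
a ±2-point band).

## Known limitations

* The percentage-difference convention (higher/lower log-ratio of closed
  geometric-mean shares) is one documented reading of a statistic whose
  formula is not fully specified in the source material; two printed
  difference cells there (standing/stepping) are mutually inconsistent
  under any simple log-ratio reading and are not reproduced.
* Reallocation CIs ignore uncertainty in the base composition.
* The exclusion cascade order is fixed; reordering changes per-reason
  counts (not the final analysis set).
* Backward elimination inherits the usual caveats of stepwise selection;
  it is provided because the emulated analysis used it, not as a
  recommendation.
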
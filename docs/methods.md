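# Methods

## The measurement and its scoring

The test measures speech-on-speech masking with two masker talkers in a
virtual auditory scene, in two configurations: *colocated* (target and
maskers at 0°) and *separated* (maskers at ±45°). A listener's threshold is
the target-to-masker ratio (TMR, dB) at criterion performance; *spatial
release from masking* (SRM) is the colocated minus the separated threshold.
Each condition is run as a 20-trial progressive track: two trials at each of
the ten TMRs +10, +8, …, −8 dB, presented in descending order. A trial is
correct only when both the color and the number of the closed-set response
match the target sentence (response set of 4 colors × 8 numbers). The
threshold estimate is

    TMR threshold = 10 − (number of correct trials),

an integer in [−10, +10]. The rule depends only on the count of correct
responses, so trial order never matters. The estimator is known to be
accurate for true thresholds between about −6 and +6 dB TMR and to
*underestimate* thresholds of very good listeners (estimates pile up at the
−10 dB floor); `sr2norm` documents this behavior and does not correct for
it.

## Normative model

For each measure (colocated, separated, SRM) and run label (run 1, run 2,
average of both runs) the normative function is an ordinary least-squares
regression

    predicted threshold = constant + age·β_age + PTA·β_PTA,

where age is in years and PTA is the bilateral standard pure-tone average
(0.5/1/2/4 kHz over both ears, dB HL) — the hearing-loss summary least
confounded with age among the candidates screened. Fitting proceeds by
backward elimination: the full model includes age, PTA and their
interaction; the interaction is removed first when p ≥ α (α = 0.05), then
non-significant main effects are removed one at a time, largest p first,
refitting after each removal. If the interaction survives, the main effects
are retained (model hierarchy). The exact elimination sequence is a design
choice — the source analyses report only which terms survived — and this
ordering is the conventional reading of those results. A term whose entire
numerical contribution is negligible relative to the outcome scale (as
happens in noise-free synthetic fits, where t-statistics degenerate) is
treated as non-significant.

*Model error* is the residual spread of the final fit. The default is the
RMSE (√ of the mean squared residual, no df correction); MAE is available by
option. The wording of the source description ("average difference between
predicted and observed") is ambiguous between the two, but the Z-transform
treats model error as an SD, which RMSE estimates; both are implemented and
the choice is recorded in every model file.

Z-scores and flagging:

    Z = (observed − predicted) / model error,

with |Z| at or beyond k = 2 SDs flagging performance as abnormal for the
listener's age and hearing. Flagging is two-sided — remarkably good and
remarkably poor performers are both of clinical interest — and the boundary
is inclusive (with a 10⁻⁹ guard so that thresholds constructed exactly at
k·SD are not lost to float rounding). A participant is listed as an outlier
when any of the nine measures (3 measures × 3 run labels) is flagged.

The correlation screen reports Pearson r of age, SRT, standard PTA and
high-frequency PTA against the three average-run outcomes plus the three
hearing-measure-vs-age cells — 15 correlations — with a Bonferroni criterion
of .05/15 = .0033. The corresponding critical |r| is computed exactly from
the t-distribution for the cohort's n (≈ .32 at n = 82) rather than
hard-coded. Retest-delay correlations with run-2 − run-1 difference scores
are reported alongside when the delay is recorded, but delay never enters
the normative models (its measured effects are on the order of hundredths
of a dB per week).

Predictions requested outside the supported ranges (age 18–80 years, PTA
0–45 dB HL) are computed but tagged as extrapolations; the norms were built
on adults in those ranges and linearity is untested outside them (and
doubtful for children and for PTAs above ~40 dB HL, where predicted SRM
approaches zero).

## Synthetic cohort generator

The generator exists so the whole pipeline — scoring, fitting, Z-scoring,
flagging, file I/O, CLI — can be validated end to end without access to the
original participant data. It emulates:

- **Ages** from a truncated normal on [18, 80]. The latent (μ, σ) are solved
  (bounded least squares on the analytic truncated moments) so the *realized*
  mean matches the target 46.74 years. Note a hard limit: no truncated
  normal on a width-62 interval can exceed an SD of 62/√12 ≈ 17.9, so the
  target SD of 18.66 is approached (≈ 17.9) but not attainable; the real
  cohort's age distribution was flatter than any truncated normal. Sampled
  ages are rounded to whole years.
- **PTA given age** as a truncated linear-Gaussian model on [0, 45]:
  PTA | age ~ TruncNormal(a + b·age, σ_e). The three parameters are
  calibrated by a deterministic root-solve (Gauss–Legendre quadrature over
  the age density, analytic truncated-normal conditional moments) so the
  marginal PTA hits mean 12.48 dB HL, SD 8.89, and corr(age, PTA) = .51.
  Monte-Carlo checks at n = 10 000 recover all three within sampling error.
- **Audiograms** as symmetric flat-plus-sloping profiles (flat through
  1 kHz, linearly rising above on a log-frequency axis) scaled so the
  bilateral standard PTA equals the sampled value exactly. Only the PTA
  feeds the models; the shape is cosmetic but satisfies all audiogram
  invariants. Interaural asymmetry is not modeled.
- **Latent thresholds** per condition from the published average-run
  regressions (colocated: 0.549 + 0.033·age; separated: −8.617 + 0.053·age
  + 0.164·PTA) plus an individual deviation u ~ N(0, SD = the model error:
  1.045 / 1.864 dB). Run 1 uses u; run 2 uses ρ·u + √(1−ρ²)·ε plus a
  practice improvement of −0.7 dB (colocated) / −1.4 dB (separated), so both
  runs share the marginal deviation SD and correlate at ρ (default 0.8; the
  original work established good test–retest reliability but printed no
  correlation, so ρ is a documented assumption). Deviations are independent
  across conditions, which makes the simulated SRM slightly more variable
  than the real cohort's. The practice effect acts on the latent threshold,
  not on the score: learning changes the listener, not the scoring rule.
- **Responses**: each trial is a Bernoulli draw from a logistic psychometric
  function with guessing floor 1/32 and no lapses, p = chance +
  (1 − chance)·logistic((TMR − location)/s). The slope default s = 2.0 dB is
  a realism assumption (configurable, not a published value).

**Estimator-scale calibration.** The published normative coefficients
describe *track estimates*, so the generator's latent thresholds live on the
estimator's scale. If the psychometric 50% point were placed at the latent
threshold θ, the track would read ≈ 1.3 dB too low (its level grid is
centered at +1 dB, and the guessing floor inflates the correct count by
20·chance/2 ≈ 0.3 trials). By default the simulator therefore places the
psychometric location at the value where the *analytic expected estimate*
equals θ, found by vectorized bisection of the strictly increasing
expected-estimate curve (exact to ~10⁻¹⁵; in the step-listener limit the
location is θ + 1). This makes the track estimator unbiased by construction
wherever the expectation is attainable, i.e. θ ∈ (−10, 10 − 20·chance), and
Monte-Carlo checks confirm the mean estimate stays within 0.2 dB of θ across
the ±6 dB accurate range. `track_calibration=False` gives the literal
50%-point-at-θ convention, which reproduces the textbook step-listener
example (θ = 1 → 10 correct → estimate 0) and the estimator's inherent
bias. Estimates still saturate at ±10 dB: latent thresholds below −10 dB
pile up at the −10 floor exactly as real very-good listeners do.

- **Cosmetics** with no generative effect on thresholds: gender (49:33
  male:female odds), hearing-aid use (5/82), per-ear SRTs tracking the ear's
  own standard-frequency average plus N(0, 2) noise, and retest delay drawn
  from the study's categorical mixture (16 same-day, 7 within a week, 12
  within a month, 14 within a year, 33 beyond a year; uniform days within
  each bracket). Retest delay deliberately has no effect on simulated
  thresholds, matching its exclusion from the normative models.

What passing tests on synthetic cohorts do **not** show: the generator is
linear-Gaussian by construction, so it cannot probe nonlinearity of real
norms at high PTAs, asymmetric-hearing effects, informational-masking
structure, talker confusions, or lapse behavior. Parameter-recovery results
demonstrate the *fitting machinery* is unbiased and calibrated, not that the
published coefficients are correct for any new population.

## Numerical choices

- OLS is solved via statsmodels with an explicit intercept column;
  rank-deficient designs and n < p + 2 are rejected. p-values are two-sided
  t-tests with n − p − 1 df; no small-sample corrections beyond adjusted R².
- Cohort CSVs are round-trip exact: floats are written at shortest-repr
  precision and parsed with exact conversion. Model JSON round-trips all
  coefficients bit-identically. Derived columns (PTA variants, asymmetry,
  run averages, SRM) are always recomputed from raw data on read; a stored
  PTA disagreeing by > 0.05 dB draws a warning (stored summaries may be
  rounded).
- Validation is diagnostic, never silently coercive: schema problems raise
  errors naming the column, parse problems name row and column, and
  soft-invariant violations (threshold outside [−10, 10], age outside
  18–80, PTA above 45) are warnings carrying row numbers; rows are never
  dropped.
- Distribution calibrations are deterministic solves cached per parameter
  set; all stochastic draws flow from one seeded `numpy` Generator in a
  fixed order, so a config + seed reproduces a cohort byte for byte.

## Problem sizes used in the validation suite

Worked scoring examples are exact. Parameter-recovery runs use n = 2000
synthetic listeners (uniform ages, calibrated PTA model, Normal residuals at
the generative model error), at which size 3 Monte-Carlo SEs correspond to
roughly ±0.13 on the SRM constant and ±0.005 on its PTA slope. Replicate
recovery at the study's own n = 82 uses 120 replicates for bias and CI
coverage. Estimator-calibration checks use 4000 tracks per latent threshold;
demographic moment checks use n = 10 000.

## Known limitations

- The generator's age marginal cannot reach the target SD (see above).
- Generated run-1/run-2 means are both anchored on the published
  *average-run* models (run 2 then shifted by the practice effect), so
  simulated run-1 means sit ≈ 0.3–0.7 dB from the published run-1 means;
  the run-1 − run-2 practice differences are reproduced.
- SRM deviations are the difference of two independent condition deviations;
  the real between-condition correlation is unknown and not modeled.
- The psychometric slope and between-run persistence defaults are plausible
  but unvalidated against trial-level human data.
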
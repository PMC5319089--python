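# Methods

## Design and model

A two-stage preference trial allocates a fraction θ of the N participants
to a choice arm; the rest form a conventional random arm.  Within the
choice arm, participants prefer treatment A with probability α, B with
probability β, and are undecided with probability γ (α + β + γ = 1).
Choosers receive their preferred treatment; the undecided are re-randomised
1:1, as is the whole random arm.  "No preference" is an observed category
elicited from the participant, not missing data; random-arm preferences are
latent and never imputed at the individual level.

Outcomes follow `Y = mu + tau_i + nu_j + pi_ij + eps`, a fixed-effects
linear model with additive error.  The identifying constraints are
`tau1 + tau2 = 0`, preference-weighted zero sums for `nu_j` and for
`pi_ij` (i = 1, 2), and `pi_1j + pi_2j = 0`.  Under them the random-arm
marginal means satisfy `mu_i = alpha*mu_i1 + beta*mu_i2 + gamma*mu_i3`
(arm equivalence), which both identifies the two unobservable cell means
and underpins every selection/preference estimator.

## Estimators

All estimators are functions of the six observable subgroup summaries
(counts, means, sample SDs with denominator n−1).  Two algebraically
identical routes are implemented for each contrast — the compact z/w form
used in computation and a mean-form plug-in kept as a cross-check; the test
suite verifies their equality to 1e−10 (relative, for magnitudes above 1)
on the worked example and on thousands of random summaries.  The preference
proportions are always the empirical choice-arm proportions; no shrinkage
or external priors.

When the denominator of a second (undecided-vs-decided) contrast is
requested with no undecided participants, the operation raises rather than
returning a conventional value: that contrast does not exist in a γ = 0
design.

One transcription decision: the printed definition of `w2` in the source
material for this methodology contains an inconsistent subscript; the
implementation uses the form `w2 = m2 (X̄2 − V̄2)`, which is the only one
consistent with the worked example's published selection estimate and with
the symmetry to `w1`.

## Variances and tests

*Conditional* variances assume a common outcome variance (estimated by the
SD pooled over all populated subgroups, df = N minus the number of cells)
and treat the preference split as fixed.  The two first contrasts share one
conditional variance and the two second contrasts another.

*Unconditional* variances allow a different variance in every subgroup and
account for the multinomial variability of the preference split: first the
exact variance of the numerator statistic `T = (z1−z2) − ĝ(w1−w2)` (or
`T*` with sums), then a first-order correction for the random denominator
`2 â b̂ m`.  Population symbols in these formulas are replaced by their
sample counterparts (plug-in policy); negative values that can arise from
the correction are clipped to zero with a warning.  These formulas assume
an even random-arm split; the treatment-effect SE itself always uses the
actual n1, n2.

Hypothesis tests are large-sample normal.  For the unconditional method the
test statistic is the numerator form `z = T / sqrt(var T)`, while the
confidence interval uses the delta-method SE of the contrast.  The split is
deliberate: the contrast is T over a random denominator, and plugging the
realised T into the correction terms makes that SE anticorrelated with the
estimate's magnitude — in simulation the estimate/SE test rejects a true
null about 13% of the time at nominal 5%, whereas the numerator test holds
the level (5.5% at R = 5000, N = 500).  Conditional tests use estimate/SE
directly and are well calibrated (5.2%/5.0% in the same study).

A stratified bootstrap (resampling within each of the six observable cells,
sizes fixed, seeded and deterministic) provides SEs where no closed form is
implemented, in particular for the unconditional second contrasts.

### Known limitation of the unconditional expansion

Validating the formulas at the *population* inputs against the empirical
spread of estimates over simulated replicates: the conditional variances
track the empirical SDs within a few percent for undecided fractions
γ ∈ {0.2, 0.5, 0.7}, and the unconditional ones do so for γ ≤ 0.5.  At
γ = 0.7 with only ≈40 choosers per treatment the unconditional expansion
under-covers (SE/SD ≈ 0.88 for the selection contrast, ≈ 0.92 for the
preference contrast).  Brute-force evaluation shows the printed covariance
term between T and the denominator overstates the actual covariance under
multinomial sampling in that regime (a multinomial-moment derivation gives
`cov(T, âb̂) = ab[(1−2a)d1 − (1−2b)d2 − g((1−4a)e1 − (1−4b)e2)]`, which
matches simulation).  The printed expansion is retained because it is the
published method and is accurate on realistic designs such as the worked
example; the conditional variances — which the package reports by
default — are the safer choice when the undecided fraction is very large.

## Assumption checks and the cost of ignoring undecideds

Two simplifications are testable because undecideds are re-randomised
within the choice arm: undecideds respond like the random arm
(`mu_i3 = mu_i`), and the exclusion restriction (`mu_ii = mu_i3`).  Both
are checked by two-sample z-tests, pooled SD by default (a per-cell Welch
option exists), reported unadjusted per treatment with an optional joint
2-df chi-square combination.

`bias_if_ignored` gives the asymptotic bias of a γ = 0-style analysis that
discards the undecideds' outcome data while keeping the observed preference
proportions: `(a d1 ∓ b d2)/(2ab)` minus the true contrast, evaluated on
the generating cell-mean grid.  This form has the property that the bias
vanishes exactly when the exclusion-restriction differences e1 = e2 = 0 and
tends to zero with γ.  A variant that also renormalises the proportions
over deciders only (`renormalize=True`) — i.e. pretends the undecideds
never existed — is provided; note it remains biased even under the
exclusion restriction, because the random arm still contains
undecided-type participants.

## Simulator

`ModelParams` holds the grand mean, the five contrast values, (α, β, γ),
θ, the error SD σ, and N.  The cell-mean grid is obtained by solving the
constraint system exactly (two 3×3 linear solves); a round-trip test
recovers all five contrasts from the grid to 1e−10.  Errors are normal —
the model is silent on the error law, and normality matches the
large-sample inference being validated.  Arm entry, preference, and the
two 1:1 randomisations are independent fair draws by default; a `blocked`
option fixes the first-stage split at round(θN) and gives exact-half
randomisations, matching the fixed-design assumption of the variance
derivations.  A single root seed spawns one independent stream per
replicate, so studies are exactly reproducible and one replicate is
bit-identical to a direct `simulate_trial` + `summarize` call.

Default parameter values are the conditions of the bundled trial: the
observed preference split (19/130, 21/130, 90/130), allocation fraction
130/227, pooled SD 7.58, the full-precision contrast estimates
(12.1, 3.05, 0.57, 0.95, −3.23) and N = 227, with grand mean 11.15 (the
midpoint of the random-arm means).

What the generator does and does not emulate: it reproduces the design's
sampling structure (two-stage allocation, multinomial preferences,
re-randomisation) with homoscedastic normal errors and no missingness.
Real trials add refusal/dropout (the example trial had 46 refusers whose
outcomes are unavailable), possibly heteroscedastic or skewed outcomes,
and covariates — so passing simulation checks validates the estimators and
variance algebra under the stated model, not robustness to those features.
Outcome-influencing disappointment in the random arm ("reluctant
acquiescence") is deliberately not modelled.

## Study sizes used in the validation suite

Chosen as the package's own trade-off between Monte-Carlo resolution and a
test suite that runs in about a minute: parameter recovery at N = 10 000
with R = 2000 replicates (bias bounded by 4 Monte-Carlo SEs); variance
calibration at N = 500 (and N = 520 for the γ grid) with R = 3000–5000,
formula-to-empirical SD ratio within 10%; type-I error at R = 5000 against
the exact binomial 99% interval around 0.05; bootstrap agreement with the
delta-method SE within 15% at B = 2000.

## Numerical choices and degenerate inputs

- Full floating precision everywhere; published values that carried rounded
  intermediates are matched at the documented full-precision anchors.
- Sample SDs of cells with fewer than two members are NaN; the pooled SD
  refuses such cells and points at the per-cell mode.
- `w1`, `w2` are defined as 0 when γ̂ = 0 so the no-undecideds reduction
  `(z1 ∓ z2)/(2 â b̂ m)` holds without NaN propagation.
- Estimation requires both decided cells and both random-arm cells
  non-empty (the denominators 2 â b̂ m vanish otherwise); simulation
  replicates violating this are counted as failed, not silently dropped.
- Normal, not t, quantiles throughout, in keeping with the large-sample
  derivations; no small-sample correction is attempted.

## Other known limitations

- The published point value for the second preference contrast of the
  worked example is inconsistent with the published estimator evaluated on
  the published summary (two independent routes here give −3.226); the
  implementation follows the formulas and does not target that value.
- Similarly, the published SD of the selection test statistic (40.8) is not
  recoverable from the published inputs; term-by-term evaluation gives
  39.03, which is what the tests assert.
- Unequal random-arm allocation enters only through the treatment-effect
  SE; the contrast variance formulas keep the even-split assumption.
- No covariates, stratification, non-numeric outcomes, or refusal
  processes.
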
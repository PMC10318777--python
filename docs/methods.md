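# Methods

## Model and procedure

`pbam` corrects non-differential or differential misclassification of a
binary exposure in case-control data by record-level probabilistic bias
analysis. The procedure per replicate:

1. Draw (sensitivity, specificity) per outcome group from the bias priors.
2. Invert the 2×2 classification matrix on each group's observed margins
   (A\*, B\*) to get expected true counts (A, B). The inversion conserves
   the group total exactly, and the PPV/NPV denominators equal A\* and B\*
   respectively — both identities are enforced by tests.
3. Screen the draw: it is valid iff Sen+Spe > 1 in both groups and all four
   predictive values lie in [0, 1], which is algebraically equivalent to
   0 ≤ A ≤ group total in each group. Invalid draws are discarded and
   redrawn; draws with Sen+Spe ≤ 1 count as invalid rather than errors.
   After `max_redraws` (default 10⁵) consecutive failures the engine stops
   with the specificity floor implied by the margins (Spe must be at least
   B\*/(A\*+B\*) in each group), so a prior incompatible with the data can
   never loop silently. A redraw resamples the full four-parameter draw,
   not only the offending group.
4. Impute expected exposure per record with one uniform per record:
   observed-exposed stay exposed if U < PPV, observed-unexposed stay
   unexposed if U < NPV. Expected counts are never rounded or used to
   rebuild tables; imputation is strictly record-level.
5. Refit the multivariable logistic regression (maximum likelihood,
   `statsmodels`) of outcome on imputed exposure plus the declared
   confounders; categorical confounders expand to indicator contrasts,
   numeric ones (age) enter linearly. The exposure coefficient's
   exponential is the replicate's adjusted OR; the imputed case-group
   exposure prevalence is stored alongside for attributable-fraction
   estimation. Non-identifiable or non-convergent fits (e.g. separation
   after rare-exposure imputation) are skipped and counted, never fatal.

With random error included, steps 1–5 run `n_monte_carlo` times inside each
of `n_bootstrap` bootstrap resamples drawn stratified within cases and
within controls (preserving the design margins). The pooled replicate
distribution is summarized by its 50th percentile (point estimate) and
2.5th/97.5th percentiles (95% MCSA interval), using linear interpolation
between order statistics. With `include_random_error=False` a single
Monte-Carlo pass propagates bias-parameter uncertainty only.

## Bias priors

Pooled validation estimates (estimate, 95% CI) are converted to priors with
a shared dispersion rule, sd = CI width / (2·1.96):

- **triangular**: support = CI, mode = estimate;
- **beta**: moment-matched, α = mν, β = (1−m)ν with ν = m(1−m)/sd² − 1,
  failing informatively when the CI is too wide for any beta with that
  mean;
- **logit-logistic**: a logistic distribution on the probability scale,
  location = estimate (its median), scale = beta-fit sd·√3/π so its sd
  matches the beta fit; identity-link draws are kept in (0,1) by inverting
  the CDF of the truncated distribution (deterministic, preserves the
  truncated marginal — equivalent in law to rejection resampling). A
  logit-link variant, expit(logit(loc) + scale·logit(U)), is available via
  `link="logit"` and needs no truncation.

Differential scenarios couple draws with a Gaussian copula, which preserves
marginals exactly for all three families. The correlation applies by
default to the same parameter across groups (case vs control sensitivity,
case vs control specificity) — the standard construction, under which
correlation → 1 with identical group priors collapses to the
non-differential analysis; coupling sensitivity with specificity within
each group is available via `correlate="within_group"`. Point-mass priors
(zero-width triangulars) reproduce the conventional analysis exactly and
are the backbone of the equivalence tests.

Validation studies are pooled by DerSimonian–Laird inverse-variance random
effects: weights 1/(se²+τ²), τ² from Cochran's Q truncated at zero, CI =
estimate ± 1.96·pooled se truncated to [0,1]. Pooling is on the raw
proportion scale by default (pooled values read directly as percentages);
a logit-scale option with delta-method standard errors is provided for
estimates near the boundary. The τ² truncation is the reason pooling is
implemented directly rather than delegated: the obvious library routine
returns untruncated τ², which produces undefined weights for homogeneous
inputs. It is cross-checked against `statsmodels.combine_effects` on
heterogeneous inputs in the test suite.

## Synthetic data

The generator draws a source population from a logistic structural model:
confounders with fixed marginals (age normal with mean 42 and sd 9.5;
smoking 3%; physical activity 10.9%; education and SES ordinal multinomials
resembling an urban female population); true exposure logistic in the
centered confounders with intercept logit(exposure_prevalence); outcome
logistic in true exposure (coefficient ln(true_or)) and the centered
confounders with intercept logit(baseline_outcome_prob). Case-control
sampling keeps the first `n_cases` cases and `n_controls` controls,
oversampling in batches with a hard cap (default 10⁷ draws) and an explicit
failure naming the cap. Self-report error is overlaid per outcome group
with the configured sensitivities/specificities. Because confounder terms
are centered, the configured prevalences are approximate marginal
calibrations, exact when all confounder effects are zero.

What it emulates: a roughly 1000-case / 1000-control study, rare exposure,
the age/smoking/education/physical-activity/SES confounder set, group-
specific misreporting. Deliberately not emulated: non-linear age effects
(age enters linearly in generation and analysis), matching or survey
weights, confounder misclassification, missing data mechanisms, and
dose-response in the exposure. Confounder effect defaults are illustrative
round numbers, not estimates of any study; case/control age means separate
through the age→outcome coefficient rather than being set per group.
Passing tests therefore demonstrate correctness of the correction machinery
under a known generative model, not the realism of any particular effect
size.

## Numerical choices

- Percentiles: linear interpolation between order statistics
  (`numpy.percentile`, method="linear"); pinned for reproducibility.
- RNG: one master `SeedSequence` spawns an independent substream per
  bootstrap sample, so replicate streams are well-separated and results
  are reproducible bit-for-bit for a given seed regardless of execution
  order. The engine runs serially; the seeding scheme means a parallel
  backend could be added without changing results.
- Logistic fits: Newton MLE with a 100-iteration cap; a fit is treated as
  non-convergent if the optimizer reports failure, the exposure
  coefficient is non-finite, or |log OR| > 30 (a separation guard).
- Singular draws (Sen+Spe = 1) raise a dedicated error in the low-level
  inversion and are screened out as invalid by the engine.
- Zero-width validation CIs are rejected at pooling (no recoverable se);
  degenerate priors are expressed as point-mass triangulars instead.
- Beta fitting requires sd² < m(1−m); the error message states the bound.

## Design choices where the method is underdetermined

- **Pooling scale**: raw proportions by default, logit behind an option —
  pooled sensitivities/specificities are then directly the quoted
  percentages.
- **Bias-draw correlation semantics**: across-groups by default (see
  above), within-group behind an option.
- **Logit-logistic sampler**: the identity-link location/scale form is the
  unique simple parameterization whose (location, scale) equal (pooled
  estimate, beta-sd·√3/π); the logit-link form is the documented
  alternative.
- **Bootstrap scheme**: stratified within outcome groups, preserving case
  and control counts — the natural resampling for a case-control design.
- **Redraw scope**: a discarded draw resamples all four parameters.
- **Interval E-value**: computed at the MCSA limit closer to the null, set
  to 1 when the interval crosses 1.
- **PAF reporting**: percent, per-replicate computation using that
  replicate's own corrected case prevalence and OR, summarized by the same
  percentile rule as the ORs.

## Problem sizes used in the test suite

Distributional checks run at 10⁵–10⁶ draws with 3σ tolerances from the
corresponding closed-form variances. End-to-end parameter recovery uses
20,000 subjects per arm with 200 Monte-Carlo replicates and point-mass
priors (tolerance: 3 simulation standard errors of the true-exposure crude
log-OR); the full 500 × 1000 replicate design is exercised as arithmetic on
the configuration and at reduced replicate counts through the same code
path. These sizes were chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo tolerances meaningful.

## Known limitations

- Binary exposure and binary outcome only; no polytomous exposure, no
  outcome or confounder misclassification.
- The OR→RR substitution in PAF and E-values leans on the rare-outcome
  assumption; with common outcomes both are biased away from the truth.
- Predictive-value imputation conditions on the observed margins of the
  analyzed (possibly bootstrap-resampled) table; very small groups can
  make the screen reject nearly all prior mass, which surfaces in the
  reported acceptance rate.
- No missing-data machinery beyond fail/complete-case policies at read
  time.
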
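# Methods

## Model

The estimand is the prevalence `pi_i` of abdominal obesity in every
cell *i* of a six-way cross-classification (age × sex × education ×
urban–rural × region × occupation; 4·2·2·2·5·11 = 1760 cells).  The
model has three layers:

1. **Data.** `y_i ~ Binomial(n_i, pi_i)`.  With a median cell count of
   1, modelling individual-level randomness explicitly is essential;
   cells with `n_i = 0` carry no likelihood but remain in the state so
   that census weights covering all 1760 cells can be applied.
2. **Cells.** `logit(pi_i) = eta_i ~ Normal(x_i' beta, sigma^2)`.  The
   design row `x_i` contains one indicator per included term:
   intercept, main effects for all six factors, and all pairwise
   interactions among age, sex, education and occupation (135 columns;
   13 ones per row).  No reference levels are dropped — every level of
   every term has its own coefficient, and identifiability comes from
   the zero-centred shrinkage priors, as in hierarchical ANOVA.
3. **Effects.** Within each term, coefficients are
   `Normal(0, tau_term^2)`.  Terms with three or fewer levels (sex,
   education, urbanicity main effects) have too few coefficients to
   estimate a spread, so `tau` is fixed at 1; terms with four or more
   levels get `tau_term ~ HalfNormal(A)` with `A = 1` for main effects
   and `A = 0.5` for interactions, encoding the expectation that
   interactions are smaller than main effects.  `sigma ~ HalfNormal(1)`.

The intercept gets a `Normal(0, 10^2)` prior: wide enough to be
uninformative about the overall level, so the pooled prevalence is not
shrunk towards 50%.  All scales are configurable (`ModelConfig`,
`HyperParameters`).

Obesity coding uses the non-strict convention (`waist >= cutoff` is
obese), with cutoffs 90/80 cm (men/women, Asian standard) and
102/88 cm (European standard).  Region has five levels with default
labels Bangkok/Central/North/Northeast/South — any five labels work;
occupation has eleven (nine ISCO major groups plus "No occupation" and
"Other", all entering the model as ordinary levels).  The
sedentary/non-sedentary grouping of occupations is reporting metadata
only and never enters the model.

## Sampling

The posterior is sampled by a blocked Gibbs scheme over
`(eta, beta, tau, sigma)`:

* **eta** — cells with data get a per-cell adaptive random-walk
  Metropolis update, vectorised across cells (target acceptance 0.44;
  step sizes adapt only during burn-in, so retained draws come from a
  valid Markov chain).  Empty cells are exact Gaussian conditional
  draws.
* **beta** — given `eta`, the latent layer is linear-Gaussian, so the
  full coefficient vector has an exact multivariate-normal conditional,
  drawn via a Cholesky solve of the 135×135 posterior precision.
* **tau, sigma** — univariate slice sampling on the log scale.

Two extra move families fix the pathologies plain Gibbs has on sparse
tables. (1) *Interweaved rescalings*: propose `tau' = c·tau` together
with `beta_block' = c·beta_block` (and `sigma' = c·sigma` together with
`eta' = m + c(eta − m)`); the funnel-shaped prior terms cancel
analytically in the acceptance ratio, so these moves traverse the
scale hierarchy even when individual conditionals are nearly
degenerate. (2) *Translation (ASIS) sweeps*: propose a shift of one
coefficient jointly with the logits of its cells, leaving the Gaussian
layer invariant; this breaks the stiff `beta <-> eta` coupling that
appears when `sigma` is small.  Proposal scales for both adapt during
burn-in only.

Defaults: 4 chains, 2000 iterations, 1000 burn-in, no thinning.  All
randomness descends from one seed through `numpy.random.SeedSequence`
spawning, so identical seed + config reproduce bit-identical draws.
A run refuses to report when any parameter has split R-hat > 1.1 or
ESS < 100 (computed through arviz) unless explicitly overridden;
constant chains are reported as R-hat 1 and flagged degenerate.

### Verification

`grid_posterior_oracle` computes marginal posterior quantiles for toy
models (at most three free parameters: the cell logits, optionally
sigma) by dense-grid numerical integration.  The Gaussian latent layer
is integrated exactly over each grid cell via CDF differences rather
than point-evaluated — the joint posterior has an integrable ridge at
`sigma -> 0` that a fixed point-grid cannot resolve.  The test suite
checks the sampler against this oracle (agreement within 0.01 on the
probability scale), against the conjugate Beta posterior in the
diffuse-latent limit, and via a simulation-based calibration check:
with ground truth drawn from the model's own prior, 95% credible
intervals for the 1760 cell prevalences cover the truth at a rate
consistent with 95%.

## Post-stratification

For a reporting group *g*, each posterior draw *s* yields
`pibar_g^(s) = sum_{i in g} w_i pi_i^(s) / sum_{i in g} w_i`; the point
estimate is the median over draws and the 95% interval the 2.5/97.5%
quantiles, computed with linear interpolation between order statistics
(fixed convention, so intervals reproduce across implementations).
Direct estimates for a group pool counts first (`sum y / sum n`),
matching survey tabulation practice; they are undefined (emitted as
empty fields) when the pooled `n` is zero.  Report tables round
percentages to one decimal place.  Occupation-specific panels use the
identity grouping (each occupation's estimate weights only its own
cells).

## Missing data

Missing categorical fields and waist measurements are single-imputed
by k-nearest neighbours (default k = 5, the convention of the standard
kNN-imputation implementations).  Distance is the Gower dissimilarity
over all other variables: 0/1 mismatch for categorical variables,
range-scaled absolute difference for numeric ones, averaged over the
variables observed in both records; records sharing no observed
variable are maximally distant.  Categorical values are imputed by the
donor mode (ties go to the nearest donor's value), numeric values by
the donor median.  Distance ties are broken by record order after a
seeded shuffle, making results deterministic under a seed without
hidden dependence on file order.  Donors always come from the original
records, so imputations do not chain, observed values are never
altered, and imputing a complete table is the identity.  Imputation
uncertainty is not propagated (single imputation); at the default
missingness of a few per thousand this is negligible.

## Synthetic data

The survey and census microdata the package is designed for are
access-restricted, so `synthetic` generates stand-ins calibrated to
the published structure of the 2009 survey round:

* **Allocation.** 10,127 respondents are spread over the 1760 cells by
  a multinomial whose probabilities are symmetric-Dirichlet with
  concentration 0.3.  This value was chosen by matching beta-binomial
  cell-count probabilities to the published sparsity profile: median
  respondent count over all cells of 1 (mean 5.8) and, at typical
  prevalences, roughly 56% of cells with zero obese respondents.
* **Outcomes.** `y_i ~ Binomial(n_i, pi_i)` at known true prevalences.
  Respondent-level generation draws waist circumference from a
  sex-specific two-component normal mixture, location-shifted per cell
  so that the exceedance probability over the sex's cutoff equals
  `pi_i` exactly (degenerate prevalences 0/1 are forced to the correct
  side of the cutoff).  Tabulating the records therefore reproduces
  the cell-count distribution.
* **Missingness.** Completely at random, at per-variable defaults
  matching the published missing counts (education 0.0022, urbanicity
  0.0007, occupation 0.0034, waist 0.0013).
* **Ground truth.** Two named scenarios. `default_scenario` emulates
  the study: intercept pinned at the pooled observed prevalence
  (logit(3570/10127) ≈ −0.61), effect blocks drawn with study-like
  spreads (0.4 logit units for main effects, 0.15 for interactions,
  residual sigma 0.3) and recentred to sum to zero so the intercept
  controls the overall level.  `calibration_scenario` draws everything
  except the intercept from the model's own prior — the regime where
  Bayesian interval coverage is exactly 95% on average — and exists
  for the coverage checks; unconstrained prior draws of the intercept
  would produce populations with prevalence indistinguishable from 0
  or 1, which no health survey resembles.
* **Census weights.** Gamma-distributed positive weights with
  configurable dispersion (0 gives exactly equal weights), normalised
  to person counts or proportions.

All generator randomness flows from one root seed with a named
substream per operation, so individual components can be regenerated
independently.

What passing tests on these data do **not** show: the generator has no
cluster sampling (the model deliberately omits clustering too, so
model-based intervals understate design effects), missingness is MCAR
rather than whatever drives real item nonresponse, and the joint
distribution of occupation by region/urbanicity is exchangeable rather
than realistic.  Conclusions about real surveys therefore rest on the
model, not on any claimed realism of the generator.

## Problem sizes and numerical choices

Study-scale fits in the test suite and the acceptance script use 2
chains × 2500 iterations (1000 burn-in) on the full 1760-cell
classification — about 20 seconds per fit — which keeps split R-hat
near 1 for this model while leaving the calibration study (four
replicate surveys) comfortably fast; production analyses should use
the 4-chain default and more iterations.  The coverage check pools
four replicates and compares the mean against 0.95 with a 99% band
from the between-replicate spread (floored at the pooled binomial
standard error).  The grid oracle uses 4001/801/121 points per
dimension for 1/2/3 free parameters.  Waist values are rounded to
0.1 cm and clipped to a plausibility range of 30–250 cm (clipping
never crosses a cutoff, so obesity status is preserved).

## Known limitations

* No survey-design variance: clustering and unequal selection beyond
  the modelled factors are ignored by construction.
* Single imputation; imputation uncertainty is not propagated.
* The sampler is specialised to this model family (binomial-logit with
  Gaussian effect hierarchy); it is not a general-purpose PPL.
* `summarize_run` emits tables only; plotting is left to the caller.
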
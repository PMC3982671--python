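# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The accounting model

Helping is evaluated with Hamilton's condition *rb > c*, with all three
terms expressed in **male genetic equivalents**: recruits weighted by the
relatedness linking them to the focal bird. Only males are counted because
female fledglings mostly disperse out of any study area, so male recruitment
is the component of reproductive success that can be measured exhaustively.
Effects are tracked one year ahead only (the species is short-lived and no
longer-range effects are assumed).

Benefit pathways per helper:

1. *Current brood*: the recruitment model (below) gives the per-fledgling
   marginal effect of a helper, ∂p/∂helpers; multiplying by mean brood size
   (8.9 fledglings) and brood sex ratio (0.53 male) gives male recruits per
   helper; weighting by helper-to-brood relatedness r_h−b gives genetic
   equivalents.
2. *Male breeder*: load-lightening raises helped males' annual survival
   (0.43 → 0.52 at the modal brood size); dividing the difference by the
   mean number of helpers at helped nests (1.8) gives a per-helper survival
   effect, which is chained through the annual probability that a pair
   produces a male recruit (0.26) and the breeder-to-own-brood relatedness
   (0.48, below 0.5 because of extra-pair paternity), then weighted by
   helper-to-male-breeder relatedness r_h−m. Female breeders show no
   survival response, so that pathway carries a zero benefit and is only
   reported.

Cost: the helper's own survival loss, chained through the same
0.26 × 0.48 conversion and weighted by the helper's relatedness to self (1).

### Precision conventions

Chained summary values are reported under two conventions. `full` keeps
machine precision throughout. `printed` rounds each intermediate half-up to
conventional reporting precision before the next step; this is the
convention under which a chain of published roundings (e.g.
8.9 × 0.53 × 0.062 = 0.292; 0.292 × 0.16 = 0.0467) reproduces exactly.
Rounding is half away from zero (`round_half_up`), applied only at the
reporting layer; analyses keep full precision internally.

## Relatedness estimation

The Queller–Goodnight moment estimator: for focal *x* = (a, b) and partner
*y* = (c, d) at a locus with allele frequencies *p*,

    num = ½(S_ac + S_ad + S_bc + S_bd) − p_a − p_b
    den = 1 + S_ab − p_a − p_b.

Numerical choices:

- **Multilocus combination** is ratio-of-sums (Σnum / Σden per direction),
  not the mean of per-locus ratios; low-information loci (den near 0) are
  thereby weighted by the information they carry rather than destabilizing
  the estimate.
- **Symmetrization** averages the two directed multilocus ratios. If exactly
  one direction has a zero denominator the other is returned; both zero is
  an `UndefinedRelatednessError`.
- **Missing data**: loci missing in either member are skipped; a pair with
  no co-typed locus is an error.
- **Reference frequencies** are counted over all genotyped individuals
  including the focal pair (the common whole-sample convention); an
  exclude-pair correction is available (`exclude_pair=True`), as is a
  delete-one-locus jackknife s.e. (`jackknife_se_over_loci`). Default
  summary standard errors are plain over-assignments s.e.
- Helpers observed provisioning a nest only once are excluded
  (`min_visits=2`); relatedness to the brood is the mean of pairwise values
  over genotyped brood members; components with missing genotypes are
  dropped per component, so attained n can differ between the male-breeder,
  female-breeder and brood summaries. If every assignment is filtered out
  the summary is returned with n = 0 per component; only a helper table
  with no rows at all is an error.

Calibration (tested): over ≥5,000 simulated dyads at 19 loci with 8-allele
Dirichlet(1) frequencies, mean estimates are within ±0.02 of the pedigree
expectations 0 / 0.25 / 0.5, and self-comparisons return exactly 1.

## Recruitment model

A logit-link binomial model of fledgling recruitment on sex and helper
number with crossed random intercepts for year and natal nest. Fitting
contract: `method='mixed'` uses a variational Bayes approximation of the
crossed-random-intercept model (statsmodels `BinomialBayesMixedGLM`);
`'fixed'` is a plain logistic GLM; `'auto'` (default) tries the mixed fit
and falls back, flagged, to the fixed fit. The mixed fit's fixed-coefficient
covariance is the (diagonal) variational posterior covariance, which
slightly understates between-coefficient correlation; the fixed fit carries
the full ML covariance. Separation (|coefficient| > 15 or a perfect
separation condition) raises an error naming the covariate; a constant
outcome is rejected.

The marginal effect of a helper is the logistic derivative β_h·p(1−p),
evaluated either at a covariate point (default: male fledgling at 1.8
helpers, the mean at helped nests, which gives ≈0.063 for the study
coefficients) or averaged over the observed covariates; both schemes are
available because the evaluation point behind a reported single number is
generally a convention. The 95% CI is the 2.5/97.5 percentile of the same
quantity over multivariate-normal draws of the fixed coefficients (10,000
by default, seeded; variance components are not redrawn). Conversion to
male recruits multiplies by brood size and sex ratio; CI endpoints are
transformed identically from their unrounded values.

Validation (tested): data simulated at β = (−1.57, −0.99, 0.32) with
random-intercept sds of 0.1 recover β_h within ±0.1 at ~5,000 fledglings;
the 95% CI covers the generating β_h in ≥90% of 50 replicates at ~1,200
fledglings; the marginal effect equals the central-difference derivative of
the fitted curve to 1e−8.

## Survival effects and the quality mixture

Survival is the local return rate between breeding seasons (point
proportions; no mark-recapture detection model, since the inputs are
proportions). Failed breeders fall into three categories: those that helped,
those that had the opportunity (close kin with an active nest) but did not,
and those without an opportunity. Helping is self-selected for quality:
birds that spurn an opportunity are disproportionately low-quality, so the
decomposition assumes — explicitly, and the assumption is labelled in the
report — that no-opportunity birds share the quality composition of
opportunity birds. With p_low estimated as the spurn fraction among
opportunity birds, s_low as the decliners' survival and s_overall as the
no-opportunity survival,

    s_high = (s_overall − p_low·s_low) / (1 − p_low),

and the helping cost is s_helper − s_high (negative when costly). A result
outside [0, 1] raises an inconsistent-mixture error; recomposition
p_low·s_low + (1−p_low)·s_high = s_overall holds to 1e−12 by construction
and is property-tested. A positive cost (helping beneficial) is flagged
`non_altruistic` rather than rejected. The published 0.79 appears both as
an inferred and an input value; inference from (0.56, 0.42, 0.24) takes
precedence, with printed rounding applied for display.

A consistency check compares the survival cost:benefit ratio
(0.23/0.09 ≈ 2.56) with the provisioning feed ratio (a helper contributes
≈2.45 feeds per feed a breeder saves): the two should be of the same order
if survival consequences scale with workload.

Validation (tested): generator truth (p_low 0.42, s_low 0.24, s_high 0.79,
cost 0.23) is recovered within ±0.05 at 10,000 birds per category.

## Renesting and the opportunity cost

Per year, the renest-vs-terminate outcome of failed attempts is regressed
on failure date (logit link); the termination date is the 50% point
−intercept/slope with a delta-method s.e. Attempts failing before the
year's median first-attempt lay date are excluded — such early failures are
replaced almost deterministically and carry no information about season
end. Relative failure date = failure date − termination date + 100 (the
offset merely removes negative values; all analyses are invariant to it).
Group inflections (eventual helpers vs non-helpers) come from the same
logistic on relative date; the opportunity-cost test reports their
difference, pooled s.e., z and a verdict — a helper inflection
significantly below the non-helper inflection would mean helpers abandon
breeding early, i.e. forgo renesting opportunities.

Numerical choices: small annual samples make complete separation likely, so
fits fall back to a Jeffreys-prior (Firth) penalized logistic, implemented
by modified scoring (no penalized-logistic fitter with the Jeffreys penalty
is available in the installed stack); a fitted slope of the wrong sign
(renesting increasing with date) triggers a warning, not an error. Years
with constant outcomes are dropped from the pipeline-level analysis with a
warning. The delta-method s.e. is used throughout and labelled as such.

Validation (tested): known per-year termination dates are recovered with
MAE < 2 days at 200 attempts/year; groups generated with identical
inflections yield overlapping 95% intervals in ≥95% of 200 replicates; a
10-day generated shift is detected.

## The synthetic population

The generator emulates, at desk scale, the features the analyses rely on:

- exactly `n_pairs_per_year` socially monogamous pairs per year; nests fail
  with probability 0.72 (predation); successful broods are truncated-Poisson
  around 8.9 fledglings (range 1–12; only mean and mode are known, so a
  truncated Poisson is the least-structured choice), sex ratio 0.53 male;
- **pedigree dynamics**: adults return with probability 0.55; male
  fledglings recruit locally with probability 0.30 (male philopatry);
  female turnover is kept at ≥50% immigrants per year (female-biased
  dispersal), which is what makes kin networks run through males. Pairing
  is random with first-order inbreeding avoidance;
- **genotypes**: 19 microsatellite loci, 8 alleles each, frequencies drawn
  from a symmetric Dirichlet(1) (allele counts are not published; this is a
  typical microsatellite diversity and is configurable); founders draw from
  the locus frequencies, everyone else inherits one uniformly chosen allele
  per parent per locus; optional per-call missingness;
- **helping**: one member of each late-failing pair (failure within 40 days
  of the year's termination date) is the candidate redirected carer — the
  male with probability 0.85, matching the male bias of helping. Candidates
  carry a latent quality class (low with probability 0.42). The pair's kin
  network (relatedness ≥ 0.125 to an active nest's breeder, i.e. kin up to
  second order) defines the opportunity; high-quality candidates with an
  opportunity help, low-quality candidates spurn it — this is the
  self-selection that the quality-mixture analysis unpicks. Recipients are
  chosen among all active broods with odds multiplied by 25 for kin nests
  (the species shows strong experimental kin preference), so some helpers
  end up at non-kin nests, as observed. A configurable fraction (0.1) of
  helpers get a single recorded visit to exercise the downstream filter;
- **recruitment**: per fledgling, Bernoulli with logit β₀ + β_f·female +
  β_h·helpers + u_year + u_nest, β = (−1.57, −0.99, 0.32), random
  intercepts Gaussian with sd 0.3 (unknown in the field data; 0.3 is a
  moderate grouping effect), shared within year and nest;
- **survival**: low-quality birds survive at 0.24, high-quality at 0.79,
  minus a 0.23 helping cost for high-quality helpers (clamped at 0 with a
  warning if a configuration drives it negative);
- **renesting**: renest probability logit⁻¹(0.15·(T_year − failure date)),
  identical for eventual helpers and non-helpers, with per-year termination
  dates T defaulting to mid-season values varying ±4 days across years.

One global seed spawns an independent stream per stage (pedigree,
genotypes, helping, recruitment, survival), so a stage can be regenerated
alone; identical config + seed reproduces the dataset exactly.

Targeted generators (`simulate_dyads`, `simulate_recruitment_table`,
`simulate_survival_table`, `simulate_attempts_table`) draw directly from
each analysis's generating model at arbitrary sample size; they are the
harness for the parameter-recovery validation above, at the problem sizes
stated there (5,000 dyads; ~5,000 and ~1,200 fledglings; 10,000 birds per
category; 200–800 attempts per year).

### What the generator does not emulate

No spatially explicit ranging, winter flocks, vocal kin recognition,
predator behaviour or weather-driven season length; no renest attempts as
separate nest records (renesting enters only as the decision outcome); the
pedigree-stage recruitment used to build next year's breeding pool is a
separate realization from the recruitment analysis table. The synthetic
pedigree is kin-sparser than the field population (which accumulates
extended families over decades and receives helpers from outside the
mapped area), so at the defaults roughly a third of successful broods are
helped with ~1.4 helpers per helped nest, below the field values of ~half
and 1.8; density is configurable and none of the recovery tests depend on
it. Passing tests therefore demonstrate that the estimators recover known
generating parameters under the study's statistical structure — not that
field data would yield the published point values.

## Known limitations

- The mixed-model CI uses a diagonal variational posterior covariance;
  where CI fidelity matters more than the variance decomposition, use the
  fixed-effects fit, whose ML covariance is exact.
- The quality mixture is identified only through its stated composition
  assumption; how the low-quality fraction was defined in the field
  (per bird vs per opportunity) is unknowable from summaries, and the
  package estimates it per candidate-year.
- Survival is a return rate: permanent emigration is confounded with death,
  as in the source proportions.
- The female-breeder pathway carries no benefit term by construction; it is
  reported with its relatedness only.
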
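# Methods

This note documents the models, the numerical choices and the synthetic-data
generator behind `droughtdemog`, and what the package's validation does and
does not demonstrate.

## Survival model

Infant survival is a counting-process Cox model on the age-in-months time
axis. Person-month interval *m* of an infant spans ages (*m*−1, *m*] and
closes on the calendar date `birth + m months` (day-of-month clamped to
month end). Intervals run from birth to the species' minimum weaning age —
14 months for capuchins, 19 for spider monkeys — which also defines the
censoring horizon: infants alive at weaning age are censored there. An
infant that disappears alone before weaning age is treated as having died
(these species do not disperse that young); an infant that disappears
together with its mother is censored at the last sighting, because its fate
is unknown. A death at fractional age *a* is assigned to interval ⌈*a*⌉; a
censoring at fractional age keeps only the completed intervals, which is
inconsequential for the partial likelihood because a partially observed
interval is never in any risk set on the monthly grid.

Shared frailty is Gaussian on the log hazard (equivalently log-normal
multiplicative frailty), iid within each grouping factor (mother identity,
hydro-year). Estimation is penalized partial likelihood: an inner Newton
iteration maximizes the Efron-tied partial likelihood penalized by the
Gaussian prior jointly in (β, b) to a gradient norm of 1e-8 (at most 100
iterations, with step halving), and an outer Nelder-Mead maximizes the
Laplace-approximated integrated partial likelihood

  ILL(θ) = ℓ(β̂, b̂) − ½ b̂'Σ(θ)⁻¹b̂ − ½ log|Σ(θ)| − ½ log|H_bb|

over the log variance components (simplex tolerance 0.02 on log-variances).
A variance estimate below 1e-4 is reported as 0 with a boundary flag.
Standard errors come from the β block of the inverse penalized observed
information. Efron's tie correction is the default because the monthly age
grid produces heavily tied event times; the Efron sums over tied deaths are
accumulated in closed form (a fixed number of rank-one updates per event
time), so fitting cost does not grow with tie multiplicity. Breslow ties
are retained for cross-implementation comparisons. With no frailty terms
the same code path reproduces an ordinary Cox fit, verified against an
independent reference implementation to |Δβ| < 1e-6.

Models whose binary covariate has zero events in one condition are excluded
before fitting: their likelihood is monotone in that coefficient and no
finite maximizer exists. The fitter also flags non-convergence if any |β|
exceeds 12 during iteration.

Survival prediction uses the Breslow baseline cumulative hazard evaluated
at b = 0, S(t|x) = exp(−Λ₀(t)·e^{x'β}), with a Wald band on the cumulative
hazard combining the natural (Poisson-type) variance of the Breslow
increments with the delta-method contribution of β̂.

## Infanticide risk

Capuchin person-months are classified high-risk when (i) an alpha-male
replacement in the natal group occurred after the infant's estimated
conception — gestation is 5.5 months, implemented deterministically as
birth − 5 months − 15 days — and on or before the interval's closing date,
and (ii) the infant is under 12 months old at evaluation. Condition "on or
before the closing date" enforces causality: a replacement cannot raise
risk before it happens. Replacements are tenure starts after a group's
first recorded tenure. Spider monkey analyses carry no risk term.

## Environmental covariates

SPEI: monthly water balance D = P − PET, with PET from the
temperature-only Hargreaves equation (constant 0.0023; extraterrestrial
radiation from the standard solar-geometry formulas, averaged over the days
of each month, in evaporation-equivalent mm). For scale k, the trailing
k-month sums are fitted with a three-parameter log-logistic by unbiased
probability-weighted moments **separately for each calendar month**, so
SPEI measures anomalies relative to the month's own climatology and dry
seasons are not systematically "droughts". Cumulative probabilities map to
z-scores by the classical rational approximation of the normal quantile
(max error ~4.5e-4). Two numerical conventions: samples whose skew
conflicts with the log-logistic's support orientation are fitted mirrored
(fit −X, negate z) — the moment-matched distribution is identical to a
generalized-logistic fit with the opposite-signed shape; and values outside
the fitted support are floored at machine epsilon, giving |z| ≈ 8.2. Such
saturation arises only when a calibration sample contains an extreme
outlier relative to its size (e.g. a severe drought inside a short record);
with a 40-year calibration the standardization is clean (per-series mean
within 0.05 of 0 and sd within 0.05 of 1). Rank-based downstream uses
(extreme-decile flags) are unaffected by the saturation.

Fruit biomass: per species-month availability is the mean 0–4 phenology
score of *living* monitored trees divided by 4; landscape biomass is
Σ_species density × species crop mass × availability. Species densities are
fixed for the whole series (tree deaths do not reduce them), which, as a
consequence, overestimates availability after mortality waves — a
deliberate convention carried over from how such series are constructed in
the field. Unmonitored species-months are imputed by the species'
calendar-month mean and flagged.

Windows: monthly series are expanded to daily resolution by linear
interpolation anchored on the 1st of each month (the anchor day is
configurable; field series rarely record the within-month observation day).
For an interval closing at date c, `fruit_mean_k` is the mean of the daily
series over (c − k months, c], and `spei_k` is the k-month SPEI
interpolated to c (SPEI is already integrative, so no further averaging).
Extreme flags mark values at or beyond the type-7 empirical 10th/90th
percentiles of the covariate's **full monthly series** (not the realized
person-month sample, so thresholds do not depend on cohort composition;
computing them over the person-month sample is available as an option).
Closed inequalities at the thresholds. Rows with any missing covariate are
dropped listwise.

## Model set and averaging

Per species: one null model, one per single environmental variable, and all
one-fruit × one-drought pairs (100 specifications for 9 + 9 variables).
Capuchin models always contain the infanticide-risk term. Continuous terms
are z-scored (ddof = 1) over the analysis rows, with metadata retained for
back-transformation. AICc uses the Laplace integrated log-likelihood with
k = #fixed coefficients + #variance components and n = number of events —
the standard effective sample size for Cox partial likelihoods; both
choices are conventions (alternatives differ only in the small-sample
correction term) and are documented rather than configurable silently.
Akaike weights follow from ΔAICc; averaging is **conditional** (weights
renormalized over the models containing each term) with unconditional
standard errors per Burnham–Anderson and Wald intervals at 80/95/99%.
Collinearity among paired variables is screened by VIF over the analysis
rows.

## Tree mortality

Tree biographies derive from the phenology records; a death is dated to the
month after the last visible sign of life, and each dead tree is replaced
by a new tree of the same species the following month. Species-month rows
(at-risk counts entering the month, deaths dated to it) keep species
identifiable as a grouping factor. Annual mortality is deaths per unique
trees monitored in the hydro-year. The GLMM has logit link, fixed intercept
and one climate slope, random species intercepts and slopes with a full
2×2 covariance (diagonal optional), random hydro-year intercepts, and a
Laplace-approximated marginal likelihood (crossed random effects preclude
quadrature); the outer optimizer works on Cholesky-parameterized
covariances, clamped to keep proposals invertible. AICc for these models
uses n = species-month rows. Replacement trees are not a random sample of
the landscape (they are chosen as fruiting-capable adults); no correction
is attempted.

## Synthetic-data generator

The generator emulates the study system's conditions: ~1708 mm normal
annual rainfall concentrated in a May–November wet season, severe-drought
hydro-years at ~661 mm, a hydro-year starting 15 May at latitude 10.84° N;
capuchin gestation 5.5 months / weaning 14 / mean interbirth 26 months and
spider monkey 7.5 / 19 / 35; ~250 monitored trees with monthly death
probability logistic in the 12-month SPEI; alpha replacements as a Poisson
process (default one per three years per group). Wet-season rain is
gamma-distributed on wet days and each hydro-year is rescaled to its target
within a few percent. Interbirth intervals are gamma-distributed around the
species mean (their true distribution is not published; the mean is the
only anchored quantity). Mothers disappear at a small monthly probability
(0.003), jointly censoring their current infant — exercising the
joint-disappearance censoring rule.

The monthly death indicator is drawn from the complementary log-log hazard
h = 1 − exp(−exp(η)) with η = log-baseline + β_risk·I(low risk) +
β_drought·I(SPEI-12 bottom decile) + β_fruit·z(12-month fruit mean) +
b_mother + b_year. Under this mechanism each configured β is exactly a log
hazard ratio in continuous time, so the Cox stage's estimand equals the
configured value — parameter recovery is a sharp test. Crucially, the
covariates entering η are computed with the same windowing, interpolation
and threshold code the analysis pipeline uses, so generator and analysis
agree row-for-row on the covariates (asserted exactly in the tests). The
one exception is the fruit z-score: the generator standardizes against the
monthly reference series while the analysis z-scores over person-month
rows; the two standard deviations differ by a few percent, a small known
attenuation accepted for the per-SD fruit effect. Default frailty standard
deviations are 0.5 on the log hazard for both mother and hydro-year —
moderate clustering of the kind mixed-effects survival models are built
for. Ground truth (frailty draws, per-month hazards and covariate states)
is written to sidecar tables so tests never read truth through the
analysis path.

What the generator does not emulate: observer-effort gaps beyond the
censoring probability, within-month timing of deaths, spatial structure
(all groups share one landscape series), birth seasonality, and
density-dependence or maternal condition effects on birth spacing. Passing
recovery tests therefore demonstrates the correctness of the estimation
machinery under the stated model, not robustness to the many ways real
field data violate it.

## Validation scales

The recovery experiments fit cohorts of ≥300 infants (70–95 mothers over 15
simulated years, ~75–110 deaths per cohort) across 50 replicates in the
test suite; the acceptance script uses 250 replicates for the
drought-effect design, whose per-replicate estimate is the noisiest (the
drought indicator is clustered within the single drought hydro-year and
competes with the year frailty, giving a log-HR spread of ~0.4 per
replicate and a corresponding upward Jensen offset of the cross-replicate
mean hazard ratio of several percent). Selection-consistency experiments
run the full 100-model set on 5 replicate cohorts of ~260 infants and the
tree-GLMM scale comparison on 5 replicates of ~220 trees over 12 years.
These sizes were chosen to keep each experiment's Monte Carlo error well
inside the tolerances it is checked against.

## Known limitations

- The Laplace approximation can bias variance components at few levels per
  factor (here ~12–15 hydro-years); fixed-effect hazard ratios are far less
  affected, which the recovery tests confirm.
- The fruit-biomass formula (density × species crop mass × normalized
  score) is a structural reconstruction of how such series are built from
  transects and phenology; species crop-mass constants are synthetic, so
  the biomass stage is validated structurally (linearity, conservation,
  living-trees-only), not against field biomass values.
- AICc's (k, n) conventions for mixed survival models are not settled;
  rankings could shift slightly under alternatives (n = subjects or rows).
- The SPEI saturation behaviour for out-of-support values (|z| ≈ 8.2) is a
  property of the classical construction on short calibration records, kept
  deliberately for fidelity to the reference procedure.
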
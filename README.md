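# droughtdemog

Survival analysis of drought- and food-driven infant mortality in wild
primate populations, built as a reusable, fully tested pipeline: from raw
daily weather and monthly tree-phenology records, through drought-index and
fruit-biomass covariate construction, to time-varying Cox proportional
hazards models with shared frailty terms, AICc multimodel inference, and
binomial mixed models of fruit-tree mortality.

## Who this is for

Field demographers and behavioural ecologists with long-term individual
life-history data (births, disappearances, deaths), station weather records
and resource-phenology monitoring, who want to relate monthly mortality risk
to time-varying environmental conditions. Because such datasets are rarely
shareable, the package ships a synthetic-data generator that emulates all
raw inputs with configurable, known ground truth, so every stage of the
pipeline is testable end to end without field data.

## The model

Infant survival is analysed on a monthly grid aligned to each infant's birth:
interval *m* covers ages (*m*−1, *m*] months, up to the species' minimum
weaning age (14 months for white-faced capuchins, 19 for Geoffroy's spider
monkeys). Each person-month row carries time-varying covariates evaluated in
windows ending on the interval's closing date:

- **SPEI** (Standardized Precipitation-Evapotranspiration Index) at 1-, 6-
  and 12-month scales, built from daily rain and temperature records via
  Hargreaves potential evapotranspiration, a trailing-window water balance
  D = P − PET, a per-calendar-month log-logistic fit by unbiased
  probability-weighted moments, and normal-score standardization;
- **ripe fruit biomass** (kg/ha), the density-weighted sum over species of
  normalized mean phenology scores of living monitored trees, averaged
  daily over the trailing 1/6/12 months;
- **extreme-decile indicators** (top/bottom 10% of each covariate's full
  series) capturing threshold responses such as severe drought;
- a binary **infanticide-risk** state for capuchins: high if an alpha-male
  replacement occurred after the infant's estimated conception and the
  infant is under one year old.

The hazard model is a counting-process Cox partial likelihood with Gaussian
shared frailty (log-normal multiplicative effects) for mother identity and
hydro-year (the 12 months starting 15 May):

    h_i(t) = h_0(t) exp(x_i(t)'β + b_mother(i) + b_year(i,t)),
    b_f ~ N(0, σ_f²)

fitted by penalized partial likelihood with a Laplace-approximated
integrated likelihood over the variance components (Efron ties). Candidate
models (null, single-variable, and one-fruit × one-drought pairs — 100
specifications for the full 9 + 9 variable set) are ranked by AICc and
summarized by conditional model averaging with 80/95/99% confidence
intervals. Tree mortality is modelled with binomial GLMMs (random species
intercepts and slopes, random hydro-year intercepts, Laplace approximation).

## Worked example

```python
import numpy as np
from droughtdemog import (SimulationConfig, simulate_dataset,
                          build_analysis_table, fit_cox_frailty)

# a 15-year study, one severe-drought hydro-year, known hazard parameters:
# low infanticide risk multiplies the monthly hazard by 0.237, a 12-month
# extreme-drought state multiplies it by 2.98
cfg = SimulationConfig(seed=3, drought_years={2012})
data = simulate_dataset(cfg)

pm = build_analysis_table(data.biography, data.tenures, data.fruit_daily,
                          data.spei_monthly, "capuchin")
fit = fit_cox_frailty(pm, ["risk_low", "spei_lo_12"])
print(f"infants {pm['individual_id'].nunique()}, events {fit.n_events_}")
print(fit.hazard_ratios()[["hr", "hr_lo_95", "hr_hi_95"]].round(3))
print({k: round(v, 3) for k, v in fit.variance_components_.items()})
```

Output:

```
infants 334, events 74
               hr  hr_lo_95  hr_hi_95
risk_low    0.342     0.187     0.628
spei_lo_12  1.807     0.721     4.529
{'mother_id': 0.327, 'hydro_year': 0.26}
```

One simulated cohort of 334 infants produced 74 deaths. The fitted hazard
ratios estimate the configured effects: low infanticide risk is associated
with roughly a three-fold reduction in death hazard (HR 0.34, truth 0.237),
and a 12-month extreme-drought state with an HR of 1.8 in this particular
replicate (truth 2.98 — single-replicate estimates of strongly
year-clustered effects are noisy, which is why validation averages over
many replicates; at 50 replicates the means land within a few percent of
truth). The variance components are the estimated mother-identity and
hydro-year frailty variances on the log-hazard scale (truth 0.25 each).

A command-line interface mirrors the library
(`droughtdemog simulate|spei|biomass|fit|run-all`), e.g.:

```bash
droughtdemog simulate --out raw/ --seed 1
droughtdemog spei --daily raw/climate.csv --lat 10.84 --out spei.csv
```

## Layout

- `src/droughtdemog/climate.py` — monthly water balance, Hargreaves PET, SPEI.
- `src/droughtdemog/biomass.py` — transect densities, monthly fruit biomass.
- `src/droughtdemog/prep.py` — person-month table, windows, extremes, risk rule.
- `src/droughtdemog/cox.py` — `CoxPHFrailty` estimator (partial likelihood,
  frailty, hazard ratios, survival prediction).
- `src/droughtdemog/selection.py` — model enumeration, AICc, weights, VIF,
  conditional averaging.
- `src/droughtdemog/glmm.py`, `trees.py` — tree mortality counts, rates and GLMMs.
- `src/droughtdemog/simulate.py` — the synthetic-data generator.
- `src/droughtdemog/experiments.py` — parameter-recovery and selection
  experiments.
- `src/droughtdemog/pipeline.py`, `cli.py` — orchestration and CLI.

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
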
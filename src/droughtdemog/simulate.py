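"""Synthetic field-data generator with known ground truth.

Emulates the five raw inputs of the analysis pipeline - daily station
weather, monthly tree phenology, botanical transects, individual
biographies and alpha-male tenures - for a seasonally dry tropical forest
site with rare severe-drought years.  All downstream stages can therefore
be exercised and validated against configured parameters without access to
field data.

The infant-mortality mechanism is a complementary log-log monthly hazard

    h = 1 - exp(-exp(eta)),
    eta = log_baseline + beta_low_risk * I(low infanticide risk)
          + beta_extreme_drought * I(12-month SPEI in bottom decile)
          + beta_fruit_z * z(12-month mean fruit biomass)
          + b_mother + b_hydro_year,

so each configured beta is, by construction, a log hazard ratio that the
Cox stage should recover.  The covariates entering eta are computed with
the *same* windowing, interpolation and threshold functions the analysis
pipeline uses, which makes parameter recovery a sharp end-to-end test.
Ground truth (frailty draws, per-month hazards) is returned in sidecar
tables separate from the "observed" CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from droughtdemog.biomass import monthly_biomass, species_density
from droughtdemog.climate import interpolate_daily, monthly_water_balance, spei
from droughtdemog.prep import (
    _monthly_reference_series,
    add_months,
    assign_hydro_year,
)

__all__ = [
    "SpeciesParams",
    "HazardParams",
    "TreeParams",
    "SimulationConfig",
    "generate_climate",
    "generate_phenology_and_trees",
    "generate_population",
    "simulate_dataset",
    "write_dataset",
    "SimulatedData",
]


@dataclass
class SpeciesParams:
    gestation_months: float
    min_weaning_age_months: int
    mean_interbirth_months: float


@dataclass
class HazardParams:
    """Ground-truth monthly-hazard parameters (log hazard-ratio scale)."""

    log_baseline_monthly_hazard: float = -3.0
    beta_low_risk: float = math.log(0.237)
    beta_extreme_drought: float = math.log(2.98)
    beta_fruit_z: float = 0.0
    sd_mother_frailty: float = 0.5
    sd_year_frailty: float = 0.5


@dataclass
class TreeParams:
    n_trees: int = 250
    n_species: int = 30
    logit_death_intercept: float = -5.85
    beta_spei12: float = -0.9
    transect_area_ha: float = 13.94


_DEFAULT_SPECIES = {
    "capuchin": SpeciesParams(5.5, 14, 26.0),
    "spider_monkey": SpeciesParams(7.5, 19, 35.0),
}


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic site.

    Annual rainfall targets (normal 1708 mm, drought 661 mm), latitude,
    hydro-year start, gestation/weaning/interbirth parameters and monitored
    tree-count scale all follow the study system the package models.
    """

    seed: int = 0
    n_years: int = 15
    start_year: int = 2005
    hydro_year_start: tuple = (5, 15)
    drought_years: frozenset = field(default_factory=frozenset)
    annual_rain_normal_mm: float = 1708.0
    annual_rain_drought_mm: float = 661.0
    rain_rel_tol: float = 0.10
    latitude_deg: float = 10.84
    species: tuple = ("capuchin",)
    n_mothers: int = 70
    n_groups: int = 4
    species_params: dict = field(default_factory=lambda: dict(_DEFAULT_SPECIES))
    hazard_params: HazardParams = field(default_factory=HazardParams)
    tree_params: TreeParams = field(default_factory=TreeParams)
    alpha_replacement_rate_per_year: float = 1.0 / 3.0
    mother_disappearance_monthly_prob: float = 0.003
    confirmed_death_prob: float = 0.7

    def __post_init__(self):
        if isinstance(self.hazard_params, dict):
            self.hazard_params = HazardParams(**self.hazard_params)
        if isinstance(self.tree_params, dict):
            self.tree_params = TreeParams(**self.tree_params)
        self.species_params = {
            k: (SpeciesParams(**v) if isinstance(v, dict) else v)
            for k, v in self.species_params.items()
        }
        self.drought_years = frozenset(self.drought_years)
        self.hydro_year_start = tuple(self.hydro_year_start)
        if self.annual_rain_drought_mm >= self.annual_rain_normal_mm:
            raise ValueError("drought rainfall target must be below the normal target")
        if min(self.annual_rain_drought_mm, self.annual_rain_normal_mm) <= 0:
            raise ValueError("rainfall targets must be positive")
        if self.n_years < 2:
            raise ValueError("need n_years >= 2")
        if self.hazard_params.sd_mother_frailty < 0 or self.hazard_params.sd_year_frailty < 0:
            raise ValueError("frailty standard deviations must be >= 0")
        labels = set(range(self.start_year, self.start_year + self.n_years))
        if not self.drought_years <= labels:
            raise ValueError(
                f"drought years {sorted(self.drought_years - labels)} outside the "
                f"simulated hydro-years {self.start_year}..{self.start_year + self.n_years - 1}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path):
        d = asdict(self)
        d["drought_years"] = sorted(self.drought_years)
        d["hydro_year_start"] = list(self.hydro_year_start)
        d["species"] = list(self.species)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# climate


def generate_climate(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily rainfall and temperature records.

    Wet-season (hydro-year start to mid-November) rain falls on
    gamma-distributed wet days; each complete hydro-year's total is then
    rescaled to its target (normal or drought) up to a few percent of
    noise, so totals land well inside the configured relative tolerance.
    Temperatures follow a smooth seasonal cycle with noise and always
    satisfy Tmax > Tmin.
    """
    start = pd.Timestamp(config.start_year - 1, 1, 1)
    end = pd.Timestamp(config.start_year + config.n_years, 12, 31)
    days = pd.date_range(start, end, freq="D")
    doy = days.dayofyear.to_numpy()

    hm, hd = config.hydro_year_start
    wet_start = (pd.Timestamp(2001, hm, hd).dayofyear)
    wet_end = pd.Timestamp(2001, 11, 15).dayofyear
    in_wet = (doy >= wet_start) & (doy <= wet_end)
    p_wet = np.where(in_wet, 0.55, 0.04)
    is_wet = rng.random(len(days)) < p_wet
    rain = np.where(is_wet, rng.gamma(0.9, 12.0, len(days)), 0.0)

    hydro = assign_hydro_year(days, start=config.hydro_year_start)
    labels = np.arange(config.start_year - 1, config.start_year + config.n_years)
    for label in labels:
        target = (
            config.annual_rain_drought_mm
            if label in config.drought_years
            else config.annual_rain_normal_mm
        )
        mask = hydro == label
        total = rain[mask].sum()
        if total <= 0:  # force at least a few wet days, then rescale
            idx = np.flatnonzero(mask & in_wet)[:5]
            rain[idx] = rng.gamma(0.9, 12.0, len(idx))
            total = rain[mask].sum()
        noise = 1.0 + rng.normal(0.0, 0.25) * config.rain_rel_tol
        noise = float(np.clip(noise, 1.0 - 0.6 * config.rain_rel_tol, 1.0 + 0.6 * config.rain_rel_tol))
        rain[mask] *= target * noise / total

    season = np.sin(2 * np.pi * (doy - 120) / 365.0)
    tmax = 33.0 + 2.0 * season + rng.normal(0.0, 1.0, len(days))
    trange = np.clip(9.0 + 2.0 * season + rng.normal(0.0, 0.7, len(days)), 2.0, None)
    tmin = tmax - trange
    return pd.DataFrame(
        {"date": days, "rain_mm": rain, "tmin_c": tmin, "tmax_c": tmax}
    )


# ---------------------------------------------------------------------------
# phenology, transects, tree mortality


def generate_phenology_and_trees(
    config: SimulationConfig,
    spei12: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly phenology rows (score 0-4, alive/dead) and a transect table.

    Per-month tree death is Bernoulli on the logit scale in the 12-month
    SPEI; a dead tree is replaced the following month by a new tree of the
    same species, keeping the monitored count constant.  Species fruiting
    is seasonal (species-specific peak month), so landscape biomass has the
    strong within-year structure the covariate windows expect.
    """
    tp = config.tree_params
    months = pd.period_range(
        pd.Period(f"{config.start_year}-01", "M"),
        pd.Period(f"{config.start_year + config.n_years}-12", "M"),
    )
    spp = [f"sp{i:02d}" for i in range(tp.n_species)]
    peak = rng.integers(0, 12, tp.n_species)
    amp = rng.uniform(1.0, 2.0, tp.n_species)

    tree_species = np.arange(tp.n_trees) % tp.n_species
    next_id = tp.n_trees
    tree_ids = np.arange(tp.n_trees)
    s = spei12.reindex(months)

    rows_tree, rows_species, rows_month, rows_score, rows_status = [], [], [], [], []
    for m in months:
        s_m = s[m] if np.isfinite(s[m]) else 0.0
        p_death = 1.0 / (1.0 + np.exp(-(tp.logit_death_intercept + tp.beta_spei12 * s_m)))
        dies = rng.random(tp.n_trees) < p_death
        mu = 2.0 + amp[tree_species] * np.sin(2 * np.pi * (m.month - 1 - peak[tree_species]) / 12.0)
        score = np.clip(np.round(mu + rng.normal(0.0, 0.8, tp.n_trees)), 0, 4).astype(int)
        rows_tree.append(tree_ids.copy())
        rows_species.append(tree_species.copy())
        rows_month.append(np.full(tp.n_trees, m))
        rows_score.append(np.where(dies, 0, score))
        rows_status.append(np.where(dies, "dead", "alive"))
        n_dead = int(dies.sum())
        if n_dead:  # replacements enter next month with fresh ids
            tree_ids = tree_ids.copy()
            tree_ids[dies] = np.arange(next_id, next_id + n_dead)
            next_id += n_dead
    phen = pd.DataFrame(
        {
            "tree_id": [f"t{i:05d}" for i in np.concatenate(rows_tree)],
            "species": [spp[i] for i in np.concatenate(rows_species)],
            "month": np.concatenate(rows_month),
            "fruit_score": np.concatenate(rows_score),
            "status": np.concatenate(rows_status),
        }
    )
    phen.loc[phen["status"] == "dead", "fruit_score"] = 0

    transects = pd.DataFrame(
        {
            "species": spp,
            "stems": rng.poisson(80, tp.n_species) + 1,
            "mean_fruit_mass_kg": np.exp(rng.normal(np.log(5.0), 0.5, tp.n_species)),
        }
    )
    return phen, transects


# ---------------------------------------------------------------------------
# population


@dataclass
class _Environment:
    fruit_daily: pd.Series
    fruit_csum: pd.Series
    spei_monthly: dict
    spei12_daily: pd.Series
    spei12_lo_threshold: float
    fruit12_ref_mean: float
    fruit12_ref_sd: float


def _build_environment(fruit_daily: pd.Series, spei_monthly: dict) -> _Environment:
    refs = _monthly_reference_series(fruit_daily, spei_monthly, (12,))
    spei12 = spei_monthly[12].dropna()
    return _Environment(
        fruit_daily=fruit_daily,
        fruit_csum=fruit_daily.cumsum(),
        spei_monthly=spei_monthly,
        spei12_daily=interpolate_daily(spei12, anchor_day=1),
        spei12_lo_threshold=float(np.quantile(spei12.to_numpy(), 0.10)),
        fruit12_ref_mean=float(np.mean(refs["fruit_mean_12"])),
        fruit12_ref_sd=float(np.std(refs["fruit_mean_12"], ddof=1)),
    )


def _alpha_tenures(
    config: SimulationConfig, start, end, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-group alpha tenures: replacements are a sparse Poisson process."""
    rows = []
    rate_per_day = config.alpha_replacement_rate_per_year / 365.25
    for g in range(config.n_groups):
        t = pd.Timestamp(start)
        male = 0
        starts = [t]
        while True:
            gap = rng.exponential(1.0 / rate_per_day)
            t = t + pd.Timedelta(days=float(gap))
            if t >= end:
                break
            starts.append(t)
        for i, s in enumerate(starts):
            rows.append(
                {
                    "group_id": f"g{g}",
                    "male_id": f"g{g}m{i}",
                    "start_date": s,
                    "end_date": starts[i + 1] if i + 1 < len(starts) else pd.NaT,
                }
            )
    return pd.DataFrame(rows)


def generate_population(
    config: SimulationConfig,
    env: _Environment,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Biographies, alpha tenures and ground-truth sidecars.

    Births follow a per-mother renewal process with the species' mean
    interbirth interval; each infant-month death indicator is drawn from
    the complementary log-log hazard; mothers disappear (censoring their
    current infant jointly) as a rare monthly event.
    """
    sim_start = env.fruit_daily.index[0]
    sim_end = env.fruit_daily.index[-1]
    birth_start = pd.Timestamp(sim_start.year + 1, 1, 1)

    hp = config.hazard_params
    bio_rows, truth_rows, frailty_rows = [], [], []
    tenures = _alpha_tenures(config, sim_start - pd.Timedelta(days=400), sim_end, rng)
    ten_by_group = {
        g: np.sort(grp["start_date"].to_numpy())
        for g, grp in tenures.groupby("group_id")
    }

    year_labels = np.arange(sim_start.year - 1, sim_end.year + 1)

    for species in config.species:
        sp = config.species_params[species]
        weaning = int(sp.min_weaning_age_months)
        birth_end = add_months(sim_end, -(weaning + 1))
        b_year = dict(
            zip(year_labels, rng.normal(0.0, hp.sd_year_frailty, len(year_labels)))
        )
        for y, b in b_year.items():
            frailty_rows.append(
                {"species": species, "factor": "hydro_year", "level": y, "value": b}
            )
        n_groups = config.n_groups if species == "capuchin" else 1
        infant_counter = 0
        for i in range(config.n_mothers):
            mother_id = f"{species[:3]}_M{i:04d}"
            group = f"g{i % n_groups}"
            b_mother = rng.normal(0.0, hp.sd_mother_frailty)
            frailty_rows.append(
                {
                    "species": species,
                    "factor": "mother_id",
                    "level": mother_id,
                    "value": b_mother,
                }
            )
            # mother disappearance time (months from birth_start)
            if config.mother_disappearance_monthly_prob > 0:
                gone_after = rng.geometric(config.mother_disappearance_monthly_prob)
            else:
                gone_after = np.inf
            mother_gone = (
                add_months(birth_start, int(gone_after))
                if np.isfinite(gone_after) and int(gone_after) < 10000
                else pd.NaT
            )
            if pd.notna(mother_gone) and mother_gone > sim_end:
                mother_gone = pd.NaT

            t = birth_start + pd.Timedelta(
                days=float(rng.uniform(0, sp.mean_interbirth_months * 30.44))
            )
            births = []
            while t <= birth_end:
                births.append(t)
                gap = max(
                    sp.gestation_months + 2.0,
                    rng.gamma(10.0, sp.mean_interbirth_months / 10.0),
                )
                t = t + pd.Timedelta(days=float(gap * 30.44))
            replacements = ten_by_group[group]

            for birth in births:
                if pd.notna(mother_gone) and birth >= mother_gone:
                    break
                infant_id = f"{species[:3]}_I{infant_counter:05d}"
                infant_counter += 1
                closes = [add_months(birth, m) for m in range(1, weaning + 1)]
                closes_idx = pd.DatetimeIndex(closes)
                spei12_at = env.spei12_daily.reindex(closes_idx).to_numpy()
                drought = (spei12_at <= env.spei12_lo_threshold).astype(float)
                csum = env.fruit_csum
                starts = pd.DatetimeIndex([add_months(c, -12) for c in closes])
                fruit12 = (
                    csum.reindex(closes_idx).to_numpy() - csum.reindex(starts).to_numpy()
                ) / (closes_idx - starts).days.to_numpy()
                fruit_z = (fruit12 - env.fruit12_ref_mean) / env.fruit12_ref_sd
                years = assign_hydro_year(closes_idx, start=config.hydro_year_start)
                by = np.array([b_year[y] for y in years])

                if species == "capuchin":
                    # first replacement after the estimated conception
                    whole = int(math.floor(sp.gestation_months))
                    frac = 15 if sp.gestation_months != whole else 0
                    conception = add_months(birth, -whole) - pd.Timedelta(days=frac)
                    pos = np.searchsorted(replacements, np.datetime64(conception), side="right")
                    first_rep = replacements[pos] if pos < len(replacements) else None
                    ages = np.arange(1, weaning + 1)
                    high = np.zeros(weaning, dtype=bool)
                    if first_rep is not None:
                        high = (closes_idx.to_numpy() >= first_rep) & (ages < 12)
                    low = ~high
                else:
                    low = np.ones(weaning, dtype=bool)

                eta = (
                    hp.log_baseline_monthly_hazard
                    + hp.beta_low_risk * low.astype(float) * (species == "capuchin")
                    + hp.beta_extreme_drought * np.nan_to_num(drought)
                    + hp.beta_fruit_z * np.nan_to_num(fruit_z)
                    + b_mother
                    + by
                )
                h = 1.0 - np.exp(-np.exp(eta))
                if not ((h > 0.0) & (h < 1.0)).all():
                    raise FloatingPointError("monthly hazard outside (0, 1)")
                u = rng.random(weaning)
                death_month = int(np.argmax(u < h)) + 1 if (u < h).any() else None

                # joint mother-infant disappearance truncates observation at
                # the mother's last sighting; only completed age-months of
                # the infant remain observable
                censored_jointly = pd.notna(mother_gone) and mother_gone <= closes[-1]
                n_complete = (
                    sum(c <= mother_gone for c in closes) if censored_jointly else None
                )
                if censored_jointly and (
                    death_month is None or n_complete < death_month
                ):
                    depart = mother_gone
                    dep_type, event = "disappearance_unknown", 0
                    n_obs = n_complete
                elif death_month is not None:
                    depart = closes[death_month - 1]
                    confirmed = rng.random() < config.confirmed_death_prob
                    dep_type = "death" if confirmed else "disappearance_unknown"
                    event = 1
                    n_obs = death_month
                else:
                    depart = sim_end
                    dep_type, event = "censored_alive", 0
                    n_obs = weaning

                bio_rows.append(
                    {
                        "individual_id": infant_id,
                        "species": species,
                        "sex": "f" if rng.random() < 0.5 else "m",
                        "mother_id": mother_id,
                        "group_id": group,
                        "birth_date": birth,
                        "entry_type": "birth",
                        "departure_type": dep_type,
                        "departure_date": depart,
                        "last_seen_date": depart,
                    }
                )
                for m in range(1, n_obs + 1):
                    truth_rows.append(
                        {
                            "individual_id": infant_id,
                            "species": species,
                            "interval_index": m,
                            "hazard": h[m - 1],
                            "eta": eta[m - 1],
                            "low_risk": bool(low[m - 1]),
                            "extreme_drought": bool(drought[m - 1]),
                            "fruit_z": fruit_z[m - 1],
                            "event": int(event and m == n_obs),
                        }
                    )
            # mother's own biography row (for joint-disappearance handling)
            bio_rows.append(
                {
                    "individual_id": mother_id,
                    "species": species,
                    "sex": "f",
                    "mother_id": None,
                    "group_id": group,
                    "birth_date": pd.NaT,
                    "entry_type": "start_of_observation",
                    "departure_type": (
                        "disappearance_unknown" if pd.notna(mother_gone) else "censored_alive"
                    ),
                    "departure_date": mother_gone if pd.notna(mother_gone) else sim_end,
                    "last_seen_date": mother_gone if pd.notna(mother_gone) else sim_end,
                }
            )

    bio_cols = [
        "individual_id",
        "species",
        "sex",
        "mother_id",
        "group_id",
        "birth_date",
        "entry_type",
        "departure_type",
        "departure_date",
        "last_seen_date",
    ]
    biography = pd.DataFrame(bio_rows, columns=bio_cols)
    dupes = biography.groupby("mother_id")["species"].nunique()
    if (dupes > 1).any():
        raise ValueError("mother id reused across species")
    truth = pd.DataFrame(truth_rows)
    frailties = pd.DataFrame(frailty_rows)
    return biography, tenures, truth, frailties


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedData:
    """Bundle of generated raw tables plus derived environmental series."""

    config: SimulationConfig
    climate: pd.DataFrame
    phenology: pd.DataFrame
    transects: pd.DataFrame
    biography: pd.DataFrame
    tenures: pd.DataFrame
    truth_person_months: pd.DataFrame
    truth_frailties: pd.DataFrame
    water_balance: pd.DataFrame
    spei_monthly: dict
    fruit_monthly: pd.DataFrame
    fruit_daily: pd.Series


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Generate the full raw-data bundle for one simulated study."""
    rng = np.random.default_rng(config.seed)
    climate = generate_climate(config, rng)
    wb = monthly_water_balance(climate, config.latitude_deg)
    spei_monthly = {k: spei(wb["d_mm"], k) for k in (1, 6, 12)}
    phen, transects = generate_phenology_and_trees(config, spei_monthly[12], rng)
    dens = species_density(
        transects, config.tree_params.transect_area_ha
    )
    fruit = monthly_biomass(phen, dens)
    fruit_daily = interpolate_daily(fruit["biomass_kg_per_ha"], anchor_day=1)
    env = _build_environment(fruit_daily, spei_monthly)
    biography, tenures, truth, frailties = generate_population(config, env, rng)
    return SimulatedData(
        config=config,
        climate=climate,
        phenology=phen,
        transects=transects,
        biography=biography,
        tenures=tenures,
        truth_person_months=truth,
        truth_frailties=frailties,
        water_balance=wb,
        spei_monthly=spei_monthly,
        fruit_monthly=fruit,
        fruit_daily=fruit_daily,
    )


def write_dataset(data: SimulatedData, outdir) -> dict:
    """Write the five observed CSVs plus ground-truth sidecars (ISO dates)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name, df):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False, date_format="%Y-%m-%d")
        paths[name] = p

    _write("climate", data.climate)
    _write("phenology", data.phenology)
    _write("transects", data.transects)
    _write("biography", data.biography)
    _write("alpha_tenure", data.tenures)
    _write("truth_person_months", data.truth_person_months)
    _write("truth_frailties", data.truth_frailties)
    return paths
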
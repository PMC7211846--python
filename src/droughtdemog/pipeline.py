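"""End-to-end orchestration: raw tables to fitted models and report CSVs.

A single config (YAML or ``PipelineConfig``) names the five raw inputs - or
a simulate block that generates them - and the pipeline runs every stage in
order, writing plain CSV artifacts and a JSON manifest with input hashes so
reruns are verifiably reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import droughtdemog
from droughtdemog.biomass import monthly_biomass, species_density
from droughtdemog.climate import interpolate_daily, monthly_water_balance, spei
from droughtdemog.cox import fit_cox_frailty
from droughtdemog.prep import build_analysis_table
from droughtdemog.selection import (
    enumerate_models,
    env_variables,
    model_average,
    run_model_set,
)
from droughtdemog.simulate import SimulationConfig, simulate_dataset, write_dataset
from droughtdemog.trees import (
    annual_mortality_rate,
    attach_climate,
    build_species_months,
    fit_binomial_glmm,
)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``inputs`` (paths to the five raw CSVs) or ``simulate`` (a
    :class:`SimulationConfig` block) must be provided.  All scientific
    defaults (scales, extreme decile, weaning ages, hydro-year start) are
    the study-system values baked into the stage modules.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    inputs: dict | None = None
    simulate: SimulationConfig | None = None
    species: tuple = ("capuchin",)
    scales: tuple = (1, 6, 12)
    extreme_lower_q: float = 0.10
    extreme_upper_q: float = 0.90
    latitude_deg: float = 10.84
    transect_area_ha: float = 13.94
    model_set: str = "full"  # 'full', 'singles' or 'none'
    fit_trees: bool = True

    def __post_init__(self):
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        self.species = tuple(self.species)
        self.scales = tuple(self.scales)
        if self.inputs is None and self.simulate is None:
            raise ValueError("config needs either 'inputs' paths or a 'simulate' block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.simulate is not None:
        sim = cfg.simulate
        if sim.seed != cfg.seed:
            sim.seed = cfg.seed
        data = simulate_dataset(sim)
        raw_dir = out / "raw"
        paths = write_dataset(data, raw_dir)
        tables = {
            "climate": data.climate,
            "phenology": data.phenology,
            "transects": data.transects,
            "biography": data.biography,
            "alpha_tenure": data.tenures,
        }
        return {"tables": tables, "paths": paths}
    paths = {k: Path(v) for k, v in cfg.inputs.items()}
    tables = {
        "climate": pd.read_csv(paths["climate"], parse_dates=["date"]),
        "phenology": pd.read_csv(paths["phenology"]),
        "transects": pd.read_csv(paths["transects"]),
        "biography": pd.read_csv(
            paths["biography"],
            parse_dates=["birth_date", "departure_date", "last_seen_date"],
        ),
        "alpha_tenure": pd.read_csv(
            paths["alpha_tenure"], parse_dates=["start_date", "end_date"]
        ),
    }
    return {"tables": tables, "paths": paths}


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loaded = _load_inputs(cfg, out)
    tables = loaded["tables"]
    artifacts: dict[str, Path] = {}

    def _save(name, obj, index=False):
        p = out / f"{name}.csv"
        obj.to_csv(p, index=index)
        artifacts[name] = p

    # --- climate stage -----------------------------------------------------
    wb = monthly_water_balance(tables["climate"], cfg.latitude_deg)
    _save("water_balance", wb, index=True)
    spei_monthly = {k: spei(wb["d_mm"], k) for k in cfg.scales}
    spei_df = pd.DataFrame({f"spei_{k}": v for k, v in spei_monthly.items()})
    _save("spei", spei_df, index=True)

    # --- fruit stage -------------------------------------------------------
    dens = species_density(tables["transects"], cfg.transect_area_ha)
    fruit = monthly_biomass(tables["phenology"], dens)
    _save("fruit_biomass", fruit, index=True)
    fruit_daily = interpolate_daily(fruit["biomass_kg_per_ha"], anchor_day=1)

    # --- per-species survival stage ----------------------------------------
    fruit_vars, drought_vars = env_variables(cfg.scales)
    for species in cfg.species:
        pm = build_analysis_table(
            tables["biography"],
            tables["alpha_tenure"] if species == "capuchin" else None,
            fruit_daily,
            spei_monthly,
            species,
            scales=cfg.scales,
            lower_q=cfg.extreme_lower_q,
            upper_q=cfg.extreme_upper_q,
        )
        if species != "capuchin":
            assert "infanticide_risk" not in pm.columns
        _save(f"person_months_{species}", pm)
        if pm.empty or pm["event"].sum() == 0:
            warnings.warn(f"no events for {species}; skipping model fits", stacklevel=2)
            continue

        # per-hydro-year frailty estimates from the risk-only (capuchin) or
        # null (spider monkey) model
        base_terms = ["risk_low"] if species == "capuchin" else []
        base_fit = fit_cox_frailty(pm, base_terms)
        frailty = pd.DataFrame(
            {
                "hydro_year": base_fit.level_effects_["hydro_year"].index,
                "log_excess_hazard": base_fit.level_effects_["hydro_year"].to_numpy(),
                "excess_hazard_ratio": np.exp(
                    base_fit.level_effects_["hydro_year"].to_numpy()
                ),
            }
        )
        _save(f"hydro_year_frailty_{species}", frailty)

        if cfg.model_set != "none":
            specs = enumerate_models(fruit_vars, drought_vars, species)
            if cfg.model_set == "singles":
                specs = [s for s in specs if len(s.fixed_terms) <= (2 if species == "capuchin" else 1)]
            cont = [v for v in fruit_vars + drought_vars if "hi" not in v and "lo" not in v]
            table, fits = run_model_set(pm, specs, scale_terms=cont)
            _save(f"model_table_{species}", table)
            avg = model_average(table, fits)
            _save(f"averaged_coefficients_{species}", avg, index=True)

            best_label = table.loc[table["converged"].astype(bool), "label"].iloc[0]
            best = fits.get(best_label)
            if best is not None and best.fixed_terms:
                curves = []
                for term in best.fixed_terms:
                    for value, tag in ((0.0, "baseline"), (1.0, "elevated")):
                        profile = {t: 0.0 for t in best.fixed_terms}
                        profile[term] = value
                        c = best.predict_survival(profile)
                        c["profile"] = f"{term}={tag}"
                        curves.append(c)
                _save(f"survival_predictions_{species}", pd.concat(curves))

    # --- tree stage ---------------------------------------------------------
    if cfg.fit_trees:
        sm = build_species_months(tables["phenology"])
        sm = attach_climate(sm, spei_monthly, cfg.scales)
        _save("tree_species_months", sm)
        rates = annual_mortality_rate(tables["phenology"])
        _save("tree_annual_mortality", rates.reset_index())
        records = []
        for k in cfg.scales:
            for col in (f"spei_{k}", f"spei_lo_{k}", f"spei_hi_{k}"):
                if sm[col].nunique() < 2:
                    continue
                fit = fit_binomial_glmm(sm, col)
                records.append(
                    {
                        "model": col,
                        "aicc": fit.aicc_,
                        "slope": fit.coef_[col],
                        "converged": fit.converged_,
                    }
                )
        glmm_table = pd.DataFrame(records).sort_values("aicc").reset_index(drop=True)
        glmm_table["delta_aicc"] = glmm_table["aicc"] - glmm_table["aicc"].min()
        _save("tree_glmm_table", glmm_table)

    manifest = {
        "version": droughtdemog.__version__,
        "seed": cfg.seed,
        "species": list(cfg.species),
        "inputs": {k: _sha256(p) for k, p in loaded["paths"].items()},
        "artifacts": {k: _sha256(p) for k, p in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
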
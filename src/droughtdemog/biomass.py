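"""Landscape-scale available ripe fruit biomass from phenology and transects.

Monthly availability of each species is the mean fruit score of its living
monitored trees, normalized to [0, 1]; landscape biomass is the
density-weighted sum over species of availability times a species-level
maximum crop biomass per stem:

    biomass(month) = sum_s density_s * crop_mass_s * availability_{s,month}

Tree deaths remove trees from the availability denominator but never reduce
the species densities, which are treated as fixed for the whole series, so
post-drought biomass is, if anything, overestimated.  Species-months with no
living monitored tree are imputed from the species' calendar-month mean and
flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["species_density", "monthly_biomass", "FRUIT_SCORE_MAX"]

#: Top of the ordinal phenology score scale (scores run 0..4).
FRUIT_SCORE_MAX = 4


def species_density(
    transects: pd.DataFrame,
    total_area_ha: float,
    known_species: list | None = None,
) -> pd.DataFrame:
    """Per-species stem densities from pooled botanical transects.

    Parameters
    ----------
    transects : DataFrame
        Columns ``species`` and ``stems`` (count over all transects); an
        optional ``mean_fruit_mass_kg`` column is carried through.
    total_area_ha : float
        Total transect area in hectares.
    known_species : list, optional
        If given, any transect species outside this list raises.

    Returns
    -------
    DataFrame indexed by species with ``stems_per_ha`` (and
    ``mean_fruit_mass_kg`` when present in the input).
    """
    if total_area_ha <= 0:
        raise ValueError("transect area must be positive")
    if known_species is not None:
        unknown = sorted(set(transects["species"]) - set(known_species))
        if unknown:
            raise ValueError(f"unknown species in transect table: {unknown}")
    agg = {"stems": "sum"}
    if "mean_fruit_mass_kg" in transects.columns:
        agg["mean_fruit_mass_kg"] = "first"
    out = transects.groupby("species").agg(agg)
    out["stems_per_ha"] = out.pop("stems") / total_area_ha
    return out


def monthly_biomass(
    phenology: pd.DataFrame,
    densities: pd.DataFrame,
    score_max: int = FRUIT_SCORE_MAX,
) -> pd.DataFrame:
    """Monthly landscape ripe-fruit biomass (kg/ha).

    Parameters
    ----------
    phenology : DataFrame
        Columns ``tree_id``, ``species``, ``month`` (year-month), ``fruit_score``
        (0..score_max) and ``status`` ('alive'/'dead').  Dead trees contribute
        no score.
    densities : DataFrame
        Indexed by species with ``stems_per_ha`` and ``mean_fruit_mass_kg``.

    Returns
    -------
    DataFrame indexed by month (``PeriodIndex``) with ``biomass_kg_per_ha``
    and ``imputed_fraction`` (share of the biomass total contributed by
    species-months imputed from calendar-month means).  Months with no
    living monitored tree of any species are NaN.
    """
    ph = phenology.copy()
    ph["month"] = pd.PeriodIndex(ph["month"], freq="M")
    missing_density = sorted(set(ph["species"]) - set(densities.index))
    if missing_density:
        raise ValueError(f"species without density entry: {missing_density}")
    multi = ph.groupby("tree_id")["species"].nunique()
    if (multi > 1).any():
        raise ValueError(f"tree ids mapped to multiple species: {list(multi[multi > 1].index)}")
    bad = ph["status"].eq("alive") & (
        (ph["fruit_score"] < 0) | (ph["fruit_score"] > score_max)
    )
    if bad.any():
        raise ValueError("fruit scores outside the 0..score_max range")

    alive = ph[ph["status"] == "alive"]
    # availability in [0,1]: mean score of living trees / score_max
    avail = (
        alive.groupby(["species", "month"])["fruit_score"].mean().div(score_max)
    )
    months = pd.period_range(ph["month"].min(), ph["month"].max(), freq="M")
    species = densities.index
    grid = avail.unstack("month").reindex(index=species, columns=months)

    # impute unmonitored species-months from the species' calendar-month mean
    imputed = grid.isna()
    cal_month = pd.Index([m.month for m in months])
    for s in species:
        row = grid.loc[s]
        if row.isna().all():
            continue
        cal_means = row.groupby(cal_month.values).mean()
        fill = pd.Series(cal_means.reindex(cal_month).to_numpy(), index=months)
        grid.loc[s] = row.fillna(fill)

    weights = densities["stems_per_ha"] * densities["mean_fruit_mass_kg"]
    contrib = grid.mul(weights, axis=0)
    biomass = contrib.sum(axis=0, min_count=1)
    imput_share = contrib.where(imputed).sum(axis=0) / biomass.replace(0.0, np.nan)

    no_living = grid.isna().all(axis=0)
    if no_living.any():
        warnings.warn(
            f"{int(no_living.sum())} months with no living monitored trees", stacklevel=2
        )
        biomass[no_living] = np.nan
    out = pd.DataFrame(
        {"biomass_kg_per_ha": biomass, "imputed_fraction": imput_share.fillna(0.0)}
    )
    out.index.name = "month"
    return out
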
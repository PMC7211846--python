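"""Fruit-tree mortality: species-month counts, annual rates, climate GLMMs.

Tree biographies come from the monthly phenology records: each monitored
tree contributes one row per month with status 'alive' or 'dead', a tree's
death is dated to the month after its last visible sign of life, and dead
trees leave the sample (replacements enter as new trees).  The species-month
table counts, per species and month, the trees at risk entering the month
and the deaths dated to it; binomial mixed models then relate the monthly
death odds to one climate variable at a time.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from droughtdemog.glmm import BinomialGLMM
from droughtdemog.prep import assign_hydro_year, extreme_flags

__all__ = [
    "build_species_months",
    "annual_mortality_rate",
    "attach_climate",
    "fit_binomial_glmm",
]


def _check_status_runs(ph: pd.DataFrame):
    order = ph.sort_values("month")
    for tree, grp in order.groupby("tree_id"):
        s = grp["status"].to_numpy()
        dead = np.flatnonzero(s == "dead")
        if dead.size and (s[dead[0]:] == "alive").any():
            raise ValueError(f"tree {tree!r} recorded alive after death")
        if dead.size > 1:
            raise ValueError(f"tree {tree!r} has multiple death records")


def build_species_months(phenology: pd.DataFrame) -> pd.DataFrame:
    """Species-month death/at-risk counts from monthly tree records.

    A tree with a row in a month (alive or dead) was at risk entering that
    month; 'dead' rows are the deaths dated to the month.  Statuses must
    form ``alive* dead?`` per tree.
    """
    ph = phenology.copy()
    ph["month"] = pd.PeriodIndex(ph["month"], freq="M")
    _check_status_runs(ph)
    grp = ph.groupby(["species", "month"])
    out = pd.DataFrame(
        {
            "n_at_risk": grp["tree_id"].nunique(),
            "n_deaths": grp["status"].apply(lambda s: int((s == "dead").sum())),
        }
    ).reset_index()
    return out


def annual_mortality_rate(phenology: pd.DataFrame) -> pd.Series:
    """Per-hydro-year tree mortality: deaths / unique trees monitored.

    The denominator counts every tree with at least one record in the
    hydro-year, whatever its fate; hydro-years with no monitored trees are
    absent from the result.
    """
    ph = phenology.copy()
    ph["month"] = pd.PeriodIndex(ph["month"], freq="M")
    _check_status_runs(ph)
    # a monthly record belongs to the hydro-year of its month midpoint
    ph["hydro_year"] = assign_hydro_year(ph["month"].dt.start_time + pd.Timedelta(days=14))
    deaths = ph[ph["status"] == "dead"].groupby("hydro_year")["tree_id"].nunique()
    monitored = ph.groupby("hydro_year")["tree_id"].nunique()
    rate = (deaths.reindex(monitored.index).fillna(0) / monitored).rename("mortality_rate")
    return rate


def attach_climate(
    species_months: pd.DataFrame,
    spei_monthly: Mapping[int, pd.Series],
    scales: Iterable[int] = (1, 6, 12),
    lower_q: float = 0.10,
    upper_q: float = 0.90,
) -> pd.DataFrame:
    """Join monthly SPEI values and extreme-decile flags onto species-months.

    Tree outcomes are recorded on the calendar-month grid, so each row takes
    the SPEI value of its own month (no interpolation); extreme flags use
    thresholds from each SPEI series' full span.  Rows whose month predates
    a defined SPEI value are dropped.
    """
    out = species_months.copy()
    out["month"] = pd.PeriodIndex(out["month"], freq="M")
    for k in scales:
        s = spei_monthly[k].dropna()
        out[f"spei_{k}"] = s.reindex(out["month"]).to_numpy()
        lo, hi = extreme_flags(
            out[f"spei_{k}"].to_numpy(), lower_q, upper_q, reference=s.to_numpy()
        )
        miss = ~np.isfinite(out[f"spei_{k}"].to_numpy())
        lo[miss] = False
        hi[miss] = False
        out[f"spei_lo_{k}"] = lo.astype(int)
        out[f"spei_hi_{k}"] = hi.astype(int)
    out["hydro_year"] = assign_hydro_year(out["month"].dt.start_time + pd.Timedelta(days=14))
    cols = [f"spei_{k}" for k in scales]
    return out.dropna(subset=cols).reset_index(drop=True)


def fit_binomial_glmm(
    species_months: pd.DataFrame,
    climate_col: str,
    random_slope: bool = True,
    random_cov: str = "full",
    **kwargs,
) -> BinomialGLMM:
    """Fit one tree-mortality GLMM with a single climate variable."""
    model = BinomialGLMM(
        climate_col,
        random_slope=random_slope,
        random_cov=random_cov,
        **kwargs,
    )
    return model.fit(species_months)
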
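"""Person-month survival table construction.

Infant survival is analysed on a monthly grid aligned to each individual's
date of birth: interval ``m`` covers ages ``(m-1, m]`` months and closes on
the date ``birth + m`` calendar months.  Each interval carries the
time-varying covariates evaluated in windows that end on the closing date:
mean daily (interpolated) fruit biomass over the trailing 1/6/12 months, the
1/6/12-month SPEI interpolated to the closing date, extreme-decile flags for
each, and - for capuchins - a binary infanticide-risk state derived from
alpha-male tenure records.

Censoring rules: an infant disappearing alone before the minimum weaning age
is treated as having died; an infant disappearing together with its mother
is censored at the last sighting; infants alive at the minimum weaning age
are censored there.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_PARAMS",
    "assign_hydro_year",
    "add_months",
    "build_person_months",
    "infanticide_risk",
    "window_covariates",
    "extreme_flags",
    "scale_continuous",
    "build_analysis_table",
]

#: Species life-history constants: minimum weaning age (months) defines the
#: survival horizon; gestation (months) locates the estimated conception.
SPECIES_PARAMS: Mapping[str, Mapping[str, float]] = {
    "capuchin": {"weaning_months": 14, "gestation_months": 5.5},
    "spider_monkey": {"weaning_months": 19, "gestation_months": 7.5},
}

HYDRO_YEAR_START = (5, 15)  # May 15, median rainy-season onset


def assign_hydro_year(date, start=HYDRO_YEAR_START):
    """Hydrological-year label of a date (or datetime array).

    The hydro-year labelled Y runs from ``start`` (default 15 May) of
    calendar year Y through the day before ``start`` of year Y+1.
    """
    d = pd.to_datetime(date)
    month, day = start
    if isinstance(d, pd.Timestamp):
        before = (d.month, d.day) < (month, day)
        return d.year - int(before)
    d = pd.DatetimeIndex(d)
    before = (d.month < month) | ((d.month == month) & (d.day < day))
    return np.asarray(d.year - before.astype(int))


def add_months(date, k: int):
    """Shift a date by k calendar months, clamping the day to month end."""
    d = pd.Timestamp(date)
    total = d.year * 12 + (d.month - 1) + int(k)
    year, month = divmod(total, 12)
    month += 1
    day = min(d.day, pd.Timestamp(year=year, month=month, day=1).days_in_month)
    return pd.Timestamp(year=year, month=month, day=day)


def _age_months(birth, date) -> float:
    """Age in (fractional) months: whole calendar months plus day fraction."""
    birth, date = pd.Timestamp(birth), pd.Timestamp(date)
    whole = (date.year - birth.year) * 12 + (date.month - birth.month)
    if add_months(birth, whole) > date:
        whole -= 1
    lo, hi = add_months(birth, whole), add_months(birth, whole + 1)
    frac = (date - lo) / (hi - lo)
    return whole + float(frac)


def build_person_months(
    biographies: pd.DataFrame,
    species: str,
    weaning_months: int | None = None,
) -> pd.DataFrame:
    """Build the person-month skeleton (no covariates) for one species.

    Parameters
    ----------
    biographies : DataFrame
        One row per individual: ``individual_id``, ``species``, ``sex``,
        ``mother_id``, ``birth_date``, ``entry_type``, ``departure_type``,
        ``departure_date``, ``last_seen_date`` and optionally ``group_id``.
        Mothers may appear as their own rows (used to classify joint
        mother-infant disappearances).
    species : str
        'capuchin' or 'spider_monkey'; sets the weaning horizon.

    Returns
    -------
    DataFrame with one row per infant per month of age: ``individual_id``,
    ``mother_id``, ``group_id``, ``birth_date``, ``interval_index`` (1-based),
    ``window_close_date``, ``event``.
    """
    if weaning_months is None:
        weaning_months = int(SPECIES_PARAMS[species]["weaning_months"])
    bio = biographies[biographies["species"] == species]
    infants = bio[bio["birth_date"].notna() & bio["mother_id"].notna()]
    by_id = biographies.set_index("individual_id", drop=False)

    rows = []
    for rec in infants.itertuples(index=False):
        birth = pd.Timestamp(rec.birth_date)
        departure = pd.Timestamp(
            rec.departure_date if pd.notna(rec.departure_date) else rec.last_seen_date
        )
        if departure < birth:
            raise ValueError(f"{rec.individual_id}: departure precedes birth")
        age = _age_months(birth, departure)

        if rec.departure_type == "death":
            is_death = age < weaning_months or math.isclose(age, weaning_months)
        elif rec.departure_type == "disappearance_unknown":
            # death unless the mother vanished on the same date (joint
            # disappearance => censored); unknown mother => treated as an
            # infant-only disappearance, with a warning
            if rec.mother_id in by_id.index:
                mother = by_id.loc[rec.mother_id]
                joint = (
                    mother["departure_type"] == "disappearance_unknown"
                    and pd.notna(mother["departure_date"])
                    and pd.Timestamp(mother["departure_date"]) == departure
                )
            else:
                warnings.warn(
                    f"{rec.individual_id}: mother {rec.mother_id} not in biography; "
                    "disappearance classified as death",
                    stacklevel=2,
                )
                joint = False
            is_death = not joint and age < weaning_months
        else:  # censored_alive, emigration
            is_death = False

        if is_death and age < weaning_months + 0.5:
            n_rows = max(1, math.ceil(age - 1e-9))
            n_rows = min(n_rows, weaning_months)
            event_row = n_rows
        else:
            n_rows = min(math.floor(age + 1e-9), weaning_months)
            event_row = None

        group = getattr(rec, "group_id", None)
        for m in range(1, n_rows + 1):
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "mother_id": rec.mother_id,
                    "group_id": group,
                    "birth_date": birth,
                    "interval_index": m,
                    "window_close_date": add_months(birth, m),
                    "event": int(event_row == m),
                }
            )
    cols = [
        "individual_id",
        "mother_id",
        "group_id",
        "birth_date",
        "interval_index",
        "window_close_date",
        "event",
    ]
    return pd.DataFrame(rows, columns=cols)


def infanticide_risk(
    birth_date,
    age_months: int,
    tenures: pd.DataFrame,
    gestation_months: float = 5.5,
) -> str:
    """Infanticide-risk state ('high'/'low') for one capuchin person-month.

    Risk is high iff an alpha-male replacement in the natal group occurred
    after the infant's estimated conception (``gestation_months`` before
    birth, implemented as birth - 5 months - 15 days for the default 5.5)
    and on or before the evaluation date, and the infant is under one year
    old at evaluation.
    """
    birth = pd.Timestamp(birth_date)
    eval_date = add_months(birth, age_months)
    if tenures.empty:
        raise ValueError("no alpha-tenure records for the infant's group")
    starts = pd.to_datetime(tenures["start_date"]).sort_values()
    ends = pd.to_datetime(tenures["end_date"], errors="coerce")
    span_end = pd.Timestamp.max if ends.isna().any() else ends.max()
    if starts.iloc[0] > birth or span_end < eval_date:
        raise ValueError("alpha-tenure records do not cover the infant's life")
    if age_months >= 12:
        return "low"
    # fractional gestation months resolved as whole months + 15 days
    whole = int(math.floor(gestation_months))
    frac_days = 15 if gestation_months != whole else 0
    conception = add_months(birth, -whole) - pd.Timedelta(days=frac_days)
    # replacements are tenure starts after the group's first recorded tenure
    replacements = starts.iloc[1:]
    hit = ((replacements > conception) & (replacements <= eval_date)).any()
    return "high" if hit else "low"


def window_covariates(
    fruit_daily: pd.Series,
    spei_monthly: Mapping[int, pd.Series],
    close_date,
    scales: Iterable[int] = (1, 6, 12),
    anchor_day: int = 1,
) -> dict:
    """Windowed environmental covariates for one interval-closing date.

    ``fruit_mean_k`` is the mean of the daily (interpolated) fruit series
    over the half-open window ``(close - k months, close]``; ``spei_k`` is
    the k-month SPEI linearly interpolated to the closing date.  Covariates
    whose window extends beyond the available data are NaN.
    """
    from droughtdemog.climate import interpolate_daily

    close = pd.Timestamp(close_date)
    out = {}
    for k in scales:
        start = add_months(close, -k)
        window = fruit_daily.loc[start + pd.Timedelta(days=1): close]
        expected = (close - start).days
        out[f"fruit_mean_{k}"] = (
            float(window.mean()) if len(window) == expected else np.nan
        )
        daily = interpolate_daily(spei_monthly[k].dropna(), anchor_day=anchor_day)
        out[f"spei_{k}"] = (
            float(daily.loc[close]) if daily.index[0] <= close <= daily.index[-1] else np.nan
        )
    return out


def extreme_flags(
    values,
    lower_q: float = 0.10,
    upper_q: float = 0.90,
    reference=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Extreme-decile flags: (lo, hi) boolean arrays.

    Thresholds are type-7 empirical quantiles of ``reference`` (the
    covariate's full time series; defaults to ``values``), with closed
    inequalities: lo iff value <= 10th percentile, hi iff value >= 90th.
    """
    x = np.asarray(values, dtype=float)
    ref = np.asarray(values if reference is None else reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    if ref.size < 10:
        raise ValueError("need >= 10 non-missing reference values for extreme flags")
    if np.ptp(ref) == 0.0:
        warnings.warn("constant covariate: no extremes flagged", stacklevel=2)
        return np.zeros(x.shape, bool), np.zeros(x.shape, bool)
    q_lo, q_hi = np.quantile(ref, [lower_q, upper_q])  # linear = type 7
    return x <= q_lo, x >= q_hi


def scale_continuous(
    df: pd.DataFrame, columns: Iterable[str]
) -> tuple[pd.DataFrame, dict]:
    """Z-score columns over the rows entering the model (ddof=1 sd).

    Returns the scaled frame and per-column ``(mean, sd)`` metadata for
    back-transforming coefficients.
    """
    out = df.copy()
    meta = {}
    for col in columns:
        x = out[col].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance; cannot scale")
        out[col] = (x - mu) / sd
        meta[col] = (float(mu), float(sd))
    return out, meta


def _risk_vector(pm: pd.DataFrame, tenures: pd.DataFrame, gestation_months: float):
    """Vectorized infanticide-risk states for a person-month table.

    Equivalent to calling :func:`infanticide_risk` row by row (asserted in
    the test suite) but evaluated once per infant: risk is high from the
    first alpha replacement after the estimated conception through the
    11th month of age.
    """
    whole = int(math.floor(gestation_months))
    frac = pd.Timedelta(days=15 if gestation_months != whole else 0)
    reps_by_group = {
        g: np.sort(grp["start_date"].to_numpy()[1:])  # first start is not a replacement
        for g, grp in tenures.sort_values("start_date").groupby("group_id")
    }
    out = np.empty(len(pm), dtype=object)
    close = pd.DatetimeIndex(pm["window_close_date"]).to_numpy()
    ages = pm["interval_index"].to_numpy()
    for (birth, group), idx in pm.groupby(["birth_date", "group_id"]).groups.items():
        reps = reps_by_group.get(group, np.array([], dtype="datetime64[ns]"))
        conception = np.datetime64(add_months(birth, -whole) - frac)
        pos = np.searchsorted(reps, conception, side="right")
        loc = np.asarray(idx)
        if pos >= len(reps):
            out[loc] = "low"
            continue
        high = (close[loc] >= reps[pos]) & (ages[loc] < 12)
        out[loc] = np.where(high, "high", "low")
    return out


def _monthly_reference_series(
    fruit_daily: pd.Series,
    spei_monthly: Mapping[int, pd.Series],
    scales: Iterable[int],
) -> dict[str, np.ndarray]:
    """Reference series for extreme-decile thresholds.

    Each covariate's thresholds come from its own full time series evaluated
    on a monthly grid (first-of-month anchors), not from the realized
    person-month sample.
    """
    refs: dict[str, np.ndarray] = {}
    months = pd.date_range(
        fruit_daily.index[0].normalize(), fruit_daily.index[-1], freq="MS"
    )
    csum = fruit_daily.cumsum()
    for k in scales:
        vals = []
        for close in months:
            start = add_months(close, -k)
            if start >= fruit_daily.index[0] and close <= fruit_daily.index[-1]:
                total = csum.loc[close] - csum.loc[start]
                vals.append(total / (close - start).days)
        refs[f"fruit_mean_{k}"] = np.asarray(vals, dtype=float)
        refs[f"spei_{k}"] = spei_monthly[k].dropna().to_numpy(dtype=float)
    return refs


def build_analysis_table(
    biographies: pd.DataFrame,
    tenures: pd.DataFrame | None,
    fruit_daily: pd.Series,
    spei_monthly: Mapping[int, pd.Series],
    species: str,
    scales: Iterable[int] = (1, 6, 12),
    lower_q: float = 0.10,
    upper_q: float = 0.90,
    anchor_day: int = 1,
) -> pd.DataFrame:
    """Full person-month analysis table for one species.

    Joins the person-month skeleton with windowed environmental covariates,
    extreme-decile flags (thresholds from the full environmental series),
    hydro-year labels and, for capuchins, the infanticide-risk state (plus a
    numeric ``risk_low`` indicator).  Rows with any missing environmental
    covariate are dropped (listwise) with a warning.
    """
    from droughtdemog.climate import interpolate_daily

    scales = tuple(scales)
    pm = build_person_months(biographies, species)
    if pm.empty:
        return pm

    close = pd.DatetimeIndex(pm["window_close_date"])
    csum = fruit_daily.cumsum()
    first_day, last_day = fruit_daily.index[0], fruit_daily.index[-1]

    for k in scales:
        starts = pd.DatetimeIndex([add_months(c, -k) for c in close])
        ok = (starts >= first_day) & (close <= last_day)
        vals = np.full(len(pm), np.nan)
        if ok.any():
            tot = csum.reindex(close[ok]).to_numpy() - csum.reindex(starts[ok]).to_numpy()
            ndays = (close[ok] - starts[ok]).days.to_numpy()
            vals[np.asarray(ok)] = tot / ndays
        pm[f"fruit_mean_{k}"] = vals

        spei_daily = interpolate_daily(spei_monthly[k].dropna(), anchor_day=anchor_day)
        in_span = (close >= spei_daily.index[0]) & (close <= spei_daily.index[-1])
        sv = np.full(len(pm), np.nan)
        sv[np.asarray(in_span)] = spei_daily.reindex(close[in_span]).to_numpy()
        pm[f"spei_{k}"] = sv

    refs = _monthly_reference_series(fruit_daily, spei_monthly, scales)
    for k in scales:
        for stem in ("fruit_mean", "spei"):
            col = f"{stem}_{k}"
            short = "fruit" if stem == "fruit_mean" else "spei"
            lo, hi = extreme_flags(
                pm[col].to_numpy(), lower_q, upper_q, reference=refs[col]
            )
            missing = ~np.isfinite(pm[col].to_numpy())
            lo[missing] = False
            hi[missing] = False
            pm[f"{short}_lo_{k}"] = lo.astype(int)
            pm[f"{short}_hi_{k}"] = hi.astype(int)

    pm["hydro_year"] = assign_hydro_year(pm["window_close_date"])

    if species == "capuchin":
        if tenures is None or tenures.empty:
            raise ValueError("capuchin analysis requires alpha-tenure records")
        gest = SPECIES_PARAMS[species]["gestation_months"]
        pm["infanticide_risk"] = _risk_vector(pm, tenures, gest)
        pm["risk_low"] = (pm["infanticide_risk"] == "low").astype(int)

    env_cols = [f"{s}_{k}" for k in scales for s in ("fruit_mean", "spei")]
    n_missing = int(pm[env_cols].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"dropping {n_missing} person-month rows with missing covariates",
            stacklevel=2,
        )
        pm = pm.dropna(subset=env_cols).reset_index(drop=True)
    return pm
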
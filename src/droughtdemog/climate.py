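"""Monthly climatic water balance and the multi-scalar SPEI.

The Standardized Precipitation-Evapotranspiration Index (SPEI) is a z-scored
drought index built from the monthly climatic water balance
``D = P - PET``: the balance is summed over a trailing window of *k* months,
a three-parameter log-logistic distribution is fitted to those sums by
unbiased probability-weighted moments, and the fitted cumulative
probabilities are mapped to standard-normal deviates.  Negative values mean
water deficit (drought), positive values water surplus.

Potential evapotranspiration uses the temperature-only Hargreaves equation
with extraterrestrial radiation from standard solar geometry (FAO-56
formulas), so daily rain-gauge and min/max thermometer records are the only
climate inputs required.

Distribution fitting is performed separately for each calendar month by
default, so that SPEI values measure anomalies relative to the month's own
climatology rather than the seasonal cycle.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

__all__ = [
    "aggregate_monthly",
    "extraterrestrial_radiation_mm",
    "hargreaves_pet",
    "monthly_water_balance",
    "spei",
    "interpolate_daily",
]

# Solar constant, MJ m^-2 min^-1 (FAO-56).
_GSC = 0.0820
# MJ m^-2 day^-1 -> mm day^-1 of evaporation equivalent.
_MJ_TO_MM = 0.408


def aggregate_monthly(daily: pd.DataFrame) -> pd.DataFrame:
    """Aggregate daily climate records to calendar months.

    Parameters
    ----------
    daily : DataFrame
        Columns ``date`` (parseable to datetime), ``rain_mm``, ``tmin_c``,
        ``tmax_c``.  Duplicate dates are rejected.

    Returns
    -------
    DataFrame indexed by monthly ``PeriodIndex`` with columns ``precip_mm``
    (sum of daily rain), ``tmin_c`` / ``tmax_c`` (means over available days),
    ``n_days`` (days with records) and ``completeness`` (fraction of the
    month's calendar days with a record).  Months inside the span with no
    records at all appear as rows of NaN with ``completeness`` 0.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        dupes = df.loc[df["date"].duplicated(), "date"].dt.date.unique()[:5]
        raise ValueError(f"duplicate dates in daily climate records: {list(dupes)}")
    if (df["tmax_c"] < df["tmin_c"]).any():
        raise ValueError("tmax_c < tmin_c in daily climate records")
    if (df["rain_mm"] < 0).any():
        raise ValueError("negative rainfall in daily climate records")

    month = df["date"].dt.to_period("M")
    out = pd.DataFrame(
        {
            "precip_mm": df.groupby(month)["rain_mm"].sum(),
            "tmin_c": df.groupby(month)["tmin_c"].mean(),
            "tmax_c": df.groupby(month)["tmax_c"].mean(),
            "n_days": df.groupby(month)["date"].count(),
        }
    )
    # reindex over the full span so silent gaps become explicit NaN rows
    full = pd.period_range(out.index.min(), out.index.max(), freq="M")
    out = out.reindex(full)
    out["n_days"] = out["n_days"].fillna(0).astype(int)
    out["completeness"] = out["n_days"] / out.index.days_in_month
    if (out["n_days"] == 0).any():
        missing = [str(m) for m in out.index[out["n_days"] == 0][:5]]
        warnings.warn(f"months with no climate records: {missing}", stacklevel=2)
    return out


def extraterrestrial_radiation_mm(day_of_year: np.ndarray | int, latitude_deg: float):
    """Daily extraterrestrial radiation in evaporation-equivalent mm/day.

    Standard solar geometry: inverse relative earth-sun distance, solar
    declination, and sunset hour angle, as in FAO-56.
    """
    j = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    # sunset hour angle; clip guards |phi| near polar day/night
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra_mj = (
        (24.0 * 60.0 / np.pi)
        * _GSC
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return ra_mj * _MJ_TO_MM


def hargreaves_pet(
    month: pd.Period | str,
    mean_tmin: float,
    mean_tmax: float,
    latitude_deg: float,
) -> float:
    """Monthly potential evapotranspiration (mm) by the Hargreaves equation.

    ``PET = 0.0023 * Ra * (Tmean + 17.8) * sqrt(Tmax - Tmin)`` per day,
    summed over the days of the month, with ``Ra`` the month's mean daily
    extraterrestrial radiation in mm-equivalent.
    """
    if not -60.0 <= latitude_deg <= 60.0:
        raise ValueError("latitude must be within [-60, 60] degrees")
    if mean_tmax < mean_tmin:
        raise ValueError("mean_tmax < mean_tmin")
    p = pd.Period(month, freq="M")
    tmean = 0.5 * (mean_tmax + mean_tmin)
    if tmean <= -17.8:
        warnings.warn(f"Hargreaves PET clamped to 0 for {p} (Tmean <= -17.8)", stacklevel=2)
        return 0.0
    start = p.start_time.dayofyear
    days = np.arange(start, start + p.days_in_month)
    # wrap around year end; Ra uses a 365-day cycle
    days = np.where(days > 365, days - 365, days)
    ra = extraterrestrial_radiation_mm(days, latitude_deg).mean()
    pet_daily = 0.0023 * ra * (tmean + 17.8) * np.sqrt(mean_tmax - mean_tmin)
    return float(max(pet_daily, 0.0) * p.days_in_month)


def monthly_water_balance(daily: pd.DataFrame, latitude_deg: float) -> pd.DataFrame:
    """Monthly precipitation, Hargreaves PET and water balance D = P - PET."""
    monthly = aggregate_monthly(daily)
    pet = [
        hargreaves_pet(m, r.tmin_c, r.tmax_c, latitude_deg)
        if np.isfinite(r.tmin_c) and np.isfinite(r.tmax_c)
        else np.nan
        for m, r in monthly.iterrows()
    ]
    out = monthly[["precip_mm"]].copy()
    out["pet_mm"] = pet
    out["d_mm"] = out["precip_mm"] - out["pet_mm"]
    out["completeness"] = monthly["completeness"]
    return out


def _unbiased_pwms(x: np.ndarray) -> tuple[float, float, float]:
    """First three unbiased probability-weighted moments w_s = E[X(1-F)^s].

    These are the descending-weight (alpha) PWMs entering the classical
    log-logistic parameter formulas.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    i = np.arange(1, n + 1, dtype=float)
    w0 = x.mean()
    w1 = np.sum((n - i) / (n - 1.0) * x) / n
    w2 = np.sum((n - i) * (n - i - 1.0) / ((n - 1.0) * (n - 2.0)) * x) / n
    return w0, w1, w2


def _fit_loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit a 3-parameter log-logistic by unbiased PWMs.

    Returns (shape beta, scale alpha, location gamma) for
    ``F(x) = [1 + (alpha / (x - gamma))**beta]**-1``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values to fit the log-logistic")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate (constant) water-balance series")
    w0, w1, w2 = _unbiased_pwms(x)
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0.0:
        raise ValueError("log-logistic PWM fit failed (zero denominator)")
    beta = (2.0 * w1 - w0) / denom
    if beta <= 1.0:
        raise ValueError(f"log-logistic PWM fit failed (shape {beta:.3f} <= 1)")
    g1g2 = _gamma_fn(1.0 + 1.0 / beta) * _gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g1g2
    gamma = w0 - alpha * g1g2
    if alpha <= 0.0:
        raise ValueError("log-logistic PWM fit failed (non-positive scale)")
    return beta, alpha, gamma


# Abramowitz & Stegun 26.2.23 rational approximation of the normal quantile.
_C0, _C1, _C2 = 2.515517, 0.802853, 0.010328
_D1, _D2, _D3 = 1.432788, 0.189269, 0.001308


def _std_normal_from_prob(f: np.ndarray) -> np.ndarray:
    """Map cumulative probabilities to standard-normal deviates (A&S 26.2.23)."""
    f = np.asarray(f, dtype=float)
    eps = np.finfo(float).eps
    f = np.clip(f, eps, 1.0 - eps)
    out = np.empty_like(f)
    lower = f <= 0.5
    p = np.where(lower, f, 1.0 - f)
    t = np.sqrt(-2.0 * np.log(p))
    z = t - (_C0 + _C1 * t + _C2 * t * t) / (1.0 + _D1 * t + _D2 * t * t + _D3 * t ** 3)
    out[lower] = -z[lower]
    out[~lower] = z[~lower]
    return out


def _standardize_loglogistic(x_fit: np.ndarray, x_all: np.ndarray) -> np.ndarray:
    """Fit the log-logistic to x_fit and standardize x_all.

    The three-parameter log-logistic requires positive skew; samples with
    negative skew (e.g. rain-free calendar months where the balance is
    minus PET) are handled by fitting the mirrored sample and negating the
    resulting z-scores.
    """
    try:
        beta, alpha, gamma = _fit_loglogistic_pwm(x_fit)
        f = _loglogistic_cdf(x_all, beta, alpha, gamma)
        return _std_normal_from_prob(f)
    except ValueError:
        beta, alpha, gamma = _fit_loglogistic_pwm(-x_fit)
        f = _loglogistic_cdf(-x_all, beta, alpha, gamma)
        return -_std_normal_from_prob(f)


def _loglogistic_cdf(x: np.ndarray, beta: float, alpha: float, gamma: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    eps = np.finfo(float).eps
    shifted = x - gamma
    with np.errstate(divide="ignore", over="ignore"):
        f = np.where(shifted > 0.0, 1.0 / (1.0 + (alpha / np.maximum(shifted, eps)) ** beta), eps)
    return np.clip(f, eps, 1.0 - eps)


def spei(
    d_series: pd.Series,
    scale_months: int,
    calibration: tuple | None = None,
    by_calendar_month: bool = True,
) -> pd.Series:
    """Standardized Precipitation-Evapotranspiration Index.

    Parameters
    ----------
    d_series : Series
        Monthly water balance ``D = P - PET`` (mm) with a monthly
        ``PeriodIndex``, no gaps.
    scale_months : int
        Aggregation scale k; each month's value standardizes the sum of D
        over the trailing k months (window fully inside the series, so the
        first k-1 months are NaN).
    calibration : (start, end), optional
        Period range used to fit the distribution; defaults to the full
        series.
    by_calendar_month : bool
        If True (default) a separate log-logistic is fitted for each of the
        12 calendar months, so SPEI measures within-month anomalies; if
        False a single distribution is fitted to all windows.

    Returns
    -------
    Series of SPEI values (z-units) on the input index.
    """
    if not isinstance(d_series.index, pd.PeriodIndex):
        d_series = d_series.copy()
        d_series.index = pd.PeriodIndex(d_series.index, freq="M")
    if scale_months < 1:
        raise ValueError("scale_months must be >= 1")
    n = d_series.size
    if n < scale_months + 20:
        raise ValueError(
            f"series of {n} months too short to fit SPEI at scale {scale_months}"
        )
    if d_series.isna().any():
        raise ValueError("water-balance series contains missing values")

    x = d_series.rolling(scale_months).sum()

    if calibration is None:
        calib_mask = x.notna()
    else:
        start, end = (pd.Period(calibration[0], freq="M"), pd.Period(calibration[1], freq="M"))
        calib_mask = x.notna() & (x.index >= start) & (x.index <= end)
        if calib_mask.sum() < 20:
            raise ValueError("calibration period too short (need >= 20 windowed months)")

    out = pd.Series(np.nan, index=x.index, name=f"spei_{scale_months}")
    valid = x.notna()
    if by_calendar_month:
        for m in range(1, 13):
            sel = valid & (x.index.month == m)
            fit_sel = calib_mask & (x.index.month == m)
            if not sel.any():
                continue
            out[sel] = _standardize_loglogistic(
                x[fit_sel].to_numpy(), x[sel].to_numpy()
            )
    else:
        out[valid] = _standardize_loglogistic(
            x[calib_mask].to_numpy(), x[valid].to_numpy()
        )
    return out


def interpolate_daily(
    monthly: pd.Series,
    anchor_day: int = 1,
) -> pd.Series:
    """Expand a monthly series to daily resolution by linear interpolation.

    Each month's value is anchored at ``anchor_day`` of that month (clamped
    to the month's length); days between anchors are linear in time and no
    extrapolation happens outside the first/last anchor.
    """
    s = monthly.dropna()
    if s.size < 2:
        raise ValueError("need at least 2 non-missing months to interpolate")
    if not isinstance(s.index, pd.PeriodIndex):
        s = s.copy()
        s.index = pd.PeriodIndex(s.index, freq="M")
    s = s.sort_index()
    anchors = [
        p.start_time + pd.Timedelta(days=min(anchor_day, p.days_in_month) - 1)
        for p in s.index
    ]
    anchors = pd.DatetimeIndex(anchors)
    days = pd.date_range(anchors[0], anchors[-1], freq="D")
    values = np.interp(
        days.view("int64").astype(float),
        anchors.view("int64").astype(float),
        s.to_numpy(dtype=float),
    )
    return pd.Series(values, index=days, name=monthly.name)
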
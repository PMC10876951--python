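"""Seasonal fire-weather aggregation, z-score anomaly flags, and
regression of burned area on fire-weather proxies.

The seasonal window is 1 March – 30 September inclusive (214 days in
non-leap years, 215 in leap years); seasonal values are simple means over
the days available in the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeasonalIndex",
    "ZFlag",
    "RegressionFit",
    "validate_daily_weather",
    "seasonal_mean",
    "seasonal_series",
    "zscore_series",
    "regress_burned_area",
    "SEASON_START",
    "SEASON_END",
]

SEASON_START = (3, 1)  # 1 March
SEASON_END = (9, 30)  # 30 September

#: z-score threshold flagging abnormal disturbance years
DISTURBANCE_Z_THRESHOLD = 3.0
#: z-score threshold flagging abnormal fire-weather years
WEATHER_Z_THRESHOLD = 2.0


@dataclass(frozen=True)
class SeasonalIndex:
    """March–September mean of the three fire-weather indices for one year."""

    year: int
    mean_fwi: float
    mean_isi: float
    mean_dc: float
    n_days: int
    completeness: float  # fraction of window days present


@dataclass(frozen=True)
class ZFlag:
    year: int
    z: float
    abnormal: bool
    threshold: float


@dataclass(frozen=True)
class RegressionFit:
    """Simple OLS of burned area on one seasonal fire-weather index."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    prediction: float
    prediction_floored: bool
    target_year: int
    n: int


def validate_daily_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Check the daily weather contract: unique sorted dates, indices >= 0."""
    required = {"date", "fwi", "isi", "dc"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"daily weather missing columns: {sorted(missing)}")
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"])
    if out["date"].duplicated().any():
        raise ValueError("daily weather has duplicate dates")
    out = out.sort_values("date").reset_index(drop=True)
    for col in ("fwi", "isi", "dc"):
        if (out[col] < 0).any():
            raise ValueError(f"{col} contains negative values")
    return out


def _window_mask(dates: pd.Series, year: int) -> pd.Series:
    start = pd.Timestamp(year, *SEASON_START)
    end = pd.Timestamp(year, *SEASON_END)
    return (dates >= start) & (dates <= end)


def seasonal_mean(weather: pd.DataFrame, year: int) -> SeasonalIndex:
    """March–September mean of FWI/ISI/DC for one year.

    Missing days are excluded from the mean and reported through
    ``completeness``.
    """
    weather = validate_daily_weather(weather)
    sel = weather[_window_mask(weather["date"], year)]
    if sel.empty:
        raise ValueError(f"no in-window days for year {year}")
    window_days = (
        pd.Timestamp(year, *SEASON_END) - pd.Timestamp(year, *SEASON_START)
    ).days + 1
    return SeasonalIndex(
        year=year,
        mean_fwi=float(sel["fwi"].mean()),
        mean_isi=float(sel["isi"].mean()),
        mean_dc=float(sel["dc"].mean()),
        n_days=int(len(sel)),
        completeness=float(len(sel) / window_days),
    )


def seasonal_series(weather: pd.DataFrame) -> pd.DataFrame:
    """Seasonal means for every year present in the daily series."""
    weather = validate_daily_weather(weather)
    years = sorted(weather["date"].dt.year.unique())
    rows = []
    for year in years:
        if _window_mask(weather["date"], year).any():
            si = seasonal_mean(weather, year)
            rows.append(
                {
                    "year": si.year,
                    "mean_fwi": si.mean_fwi,
                    "mean_isi": si.mean_isi,
                    "mean_dc": si.mean_dc,
                    "n_days": si.n_days,
                    "completeness": si.completeness,
                }
            )
    return pd.DataFrame(rows)


def zscore_series(values: dict[int, float], threshold: float) -> list[ZFlag]:
    """Standard score of each year against the whole series.

    The focal year is included in the baseline; the sample standard deviation
    (ddof=1) is used. A degenerate series (sd = 0) yields z = 0 everywhere.
    Years are abnormal when ``z >= threshold``.
    """
    if len(values) < 3:
        raise ValueError("zscore_series requires at least 3 years")
    years = sorted(values)
    x = np.array([values[y] for y in years], dtype=float)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return [
        ZFlag(year=y, z=float(zi), abnormal=bool(zi >= threshold), threshold=threshold)
        for y, zi in zip(years, z)
    ]


def regress_burned_area(
    srf_area_by_year: dict[int, float],
    index_by_year: dict[int, float],
    predictor_name: str,
    target_year: int = 2022,
) -> RegressionFit:
    """OLS of annual burned (SRF) area on one seasonal fire-weather index.

    Fit over the years shared by both series, excluding the target year;
    predict the target year from its index value. Negative predictions are
    floored at zero and flagged.
    """
    fit_years = sorted(
        (set(srf_area_by_year) & set(index_by_year)) - {target_year}
    )
    if len(fit_years) < 10:
        raise ValueError("need at least 10 paired years to fit")
    x = np.array([index_by_year[y] for y in fit_years], dtype=float)
    y = np.array([srf_area_by_year[y] for y in fit_years], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    if target_year not in index_by_year:
        raise ValueError(f"no index value for target year {target_year}")
    raw = res.slope * index_by_year[target_year] + res.intercept
    floored = raw < 0
    return RegressionFit(
        predictor=predictor_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        prediction=float(max(raw, 0.0)),
        prediction_floored=bool(floored),
        target_year=target_year,
        n=len(fit_years),
    )
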
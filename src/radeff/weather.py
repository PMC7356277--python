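"""Daily weather series, thermal time and cumulative incident PAR.

The analysis is driven by a daily weather table with one row per day after
planting (dap): incident photosynthetically active radiation (PAR,
MJ m^-2 d^-1) and minimum/maximum air temperature (degC).  Thermal time is
accumulated above a base temperature and is the independent variable of both
the canopy-dynamics and the tuber-partitioning models.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyClimate",
    "WeatherProfile",
    "LIMA_2017_PROFILE",
    "DEFAULT_PLANTING_DATE",
    "generate_weather",
    "validate_weather",
    "thermal_time",
    "cumulative_par",
]

#: Default base temperature for potato thermal-time accumulation, degC.
DEFAULT_T_BASE = 2.0

#: Planting date of the reference Lima winter trial.
DEFAULT_PLANTING_DATE = _dt.date(2017, 7, 5)


@dataclass(frozen=True)
class MonthlyClimate:
    """Mean +/- standard error of daily conditions for one calendar month.

    Units: temperatures degC, radiation MJ m^-2 d^-1, VPD kPa, RH %.
    """

    tmax: float
    tmax_se: float
    tmin: float
    tmin_se: float
    solar: float
    solar_se: float
    par: float
    par_se: float
    vpd: float = np.nan
    vpd_se: float = np.nan
    rh: float = np.nan
    rh_se: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite([self.tmax, self.tmin, self.solar, self.par]).all():
            raise ValueError("monthly means must be finite")
        if self.par > self.solar:
            raise ValueError(
                f"monthly PAR mean ({self.par}) exceeds solar radiation mean ({self.solar})"
            )
        if self.tmin > self.tmax:
            raise ValueError("monthly tmin mean exceeds tmax mean")


@dataclass(frozen=True)
class WeatherProfile:
    """Monthly climate normals used to synthesize daily weather.

    Maps calendar month number (1-12) to :class:`MonthlyClimate`.
    """

    months: dict[int, MonthlyClimate] = field(default_factory=dict)

    def climate(self, month: int) -> MonthlyClimate:
        try:
            return self.months[month]
        except KeyError:
            raise KeyError(
                f"month {month} absent from weather profile (covers {sorted(self.months)})"
            ) from None


#: Growing-season climate of the 2017 winter trial in Lima, Peru
#: (coastal desert: low radiation, mild temperatures, heavy overcast).
LIMA_2017_PROFILE = WeatherProfile(
    months={
        7: MonthlyClimate(19.8, 0.29, 15.3, 0.14, 8.5, 0.77, 3.7, 0.27, 0.24, 0.01, 85.4, 0.61),
        8: MonthlyClimate(19.2, 0.27, 14.3, 0.10, 8.8, 0.69, 3.6, 0.27, 0.18, 0.01, 88.7, 0.57),
        9: MonthlyClimate(19.0, 0.38, 14.0, 0.08, 9.4, 0.96, 3.8, 0.36, 0.14, 0.01, 91.2, 0.59),
        10: MonthlyClimate(21.5, 0.30, 14.6, 0.08, 16.8, 0.68, 7.2, 0.27, 0.17, 0.01, 89.6, 0.46),
        11: MonthlyClimate(22.1, 0.26, 15.2, 0.19, 16.1, 0.73, 6.8, 0.29, 0.24, 0.01, 86.2, 0.57),
    }
)


def generate_weather(
    profile: WeatherProfile,
    planting_date: _dt.date,
    n_days: int,
    seed: int,
    dispersion: float = 1.0,
) -> pd.DataFrame:
    """Draw a daily weather series around monthly means.

    Day-to-day variability is reconstructed from the profile's standard
    errors: the daily standard deviation for a month with ``m`` days is taken
    as ``SE * sqrt(m)`` (the SE of a monthly mean of ``m`` independent days),
    scaled by ``dispersion``.  ``dispersion=0`` yields every day exactly at
    its monthly mean.  dap 1 is the day after planting.

    Returns a DataFrame with columns ``dap, date, par_inc, tmin, tmax``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for dap in range(1, n_days + 1):
        date = planting_date + _dt.timedelta(days=dap)
        clim = profile.climate(date.month)
        m = calendar.monthrange(date.year, date.month)[1]
        scale = dispersion * np.sqrt(m)
        par = clim.par + rng.normal() * clim.par_se * scale
        tmin = clim.tmin + rng.normal() * clim.tmin_se * scale
        tmax = clim.tmax + rng.normal() * clim.tmax_se * scale
        par = max(par, 0.0)
        if tmin > tmax:  # rare overlap under heavy dispersion
            tmin, tmax = tmax, tmin
        rows.append((dap, date, par, tmin, tmax))
    return pd.DataFrame(rows, columns=["dap", "date", "par_inc", "tmin", "tmax"])


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Check the weather-table schema and physical invariants.

    Raises ``ValueError`` naming the first offending row.
    """
    required = {"dap", "par_inc", "tmin", "tmax"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    if len(weather) == 0:
        raise ValueError("weather table is empty")
    dap = weather["dap"].to_numpy()
    if dap[0] != 1 or not np.array_equal(dap, np.arange(1, len(dap) + 1)):
        raise ValueError("weather dap must run 1..n without gaps")
    bad = weather.index[weather["tmin"] > weather["tmax"]]
    if len(bad):
        raise ValueError(f"tmin > tmax at row {bad[0]} (dap {weather.loc[bad[0], 'dap']})")
    bad = weather.index[weather["par_inc"] < 0]
    if len(bad):
        raise ValueError(f"negative par_inc at row {bad[0]} (dap {weather.loc[bad[0], 'dap']})")
    return weather


def thermal_time(weather: pd.DataFrame, t_base: float = DEFAULT_T_BASE) -> np.ndarray:
    """Cumulative thermal time (degC d) at the end of each day.

    The daily increment is ``max(0, (tmin + tmax)/2 - t_base)``.
    """
    if len(weather) == 0:
        raise ValueError("weather series is empty")
    tmean = (weather["tmin"].to_numpy() + weather["tmax"].to_numpy()) / 2.0
    inc = np.maximum(tmean - t_base, 0.0)
    return np.cumsum(inc)


def cumulative_par(weather: pd.DataFrame, from_dap: int, to_dap: int) -> float:
    """Cumulative incident PAR (MJ m^-2) over the closed dap interval."""
    n = len(weather)
    if not (1 <= from_dap <= to_dap <= n):
        raise ValueError(
            f"dap interval [{from_dap}, {to_dap}] outside weather series (1..{n})"
        )
    sel = (weather["dap"] >= from_dap) & (weather["dap"] <= to_dap)
    return float(weather.loc[sel, "par_inc"].sum())
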
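"""Cumulative growing degree days (thermal time).

Daily thermal time follows the Peterson form: the average of the daily
minimum and maximum temperature minus a base threshold of 4.0 degC, with
values below the base or above an upper cap of 25 degC set to those limits.
Accumulation runs from 1 January up to, but excluding, the target date
(imaging flights happen in the morning, before that day's heat sum).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDataError
from .types import as_date


@dataclass(frozen=True)
class GddConfig:
    base_temp: float = 4.0   # degC
    upper_cap: float = 25.0  # degC
    start: _dt.date = _dt.date(2020, 1, 1)
    end_exclusive: bool = True
    #: if True, clamp the daily min and max separately before averaging
    #: (default reading); if False, clamp the daily mean instead
    clamp_extremes: bool = True

    def __post_init__(self):
        if self.base_temp >= self.upper_cap:
            raise ConfigurationError("base_temp must be below upper_cap")


def daily_gdd(tmin: np.ndarray, tmax: np.ndarray,
              config: GddConfig = GddConfig()) -> np.ndarray:
    """Per-day thermal-time contribution in degC*day (always >= 0)."""
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if config.clamp_extremes:
        lo = np.clip(tmin, config.base_temp, config.upper_cap)
        hi = np.clip(tmax, config.base_temp, config.upper_cap)
        mean = (lo + hi) / 2.0
    else:
        mean = np.clip((tmin + tmax) / 2.0, config.base_temp, config.upper_cap)
    return mean - config.base_temp


def _check_contiguous(dates: pd.Series, start: _dt.date, end: _dt.date) -> None:
    wanted = pd.date_range(start, end, freq="D").date
    have = set(dates)
    missing = [d for d in wanted if d not in have]
    if missing:
        raise MissingDataError(
            f"daily series has {len(missing)} missing date(s), first: {missing[0]}",
            missing_dates=missing)


def cumulative_gdd(temps: pd.DataFrame, end_date,
                   config: GddConfig = GddConfig()) -> float:
    """Accumulated GDD from ``config.start`` to ``end_date``.

    ``temps`` must have columns ``date``, ``tmin``, ``tmax`` covering the
    accumulation window contiguously. With the default end-exclusive
    convention the end date itself does not contribute.
    """
    end_date = as_date(end_date)
    t = temps.copy()
    t["date"] = [as_date(d) for d in t["date"]]
    last = end_date - _dt.timedelta(days=1) if config.end_exclusive else end_date
    if last < config.start:
        return 0.0
    _check_contiguous(t["date"], config.start, last)
    sel = t[(t["date"] >= config.start) & (t["date"] <= last)].sort_values("date")
    return float(np.sum(daily_gdd(sel["tmin"].values, sel["tmax"].values, config)))


def gdd_table(temps: pd.DataFrame, dates, config: GddConfig = GddConfig()) -> pd.Series:
    """Cumulative GDD for each requested date (e.g. imaging dates)."""
    out = {as_date(d): cumulative_gdd(temps, d, config) for d in dates}
    return pd.Series(out, name="gdd").sort_index()
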
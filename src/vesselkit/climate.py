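"""Calendar-anchored 30-day climate windows for ring-year correlation analysis.

The dormant-to-growing-season span relevant for early-wood formation runs
from May of the year before ring formation to July of the ring year.  It is
covered by 30-day windows anchored on the 1st and 16th of each month (a
15-day stepping that never drifts across month boundaries), 29 windows in
total; the last admissible start is current-year July 1.  Each window is
summarised by its mean temperature, precipitation sum and heat-moisture
index HMI = (T̄ + 10) / (P / 1000).
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowDef",
    "ClimateWindow",
    "make_windows",
    "heat_moisture_index",
    "window_stats",
    "assemble_climate_matrix",
    "daily_frame_to_series",
    "MissingDataError",
]

WINDOW_DAYS = 30
#: fraction of window days that may be missing before summaries are dropped
MISSING_TOLERANCE = 0.10

_MONTH_ABBR = calendar.month_abbr  # 1-indexed


class MissingDataError(ValueError):
    """Daily data do not cover a requested window or year range."""


@dataclass(frozen=True)
class WindowDef:
    """One 30-day window anchor: month/day plus previous/current-year flag."""

    month: int
    day: int  # 1 or 16
    relation: str  # "previous_year" | "current_year"

    @property
    def label(self) -> str:
        prefix = "prev" if self.relation == "previous_year" else "curr"
        return f"{prefix}-{_MONTH_ABBR[self.month]}-{self.day}"

    def start(self, ring_year: int) -> dt.date:
        year = ring_year - 1 if self.relation == "previous_year" else ring_year
        return dt.date(year, self.month, self.day)

    def dates(self, ring_year: int) -> pd.DatetimeIndex:
        return pd.date_range(self.start(ring_year), periods=WINDOW_DAYS, freq="D")


@dataclass(frozen=True)
class ClimateWindow:
    """Summaries of one window in one ring year (NaN where undefined)."""

    label: str
    relation: str
    ring_year: int
    tmean_mean: float
    precip_sum: float
    hmi: float


def make_windows() -> list[WindowDef]:
    """The 29 window anchors from previous-year May 1 to current-year July 1.

    Anchors fall on the 1st and 16th of every month from May of the previous
    year through July of the current year; the July 16 start is omitted
    because its 30-day span would run past July.
    """
    windows = [
        WindowDef(month, day, "previous_year")
        for month in range(5, 13)
        for day in (1, 16)
    ]
    windows += [
        WindowDef(month, day, "current_year")
        for month in range(1, 8)
        for day in (1, 16)
        if not (month == 7 and day == 16)
    ]
    return windows


def heat_moisture_index(tmean_mean: float, precip_sum: float) -> float:
    """HMI = (T̄ + 10) / (P / 1000); NaN when P = 0 (index undefined).

    The annual heat-moisture functional form applied to 30-day aggregates:
    higher values indicate warmer and/or drier (more arid) conditions.
    """
    if precip_sum < 0:
        raise ValueError("precipitation sum cannot be negative")
    if precip_sum == 0 or np.isnan(precip_sum):
        return float("nan")
    return (tmean_mean + 10.0) / (precip_sum / 1000.0)


def daily_frame_to_series(daily: pd.DataFrame) -> pd.DataFrame:
    """Normalise a daily-climate table to a date-indexed frame.

    Expects columns ``date``, ``tmean_c``, ``precip_mm`` (extra columns are
    kept).  Dates must be unique; precipitation must be non-negative.
    """
    if "date" in daily.columns:
        out = daily.copy()
        out["date"] = pd.to_datetime(out["date"])
        out = out.set_index("date")
    else:
        out = daily.copy()
        out.index = pd.to_datetime(out.index)
    if out.index.has_duplicates:
        raise ValueError("daily climate dates must be unique")
    if (out["precip_mm"].dropna() < 0).any():
        raise ValueError("precipitation must be non-negative")
    return out.sort_index()


def window_stats(
    daily: pd.DataFrame, window: WindowDef, ring_year: int
) -> ClimateWindow:
    """Summarise one window of one ring year from date-indexed daily data.

    Previous-year windows are anchored to ring_year − 1.  Up to 10% of the 30
    days may be missing (summaries then use the present days); more missing
    days make all three summaries NaN.  A window entirely outside the data
    range raises :class:`MissingDataError`.
    """
    dates = window.dates(ring_year)
    if dates[-1] < daily.index.min() or dates[0] > daily.index.max():
        raise MissingDataError(
            f"window {window.label} of ring year {ring_year} is outside the data range"
        )
    sub = daily.reindex(dates)
    tmean = sub["tmean_c"]
    precip = sub["precip_mm"]
    n_missing = int(tmean.isna().sum() + (precip.isna() & ~tmean.isna()).sum())
    if n_missing > MISSING_TOLERANCE * WINDOW_DAYS:
        t_mean = p_sum = hmi = float("nan")
    else:
        t_mean = float(tmean.mean())
        p_sum = float(precip.sum())
        hmi = heat_moisture_index(t_mean, p_sum)
    return ClimateWindow(window.label, window.relation, ring_year, t_mean, p_sum, hmi)


def assemble_climate_matrix(
    daily: pd.DataFrame, ring_years: list[int] | np.ndarray
) -> pd.DataFrame:
    """Window × ring-year table of the three climate summaries.

    One row per (window, ring year) with columns ``window_label``,
    ``relation``, ``ring_year``, ``tmean_mean``, ``precip_sum``, ``hmi``.
    The yearly series of each window are directly comparable across years
    because the anchors are identical calendar dates.
    """
    ring_years = sorted(int(y) for y in ring_years)
    if not ring_years:
        raise ValueError("ring_years is empty")
    daily = daily if isinstance(daily.index, pd.DatetimeIndex) else daily_frame_to_series(daily)
    missing_years = [
        y
        for y in ring_years
        if dt.date(y - 1, 5, 1) < daily.index.min().date()
        or dt.date(y, 7, 30) > daily.index.max().date()
    ]
    if missing_years:
        raise MissingDataError(
            f"daily climate does not cover ring years {missing_years}"
        )
    rows = []
    for window in make_windows():
        for year in ring_years:
            cw = window_stats(daily, window, year)
            rows.append(
                {
                    "window_label": cw.label,
                    "relation": cw.relation,
                    "ring_year": cw.ring_year,
                    "tmean_mean": cw.tmean_mean,
                    "precip_sum": cw.precip_sum,
                    "hmi": cw.hmi,
                }
            )
    return pd.DataFrame(rows)
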
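"""Growing-season detection, thermal sums and between-survey climate deltas.

The growing season of a year starts the day after the first run of at
least ``window`` consecutive days with daily mean temperature at or above
the ``base`` threshold (+5 C by default), and ends the day after the
first subsequent run of at least ``window`` consecutive days below the
threshold; if no closing run occurs the season extends to the year end.

The annual thermal sum is the effective temperature sum over the growing
season: sum of max(tmean - base, 0) in degree-days (``gdd_mode='excess'``,
the Nordic convention). ``gdd_mode='raw'`` instead sums the plain daily
means of above-base season days.

Between-survey change is the OLS slope of the annual series regressed on
year, multiplied by the number of years between the surveys, which makes
sites with different sampling intervals comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "growing_season",
    "thermal_sum",
    "annual_precip",
    "trend_delta",
    "annual_climate",
    "climate_deltas",
]


def _first_run(mask: np.ndarray, window: int, start: int = 0) -> int:
    """Index of the first element of the first run of >= window Trues at
    or after ``start``; -1 if none."""
    run = 0
    for i in range(start, len(mask)):
        run = run + 1 if mask[i] else 0
        if run == window:
            return i - window + 1
    return -1


def growing_season(
    tmean, base: float = 5.0, window: int = 10
) -> tuple[int, int] | None:
    """Detect the growing season in one year of daily mean temperatures.

    Returns 1-based (start_day, end_day) within the year, or None when no
    qualifying warm run exists. ``start_day`` is the day after the first
    run of >= ``window`` consecutive days with tmean >= ``base``;
    ``end_day`` the day after the first subsequent run of >= ``window``
    consecutive days below ``base``, or the last day of the year.
    """
    t = np.asarray(tmean, dtype=float)
    if len(t) < window:
        raise ValidationError(
            f"series of {len(t)} days shorter than window {window}"
        )
    warm_run = _first_run(t >= base, window)
    if warm_run < 0:
        return None
    start = warm_run + window  # 0-based index of day after the run
    cold_run = _first_run(t < base, window, start=start)
    if cold_run < 0:
        end = len(t) - 1
    else:
        end = cold_run + window
        end = min(end, len(t) - 1)
    return (start + 1, end + 1)  # 1-based day-of-year


def thermal_sum(
    tmean, season: tuple[int, int] | None, base: float = 5.0, mode: str = "excess"
) -> float:
    """Thermal sum (degree-days) over a detected growing season.

    ``mode='excess'`` sums max(tmean - base, 0); ``mode='raw'`` sums the
    raw daily means of days exceeding the base. Returns 0 for a None
    season.
    """
    if season is None:
        return 0.0
    if mode not in ("excess", "raw"):
        raise ValidationError("mode must be 'excess' or 'raw'")
    t = np.asarray(tmean, dtype=float)
    start, end = season
    seg = t[start - 1 : end]
    if mode == "excess":
        return float(np.maximum(seg - base, 0.0).sum())
    return float(seg[seg > base].sum())


def annual_precip(prec) -> float:
    """Annual precipitation: plain sum of the daily series (mm)."""
    p = np.asarray(prec, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative precipitation value")
    return float(p.sum())


def trend_delta(values, years, year0: int, year1: int) -> dict:
    """OLS trend of an annual series and its change over a survey interval.

    Regresses ``values`` on ``years`` restricted to [year0, year1] and
    multiplies the slope by the interval length. Requires >= 3 annual
    values inside the interval.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(years, dtype=float)
    keep = (y >= year0) & (y <= year1) & np.isfinite(v)
    v, y = v[keep], y[keep]
    if len(v) < 3:
        raise InsufficientDataError(
            f"only {len(v)} annual values inside [{year0}, {year1}]"
        )
    slope, intercept = np.polyfit(y, v, 1)
    span = year1 - year0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "delta": float(slope * span),
        "years": span,
        "n_years": int(len(v)),
    }


def annual_climate(
    climate: pd.DataFrame,
    base: float = 5.0,
    window: int = 10,
    mode: str = "excess",
) -> pd.DataFrame:
    """Annual thermal sums and precipitation per site from daily series.

    ``climate`` is the long daily table (site, date, tmean_c, prec_mm).
    Returns one row per site x year with ``gdd`` and ``prec``.
    """
    rows = []
    for (site, year), grp in climate.groupby(
        ["site", climate["date"].dt.year], sort=True
    ):
        t = grp["tmean_c"].to_numpy()
        season = growing_season(t, base, window)
        rows.append(
            {
                "site": site,
                "year": int(year),
                "gdd": thermal_sum(t, season, base, mode),
                "prec": annual_precip(grp["prec_mm"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def climate_deltas(
    climate: pd.DataFrame,
    survey_years: dict,
    base: float = 5.0,
    window: int = 10,
    mode: str = "excess",
) -> pd.DataFrame:
    """Per-site change in thermal sum and precipitation between surveys.

    ``survey_years`` maps site -> (original_year, resurvey_year). Output
    columns: slope_gdd (Cd/yr), delta_gdd (Cd), slope_prec (mm/yr^2 as a
    trend of annual mm), delta_prec (mm/yr), years.
    """
    annual = annual_climate(climate, base, window, mode)
    rows = []
    for site, (y0, y1) in survey_years.items():
        sub = annual[annual["site"] == site]
        gdd = trend_delta(sub["gdd"], sub["year"], y0, y1)
        prc = trend_delta(sub["prec"], sub["year"], y0, y1)
        rows.append(
            {
                "site": site,
                "slope_gdd": gdd["slope"],
                "delta_gdd": gdd["delta"],
                "slope_prec": prc["slope"],
                "delta_prec": prc["delta"],
                "years": gdd["years"],
            }
        )
    return pd.DataFrame(rows)
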
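"""Climatological baselines, anomalies, warming trends, and extrapolation.

The climatological baseline is the mean annual cycle of weekly temperature
over a 30-year reference period (default 1991-2020), fitted by ordinary
least squares on an intercept plus a 6-df natural cubic spline of the day
of the year; anomalies are observed minus baseline.  Summer (ISO weeks
22-35) mean temperatures are standardized against the reference-period
distribution of summer means.  Warming is summarized by piecewise linear
trends (OLS on calendar year, with optional excluded years), and the
summer heat burden is linked to summer warmth by the OLS slope of annual
attributable deaths on summer mean temperature, which supports a linear
forward extrapolation of future burdens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .splines import SplineSpec, natural_cubic_basis
from .synthetic import week_midpoint_doy

__all__ = [
    "ClimatologyFit",
    "TrendFit",
    "fit_baseline_cycle",
    "anomalies",
    "summer_mean",
    "standardized_anomaly",
    "fit_linear_trend",
    "mortality_temperature_slope",
    "extrapolate",
    "SUMMER_WEEKS",
]

SUMMER_WEEKS = tuple(range(22, 36))


def _doy_spline_design(doy: np.ndarray, df: int = 6) -> np.ndarray:
    # df basis columns need df-1 internal knots; equally spaced over the year
    knots = np.linspace(1.0, 365.25, df + 1)
    spec = SplineSpec(internal_knots=tuple(knots[1:-1]), boundary_knots=(knots[0], knots[-1]))
    return natural_cubic_basis(np.asarray(doy, dtype=float), spec)


@dataclass
class ClimatologyFit:
    """Mean annual temperature cycle over a reference period."""

    intercept: float
    doy_spline_coef: np.ndarray
    reference_period: tuple[int, int]
    df: int = 6

    def baseline(self, week: np.ndarray | int) -> np.ndarray:
        """Baseline temperature of an ISO week; periodic, year-independent."""
        doy = week_midpoint_doy(np.atleast_1d(np.asarray(week, dtype=float)))
        return self.intercept + _doy_spline_design(doy, self.df) @ self.doy_spline_coef


def fit_baseline_cycle(
    weekly: pd.DataFrame,
    reference_period: tuple[int, int] = (1991, 2020),
    df: int = 6,
) -> ClimatologyFit:
    """OLS fit of weekly temperature on a day-of-year natural spline.

    ``weekly`` needs columns iso_year, iso_week, temp_c; only rows inside
    the reference period enter the fit.  The day of the year of a week is
    its canonical Thursday (ISO pivot day), making the baseline identical
    across years.
    """
    lo, hi = reference_period
    sub = weekly[(weekly["iso_year"] >= lo) & (weekly["iso_year"] <= hi)]
    missing_years = sorted(set(range(lo, hi + 1)) - set(sub["iso_year"]))
    if missing_years:
        raise ValueError(
            f"reference period {reference_period} not covered: missing years {missing_years}"
        )
    doy = week_midpoint_doy(sub["iso_week"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(sub)), _doy_spline_design(doy, df)])
    coef, *_ = np.linalg.lstsq(X, sub["temp_c"].to_numpy(dtype=float), rcond=None)
    return ClimatologyFit(
        intercept=float(coef[0]),
        doy_spline_coef=coef[1:],
        reference_period=reference_period,
        df=df,
    )


def anomalies(weekly: pd.DataFrame, clim: ClimatologyFit) -> pd.DataFrame:
    """Observed minus baseline temperature per week."""
    out = weekly.copy()
    out["baseline"] = clim.baseline(weekly["iso_week"].to_numpy())
    out["anomaly"] = out["temp_c"] - out["baseline"]
    return out


def summer_mean(weekly: pd.DataFrame, year: int, weeks: Iterable[int] = SUMMER_WEEKS) -> float:
    """Arithmetic mean of the summer weeks' temperatures of one year."""
    weeks = tuple(weeks)
    sub = weekly[(weekly["iso_year"] == year) & (weekly["iso_week"].isin(weeks))]
    missing = sorted(set(weeks) - set(sub["iso_week"]))
    if missing:
        raise ValueError(f"year {year} is missing summer weeks {missing}")
    return float(sub["temp_c"].mean())


def standardized_anomaly(t: float, mu: float, sigma: float) -> float:
    """z = (t - mu) / sigma; reported to two decimals in the tables."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (t - mu) / sigma


def reference_mu_sigma(
    summer_means: dict[int, float],
    reference_period: tuple[int, int] = (1991, 2020),
    ddof: int = 0,
) -> tuple[float, float]:
    """Mean and sd of reference-period summer means (population convention)."""
    vals = np.array([v for y, v in summer_means.items() if reference_period[0] <= y <= reference_period[1]])
    return float(vals.mean()), float(vals.std(ddof=ddof))


@dataclass
class TrendFit:
    """OLS linear trend of a yearly quantity on the calendar year."""

    slope: float
    intercept: float
    period: tuple[int, int]
    excluded_years: frozenset[int] = field(default_factory=frozenset)

    def predict(self, year: float) -> float:
        return self.intercept + self.slope * year


def fit_linear_trend(
    yearly: dict[int, float],
    period: tuple[int, int],
    exclude: Iterable[int] = (),
) -> TrendFit:
    """OLS trend over a year range with excluded years removed."""
    exclude = frozenset(exclude)
    pts = sorted(
        (y, v) for y, v in yearly.items()
        if period[0] <= y <= period[1] and y not in exclude
    )
    if len(pts) < 3:
        raise ValueError(f"only {len(pts)} years after exclusions; need >= 3")
    years = np.array([p[0] for p in pts], dtype=float)
    vals = np.array([p[1] for p in pts], dtype=float)
    slope, intercept = np.polyfit(years, vals, 1)
    return TrendFit(slope=float(slope), intercept=float(intercept), period=period, excluded_years=exclude)


def mortality_temperature_slope(
    summer_temps: dict[int, float],
    summer_an: dict[int, float],
    years: Iterable[int],
    population: float | None = None,
) -> float:
    """OLS slope of summer attributable deaths on summer mean temperature.

    Units: additional summer deaths per +1 degC (per million inhabitants
    when a population is given).
    """
    years = sorted(years)
    missing = [y for y in years if y not in summer_temps or y not in summer_an]
    if missing:
        raise ValueError(f"missing paired values for years {missing}")
    if len(years) < 3:
        raise ValueError("need at least 3 paired years")
    t = np.array([summer_temps[y] for y in years])
    a = np.array([summer_an[y] for y in years])
    if population is not None:
        a = a / population * 1e6
    slope, _ = np.polyfit(t, a, 1)
    return float(slope)


def extrapolate(
    temp_trend: TrendFit,
    burden_slope: float,
    anchor: tuple[int, float, float],
    target_year: int,
) -> float:
    """Project the summer burden forward along the warming trend.

    ``anchor`` is (year, attributable deaths, summer mean temperature); the
    projected burden is anchor AN plus burden_slope times the projected
    warming between the anchor year and the target year, the projected
    temperatures being read off the trend line.
    """
    a_year, a_an, a_temp = anchor
    if target_year <= a_year:
        raise ValueError("target year must be after the anchor year")
    dtemp = temp_trend.predict(target_year) - a_temp
    return a_an + burden_slope * dtemp
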
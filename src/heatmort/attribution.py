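"""Minimum mortality temperatures, attributable deaths, and Monte Carlo CIs.

The pooled (BLUP) cumulative exposure-response curve of each region is
re-referenced at its minimum: the minimum mortality temperature (MMT), the
temperature of lowest risk over the region's observed weekly temperature
range.  For every week whose mean temperature exceeds the MMT the
attributable number of deaths is

    AN_t = deaths_t * (1 - exp(-f(x_t)))

with f the cumulative log relative risk at the week's temperature relative
to the MMT (the forward, same-week attribution; a backward variant spreads
the lag-specific contributions of past weeks' exposures).  Regional weekly
numbers are summed over weeks and regions; 95% confidence intervals come
from Monte Carlo draws of the curve coefficients, each draw aggregated
before taking empirical percentiles, so intervals are coherent at every
aggregation level.  Draws are deliberately not truncated at zero: lower
bounds of uncertain burdens can be negative.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta import Blup
from .splines import SplineSpec, natural_cubic_basis

__all__ = [
    "ExposureResponse",
    "AttributionResult",
    "find_mmt",
    "cumulative_log_rr",
    "attributable_number",
    "monte_carlo_ci",
    "aggregate",
    "attributable_rate",
    "percent_excess",
    "region_rng",
]

SUMMER_WEEKS = tuple(range(22, 36))  # weeks 22-35, 30 May - 4 September


@dataclass
class ExposureResponse:
    """A cumulative exposure-response curve referenced at its MMT."""

    grid: np.ndarray
    log_rr: np.ndarray
    mmt: float
    region_id: str
    stratum: str


@dataclass
class AttributionResult:
    """Attributable deaths (and optionally rates) at some aggregation level."""

    level: str  # region | country | europe
    key: str
    stratum: str
    period: str  # week | summer | year
    an_point: float
    an_draws: np.ndarray
    population: float | None = None

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.an_draws, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def rate_per_million(self) -> tuple[float, float, float] | None:
        if self.population is None:
            return None
        point = attributable_rate(self.an_point, self.population)
        lo, hi = np.percentile(self.an_draws / self.population * 1e6, [2.5, 97.5])
        return point, float(lo), float(hi)


def _curve(coef: np.ndarray, spec: SplineSpec, x: np.ndarray) -> np.ndarray:
    return natural_cubic_basis(np.atleast_1d(x), spec) @ coef


def find_mmt(
    coef: np.ndarray,
    spec: SplineSpec,
    temp_range: tuple[float, float],
    step: float = 0.1,
) -> float:
    """Temperature of minimum risk on a fixed grid over the observed range.

    Ties break toward the lower temperature (first minimum on the ascending
    grid).
    """
    lo, hi = temp_range
    grid = np.round(np.arange(np.floor(lo / step) * step, hi + step / 2, step), 6)
    vals = _curve(np.asarray(coef), spec, grid)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite curve values on the MMT search grid")
    return float(grid[int(np.argmin(vals))])


def cumulative_log_rr(
    blup: Blup,
    spec: SplineSpec,
    x: np.ndarray,
    reference: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative log relative risk at x versus a reference temperature.

    Returns (log RR, pointwise variance); the variance is the quadratic form
    of the basis-difference rows with the BLUP covariance (delta method).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    B = natural_cubic_basis(x, spec) - natural_cubic_basis(np.array([reference]), spec)
    log_rr = B @ blup.coef
    var = np.einsum("ij,jk,ik->i", B, blup.vcov, B)
    return log_rr, var


def exposure_response(
    blup: Blup, spec: SplineSpec, temp_range: tuple[float, float], step: float = 0.1
) -> ExposureResponse:
    mmt = find_mmt(blup.coef, spec, temp_range, step)
    grid = np.round(np.arange(np.floor(temp_range[0] / step) * step, temp_range[1] + step / 2, step), 6)
    log_rr, _ = cumulative_log_rr(blup, spec, grid, mmt)
    return ExposureResponse(grid=grid, log_rr=log_rr, mmt=mmt, region_id=blup.region_id, stratum=blup.stratum)


def _forward_an(
    temps: np.ndarray, deaths: np.ndarray, coef: np.ndarray, spec: SplineSpec, mmt: float
) -> np.ndarray:
    fx = _curve(coef, spec, temps) - _curve(coef, spec, np.array([mmt]))[0]
    hot = temps > mmt
    return np.where(hot, deaths * (1.0 - np.exp(-fx)), 0.0)


def _backward_an(
    temps: np.ndarray,
    deaths: np.ndarray,
    coef: np.ndarray,
    spec: SplineSpec,
    mmt: float,
    lags: tuple[int, ...] = (0, 1, 2, 3),
) -> np.ndarray:
    """Backward attribution: each week's deaths carry the accumulated heat
    contribution of its own and the preceding max-lag weeks' exposures.

    The cumulative curve is split evenly across the lags (the reduced
    coefficients no longer identify lag-specific curves); exposures at or
    below the MMT contribute nothing.
    """
    f = _curve(coef, spec, temps) - _curve(coef, spec, np.array([mmt]))[0]
    f = np.where(temps > mmt, f, 0.0)
    n = temps.size
    acc = np.zeros(n)
    w = 1.0 / len(lags)
    for lag in lags:
        shifted = np.zeros(n)
        shifted[lag:] = f[: n - lag] if lag else f
        acc += w * shifted
    return deaths * (1.0 - np.exp(-acc))


def attributable_number(
    series: pd.DataFrame,
    blup: Blup,
    spec: SplineSpec,
    mmt: float,
    stratum: str = "total",
    direction: str = "forward",
    coef: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weekly attributable deaths for one region.

    ``series`` needs columns iso_year, iso_week, temp_c, deaths_<stratum>.
    ``coef`` overrides the BLUP point coefficients (used by the Monte Carlo
    machinery); the MMT stays fixed either way.
    """
    temps = series["temp_c"].to_numpy(dtype=float)
    lo, hi = spec.boundary_knots
    if not (lo - 0.11 <= mmt <= hi + 0.11):  # grid granularity slack
        raise ValueError(f"mmt {mmt} outside the curve domain [{lo}, {hi}]")
    deaths = series[f"deaths_{stratum}"].to_numpy(dtype=float)
    c = blup.coef if coef is None else coef
    if direction == "forward":
        an = _forward_an(temps, deaths, c, spec, mmt)
    elif direction == "backward":
        an = _backward_an(temps, deaths, c, spec, mmt)
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    out = series[["iso_year", "iso_week"]].copy()
    out["an"] = an
    return out


def region_rng(seed: int, region_id: str) -> np.random.Generator:
    """Deterministic per-region substream so aggregation is draw-aligned."""
    return np.random.default_rng([seed, zlib.crc32(region_id.encode())])


def monte_carlo_ci(
    series: pd.DataFrame,
    blup: Blup,
    spec: SplineSpec,
    mmt: float,
    stratum: str = "total",
    direction: str = "forward",
    n_sim: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Weekly attributable numbers with coefficient-uncertainty draws.

    Coefficients are drawn from N(blup.coef, blup.vcov) in a per-region
    substream of ``seed``; the MMT is held fixed at its point estimate.
    Returns (weekly point ANs, draws matrix of shape (n_sim, n_weeks)).
    """
    vcov = 0.5 * (blup.vcov + blup.vcov.T)
    if np.linalg.eigvalsh(vcov).min() < -1e-8:
        raise np.linalg.LinAlgError("BLUP covariance is not positive semidefinite")
    rng = region_rng(seed, blup.region_id)
    draws_coef = rng.multivariate_normal(blup.coef, vcov, size=n_sim, method="svd")
    point = attributable_number(series, blup, spec, mmt, stratum, direction)
    n_weeks = len(point)
    if direction == "forward":
        temps = series["temp_c"].to_numpy(dtype=float)
        deaths = series[f"deaths_{stratum}"].to_numpy(dtype=float)
        Bdiff = natural_cubic_basis(temps, spec) - natural_cubic_basis(np.array([mmt]), spec)
        hot = (temps > mmt).astype(float) * deaths
        draws = hot[None, :] * (1.0 - np.exp(-(draws_coef @ Bdiff.T)))
    else:
        draws = np.empty((n_sim, n_weeks))
        for d in range(n_sim):
            draws[d] = attributable_number(
                series, blup, spec, mmt, stratum, direction, coef=draws_coef[d]
            )["an"].to_numpy()
    return point, draws


def _select_period(df: pd.DataFrame, period: str, year: int | None) -> np.ndarray:
    mask = np.ones(len(df), dtype=bool)
    if year is not None:
        mask &= df["iso_year"].to_numpy() == year
    if period == "summer":
        mask &= df["iso_week"].isin(SUMMER_WEEKS).to_numpy()
    elif period not in ("year", "week"):
        raise ValueError("period must be 'week', 'summer' or 'year'")
    return mask


def aggregate(
    parts: list[tuple[pd.DataFrame, np.ndarray]],
    level: str,
    key: str,
    stratum: str,
    period: str = "summer",
    year: int | None = None,
    population: float | None = None,
) -> AttributionResult:
    """Sum point estimates and draw-wise totals across regions and weeks.

    Every element of ``parts`` is the (weekly point frame, draws matrix) of
    one region; draws must be aligned (same count, same draw indexing) so
    that percentiles are taken of the aggregated totals.
    """
    if not parts:
        raise ValueError("nothing to aggregate")
    n_sims = {p[1].shape[0] for p in parts}
    if len(n_sims) != 1:
        raise ValueError(f"mismatched Monte Carlo draw counts: {sorted(n_sims)}")
    total_point = 0.0
    total_draws = np.zeros(n_sims.pop())
    for weekly, draws in parts:
        mask = _select_period(weekly, period, year)
        total_point += float(weekly.loc[mask, "an"].sum())
        total_draws = total_draws + draws[:, mask].sum(axis=1)
    return AttributionResult(
        level=level,
        key=key,
        stratum=stratum,
        period=period,
        an_point=total_point,
        an_draws=total_draws,
        population=population,
    )


def attributable_rate(an: float, population: float) -> float:
    """Deaths per million inhabitants."""
    if population <= 0:
        raise ValueError("population must be positive")
    return an / population * 1e6


def percent_excess(a: float, b: float) -> float:
    """Percent excess of a over b: 100 * (a/b - 1)."""
    if b <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (a / b - 1.0)
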
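"""Location-specific quasi-Poisson regression and reduction to cumulative curves.

For each region (and stratum) the weekly death counts are regressed, with a
log link, on an intercept, a natural cubic spline of the week index (8 df
per year, controlling seasonality and long-term trends) and the
temperature cross-basis (natural cubic spline with knots at the 10th/50th/
90th centiles of the region's weekly temperatures, integer lags 0-3 weeks).
Point estimates are Poisson maximum likelihood; the covariance is scaled by
the Pearson dispersion, which is what "quasi-Poisson" means operationally.

The cross-basis block of the fit is then summed over lags to give the
4-coefficient overall cumulative exposure-response association per region,
with its 4x4 covariance, which is what the second stage pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .splines import (
    CrossBasis,
    SplineSpec,
    build_cross_basis,
    reduction_transform,
    spec_from_percentiles,
    time_spline,
)

__all__ = [
    "FirstStageFit",
    "ReducedAssoc",
    "fit_quasipoisson",
    "qaic",
    "reduce_to_cumulative",
    "fit_region",
    "fit_all_regions",
    "reduced_to_frame",
    "frame_to_reduced",
]

logger = logging.getLogger("heatmort")


@dataclass
class FirstStageFit:
    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    loglik: float  # Poisson log-likelihood at the ML estimates
    converged: bool
    n_obs: int
    n_params: int

    @property
    def qaic(self) -> float:
        return qaic(self)


@dataclass
class ReducedAssoc:
    """Overall cumulative exposure-response association of one region/stratum."""

    region_id: str
    stratum: str
    eta: np.ndarray  # 4-vector of cumulative coefficients
    sigma: np.ndarray  # 4x4 covariance
    spec: SplineSpec
    temp_percentiles: dict[str, float]


def fit_quasipoisson(y: np.ndarray, design: np.ndarray) -> FirstStageFit:
    """Quasi-Poisson GLM: Poisson ML point estimates, Pearson-scaled covariance.

    ``design`` must include the intercept column.  Rows are assumed already
    restricted to weeks with complete (non-missing) data.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("death counts must be non-negative integers")
    if not np.any(y > 0):
        raise ValueError("all-zero death counts: nothing to fit")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name offending columns via QR pivoting on the gram matrix
        _, R = np.linalg.qr(X)
        bad = [j for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design is rank deficient (rank {rank} < {X.shape[1]}); "
                         f"suspect columns {bad}")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(scale="X2", maxiter=100, tol=1e-9)
    n, p = X.shape
    return FirstStageFit(
        coef=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        loglik=float(model.loglike(res.params, scale=1.0)),
        converged=bool(res.converged),
        n_obs=n,
        n_params=p,
    )


def qaic(fit: FirstStageFit) -> float:
    """Quasi-likelihood AIC: -2 * Poisson log-likelihood + 2 * phi * p.

    The parameter penalty is inflated by the Pearson dispersion so that
    overdispersion discourages overfitting; lower is better.
    """
    return -2.0 * fit.loglik + 2.0 * fit.dispersion * fit.n_params


def reduce_to_cumulative(
    fit: FirstStageFit,
    cb: CrossBasis,
    cb_slice: slice,
    region_id: str = "",
    stratum: str = "total",
    temps: np.ndarray | None = None,
) -> ReducedAssoc:
    """Sum the cross-basis block over lags: eta = M theta, sigma = M V M^T."""
    M = reduction_transform(cb)
    theta = fit.coef[cb_slice]
    V = fit.vcov[cb_slice, cb_slice]
    pct = {}
    if temps is not None:
        t = np.asarray(temps, dtype=float)
        t = t[np.isfinite(t)]
        pct = {
            "min": float(t.min()),
            "p10": float(np.percentile(t, 10)),
            "p50": float(np.percentile(t, 50)),
            "p90": float(np.percentile(t, 90)),
            "p95": float(np.percentile(t, 95)),
            "max": float(t.max()),
        }
    return ReducedAssoc(
        region_id=region_id,
        stratum=stratum,
        eta=M @ theta,
        sigma=M @ V @ M.T,
        spec=cb.spec,
        temp_percentiles=pct,
    )


@dataclass(frozen=True)
class ModelConfig:
    """First-stage model settings."""

    df_per_year: float = 8.0
    lags: tuple[int, ...] = (0, 1, 2, 3)
    knot_percentiles: tuple[float, ...] = (10.0, 50.0, 90.0)
    calibration_start: tuple[int, int] | None = None  # (iso_year, iso_week)
    calibration_end: tuple[int, int] | None = None
    min_weeks: int = 104
    min_events: int = 10


def _window_mask(df: pd.DataFrame, cfg: ModelConfig) -> np.ndarray:
    key = df["iso_year"] * 100 + df["iso_week"]
    mask = np.ones(len(df), dtype=bool)
    if cfg.calibration_start is not None:
        mask &= key.to_numpy() >= cfg.calibration_start[0] * 100 + cfg.calibration_start[1]
    if cfg.calibration_end is not None:
        mask &= key.to_numpy() <= cfg.calibration_end[0] * 100 + cfg.calibration_end[1]
    return mask


def fit_region(
    weekly: pd.DataFrame,
    stratum: str,
    cfg: ModelConfig = ModelConfig(),
    spec: SplineSpec | None = None,
) -> tuple[FirstStageFit, ReducedAssoc, CrossBasis]:
    """Fit one region/stratum and reduce to the cumulative association.

    ``weekly`` holds one region's rows (iso_year, iso_week, temp_c,
    deaths_<stratum>) in chronological order.  The calibration window
    restricts the rows used; knots come from that window's temperatures
    unless an explicit spline spec is supplied.
    """
    df = weekly.loc[_window_mask(weekly, cfg)].reset_index(drop=True)
    temp = df["temp_c"].to_numpy(dtype=float)
    y = df[f"deaths_{stratum}"].to_numpy(dtype=float)
    if spec is None:
        spec = spec_from_percentiles(temp, cfg.knot_percentiles)

    cb = build_cross_basis(temp, spec, cfg.lags)
    ts = time_spline(len(df), cfg.df_per_year)
    X = np.column_stack([np.ones(len(df)), ts, cb.matrix])
    keep = cb.valid & np.isfinite(y) & np.isfinite(temp)
    # a missing temperature invalidates that week and the following max-lag weeks
    # (already encoded in cb.valid through NaN propagation of lagged values)
    Xk, yk = X[keep], y[keep]
    if keep.sum() < cfg.min_weeks:
        raise ValueError(f"only {keep.sum()} usable weeks (< {cfg.min_weeks})")
    if yk.sum() < cfg.min_events:
        raise ValueError(f"only {int(yk.sum())} events (< {cfg.min_events})")

    fit = fit_quasipoisson(yk, Xk)
    cb_cols = slice(1 + ts.shape[1], 1 + ts.shape[1] + cb.n_columns)
    red = reduce_to_cumulative(fit, cb, cb_cols, stratum=stratum, temps=temp[keep])
    return fit, red, cb


def fit_all_regions(
    weekly: pd.DataFrame,
    regions: pd.DataFrame,
    cfg: ModelConfig = ModelConfig(),
    strata: tuple[str, ...] | None = None,
    specs: dict[str, SplineSpec] | None = None,
) -> tuple[list[ReducedAssoc], list[dict]]:
    """Fit every region x stratum; failures are recorded, not silently dropped.

    Returns the reduced associations and a list of exclusion records
    ``{region_id, stratum, reason}``.
    """
    if strata is None:
        strata = tuple(
            c.removeprefix("deaths_") for c in weekly.columns if c.startswith("deaths_")
        )
    reduced: list[ReducedAssoc] = []
    excluded: list[dict] = []
    for rid, grp in weekly.groupby("region_id", sort=True):
        grp = grp.sort_values(["iso_year", "iso_week"])
        for s in strata:
            try:
                fit, red, _ = fit_region(
                    grp, s, cfg, spec=None if specs is None else specs.get(rid)
                )
            except Exception as exc:  # noqa: BLE001 - report, don't crash the sweep
                logger.warning("region=%s stratum=%s excluded: %s", rid, s, exc)
                excluded.append({"region_id": rid, "stratum": s, "reason": str(exc)})
                continue
            red.region_id = str(rid)
            logger.info(
                "region=%s stratum=%s fit ok dispersion=%.3f n_obs=%d",
                rid, s, fit.dispersion, fit.n_obs,
            )
            reduced.append(red)
    return reduced, excluded


def frame_to_reduced(df: pd.DataFrame) -> list[ReducedAssoc]:
    """Inverse of :func:`reduced_to_frame` (CSV round trip)."""
    out = []
    iu = np.triu_indices(4)
    knot_cols = sorted((c for c in df.columns if c.startswith("knot")), key=lambda c: int(c[4:]))
    for _, row in df.iterrows():
        sigma = np.zeros((4, 4))
        for a, b in zip(*iu):
            sigma[a, b] = sigma[b, a] = row[f"sigma_{a + 1}{b + 1}"]
        knots = [float(row[c]) for c in knot_cols]
        out.append(
            ReducedAssoc(
                region_id=str(row["region_id"]),
                stratum=str(row["stratum"]),
                eta=np.array([row[f"eta{j + 1}"] for j in range(4)]),
                sigma=sigma,
                spec=SplineSpec(internal_knots=tuple(knots[1:-1]), boundary_knots=(knots[0], knots[-1])),
                temp_percentiles={
                    c.removeprefix("temp_"): float(row[c])
                    for c in df.columns
                    if c.startswith("temp_") and np.isfinite(row[c])
                },
            )
        )
    return out


def reduced_to_frame(reduced: list[ReducedAssoc]) -> pd.DataFrame:
    """Flatten reduced associations to a table (sigma as its upper triangle)."""
    rows = []
    iu = np.triu_indices(4)
    for r in reduced:
        row = {"region_id": r.region_id, "stratum": r.stratum}
        row.update({f"eta{j + 1}": r.eta[j] for j in range(4)})
        row.update({f"sigma_{a + 1}{b + 1}": r.sigma[a, b] for a, b in zip(*iu)})
        row.update({f"temp_{k}": v for k, v in r.temp_percentiles.items()})
        row.update({f"knot{j}": k for j, k in enumerate(r.spec.all_knots)})
        rows.append(row)
    return pd.DataFrame(rows)
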
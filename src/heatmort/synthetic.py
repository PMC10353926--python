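"""Synthetic weekly temperature and mortality data with known ground truth.

Emulates the structure of the European weekly-mortality setting: regions
nested in countries, weekly regional mean temperature built from an annual
cycle plus a linear trend and AR(1) noise, and overdispersed weekly death
counts whose log-rate is a seasonal baseline plus a lagged non-linear
temperature contribution.  The temperature-mortality association varies
across regions according to a meta-regression structure: fixed effects of
three region-level predictors (mean temperature, temperature IQR, share of
the population aged 80+) plus country-level random effects.

Ground truth (per-region cumulative curve coefficients, minimum-mortality
temperatures, weekly attributable deaths) is retained so that every later
stage of the pipeline can be checked by parameter recovery.

Default magnitudes are chosen to resemble the European weekly setting:
about 130 all-cause deaths per region-week (an average region of ~660,000
inhabitants), weekly-scale cumulative relative risks of roughly 1.1-1.4 at
the hottest temperatures, and a quasi-Poisson dispersion of 1.5.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .splines import SplineSpec, natural_cubic_basis, spec_from_percentiles

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_regions",
    "generate_temperature",
    "generate_true_association",
    "generate_mortality",
    "generate_dataset",
    "true_attributable",
    "reference_curve_coefficients",
    "weeks_in_year",
    "week_midpoint_doy",
]

# Reference knot layout used to translate the canonical true curve shape into
# the 4-dimensional coefficient space shared by all regions.
REFERENCE_SPEC = SplineSpec(internal_knots=(5.0, 12.0, 20.0), boundary_knots=(-10.0, 30.0))

MEAN_WEEKS_PER_YEAR = 52.18


def _canonical_log_rr(x: np.ndarray) -> np.ndarray:
    """U-shaped weekly-scale cumulative log relative risk with minimum near 18 degC.

    Mild linear cold effect below the optimum and an accelerating heat effect
    above it; RR ~= 1.35 ten degrees above the optimum and ~= 1.11 twenty
    degrees below it.
    """
    x = np.asarray(x, dtype=float)
    cold = 0.005 * np.clip(18.0 - x, 0.0, None)
    dx = np.clip(x - 18.0, 0.0, None)
    heat = 0.010 * dx + 0.0020 * dx**2
    return cold + heat


def reference_curve_coefficients(
    spec: SplineSpec = REFERENCE_SPEC,
    fun: Callable[[np.ndarray], np.ndarray] = _canonical_log_rr,
) -> np.ndarray:
    """Least-squares projection of a log-RR shape onto a spline basis.

    The intercept of the projection is discarded: log-RR curves are defined
    only up to the reference temperature, fixed later at the MMT.
    """
    grid = np.linspace(spec.boundary_knots[0], spec.boundary_knots[1], 400)
    B = np.column_stack([np.ones(grid.size), natural_cubic_basis(grid, spec)])
    coef, *_ = np.linalg.lstsq(B, fun(grid), rcond=None)
    return coef[1:]


def _default_beta_true() -> np.ndarray:
    """Fixed-effect matrix: rows = (intercept, z mean temp, z IQR, z %80+).

    Warmer regions and regions with older populations get proportionally
    stronger curves; wider temperature variability a slightly flatter one.
    """
    eta0 = reference_curve_coefficients()
    scales = np.array([1.0, 0.25, -0.10, 0.20])
    return np.outer(scales, eta0)


def _default_psi_country() -> np.ndarray:
    eta0 = reference_curve_coefficients()
    return np.diag((0.15 * eta0) ** 2)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic-data generator.

    The defaults mirror the target study design: 35 countries with about 24
    regions each (~823 regions), weekly data for 2015-2022, counts whose
    variance is 1.5x their mean.  Tests and examples pass smaller values
    explicitly.
    """

    n_countries: int = 35
    regions_per_country: int = 24
    year_start: int = 2015
    year_end: int = 2022
    seed: int = 12345
    strata: tuple[str, ...] = ("total",)
    baseline_rate: dict[str, float] = field(default_factory=lambda: {"total": 130.0})
    overdispersion: float = 1.5
    beta_true: np.ndarray = field(default_factory=_default_beta_true)
    psi_country: np.ndarray = field(default_factory=_default_psi_country)
    # temperature process (per-region parameters drawn uniformly from ranges)
    clim_mean_range: tuple[float, float] = (4.0, 19.0)
    amplitude_range: tuple[float, float] = (6.0, 11.0)
    trend_per_year: float = 0.03
    noise_sd: float = 1.8
    ar1: float = 0.5
    peak_doy: float = 200.0
    # mortality process
    seasonal_amplitude: float = 0.10
    seasonal_peak_doy: float = 15.0
    lag_weights: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    # region demographics
    population_range: tuple[float, float] = (150_000.0, 1_500_000.0)
    pct80_range: tuple[float, float] = (3.0, 8.0)
    # calendar and truth options
    week53: str = "drop"  # or "keep"
    truth_kind: str = "in-basis"  # or "quadratic" (off-basis misspecification)

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.regions_per_country < 1:
            raise ValueError("n_countries and regions_per_country must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("empty year range")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        beta = np.asarray(self.beta_true, dtype=float)
        if beta.shape != (4, 4):
            raise ValueError("beta_true must be (1 + 3 predictors) x 4")
        psi = np.asarray(self.psi_country, dtype=float)
        if psi.shape != (4, 4) or not np.allclose(psi, psi.T):
            raise ValueError("psi_country must be symmetric 4x4")
        if np.linalg.eigvalsh(psi).min() < -1e-10:
            raise ValueError("psi_country must be positive semidefinite")
        if self.week53 not in ("drop", "keep"):
            raise ValueError("week53 must be 'drop' or 'keep'")
        if self.truth_kind not in ("in-basis", "quadratic"):
            raise ValueError("truth_kind must be 'in-basis' or 'quadratic'")
        if not np.isclose(sum(self.lag_weights), 1.0):
            raise ValueError("lag_weights must sum to 1")
        object.__setattr__(self, "beta_true", beta)
        object.__setattr__(self, "psi_country", psi)

    @property
    def n_regions(self) -> int:
        return self.n_countries * self.regions_per_country

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


def weeks_in_year(year: int, week53: str = "drop") -> int:
    """Number of ISO weeks kept for a year (52, or 53 when kept and present)."""
    if week53 == "keep" and datetime.date(year, 12, 28).isocalendar()[1] == 53:
        return 53
    return 52


def week_midpoint_doy(week: int) -> float:
    """Canonical day-of-year of an ISO week's Thursday (pivot day).

    Uses the idealized calendar in which week 1 starts on 1 January, making
    the mapping identical across years (day 4, 11, 18, ...).
    """
    return 7.0 * week - 3.0


def _week_frame(config: SimConfig) -> pd.DataFrame:
    rows = [
        (y, w)
        for y in config.years
        for w in range(1, weeks_in_year(y, config.week53) + 1)
    ]
    df = pd.DataFrame(rows, columns=["iso_year", "iso_week"])
    df["doy"] = week_midpoint_doy(df["iso_week"].to_numpy())
    df["year_frac"] = df["iso_year"] + df["doy"] / 365.25
    return df


# ---------------------------------------------------------------------------
# region metadata


def generate_regions(config: SimConfig) -> pd.DataFrame:
    """Region table: ids, country membership, demographics, climate parameters.

    ``temp_mean``/``temp_iqr`` are provisional climatological summaries here;
    :func:`generate_dataset` replaces them with the summaries of the realized
    temperature series (the quantities a real analysis would observe).
    """
    rng = np.random.default_rng(config.seed)
    recs = []
    for c in range(config.n_countries):
        country = f"C{c:02d}"
        for r in range(config.regions_per_country):
            clim_mean = rng.uniform(*config.clim_mean_range)
            amplitude = rng.uniform(*config.amplitude_range)
            pop = rng.uniform(*config.population_range)
            pct80 = rng.uniform(*config.pct80_range)
            rec = {
                "region_id": f"{country}R{r:02d}",
                "country_id": country,
                "temp_mean": clim_mean,
                "temp_iqr": 1.414 * amplitude,  # cosine-quartile approximation
                "pct_80plus": pct80,
                "clim_mean": clim_mean,
                "amplitude": amplitude,
            }
            for s in config.strata:
                rec[f"population_{s}"] = round(pop / len(config.strata))
            recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# temperature


def generate_temperature(
    region: pd.Series, config: SimConfig, rng: np.random.Generator, burnin: int = 0
) -> pd.DataFrame:
    """Weekly temperature for one region: annual cycle + trend + AR(1) noise.

    ``noise_sd`` is the marginal standard deviation of the AR(1) component.
    ``burnin`` prepends extra weeks (used internally so that lagged exposures
    are defined from the first reported week); they carry iso_year 0.
    """
    wk = _week_frame(config)
    if burnin > 0:
        pre = wk.iloc[:burnin].copy()
        pre["iso_year"] = 0
        pre["year_frac"] = wk["year_frac"].iloc[0] - (burnin - np.arange(burnin)) / MEAN_WEEKS_PER_YEAR
        wk = pd.concat([pre, wk], ignore_index=True)
    n = len(wk)
    seasonal = region["amplitude"] * np.cos(
        2 * np.pi * (wk["doy"].to_numpy() - config.peak_doy) / 365.25
    )
    trend = config.trend_per_year * (wk["year_frac"].to_numpy() - config.year_start)
    rho = config.ar1
    innov_sd = config.noise_sd * np.sqrt(max(1.0 - rho**2, 0.0))
    eps = np.empty(n)
    e = rng.normal(0.0, config.noise_sd)
    for t in range(n):
        e = rho * e + rng.normal(0.0, innov_sd)
        eps[t] = e
    wk = wk.copy()
    wk["temp_c"] = region["clim_mean"] + seasonal + trend + eps
    return wk


# ---------------------------------------------------------------------------
# true association


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def generate_true_association(
    region_meta: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """True cumulative curve coefficients per region.

    eta_i = X_i beta_true + u_{country(i)} with u ~ N(0, psi_country); the
    predictor design X has an intercept plus the z-scored region-level mean
    temperature, temperature IQR and %80+ columns.
    """
    preds = region_meta[["temp_mean", "temp_iqr", "pct_80plus"]].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(region_meta)), _standardize_columns(preds)])
    eta = X @ np.asarray(config.beta_true)

    countries = region_meta["country_id"].to_numpy()
    psi = np.asarray(config.psi_country)
    w, V = np.linalg.eigh(psi)  # PSD square root; exact for singular psi
    L = V * np.sqrt(np.clip(w, 0.0, None))
    u_by_country = {c: L @ rng.standard_normal(4) for c in pd.unique(countries)}
    eta += np.array([u_by_country[c] for c in countries])

    out = region_meta[["region_id", "country_id"]].copy()
    for j in range(4):
        out[f"eta{j + 1}"] = eta[:, j]
    return out


# ---------------------------------------------------------------------------
# mortality


def _quadratic_truth(x: np.ndarray) -> np.ndarray:
    # off-basis misspecified truth: flat below 18 degC, quadratic above
    return 0.0030 * np.clip(np.asarray(x, dtype=float) - 18.0, 0.0, None) ** 2


def _lagged_contribution(
    temp: np.ndarray, curve: Callable[[np.ndarray], np.ndarray], weights: tuple[float, ...]
) -> np.ndarray:
    """Sum_l w_l * f(x_{t-l}); NaN where any lagged exposure is undefined."""
    n = temp.size
    out = np.zeros(n)
    fx = curve(temp)
    for lag, w in enumerate(weights):
        shifted = np.full(n, np.nan)
        if lag == 0:
            shifted[:] = fx
        else:
            shifted[lag:] = fx[:-lag]
        out = out + w * shifted
    return out


def generate_mortality(
    temp: np.ndarray,
    curve: Callable[[np.ndarray], np.ndarray],
    config: SimConfig,
    doy: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Weekly death counts per stratum for one region.

    Counts are gamma-mixed Poisson (negative binomial in its NB1 form) with
    mean mu and variance phi * mu, matching the moments a quasi-Poisson fit
    assumes.  Returns per stratum ``(counts, mu)``.
    """
    contrib = _lagged_contribution(np.asarray(temp, float), curve, config.lag_weights)
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (np.asarray(doy, float) - config.seasonal_peak_doy) / 365.25
    )
    phi = config.overdispersion
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in config.strata:
        mu = np.exp(np.log(config.baseline_rate[s]) + seasonal + contrib)
        if np.nanmax(mu) > 1e9:
            raise ValueError("mortality mean overflow; check baseline_rate/curve scale")
        lam = mu if phi == 1.0 else rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0)
        counts = rng.poisson(np.nan_to_num(lam)).astype(float)
        counts[np.isnan(mu)] = np.nan
        out[s] = (counts, mu)
    return out


# ---------------------------------------------------------------------------
# dataset assembly and ground-truth attribution


@dataclass
class SyntheticDataset:
    """A complete simulated dataset with its generating truth."""

    config: SimConfig
    regions: pd.DataFrame  # region_id, country_id, population_*, temp_mean, temp_iqr, pct_80plus
    weekly: pd.DataFrame  # region_id, iso_year, iso_week, temp_c, deaths_<stratum>
    truth: pd.DataFrame  # region_id, eta1..4, mmt_true, knot columns
    truth_weekly: pd.DataFrame  # region_id, iso_year, iso_week, stratum, mu, an_true
    specs: dict[str, SplineSpec]
    curves: dict[str, Callable[[np.ndarray], np.ndarray]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta_cols = [c for c in self.regions.columns if c not in ("clim_mean", "amplitude")]
        self.regions[meta_cols].to_csv(outdir / "regions.csv", index=False)
        self.weekly.to_csv(outdir / "weekly.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def _find_mmt_grid(curve: Callable[[np.ndarray], np.ndarray], lo: float, hi: float) -> float:
    grid = np.arange(np.floor(lo * 10) / 10, np.ceil(hi * 10) / 10 + 0.05, 0.1)
    vals = curve(grid)
    return float(grid[int(np.argmin(vals))])


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Run the full generative model and package data plus ground truth."""
    regions = generate_regions(config)
    burnin = len(config.lag_weights) - 1

    # temperatures first: observed summaries become the meta-predictors
    temp_frames: dict[str, pd.DataFrame] = {}
    for i, (_, reg) in enumerate(regions.iterrows()):
        rng = np.random.default_rng([config.seed, 1, i])
        temp_frames[reg["region_id"]] = generate_temperature(reg, config, rng, burnin=burnin)
    for i, (_, reg) in enumerate(regions.iterrows()):
        obs = temp_frames[reg["region_id"]].query("iso_year > 0")["temp_c"]
        regions.loc[regions.index[i], "temp_mean"] = obs.mean()
        regions.loc[regions.index[i], "temp_iqr"] = obs.quantile(0.75) - obs.quantile(0.25)

    rng_assoc = np.random.default_rng([config.seed, 2])
    assoc = generate_true_association(regions, config, rng_assoc)

    specs: dict[str, SplineSpec] = {}
    curves: dict[str, Callable[[np.ndarray], np.ndarray]] = {}
    weekly_parts, truth_rows, truthw_parts = [], [], []
    for i, (_, reg) in enumerate(regions.iterrows()):
        rid = reg["region_id"]
        tf = temp_frames[rid]
        obs_mask = (tf["iso_year"] > 0).to_numpy()
        obs_temp = tf.loc[obs_mask, "temp_c"].to_numpy()
        spec = spec_from_percentiles(obs_temp)
        specs[rid] = spec

        eta = assoc.loc[assoc["region_id"] == rid, ["eta1", "eta2", "eta3", "eta4"]].to_numpy()[0]
        if config.truth_kind == "in-basis":
            curve = lambda x, s=spec, e=eta: natural_cubic_basis(x, s) @ e
        else:
            curve = _quadratic_truth
        curves[rid] = curve

        rng_mort = np.random.default_rng([config.seed, 3, i])
        mort = generate_mortality(
            tf["temp_c"].to_numpy(), curve, config, tf["doy"].to_numpy(), rng_mort
        )

        out = tf.loc[obs_mask, ["iso_year", "iso_week", "temp_c"]].copy()
        out.insert(0, "region_id", rid)
        for s in config.strata:
            out[f"deaths_{s}"] = mort[s][0][obs_mask].astype(int)
        weekly_parts.append(out)

        mmt = _find_mmt_grid(curve, obs_temp.min(), obs_temp.max())
        truth_rows.append(
            {
                "region_id": rid,
                "country_id": reg["country_id"],
                **{f"eta{j + 1}": eta[j] for j in range(4)},
                "mmt_true": mmt,
                **{f"knot{j}": k for j, k in enumerate(spec.all_knots)},
            }
        )

        f_ref = curve(np.array([mmt]))[0]
        fx = curve(obs_temp) - f_ref
        hot = obs_temp > mmt
        for s in config.strata:
            mu = mort[s][1][obs_mask]
            an = np.where(hot, mu * (1.0 - np.exp(-fx)), 0.0)
            tw = out[["region_id", "iso_year", "iso_week"]].copy()
            tw["stratum"] = s
            tw["mu"] = mu
            tw["an_true"] = an
            truthw_parts.append(tw)

    return SyntheticDataset(
        config=config,
        regions=regions,
        weekly=pd.concat(weekly_parts, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        truth_weekly=pd.concat(truthw_parts, ignore_index=True),
        specs=specs,
        curves=curves,
    )


def true_attributable(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-region weekly true attributable deaths.

    AN_true,t = E[deaths_t] * (1 - exp(-f_cum(x_t))) for weeks with
    temperature above the region's true MMT (f_cum referenced at the MMT),
    0 otherwise.
    """
    return dataset.truth_weekly[
        ["region_id", "iso_year", "iso_week", "stratum", "an_true"]
    ].copy()
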
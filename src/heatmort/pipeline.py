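"""Configuration-driven orchestration: simulate -> fit -> pool -> attribute -> trends.

Each stage reads and writes plain CSV/JSON files in a run directory, so
stages can be re-run individually (the CLI exposes each one) and a full run
is hermetic: every input of a stage is an output of an earlier one.
Re-running with the same configuration and seed produces byte-identical
outputs, recorded in a manifest with content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import attribution as attr
from . import climate as clim
from .first_stage import ModelConfig, fit_all_regions, frame_to_reduced, reduced_to_frame
from .meta import blup, blups_to_frame, fit_meta, frame_to_blups, heterogeneity_stats, wald_test
from .synthetic import SimConfig, generate_dataset

__all__ = [
    "RunConfig",
    "load_config",
    "run_pipeline",
    "make_report",
    "stage_simulate",
    "stage_fit",
    "stage_pool",
    "stage_attribute",
    "stage_trends",
]

logger = logging.getLogger("heatmort")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    outdir: str = "run"
    seed: int = 12345
    # synthetic data (desk-scale defaults; the generator's own defaults are
    # the full study design and too large for routine runs)
    sim: dict = field(default_factory=lambda: {
        "n_countries": 6, "regions_per_country": 4,
        "year_start": 2015, "year_end": 2022,
    })
    # first stage
    calibration_start: list | None = None  # [iso_year, iso_week]
    calibration_end: list | None = None
    df_per_year: float = 8.0
    lags: list = field(default_factory=lambda: [0, 1, 2, 3])
    knot_percentiles: list = field(default_factory=lambda: [10.0, 50.0, 90.0])
    # meta stage
    use_region_level: bool = False
    predictors: list = field(default_factory=lambda: ["temp_mean", "temp_iqr", "pct_80plus"])
    # attribution
    summer_weeks: list = field(default_factory=lambda: [22, 35])
    n_sim: int = 1000
    direction: str = "forward"
    # climate stage
    reference_period: list | None = None  # defaults to the simulated years
    trend_breakpoint: int | None = None

    def validate(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be forward or backward")
        if len(self.summer_weeks) != 2 or self.summer_weeks[0] > self.summer_weeks[1]:
            raise ValueError("summer_weeks must be [first, last]")

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            df_per_year=self.df_per_year,
            lags=tuple(self.lags),
            knot_percentiles=tuple(self.knot_percentiles),
            calibration_start=tuple(self.calibration_start) if self.calibration_start else None,
            calibration_end=tuple(self.calibration_end) if self.calibration_end else None,
        )

    @property
    def weeks(self) -> tuple[int, ...]:
        return tuple(range(self.summer_weeks[0], self.summer_weeks[1] + 1))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages (file in, file out)


def stage_simulate(config: RunConfig):
    """Generate the synthetic dataset; writes regions/weekly/truth CSVs."""
    outdir = Path(config.outdir)
    dataset = generate_dataset(config.sim_config())
    dataset.write(outdir)
    logger.info("simulated %d regions, %d region-weeks", len(dataset.regions), len(dataset.weekly))
    return dataset


def stage_fit(config: RunConfig) -> pd.DataFrame:
    """First-stage fits from weekly.csv/regions.csv; writes reduced.csv."""
    outdir = Path(config.outdir)
    weekly = pd.read_csv(outdir / "weekly.csv")
    regions = pd.read_csv(outdir / "regions.csv")
    reduced, excluded = fit_all_regions(weekly, regions, config.model_config())
    frame = reduced_to_frame(reduced)
    frame.to_csv(outdir / "reduced.csv", index=False)
    pd.DataFrame(excluded, columns=["region_id", "stratum", "reason"]).to_csv(
        outdir / "excluded.csv", index=False
    )
    return frame


def stage_pool(config: RunConfig) -> dict:
    """Meta-regression and BLUPs from reduced.csv; writes meta.json, blups.csv."""
    outdir = Path(config.outdir)
    reduced = frame_to_reduced(pd.read_csv(outdir / "reduced.csv"))
    regions = pd.read_csv(outdir / "regions.csv")
    strata = sorted({r.stratum for r in reduced})
    meta_out: dict = {}
    all_blups = []
    for s in strata:
        subset = [r for r in reduced if r.stratum == s]
        model = fit_meta(subset, regions, tuple(config.predictors),
                         use_region_level=config.use_region_level)
        stat, dof, pval = wald_test(model, tuple(config.predictors))
        Q, qdof, i2 = heterogeneity_stats(model)
        meta_out[s] = {
            "beta": model.beta.tolist(),
            "psi_country": model.psi_country.tolist(),
            "reml_loglik": model.reml_loglik,
            "wald_predictors": {"stat": stat, "dof": dof, "p": pval},
            "cochran_q": {"Q": Q, "dof": qdof, "i2": i2},
        }
        all_blups.extend(blup(model, stratum=s))
    (outdir / "meta.json").write_text(json.dumps(meta_out, indent=2))
    blups_to_frame(all_blups).to_csv(outdir / "blups.csv", index=False)
    return meta_out


def stage_attribute(config: RunConfig) -> pd.DataFrame:
    """MMTs, weekly/summer attributable numbers and Monte Carlo CIs.

    Reads weekly.csv, regions.csv, reduced.csv (for each region's spline
    spec and observed range) and blups.csv; writes results_weekly.csv,
    results_national.csv, results_europe.csv and mmt.csv.
    """
    outdir = Path(config.outdir)
    weekly = pd.read_csv(outdir / "weekly.csv")
    regions = pd.read_csv(outdir / "regions.csv").set_index("region_id")
    reduced = frame_to_reduced(pd.read_csv(outdir / "reduced.csv"))
    blups = frame_to_blups(pd.read_csv(outdir / "blups.csv"))
    specs = {(r.region_id, r.stratum): r.spec for r in reduced}

    parts: dict[str, dict[str, tuple[pd.DataFrame, np.ndarray]]] = {}
    mmt_rows = []
    for b in blups:
        series = weekly[weekly["region_id"] == b.region_id].sort_values(["iso_year", "iso_week"])
        spec = specs[(b.region_id, b.stratum)]
        temps = series["temp_c"].to_numpy(dtype=float)
        mmt = attr.find_mmt(b.coef, spec, (temps.min(), temps.max()))
        point, draws = attr.monte_carlo_ci(
            series, b, spec, mmt, stratum=b.stratum, direction=config.direction,
            n_sim=config.n_sim, seed=config.seed,
        )
        parts.setdefault(b.stratum, {})[b.region_id] = (point, draws)
        mmt_rows.append({"region_id": b.region_id, "stratum": b.stratum, "mmt": mmt})
        logger.info("region=%s stratum=%s mmt=%.1f summer_an=%.1f", b.region_id, b.stratum,
                    mmt, point[point["iso_week"].isin(config.weeks)]["an"].sum())
    pd.DataFrame(mmt_rows).to_csv(outdir / "mmt.csv", index=False)

    results_rows = []
    for s, by_region in parts.items():
        by_country: dict[str, list] = {}
        pops: dict[str, float] = {}
        for rid, part in sorted(by_region.items()):
            c = regions.loc[rid, "country_id"]
            by_country.setdefault(c, []).append(part)
            pops[c] = pops.get(c, 0.0) + float(regions.loc[rid, f"population_{s}"])
        for period in ("summer", "year"):
            agg = [
                attr.aggregate(p, "country", c, s, period=period, population=pops[c])
                for c, p in sorted(by_country.items())
            ]
            agg.append(attr.aggregate(
                [p for c in sorted(by_country) for p in by_country[c]],
                "europe", "Europe", s, period=period, population=sum(pops.values()),
            ))
            for res in agg:
                lo, hi = res.ci95
                rate = res.rate_per_million
                results_rows.append({
                    "level": res.level, "key": res.key, "stratum": s, "period": period,
                    "an": res.an_point, "an_lo": lo, "an_hi": hi,
                    "rate": rate[0], "rate_lo": rate[1], "rate_hi": rate[2],
                })
    results = pd.DataFrame(results_rows)
    results[results["level"] == "country"].to_csv(outdir / "results_national.csv", index=False)
    results[results["level"] == "europe"].to_csv(outdir / "results_europe.csv", index=False)

    weekly_rows = []
    for s, by_region in sorted(parts.items()):
        for rid, (point, _) in sorted(by_region.items()):
            w = point.copy()
            w.insert(0, "region_id", rid)
            w.insert(1, "stratum", s)
            weekly_rows.append(w)
    pd.concat(weekly_rows, ignore_index=True).to_csv(outdir / "results_weekly.csv", index=False)
    return results


def stage_trends(config: RunConfig) -> dict:
    """European summer means, anomalies, warming trends, burden slope,
    forward projections; writes climate.csv and trends.json."""
    outdir = Path(config.outdir)
    weekly = pd.read_csv(outdir / "weekly.csv")
    regions = pd.read_csv(outdir / "regions.csv").set_index("region_id")
    an_weekly = pd.read_csv(outdir / "results_weekly.csv")
    weeks = config.weeks
    years = [int(y) for y in sorted(weekly["iso_year"].unique())]
    ref = tuple(config.reference_period) if config.reference_period else (years[0], years[-1])

    pop_cols = [c for c in regions.columns if c.startswith("population_")]
    pop_total = regions[pop_cols].sum(axis=1)
    wk = weekly.copy()
    wk["w"] = wk["region_id"].map(pop_total)
    euro = (
        wk.assign(wt=wk["temp_c"] * wk["w"])
        .groupby(["iso_year", "iso_week"], as_index=False)
        .agg(wt=("wt", "sum"), w=("w", "sum"))
    )
    euro["temp_c"] = euro["wt"] / euro["w"]

    climfit = clim.fit_baseline_cycle(euro, ref)
    summer_means = {y: clim.summer_mean(euro, y, weeks) for y in years}
    mu, sigma = clim.reference_mu_sigma(summer_means, ref)
    base = float(np.mean(climfit.baseline(np.array(weeks))))
    pd.DataFrame(
        {
            "year": years,
            "summer_mean": [summer_means[y] for y in years],
            "anomaly": [summer_means[y] - base for y in years],
            "z": [clim.standardized_anomaly(summer_means[y], mu, sigma) if sigma > 0 else np.nan
                  for y in years],
        }
    ).to_csv(outdir / "climate.csv", index=False)

    stratum0 = "total" if "total" in set(an_weekly["stratum"]) else sorted(set(an_weekly["stratum"]))[0]
    sub = an_weekly[(an_weekly["stratum"] == stratum0) & an_weekly["iso_week"].isin(weeks)]
    summer_an = {int(y): float(g["an"].sum()) for y, g in sub.groupby("iso_year")}

    bp = config.trend_breakpoint or (years[0] + (years[-1] - years[0]) // 2)
    trends: dict = {"summer_means": summer_means, "summer_an": summer_an,
                    "mu": mu, "sigma": sigma, "reference_period": list(ref)}
    try:
        early = clim.fit_linear_trend(summer_means, (years[0], bp))
        trends["trend_early"] = {"slope": early.slope, "period": list(early.period)}
    except ValueError as exc:
        logger.warning("early trend fit skipped: %s", exc)
    try:
        late = clim.fit_linear_trend(summer_means, (bp + 1, years[-1]))
    except ValueError:
        late = clim.fit_linear_trend(summer_means, (years[0], years[-1]))
    trends["trend_late"] = {"slope": late.slope, "period": list(late.period)}
    slope = clim.mortality_temperature_slope(summer_means, summer_an, summer_an.keys())
    anchor = (years[-1], summer_an[years[-1]], late.predict(years[-1]))
    trends["burden_slope_per_degC"] = slope
    trends["projections"] = {
        str(t): clim.extrapolate(late, slope, anchor, t)
        for t in (years[-1] + 8, years[-1] + 18, years[-1] + 28)
    }
    (outdir / "trends.json").write_text(json.dumps(trends, indent=2, default=float))
    return trends


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order; returns the results bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))

    stage = "simulate"
    try:
        dataset = stage_simulate(config)
        stage = "fit"
        reduced_frame = stage_fit(config)
        stage = "pool"
        meta_out = stage_pool(config)
        stage = "attribute"
        results = stage_attribute(config)
        stage = "trends"
        trends = stage_trends(config)
    except Exception:
        logger.error("pipeline aborted in stage %r (partial outputs kept in %s)", stage, outdir)
        raise

    excluded = pd.read_csv(outdir / "excluded.csv")
    outputs = sorted(p.name for p in outdir.iterdir() if p.suffix in (".csv", ".json", ".yaml"))
    manifest = {
        "seed": config.seed,
        "config_sha256": _sha256(outdir / "config.yaml"),
        "n_regions": int(len(dataset.regions)),
        "n_reduced": int(len(reduced_frame)),
        "n_excluded": int(len(excluded)),
        # config.yaml is hashed separately: it embeds the run directory path
        "files": {
            name: _sha256(outdir / name)
            for name in outputs
            if name not in ("manifest.json", "config.yaml")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "dataset": dataset,
        "reduced": frame_to_reduced(reduced_frame),
        "excluded": excluded,
        "meta": meta_out,
        "blups": frame_to_blups(pd.read_csv(outdir / "blups.csv")),
        "mmts": pd.read_csv(outdir / "mmt.csv"),
        "results": results,
        "trends": trends,
        "manifest": manifest,
    }


def _fmt_ci(point: float, lo: float, hi: float) -> str:
    return f"{point:.0f} ({lo:.0f}, {hi:.0f})"


def make_report(results: pd.DataFrame, strata: list[str] | None = None) -> pd.DataFrame:
    """National summary table: AN (CI) and rate (CI) per country x stratum.

    Deaths and rates are rounded to integers.  Countries missing a stratum
    get "Not available" cells; the Europe row is the draw-wise aggregate
    carried in ``results``.
    """
    if strata is None:
        strata = sorted(results["stratum"].unique())
    sub = results[results["period"] == "summer"]
    keys = [k for k in sub[sub["level"] == "country"]["key"].unique()] + ["Europe"]
    rows = []
    for key in keys:
        row: dict = {"country": key}
        for s in strata:
            m = sub[(sub["key"] == key) & (sub["stratum"] == s)]
            if m.empty:
                row[f"an_{s}"] = "Not available"
                row[f"rate_{s}"] = "Not available"
            else:
                r = m.iloc[0]
                row[f"an_{s}"] = _fmt_ci(r["an"], r["an_lo"], r["an_hi"])
                row[f"rate_{s}"] = _fmt_ci(r["rate"], r["rate_lo"], r["rate_hi"])
        rows.append(row)
    return pd.DataFrame(rows)
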
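"""MMT search, attributable numbers, Monte Carlo CIs, aggregation."""

import numpy as np
import pandas as pd
import pytest

from heatmort.attribution import (
    aggregate,
    attributable_number,
    attributable_rate,
    cumulative_log_rr,
    find_mmt,
    monte_carlo_ci,
    percent_excess,
    region_rng,
)
from heatmort.meta import Blup
from heatmort.splines import SplineSpec, natural_cubic_basis

SPEC = SplineSpec(internal_knots=(8.0, 14.0, 20.0), boundary_knots=(-2.0, 28.0))


def project(f, spec=SPEC, lo=-2.0, hi=28.0):
    g = np.linspace(lo, hi, 400)
    B = np.column_stack([np.ones(g.size), natural_cubic_basis(g, spec)])
    return np.linalg.lstsq(B, f(g), rcond=None)[0][1:]


def make_blup(coef, vcov=None, region="C00R00"):
    return Blup(region_id=region, stratum="total",
                coef=np.asarray(coef, dtype=float),
                vcov=np.zeros((4, 4)) if vcov is None else np.asarray(vcov))


def make_series(temps, deaths=None, start_week=1):
    temps = np.asarray(temps, dtype=float)
    n = temps.size
    weeks = (start_week - 1 + np.arange(n)) % 52 + 1
    years = 2022 + (start_week - 1 + np.arange(n)) // 52
    return pd.DataFrame({
        "iso_year": years, "iso_week": weeks, "temp_c": temps,
        "deaths_total": np.full(n, 100.0) if deaths is None else np.asarray(deaths, float),
    })


class TestFindMmt:
    def test_increasing_curve_gives_range_minimum(self):
        coef = project(lambda x: 0.01 * x)
        assert find_mmt(coef, SPEC, (2.0, 26.0)) == pytest.approx(2.0, abs=0.11)

    def test_quadratic_curve_minimum_near_18(self):
        coef = project(lambda x: 0.002 * (x - 18.0) ** 2)
        assert find_mmt(coef, SPEC, (2.0, 26.0)) == pytest.approx(18.0, abs=0.5)

    def test_matches_independent_grid_argmin(self):
        """The MMT is exactly the argmin of the curve evaluated on the
        0.1 degC grid (recomputed here from scratch)."""
        coef = project(lambda x: 0.002 * (x - 18.0) ** 2)
        lo, hi = 2.3, 25.7
        mmt = find_mmt(coef, SPEC, (lo, hi))
        grid = np.round(np.arange(np.floor(lo / 0.1) * 0.1, hi + 0.05, 0.1), 6)
        vals = natural_cubic_basis(grid, SPEC) @ coef
        assert mmt == grid[np.argmin(vals)]

    def test_tie_breaks_toward_lower_temperature(self):
        # a perfectly flat curve makes every grid point a minimum
        mmt = find_mmt(np.zeros(4), SPEC, (5.0, 25.0))
        assert mmt == pytest.approx(5.0, abs=0.11)

    def test_non_finite_curve_rejected(self):
        with pytest.raises(ValueError):
            find_mmt(np.array([np.nan, 0, 0, 0]), SPEC, (5.0, 25.0))


class TestCumulativeLogRr:
    def test_zero_at_reference(self):
        b = make_blup(project(lambda x: 0.002 * (x - 18) ** 2))
        lr, var = cumulative_log_rr(b, SPEC, np.array([17.0]), reference=17.0)
        assert lr[0] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self):
        b = make_blup(project(lambda x: 0.002 * (x - 18) ** 2))
        a, _ = cumulative_log_rr(b, SPEC, np.array([24.0]), reference=12.0)
        c, _ = cumulative_log_rr(b, SPEC, np.array([12.0]), reference=24.0)
        assert a[0] == pytest.approx(-c[0], abs=1e-12)

    def test_variance_matches_sampling(self, rng):
        A = rng.normal(0, 0.01, (4, 4))
        vcov = A @ A.T + 1e-5 * np.eye(4)
        coef = project(lambda x: 0.002 * (x - 18) ** 2)
        b = make_blup(coef, vcov)
        xs = np.array([5.0, 22.0, 26.0])
        _, var = cumulative_log_rr(b, SPEC, xs, reference=18.0)
        draws = rng.multivariate_normal(coef, vcov, size=200_000)
        B = natural_cubic_basis(xs, SPEC) - natural_cubic_basis(np.array([18.0]), SPEC)
        emp = (draws @ B.T).var(axis=0)
        assert np.allclose(var, emp, rtol=0.03)


class TestAttributableNumber:
    curve = staticmethod(lambda x: 0.003 * np.clip(x - 18.0, 0, None) ** 2
                         + 0.01 * np.clip(18.0 - x, 0, None))

    def test_halving_closed_form(self):
        # strong heat effect so the curve reaches log 2 inside the domain
        coef = project(lambda x: 0.012 * np.clip(x - 18.0, 0, None) ** 2
                       + 0.01 * np.clip(18.0 - x, 0, None))
        b = make_blup(coef)
        mmt = find_mmt(coef, SPEC, (2.0, 27.0))
        # find the temperature where the curve equals ln 2 above the MMT
        grid = np.arange(mmt, 27.0, 0.001)
        f = (natural_cubic_basis(grid, SPEC) - natural_cubic_basis([mmt], SPEC)) @ coef
        x_half = grid[np.argmin(np.abs(f - np.log(2)))]
        series = make_series([x_half], deaths=[100.0])
        an = attributable_number(series, b, SPEC, mmt)["an"]
        assert an[0] == pytest.approx(50.0, abs=0.2)

    def test_cool_summer_attributes_zero(self):
        coef = project(self.curve)
        b = make_blup(coef)
        series = make_series(np.linspace(5, 15, 14), start_week=22)
        an = attributable_number(series, b, SPEC, mmt=18.0)["an"]
        assert np.allclose(an, 0.0)

    def test_an_bounded_by_deaths(self):
        coef = project(self.curve)
        b = make_blup(coef)
        series = make_series(np.linspace(10, 27, 30))
        mmt = find_mmt(coef, SPEC, (10.0, 27.0))
        an = attributable_number(series, b, SPEC, mmt)["an"].to_numpy()
        deaths = series["deaths_total"].to_numpy()
        assert np.all(an >= -1e-6) and np.all(an < deaths)

    def test_mmt_outside_range_rejected(self):
        b = make_blup(project(self.curve))
        series = make_series(np.linspace(10, 20, 10))
        with pytest.raises(ValueError):
            attributable_number(series, b, SPEC, mmt=35.0)

    def test_backward_zero_when_no_heat(self):
        b = make_blup(project(self.curve))
        series = make_series(np.full(20, 10.0))
        an = attributable_number(series, b, SPEC, mmt=18.0, direction="backward")["an"]
        assert np.allclose(an, 0.0)

    def test_backward_spreads_single_hot_week(self):
        b = make_blup(project(self.curve))
        temps = np.full(20, 10.0)
        temps[8] = 25.0
        series = make_series(temps)
        fwd = attributable_number(series, b, SPEC, mmt=18.0)["an"].to_numpy()
        bwd = attributable_number(series, b, SPEC, mmt=18.0, direction="backward")["an"].to_numpy()
        assert np.flatnonzero(fwd).tolist() == [8]
        assert np.flatnonzero(bwd).tolist() == [8, 9, 10, 11]
        # totals agree to first order (they coincide as the log RR -> 0)
        assert fwd.sum() == pytest.approx(bwd.sum(), rel=0.2)


class TestMonteCarlo:
    def test_zero_vcov_degenerate_ci(self):
        coef = project(TestAttributableNumber.curve)
        b = make_blup(coef)
        series = make_series(np.linspace(12, 26, 30))
        point, draws = monte_carlo_ci(series, b, SPEC, mmt=18.0, n_sim=100, seed=1)
        assert np.allclose(draws, point["an"].to_numpy()[None, :])

    def test_seed_reproducible_and_region_specific(self):
        coef = project(TestAttributableNumber.curve)
        vcov = 1e-4 * np.eye(4)
        series = make_series(np.linspace(12, 26, 30))
        _, d1 = monte_carlo_ci(series, make_blup(coef, vcov), SPEC, 18.0, n_sim=50, seed=9)
        _, d2 = monte_carlo_ci(series, make_blup(coef, vcov), SPEC, 18.0, n_sim=50, seed=9)
        _, d3 = monte_carlo_ci(series, make_blup(coef, vcov, region="C01R01"), SPEC, 18.0,
                               n_sim=50, seed=9)
        assert np.array_equal(d1, d2)
        assert not np.array_equal(d1, d3)

    def test_coverage_of_true_seasonal_an(self):
        """Empirical 95% CI coverage over 200 replicated estimations with
        5% relative coefficient uncertainty."""
        coef = project(lambda x: 0.008 * np.clip(x - 18, 0, None) ** 2
                       + 0.015 * np.clip(18 - x, 0, None))
        vcov = np.diag((0.05 * np.abs(coef)) ** 2)
        rng = np.random.default_rng(31)
        temps = rng.normal(15, 6, 52)
        deaths = np.full(52, 120.0)
        series = make_series(temps, deaths)
        mmt_true = find_mmt(coef, SPEC, (temps.min(), temps.max()))
        Bd = natural_cubic_basis(temps, SPEC) - natural_cubic_basis([mmt_true], SPEC)
        an_true = float(np.sum(np.where(temps > mmt_true,
                                        deaths * (1 - np.exp(-(Bd @ coef))), 0.0)))
        covered = 0
        for rep in range(200):
            est = rng.multivariate_normal(coef, vcov)
            mmt_hat = find_mmt(est, SPEC, (temps.min(), temps.max()))
            b = make_blup(est, vcov, region=f"R{rep}")
            _, draws = monte_carlo_ci(series, b, SPEC, mmt_hat, n_sim=400, seed=rep)
            lo, hi = np.percentile(draws.sum(axis=1), [2.5, 97.5])
            covered += int(lo <= an_true <= hi)
        assert 0.90 <= covered / 200 <= 0.99

    def test_point_inside_own_ci(self):
        coef = project(TestAttributableNumber.curve)
        vcov = np.diag([4e-6, 1e-6, 1e-6, 4e-6])
        series = make_series(np.linspace(10, 26, 52))
        inside = 0
        for seed in range(50):
            b = make_blup(coef, vcov, region=f"R{seed}")
            point, draws = monte_carlo_ci(series, b, SPEC, 18.0, n_sim=300, seed=seed)
            lo, hi = np.percentile(draws.sum(axis=1), [2.5, 97.5])
            inside += int(lo <= point["an"].sum() <= hi)
        assert inside >= 49


class TestAggregate:
    def make_part(self, an_weekly, draws):
        weekly = pd.DataFrame({
            "iso_year": 2022, "iso_week": np.arange(1, len(an_weekly) + 1),
            "an": an_weekly,
        })
        return weekly, np.asarray(draws, dtype=float)

    def test_single_region_identity(self):
        part = self.make_part([1.0, 2.0], [[1.0, 2.0], [0.5, 1.0]])
        res = aggregate([part], "region", "R", "total", period="year")
        assert res.an_point == pytest.approx(3.0)
        assert np.allclose(res.an_draws, [3.0, 1.5])

    def test_summer_plus_rest_equals_year(self):
        rng = np.random.default_rng(0)
        an = rng.uniform(0, 5, 52)
        draws = rng.uniform(0, 5, (40, 52))
        part = self.make_part(an, draws)
        tot = aggregate([part], "region", "R", "total", period="year")
        summer = aggregate([part], "region", "R", "total", period="summer")
        weekly = part[0]
        rest = an[~weekly["iso_week"].between(22, 35)].sum()
        assert summer.an_point + rest == pytest.approx(tot.an_point)

    def test_mismatched_draw_counts_rejected(self):
        p1 = self.make_part([1.0], [[1.0], [2.0]])
        p2 = self.make_part([1.0], [[1.0]])
        with pytest.raises(ValueError, match="draw counts"):
            aggregate([p1, p2], "country", "C", "total", period="year")

    def test_drawwise_aggregation_not_percentile_sum(self):
        """Percentiles of sums differ from sums of percentiles; the
        implementation must aggregate within draws first."""
        p1 = self.make_part([1.0], [[10.0], [0.0], [0.0], [0.0]])
        p2 = self.make_part([1.0], [[0.0], [10.0], [0.0], [0.0]])
        res = aggregate([p1, p2], "country", "C", "total", period="year")
        lo_sum_of_percentiles = 2 * np.percentile([10, 0, 0, 0], 97.5)
        assert res.ci95[1] == pytest.approx(np.percentile([10, 10, 0, 0], 97.5))
        assert res.ci95[1] != pytest.approx(lo_sum_of_percentiles)


class TestRatesAndExcess:
    def test_rate_per_million_rounding_to_printed_value(self):
        assert round(attributable_rate(61_672, 543e6)) == 114

    def test_zero_an_zero_rate(self):
        assert attributable_rate(0.0, 1e6) == 0.0

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            attributable_rate(10.0, 0.0)

    def test_aggregate_rate_is_population_weighted(self):
        an = np.array([100.0, 50.0])
        pop = np.array([2e6, 1e6])
        combined = attributable_rate(an.sum(), pop.sum())
        weighted = np.sum([attributable_rate(a, p) * p for a, p in zip(an, pop)]) / pop.sum()
        assert combined == pytest.approx(weighted)

    def test_percent_excess_examples(self):
        assert round(percent_excess(35_406, 21_667)) == 63
        assert round(percent_excess(145, 93)) == 56
        assert percent_excess(7.0, 7.0) == 0.0

    def test_percent_excess_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_excess(5.0, 0.0)


def test_region_rng_deterministic():
    a = region_rng(3, "C00R00").standard_normal(4)
    b = region_rng(3, "C00R00").standard_normal(4)
    c = region_rng(3, "C00R01").standard_normal(4)
    assert np.array_equal(a, b) and not np.array_equal(a, c)
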
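"""Trend model: pooling limits, shrinkage, correlation recovery, combination."""
import numpy as np
import pandas as pd
import pytest

import dietstrata as ds
from dietstrata.config import DrawArray, STRATUM_COLS
from dietstrata.trend_model import (
    combine_models, fit_trend_model, nearest_anchor_years,
)


def _traj_frame(countries, years, z_fn, se=0.02, avail_fn=None):
    rows = []
    for ci, c in enumerate(countries):
        for y in years:
            a = avail_fn(ci, y) if avail_fn else (y - np.mean(years)) / 10.0
            rows.append({"country": c, "year": y, "availability": a,
                         "z": z_fn(ci, a), "se_z": se, "survey_informed": True})
    traj = pd.DataFrame(rows)
    traj["avail_c"] = traj.groupby("country")["availability"].transform(
        lambda s: s - s.mean())
    return traj


class TestFitTrendModel:
    def test_pooled_limit_single_shared_line(self):
        traj = _traj_frame([f"C{i}" for i in range(10)], range(1990, 2019, 4),
                           z_fn=lambda ci, a: 1.0 + 0.5 * a, se=0.01)
        post = fit_trend_model(traj, ds.TrendSpec(chains=2, warmup=200,
                                                  draws=200, seed=3))
        mu_slope = post.flat(post.mu)[:, 1]
        assert abs(mu_slope.mean() - 0.5) < 0.05
        slope_sd = np.sqrt(post.flat(post.Sigma)[:, 1, 1])
        assert slope_sd.mean() < 0.15

    def test_extreme_country_slope_shrinks_toward_population(self):
        rng = np.random.default_rng(5)
        slopes = {f"C{i}": 0.3 for i in range(12)}
        slopes["C_EXTREME"] = 3.0
        rows = []
        for c, b in slopes.items():
            years = (1990, 2018) if c == "C_EXTREME" else tuple(range(1990, 2019, 4))
            for y in years:
                a = (y - 2004) / 10.0
                rows.append({"country": c, "year": y, "availability": a,
                             "z": 1.0 + b * a + rng.normal(0, 0.05),
                             "se_z": 0.05, "survey_informed": True})
        traj = pd.DataFrame(rows)
        traj["avail_c"] = traj.groupby("country")["availability"].transform(
            lambda s: s - s.mean())
        post = fit_trend_model(traj, ds.TrendSpec(chains=2, warmup=200,
                                                  draws=200, seed=3))
        ci = post.countries.index("C_EXTREME")
        est = post.flat(post.beta)[:, ci].mean()
        sub = traj[traj["country"] == "C_EXTREME"]
        ols = np.polyfit(sub["avail_c"], sub["z"], 1)[0]
        pop = post.flat(post.mu)[:, 1].mean()
        assert pop < est < ols

    def test_correlation_recovery_from_true_country_means(self):
        params = ds.TrueParams(slope_sd=0.3, rho=0.6, sigma_region=0.05)
        cfg = ds.WorldConfig(n_regions=4, countries_per_region=10, seed=42,
                             params=params)
        world = ds.generate_world(cfg)
        pops = ds.generate_populations(world)
        cov = ds.generate_covariates(world)
        t = world.truth.merge(pops, on=["country", "year", *STRATUM_COLS])
        g = t.groupby(["country", "year"]).apply(
            lambda s: np.average(s["true_mean"], weights=s["population"]),
            include_groups=False).reset_index(name="m")
        rng = np.random.default_rng(1)
        traj = g.merge(cov[["country", "year", "availability"]],
                       on=["country", "year"])
        traj["z"] = np.log(traj["m"]) + rng.normal(0, 0.03, len(traj))
        traj["se_z"] = 0.03
        traj["survey_informed"] = True
        traj["avail_c"] = traj.groupby("country")["availability"].transform(
            lambda s: s - s.mean())
        post = fit_trend_model(traj, ds.TrendSpec(chains=2, warmup=300,
                                                  draws=300, seed=9))
        est = post.correlation_draws().mean()
        # nominal generator correlation
        assert abs(est - 0.6) < 0.25
        # realized correlation among this world's true (intercept, slope) pairs
        am = traj.groupby("country")["availability"].mean()
        alpha_true = (world.params.country_effects
                      + world.params.country_slopes * am.to_numpy())
        realized = np.corrcoef(alpha_true, world.params.country_slopes)[0, 1]
        assert abs(est - realized) < 0.15

    def test_too_few_countries_rejected(self):
        traj = _traj_frame(["A", "B"], (1990, 2000), lambda ci, a: 1.0)
        with pytest.raises(ValueError, match="3 countries"):
            fit_trend_model(traj)


class TestCombineModels:
    @pytest.fixture()
    def setup(self, rng):
        years = (1990, 2005, 2018)
        draws = {}
        for y in years:
            idx = ds.stratum_grid(country="C001", year=y)
            flags = {} if y != 2005 else {"no-survey-this-year": True}
            draws[("C001", y)] = DrawArray(
                idx, rng.lognormal(0.5, 0.2, (264, 120)), flags)
        traj = pd.DataFrame({
            "country": "C001", "year": list(years),
            "availability": [-1.0, 0.0, 1.0],
            "z": [0.8, 1.0, 1.2], "se_z": 0.05,
            "survey_informed": [True, False, True],
        })
        traj["avail_c"] = traj["availability"] - traj["availability"].mean()
        trend = _fake_trend(["C001"], beta=0.25, n=120)
        return draws, traj, trend

    def test_anchor_year_identity(self, setup):
        draws, traj, trend = setup
        combined = combine_models(draws, trend, traj)
        assert np.array_equal(combined[("C001", 1990)].values,
                              draws[("C001", 1990)].values)
        assert combined[("C001", 2005)].flags["anchor_year"] in (1990, 2018)

    def test_multiplicative_contract(self, setup):
        draws, traj, trend = setup
        combined = combine_models(draws, trend, traj)
        # 2005 anchored to 2018 (tie resolves to the later year):
        # factor per draw = exp(beta * (a_2005 - a_2018)) = exp(-0.25)
        ratio = combined[("C001", 2005)].values / draws[("C001", 2005)].values
        assert np.allclose(ratio, np.exp(0.25 * (0.0 - 1.0)))

    def test_oracle_equivalence_draw_by_draw(self, setup, rng):
        draws, traj, trend = setup
        beta = trend.flat(trend.beta)[:, 0]
        combined = combine_models(draws, trend, traj)
        got = combined[("C001", 2005)].values
        av = dict(zip(traj["year"], traj["availability"]))
        expect = np.empty_like(got)
        for d in range(got.shape[1]):
            expect[:, d] = (draws[("C001", 2005)].values[:, d]
                            * np.exp(beta[d] * (av[2005] - av[2018])))
        assert np.allclose(got, expect, rtol=1e-14)

    def test_demographic_contrasts_preserved_per_draw(self, setup):
        draws, traj, trend = setup
        combined = combine_models(draws, trend, traj)
        idx = draws[("C001", 2005)].index
        urban = (idx["residence"] == "urban").to_numpy()
        rural = ~urban
        before = (np.log(draws[("C001", 2005)].values[urban])
                  - np.log(draws[("C001", 2005)].values[rural]))
        after = (np.log(combined[("C001", 2005)].values[urban])
                 - np.log(combined[("C001", 2005)].values[rural]))
        assert np.allclose(before, after, atol=1e-12)

    def test_flat_availability_reduces_to_intake_model(self, rng):
        years = (1990, 2005, 2018)
        draws = {("C001", y): DrawArray(ds.stratum_grid(country="C001", year=y),
                                        rng.lognormal(0.5, 0.2, (264, 50)),
                                        {} if y == 1990 else
                                        {"no-survey-this-year": True})
                 for y in years}
        traj = pd.DataFrame({
            "country": "C001", "year": list(years), "availability": 0.7,
            "z": 1.0, "se_z": 0.05,
            "survey_informed": [True, False, False]})
        traj["avail_c"] = 0.0
        trend = _fake_trend(["C001"], beta=0.9, n=50)
        combined = combine_models(draws, trend, traj)
        for y in years:
            assert np.allclose(combined[("C001", y)].values,
                               draws[("C001", y)].values)

    def test_uncombined_flag_for_missing_country(self, setup):
        draws, traj, trend = setup
        extra = DrawArray(ds.stratum_grid(country="C999", year=1990),
                          np.ones((264, 120)))
        draws[("C999", 1990)] = extra
        combined = combine_models(draws, trend, traj)
        assert combined[("C999", 1990)].flags.get("uncombined")

    def test_variance_propagates(self, rng):
        years = (1990, 2018)
        draws = {("C001", y): DrawArray(ds.stratum_grid(country="C001", year=y),
                                        rng.lognormal(0.5, 0.2, (264, 400)),
                                        {} if y == 1990 else
                                        {"no-survey-this-year": True})
                 for y in years}
        traj = pd.DataFrame({
            "country": "C001", "year": list(years),
            "availability": [0.0, 2.0], "z": 1.0, "se_z": 0.05,
            "survey_informed": [True, False]})
        traj["avail_c"] = traj["availability"] - 1.0
        trend = _fake_trend(["C001"], beta=0.3, beta_sd=0.2, n=400)
        combined = combine_models(draws, trend, traj)
        w = lambda v: np.diff(np.percentile(np.log(v), [2.5, 97.5], axis=1),
                              axis=0).mean()
        assert w(combined[("C001", 2018)].values) > w(draws[("C001", 2018)].values)


class TestAnchors:
    def test_nearest_with_tie_to_later(self):
        traj = pd.DataFrame({
            "country": "C1", "year": [1990, 2000, 2010],
            "survey_informed": [True, False, True]})
        anchors = nearest_anchor_years(traj)
        assert anchors["C1"] == {1990: 1990, 2000: 2010, 2010: 2010}

    def test_no_informed_years_absent(self):
        traj = pd.DataFrame({"country": "C1", "year": [1990],
                             "survey_informed": [False]})
        assert nearest_anchor_years(traj) == {}


def _fake_trend(countries, beta=0.25, beta_sd=0.0, alpha=1.0, n=120):
    """Hand-built trend posterior with controlled slope draws."""
    rng = np.random.default_rng(0)
    C = len(countries)
    b = beta + beta_sd * rng.standard_normal((1, n, C))
    return ds.TrendPosterior(
        countries=list(countries),
        alpha=np.full((1, n, C), alpha), beta=b,
        mu=np.tile([alpha, beta], (1, n, 1)),
        Sigma=np.tile(0.01 * np.eye(2), (1, n, 1, 1)),
        sigma_resid=np.full((1, n), 0.05),
        avail_center={c: 0.0 for c in countries},
        spec=ds.TrendSpec(seed=0), diagnostics={})
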
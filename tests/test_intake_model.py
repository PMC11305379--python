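"""Intake model: design contracts, parameter recovery, prediction behavior."""
import copy

import numpy as np
import pandas as pd
import pytest

import dietstrata as ds
from dietstrata.config import STRATUM_COLS
from dietstrata.intake_model import build_design, predict_strata


def _saturated_world(seed=31, **params_kw):
    """One-region world with every stratum surveyed at negligible noise."""
    base = dict(sigma_region=0.0, sigma_country=0.3, slope_sd=0.0, rho=0.0,
                avail_coef=0.0, residual_sigma=1e-4, overdispersion_tau=0.0,
                method_bias={m: 0.0 for m in ("24h recall", "FFQ",
                                              "short questionnaire",
                                              "household budget")})
    base.update(params_kw)
    cfg = ds.WorldConfig(
        n_regions=1, countries_per_region=3, years=(2000, 2010), seed=seed,
        params=ds.TrueParams(**base), survey_coverage_prob=1.0,
        coarse_survey_prob=0.0, representative_prob=1.0,
        method_probs=(1.0, 0.0, 0.0, 0.0),   # reference method only, so no
        cell_n_range=(1e10, 1e10), intake_cv=0.5)  # bias-vs-level confounding
    world = ds.generate_world(cfg)
    pops = ds.generate_populations(world)
    surveys = ds.harmonize_surveys(ds.simulate_surveys(world, populations=pops))
    cov = ds.generate_covariates(world)
    return world, pops, surveys, cov


class TestBuildDesign:
    def test_fully_stratified_row_matches_cell(self, small_world):
        s = small_world["surveys"]
        fine = s[(s[STRATUM_COLS] != "all").all(axis=1)]
        d = build_design(fine, small_world["covariates"],
                         populations=small_world["pops"])
        grid, demo = d.builder.grid_demo()
        row = fine.iloc[0]
        i = grid.index[(grid["age_bin"] == row["age_bin"])
                       & (grid["sex"] == row["sex"])
                       & (grid["education"] == row["education"])
                       & (grid["residence"] == row["residence"])][0]
        got = d.X[0].toarray().ravel()[1:1 + demo.shape[1]]
        assert np.array_equal(got, demo[i])

    def test_equal_population_sex_collapse_gives_half(self, small_world):
        s = small_world["surveys"].iloc[:1].copy()
        s[["sex", "education", "residence"]] = ["all", "low", "rural"]
        s["age_bin"] = "20-24"
        pops = small_world["pops"].copy()
        pops["population"] = 1.0
        d = build_design(s, small_world["covariates"], populations=pops)
        names = d.builder.fixed_names
        x = d.X[0].toarray().ravel()
        assert x[names.index("sex[male]")] == pytest.approx(0.5)

    def test_coarse_row_equals_brute_force_average(self, small_world, rng):
        s = small_world["surveys"].iloc[:1].copy()
        s[["sex", "education"]] = "all"
        s["age_bin"], s["residence"] = "30-34", "urban"
        pops = small_world["pops"].copy()
        pops["population"] = rng.uniform(10, 1000, len(pops))
        d = build_design(s, small_world["covariates"], populations=pops)
        grid, demo = d.builder.grid_demo()
        mask = ((grid["age_bin"] == "30-34")
                & (grid["residence"] == "urban")).to_numpy()
        sub = pops[(pops["country"] == s["country"].iloc[0])
                   & (pops["year"] == s["year"].iloc[0])]
        w = sub.set_index(STRATUM_COLS).loc[
            pd.MultiIndex.from_frame(grid[mask][STRATUM_COLS]),
            "population"].to_numpy()
        expect = np.average(demo[mask], axis=0, weights=w)
        got = d.X[0].toarray().ravel()[1:1 + demo.shape[1]]
        assert np.allclose(got, expect, rtol=1e-12)

    def test_unknown_country_listed_in_error(self, small_world):
        s = small_world["surveys"].copy()
        s.loc[s.index[0], "country"] = "ATLANTIS"
        with pytest.raises(ValueError, match="ATLANTIS"):
            build_design(s, small_world["covariates"])

    def test_zero_observations_rejected(self, small_world):
        with pytest.raises(ValueError, match="no observations"):
            build_design(small_world["surveys"].iloc[0:0],
                         small_world["covariates"])


class TestFitRecovery:
    def test_urban_and_education_effects_recovered(self, small_fit):
        # generator truth: urban-rural 0.5, high-low education 0.3 (log scale)
        assert abs(small_fit.coef_mean("res[urban]") - 0.5) < 0.15
        assert abs(small_fit.coef_mean("edu[high]") - 0.3) < 0.15

    def test_residual_sigma_recovered(self, small_fit):
        est = small_fit.flat(small_fit.sigma).mean()
        assert abs(est - 0.10) < 0.05

    def test_convergence_diagnostics_reported(self, small_fit):
        d = small_fit.diagnostics
        assert set(d["rhat"]) >= {"sigma", "res[urban]"}
        assert d["n_observations"] > 0

    def test_saturated_noise_free_fit_matches_observations(self):
        world, pops, surveys, cov = _saturated_world()
        spec = ds.ModelSpec(chains=2, warmup=150, draws=150, seed=2)
        post = ds.fit_intake_model(surveys, cov, spec, pops)
        da = predict_strata(post, "C001", 2000, n_draws=200)
        obs = surveys[(surveys["country"] == "C001") & (surveys["year"] == 2000)]
        merged = da.index.merge(obs, on=["country", "year", *STRATUM_COLS])
        med = np.percentile(da.values, 50, axis=1)
        assert np.allclose(med, merged["servings_wk"], rtol=0.02)

    def test_overdispersion_ordering_across_replicates(self):
        taus = {0.0: [], 0.4: []}
        for tau in taus:
            for rep in range(2):
                cfg = ds.WorldConfig(
                    n_regions=2, countries_per_region=3, years=(2000, 2010),
                    seed=60 + rep, survey_coverage_prob=1.0,
                    representative_prob=0.5, coarse_survey_prob=0.0,
                    params=ds.TrueParams(overdispersion_tau=tau,
                                         residual_sigma=0.05))
                world = ds.generate_world(cfg)
                pops = ds.generate_populations(world)
                s = ds.harmonize_surveys(ds.simulate_surveys(world, populations=pops))
                cov = ds.generate_covariates(world)
                spec = ds.ModelSpec(chains=2, warmup=150, draws=150, seed=80 + rep)
                post = ds.fit_intake_model(s, cov, spec, pops)
                taus[tau].append(post.flat(post.taus).mean())
        for a, b in zip(taus[0.0], taus[0.4]):
            assert a < b


class TestPredict:
    def test_identity_all_effects_zero(self, small_fit):
        post = copy.copy(small_fit)
        post.theta = np.zeros_like(small_fit.theta)
        post.theta[:, :, 0] = np.log(3.0 + post.spec.epsilon)
        da = predict_strata(post, "C001", 1990, n_draws=50)
        assert np.allclose(da.values, 3.0)
        assert da.values.shape == (264, 50)

    def test_reference_level_invariant_to_bias_coefficients(self, small_fit):
        base = predict_strata(small_fit, "C001", 1990, n_draws=50)
        post = copy.copy(small_fit)
        post.theta = small_fit.theta.copy()
        bias = small_fit.design.blocks["bias"]
        post.theta[:, :, bias] += 5.0   # perturb all survey-bias coefficients
        shifted = predict_strata(post, "C001", 1990, n_draws=50)
        assert np.array_equal(base.values, shifted.values)

    def test_all_draws_positive(self, small_fit):
        da = predict_strata(small_fit, "C002", 2010, n_draws=100)
        assert (da.values >= 0).all()

    def test_no_survey_country_has_wider_intervals(self, small_world):
        s = small_world["surveys"]
        held_out = "C002"
        spec = ds.ModelSpec(chains=2, warmup=150, draws=150, seed=9)
        post = ds.fit_intake_model(s[s["country"] != held_out],
                                   small_world["covariates"], spec,
                                   small_world["pops"])
        da_out = predict_strata(post, held_out, 2000, n_draws=300)
        assert da_out.flags.get("no-country-data")
        # same-region surveyed country (C001..C003 are region R01)
        da_in = predict_strata(post, "C001", 2000, n_draws=300)
        width = lambda v: np.diff(np.percentile(np.log(v + 0.01),
                                                [2.5, 97.5], axis=1), axis=0)
        assert width(da_out.values).mean() > width(da_in.values).mean()

    def test_removing_surveys_never_narrows_intervals(self, small_world, small_fit):
        s = small_world["surveys"]
        spec = ds.ModelSpec(chains=2, warmup=150, draws=150, seed=5)
        post2 = ds.fit_intake_model(s[s["country"] != "C002"],
                                    small_world["covariates"], spec,
                                    small_world["pops"])
        full = predict_strata(small_fit, "C002", 2000, n_draws=300)
        reduced = predict_strata(post2, "C002", 2000, n_draws=300)
        width = lambda v: np.diff(np.percentile(np.log(v + 0.01),
                                                [2.5, 97.5], axis=1), axis=0).mean()
        assert width(reduced.values) >= width(full.values)

    def test_unknown_covariate_country_raises(self, small_fit):
        with pytest.raises(KeyError):
            predict_strata(small_fit, "NOWHERE", 2000)


class TestShrinkage:
    def test_single_survey_country_pulled_toward_region(self):
        world, pops, surveys, cov = _saturated_world(seed=77)
        # C003 keeps one fine survey at year 2000 with modest sample sizes and
        # an upward-shifted mean; its predictions should land between the
        # observed values and the region's level on the log scale
        s = surveys[(surveys["country"] != "C003")
                    | (surveys["year"] == 2000)].copy()
        shift = 1.6
        c3 = s["country"] == "C003"
        s.loc[c3, "servings_wk"] *= shift
        s.loc[c3, "se_servings_wk"] = s.loc[c3, "servings_wk"] * 0.3
        spec = ds.ModelSpec(chains=2, warmup=200, draws=200, seed=4,
                            include_country_year=False)
        post = ds.fit_intake_model(s, cov, spec, pops)
        pred = np.log(np.percentile(
            predict_strata(post, "C003", 2000, n_draws=300).values, 50, axis=1)
            + 0.01)
        obs = s[c3].sort_values(STRATUM_COLS)
        grid_order = ds.stratum_grid().reset_index().merge(
            obs, on=STRATUM_COLS)["servings_wk"].to_numpy()
        obs_log = np.log(grid_order + 0.01)
        region_log = np.log(np.percentile(np.mean([
            predict_strata(post, c, 2000, n_draws=300).values
            for c in ("C001", "C002")], axis=0), 50, axis=1) + 0.01)
        lo = np.minimum(obs_log, region_log) - 0.05
        hi = np.maximum(obs_log, region_log) + 0.05
        assert ((pred >= lo) & (pred <= hi)).all()
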
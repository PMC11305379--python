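"""Synthetic survey world with known ground truth.

Generates a complete fictitious "world": true mean intakes for every
demographic stratum in every country-year, sparse and biased survey
observations of those means, country-year covariates, and population counts.
The generative model is log-linear with additive demographic, region,
country, and availability-slope effects, so that the downstream hierarchical
intake model is estimating a world that actually has the structure it
assumes — which makes parameter-recovery and calibration checks well posed.

True stratum means are exact closed-form quantities (``exp`` of the linear
predictor); only the survey observations carry noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    AGE_BINS, ASSESSMENT_METHODS, DAYS_PER_WEEK, EDUCATION_LEVELS,
    ENERGY_TARGET_KCAL, RESIDENCE_LEVELS, SERVING_GRAMS, SEXES, STRATUM_COLS,
    CovariateConfig, TrueParams, WorldConfig, stratum_grid,
)

__all__ = [
    "World", "generate_world", "simulate_surveys", "generate_covariates",
    "generate_populations", "collapse_cells",
]


@dataclass
class World:
    """A generated synthetic world: config, latent truth, and lookups."""
    config: WorldConfig
    params: TrueParams
    countries: pd.DataFrame          # country, region
    availability: pd.DataFrame       # country, year, availability (standardized)
    truth: pd.DataFrame              # stratum grid + true_mean (servings/week)
    _pop_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def country_list(self) -> list[str]:
        return list(self.countries["country"])

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.config.years)

    def region_of(self, country: str) -> str:
        m = dict(zip(self.countries["country"], self.countries["region"]))
        return m[country]


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_world(config: WorldConfig) -> World:
    """Generate latent parameters and the true stratum-mean table.

    The log true mean of stratum (a, s, e, r) in country c, year y is::

        intercept + age_a + sex_s + edu_e + res_r
            + region_{R(c)} + country_c + slope_c * avail_{cy}

    where ``avail`` is the standardized availability series and country
    intercept deviations and slopes are drawn from a correlated bivariate
    normal (correlation ``rho``).  Deterministic given ``config.seed``.
    """
    config.validate()
    p = config.params
    n_c = config.n_regions * config.countries_per_region
    regions = [f"R{r + 1:02d}" for r in range(config.n_regions)]
    countries = pd.DataFrame({
        "country": [f"C{i + 1:03d}" for i in range(n_c)],
        "region": [regions[i // config.countries_per_region] for i in range(n_c)],
    })

    rng = _child_rng(config.seed, 0)
    region_effects = rng.normal(0.0, p.sigma_region, size=config.n_regions)
    # correlated (country intercept, slope) deviations; robust to zero SDs
    z = rng.standard_normal((n_c, 2))
    dev = np.column_stack([
        p.sigma_country * z[:, 0],
        p.slope_sd * (p.rho * z[:, 0] + np.sqrt(1.0 - p.rho ** 2) * z[:, 1]),
    ])
    params = TrueParams(**{
        **{f: getattr(p, f) for f in (
            "global_intercept", "sex_effect", "education_effects",
            "residence_effect", "sigma_region", "sigma_country", "avail_coef",
            "slope_sd", "rho", "overdispersion_tau", "residual_sigma",
        )},
        "age_effects": np.asarray(p.age_effects, dtype=float),
        "method_bias": dict(p.method_bias),
    })
    params.region_effects = region_effects
    params.country_effects = dev[:, 0]
    params.country_slopes = p.avail_coef + dev[:, 1]

    # availability: per-country level + linear drift + innovation noise,
    # standardized over all country-years
    rng_a = _child_rng(config.seed, 1)
    years = np.asarray(config.years, dtype=float)
    t_norm = (years - years.mean()) / max((years.max() - years.min()) / 2.0, 1.0)
    base = rng_a.normal(0.0, 0.5, size=n_c)
    drift = rng_a.normal(0.0, 0.5, size=n_c)
    raw = base[:, None] + drift[:, None] * t_norm[None, :]
    raw = raw + rng_a.normal(0.0, config.avail_noise_sd, size=raw.shape)
    std = raw.std()
    avail = (raw - raw.mean()) / (std if std > 0 else 1.0)
    availability = pd.DataFrame({
        "country": np.repeat(countries["country"].to_numpy(), len(years)),
        "year": np.tile(np.asarray(config.years), n_c),
        "availability": avail.reshape(-1),
    })

    # true stratum means
    grid = stratum_grid()
    age_eff = dict(zip(AGE_BINS, params.age_effects))
    demo_eta = (
        grid["age_bin"].map(age_eff).to_numpy()
        + np.where(grid["sex"] == "male", params.sex_effect, 0.0)
        + grid["education"].map(dict(zip(EDUCATION_LEVELS, params.education_effects))).to_numpy()
        + np.where(grid["residence"] == "urban", params.residence_effect, 0.0)
    )
    frames = []
    for ci, (country, region) in enumerate(zip(countries["country"], countries["region"])):
        r_idx = regions.index(region)
        for yi, year in enumerate(config.years):
            eta = (
                params.global_intercept + demo_eta
                + params.region_effects[r_idx] + params.country_effects[ci]
                + params.country_slopes[ci] * avail[ci, yi]
            )
            g = grid.copy()
            g.insert(0, "year", year)
            g.insert(0, "country", country)
            g["true_mean"] = np.exp(eta)
            frames.append(g)
    truth = pd.concat(frames, ignore_index=True)
    return World(config=config, params=params, countries=countries,
                 availability=availability, truth=truth)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def generate_populations(world: World) -> pd.DataFrame:
    """Population counts for all 264 cells of every country-year.

    Marginal shares (age pyramid, sex split, education mix, urban share) are
    combined independently; education and urbanization drift over calendar
    time so that 1990 and 2018 stratum proportions genuinely differ, which is
    what makes change standardization a non-trivial operation.  Counts sum to
    the declared national population in every country-year.  Deterministic
    given the world's seed (cached on the world object).
    """
    if world._pop_cache is not None:
        return world._pop_cache.copy()
    cfg = world.config
    rng = _child_rng(cfg.seed, 2)
    years = np.asarray(cfg.years, dtype=float)
    y_frac = (years - years[0]) / max(years[-1] - years[0], 1.0)
    n_age = len(AGE_BINS)
    frames = []
    for country in world.country_list:
        base_pop = float(np.exp(rng.normal(np.log(2e7), 0.5)))
        growth = rng.normal(0.012, 0.005)
        k0 = rng.uniform(0.03, 0.12)
        low0 = rng.uniform(0.30, 0.60)
        high0 = rng.uniform(0.05, 0.20)
        urban0 = rng.uniform(0.30, 0.60)
        for year, f in zip(cfg.years, y_frac):
            national = base_pop * np.exp(growth * (year - cfg.years[0]))
            k = max(k0 * (1.0 - 0.25 * f), 1e-3)          # slow population ageing
            w_age = np.exp(-k * np.arange(n_age))
            w_age /= w_age.sum()
            low = float(np.clip(low0 - 0.20 * f, 0.05, 0.90))
            high = float(np.clip(high0 + 0.15 * f, 0.02, 0.80))
            med = max(1.0 - low - high, 0.05)
            w_edu = np.array([low, med, high])
            w_edu /= w_edu.sum()
            urban = float(np.clip(urban0 + 0.20 * f, 0.05, 0.95))
            w_res = np.array([1.0 - urban, urban])
            w_sex = np.array([0.5, 0.5])
            g = stratum_grid(country=country, year=int(year))
            share = (
                g["age_bin"].map(dict(zip(AGE_BINS, w_age))).to_numpy()
                * g["sex"].map(dict(zip(SEXES, w_sex))).to_numpy()
                * g["education"].map(dict(zip(EDUCATION_LEVELS, w_edu))).to_numpy()
                * g["residence"].map(dict(zip(RESIDENCE_LEVELS, w_res))).to_numpy()
            )
            g["population"] = national * share
            frames.append(g)
    pops = pd.concat(frames, ignore_index=True)
    world._pop_cache = pops
    return pops.copy()


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

_COLLAPSE_CHOICES = (("sex",), ("education",), ("sex", "education"))


def collapse_cells(cells: pd.DataFrame, weights: np.ndarray,
                   collapse_dims: tuple[str, ...]) -> pd.DataFrame:
    """Population-weighted collapse of elementary cells over ``collapse_dims``.

    The collapsed dimensions are reported as the label ``"all"``; the value
    column ``true_mean`` becomes the weighted mean of its members.
    """
    df = cells.copy()
    df["_w"] = weights
    keep = [c for c in STRATUM_COLS if c not in collapse_dims]
    grouped = df.groupby(keep, sort=False, observed=True).apply(
        lambda g: pd.Series({
            "true_mean": float(np.average(g["true_mean"], weights=np.maximum(g["_w"], 1e-12))),
            "population": float(g["_w"].sum()),
        }),
        include_groups=False,
    ).reset_index()
    for dim in collapse_dims:
        grouped[dim] = "all"
    return grouped[STRATUM_COLS + ["true_mean", "population"]]


def simulate_surveys(world: World, config: WorldConfig | None = None,
                     seed: int | None = None,
                     populations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate the raw survey corpus for the world.

    Each sampled country-year yields one survey with an assessment method, a
    representativeness flag, and per-cell sample sizes.  Observed cell means
    are the true means times ``exp(method_bias + noise)`` plus sampling error
    ``SD / sqrt(n)``, where the noise SD is ``sqrt(residual_sigma^2 +
    tau^2)`` for overdispersed surveys (non-representative or coarsely
    stratified — the same flag the likelihood applies) and
    ``residual_sigma`` otherwise.  Coarse surveys report population-weighted
    collapses over sex and/or education.

    Returns the raw (pre-harmonization) table in grams/day with per-cell SD,
    sample size, and reported energy intake.
    """
    if world.truth.empty:
        raise ValueError("cannot simulate surveys from an empty world")
    cfg = config or world.config
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed if seed is None else seed, spawn_key=(3,))
    )
    pops = populations if populations is not None else generate_populations(world)
    p = world.params
    truth = world.truth.set_index(["country", "year"])
    pops_idx = pops.set_index(["country", "year"])
    records = []
    survey_no = 0
    lo, hi = cfg.cell_n_range
    for country in world.country_list:
        for year in cfg.years:
            if rng.random() >= cfg.survey_coverage_prob:
                continue
            survey_no += 1
            survey_id = f"S{survey_no:04d}"
            method = ASSESSMENT_METHODS[rng.choice(len(ASSESSMENT_METHODS), p=cfg.method_probs)]
            representative = bool(rng.random() < cfg.representative_prob)
            coarse = bool(rng.random() < cfg.coarse_survey_prob)
            cells = truth.loc[(country, year)].reset_index(drop=True)
            w = pops_idx.loc[(country, year)].reset_index(drop=True)["population"].to_numpy()
            if coarse:
                dims = _COLLAPSE_CHOICES[rng.choice(len(_COLLAPSE_CHOICES))]
                reported = collapse_cells(cells[STRATUM_COLS + ["true_mean"]], w, dims)
            else:
                reported = cells[STRATUM_COLS + ["true_mean"]].copy()
                reported["population"] = w
            overdispersed = (not representative) or coarse
            noise_sd = np.sqrt(p.residual_sigma ** 2
                               + (p.overdispersion_tau ** 2 if overdispersed else 0.0))
            m = reported["true_mean"].to_numpy()
            n_cell = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(m)))
            n_cell = np.maximum(np.round(n_cell), 1.0)
            sd_cell = cfg.intake_cv * m
            se = sd_cell / np.sqrt(n_cell)
            bias = p.method_bias.get(method, 0.0)
            obs = m * np.exp(bias + rng.normal(0.0, noise_sd, size=len(m)))
            obs = np.maximum(obs + rng.normal(0.0, 1.0, size=len(m)) * se, 0.0)
            out = reported[STRATUM_COLS].copy()
            out.insert(0, "year", year)
            out.insert(0, "country", country)
            out.insert(0, "survey_id", survey_id)
            out["method"] = method
            out["representative"] = representative
            out["metric_type"] = "mean_daily_grams"
            out["sample_n"] = n_cell.astype(int)
            g_per_serving_wk = SERVING_GRAMS / DAYS_PER_WEEK
            out["grams_per_day"] = obs * g_per_serving_wk
            out["sd_grams_per_day"] = cfg.intake_cv * np.maximum(obs, 1e-9) * g_per_serving_wk
            # surveys report energy at the age-specific target, i.e. the corpus
            # arrives already energy-standardized (see methods note)
            out["energy_kcal_per_day"] = [
                ENERGY_TARGET_KCAL[a] if a != "all" else 2000.0 for a in out["age_bin"]
            ]
            records.append(out)
    if not records:
        return pd.DataFrame(columns=["survey_id", "country", "year", *STRATUM_COLS])
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def generate_covariates(world: World, seed: int | None = None,
                        cov_config: CovariateConfig | None = None) -> pd.DataFrame:
    """Country-year covariates: availability, SDI, obesity prevalence, region.

    The availability series is, by default, the latent series the truth was
    generated from (mode ``"latent"``), so its correlation with true intake is
    whatever the slope settings induce.  Mode ``"from_truth"`` rebuilds it as
    a standardized affine function of the true country-year mean plus noise
    calibrated so that the availability-intake correlation approximates
    ``availability_corr``.  SDI (in [0, 1]) and obesity prevalence are
    generated with configurable correlations to (log) intake.
    """
    cc = cov_config or CovariateConfig()
    cfg = world.config
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed if seed is None else seed, spawn_key=(4,))
    )
    cy_mean = (world.truth.groupby(["country", "year"], sort=False)["true_mean"]
               .mean().reset_index(name="intake_mean"))
    df = cy_mean.merge(world.availability, on=["country", "year"])
    df = df.merge(world.countries, on="country")

    z_log = df["intake_mean"].apply(np.log)
    z_log = ((z_log - z_log.mean()) / max(z_log.std(ddof=0), 1e-12)).to_numpy()

    if cc.availability_mode == "from_truth":
        r = float(np.clip(cc.availability_corr, -1.0, 1.0))
        raw = df["intake_mean"].to_numpy()
        z_raw = (raw - raw.mean()) / max(raw.std(ddof=0), 1e-12)
        noise = rng.normal(size=len(df))
        df["availability"] = r * z_raw + np.sqrt(max(1.0 - r * r, 0.0)) * noise
    elif cc.availability_mode != "latent":
        raise ValueError(f"unknown availability_mode {cc.availability_mode!r}")

    def _mix(r: float, noise: np.ndarray) -> np.ndarray:
        r = float(np.clip(r, -1.0, 1.0))
        return r * z_log + np.sqrt(max(1.0 - r * r, 0.0)) * noise

    sdi_raw = _mix(cc.intake_sdi_corr, rng.normal(size=len(df)))
    df["sdi"] = np.clip(0.5 + 0.18 * sdi_raw, 0.0, 1.0)
    obes_raw = _mix(cc.intake_obesity_corr, rng.normal(size=len(df)))
    df["obesity_prev"] = np.clip(0.18 + 0.07 * obes_raw, 0.005, 0.60)
    return df[["country", "year", "region", "availability", "sdi",
               "obesity_prev", "intake_mean"]]
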
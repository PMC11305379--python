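"""Constants, configuration objects, and core data containers.

The analysis operates on a fixed demographic grid: 22 age bins x 2 sexes x
3 education levels x 2 residence categories = 264 joint strata per
country-year.  Intakes are expressed in standardized 248 g (8 oz) servings
per week throughout; model fitting happens on the log scale.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Demographic grid
# ---------------------------------------------------------------------------

AGE_BINS: tuple[str, ...] = (
    "<1", "1-2", "3-4", "5-9", "10-14", "15-19",
    "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79",
    "80-84", "85-89", "90-94", ">=95",
)
SEXES: tuple[str, ...] = ("female", "male")
EDUCATION_LEVELS: tuple[str, ...] = ("low", "medium", "high")
RESIDENCE_LEVELS: tuple[str, ...] = ("rural", "urban")

N_STRATA = len(AGE_BINS) * len(SEXES) * len(EDUCATION_LEVELS) * len(RESIDENCE_LEVELS)

#: Age bins used for child/adolescent (ages 3-19) aggregates.
CHILD_AGE_BINS: tuple[str, ...] = ("3-4", "5-9", "10-14", "15-19")

STRATUM_COLS = ["age_bin", "sex", "education", "residence"]

# ---------------------------------------------------------------------------
# Units and harmonization constants
# ---------------------------------------------------------------------------

SERVING_GRAMS = 248.0          # one standardized serving (8 oz)
DAYS_PER_WEEK = 7.0
SSB_MIN_KCAL_PER_SERVING = 50.0   # per 237 g serving
#: beverage categories excluded from the SSB definition even when sweetened
SSB_EXCLUDED_CATEGORIES = frozenset(
    {"100% juice", "artificially sweetened", "sweetened milk", "tea", "coffee"}
)
SSB_CATEGORIES = (
    "soft drink", "energy drink", "fruit drink", "punch", "lemonade",
    "agua fresca", "100% juice", "artificially sweetened", "sweetened milk",
    "tea", "coffee", "other",
)

#: Energy-adjustment targets (kcal/day) by age bin.  Printed bands are
#: 1300 kcal for ages 3-5, 1700 for 6-10 and 2000 for 11-19; the 5-9 model
#: bin straddles two bands and is assigned by its majority overlap (1700),
#: adults and infants default to the nearest band (2000 and 1300).
ENERGY_TARGET_KCAL: dict[str, float] = {
    "<1": 1300.0, "1-2": 1300.0, "3-4": 1300.0, "5-9": 1700.0,
    "10-14": 2000.0, "15-19": 2000.0,
}
for _bin in AGE_BINS[6:]:
    ENERGY_TARGET_KCAL[_bin] = 2000.0

ASSESSMENT_METHODS: tuple[str, ...] = (
    "24h recall", "FFQ", "short questionnaire", "household budget",
)
REFERENCE_METHOD = "24h recall"

DEFAULT_YEARS: tuple[int, ...] = (1990, 1995, 2000, 2005, 2010, 2015, 2018)

#: The seven world regions conventionally used in global dietary surveillance.
#: The synthetic world uses generic region labels; this list is retained for
#: real-data region maps.
WORLD_REGIONS: tuple[str, ...] = (
    "central and eastern Europe and central Asia",
    "high income countries",
    "Latin America and the Caribbean",
    "Middle East and north Africa",
    "south Asia",
    "southeast and east Asia",
    "sub-Saharan Africa",
)

#: Headline policy threshold (servings/week) for the national count statistic.
HEADLINE_THRESHOLD = 7.0


def stratum_grid(country: str | None = None, year: int | None = None) -> pd.DataFrame:
    """Return the canonical 264-row stratum grid, in fixed order.

    Order is age (22) x sex (2) x education (3) x residence (2), with the
    constituent levels ordered as in the module constants.  When ``country``
    and/or ``year`` are given they are added as leading constant columns.
    """
    rows = [
        (a, s, e, r)
        for a in AGE_BINS for s in SEXES for e in EDUCATION_LEVELS
        for r in RESIDENCE_LEVELS
    ]
    grid = pd.DataFrame(rows, columns=STRATUM_COLS)
    if year is not None:
        grid.insert(0, "year", year)
    if country is not None:
        grid.insert(0, "country", country)
    return grid


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EstimateSummary:
    """Median and central 95% uncertainty interval of a draw distribution."""
    median: float
    lo95: float
    hi95: float
    population: float = float("nan")

    def __post_init__(self):
        if not (self.lo95 <= self.median <= self.hi95):
            raise ValueError(
                f"interval ordering violated: {self.lo95}, {self.median}, {self.hi95}"
            )


@dataclass
class DrawArray:
    """A strata-by-draws matrix of posterior mean intakes (servings/week).

    ``index`` carries one row of stratum labels per row of ``values``; the
    draw axis is the common uncertainty currency of the whole pipeline.
    """
    index: pd.DataFrame
    values: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (strata x draws)")
        if len(self.index) != self.values.shape[0]:
            raise ValueError("index length does not match number of rows")

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "DrawArray":
        return DrawArray(self.index.copy(), self.values.copy(), dict(self.flags))


# ---------------------------------------------------------------------------
# Synthetic-world configuration
# ---------------------------------------------------------------------------

def _default_age_effects() -> np.ndarray:
    """Smooth default age pattern on the log scale (reference: first bin).

    Rises from infancy to a plateau in early adulthood and declines in old
    age, echoing the age gradients seen in beverage-intake tables.
    """
    idx = np.arange(len(AGE_BINS), dtype=float)
    curve = 0.8 * (1.0 - np.exp(-idx / 4.0)) - 0.012 * np.maximum(idx - 12, 0.0) ** 1.5
    return curve - curve[0]


@dataclass
class TrueParams:
    """Latent generative parameters of the synthetic world (log scale)."""
    global_intercept: float = float(np.log(2.0))
    age_effects: np.ndarray = field(default_factory=_default_age_effects)
    sex_effect: float = 0.05                       # male vs female
    education_effects: tuple[float, float, float] = (0.0, 0.15, 0.30)
    residence_effect: float = 0.50                 # urban vs rural
    sigma_region: float = 0.30
    sigma_country: float = 0.40
    avail_coef: float = 0.30       # mean slope on the standardized availability
    slope_sd: float = 0.15         # SD of country slope deviations
    rho: float = 0.60              # corr(country intercept, country slope)
    method_bias: dict = field(default_factory=lambda: {
        "24h recall": 0.0, "FFQ": 0.15, "short questionnaire": 0.25,
        "household budget": -0.20,
    })
    overdispersion_tau: float = 0.15
    residual_sigma: float = 0.10
    # filled in by generate_world:
    region_effects: np.ndarray | None = None
    country_effects: np.ndarray | None = None
    country_slopes: np.ndarray | None = None

    def validate(self) -> None:
        if len(self.age_effects) != len(AGE_BINS):
            raise ValueError(f"age_effects must have length {len(AGE_BINS)}")
        if self.age_effects[0] != 0.0:
            raise ValueError("age_effects[0] is the reference level and must be 0")
        if len(self.education_effects) != len(EDUCATION_LEVELS):
            raise ValueError("education_effects must have 3 levels")
        if self.education_effects[0] != 0.0:
            raise ValueError("education_effects[0] is the reference level and must be 0")
        for sd_name in ("sigma_region", "sigma_country", "overdispersion_tau",
                        "residual_sigma", "slope_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        unknown = set(self.method_bias) - set(ASSESSMENT_METHODS)
        if unknown:
            raise ValueError(f"unknown assessment methods in method_bias: {unknown}")
        if self.method_bias.get(REFERENCE_METHOD, 0.0) != 0.0:
            raise ValueError(f"{REFERENCE_METHOD!r} is the reference method; bias must be 0")


@dataclass
class WorldConfig:
    """Size, coverage and noise settings of the synthetic world."""
    n_regions: int = 4
    countries_per_region: int = 5
    years: tuple[int, ...] = DEFAULT_YEARS
    n_draws: int = 4000
    seed: int = 0
    params: TrueParams = field(default_factory=TrueParams)
    survey_coverage_prob: float = 0.70
    coarse_survey_prob: float = 0.30
    representative_prob: float = 0.94
    method_probs: tuple[float, ...] = (0.24, 0.61, 0.10, 0.05)
    #: within-cell individual SD as a multiple of the cell mean
    intake_cv: float = 1.0
    cell_n_range: tuple[float, float] = (30.0, 3000.0)
    #: availability innovation noise (log-scale SD around the country trend)
    avail_noise_sd: float = 0.15

    def validate(self) -> None:
        if self.n_regions < 1 or self.countries_per_region < 1:
            raise ValueError("counts must be >= 1")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        years = tuple(self.years)
        if any(b <= a for a, b in zip(years, years[1:])) or len(years) == 0:
            raise ValueError("years must be non-empty and strictly increasing")
        for p_name in ("survey_coverage_prob", "coarse_survey_prob", "representative_prob"):
            p = getattr(self, p_name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{p_name} must lie in [0, 1]")
        if len(self.method_probs) != len(ASSESSMENT_METHODS):
            raise ValueError("method_probs must match the assessment-method list")
        if abs(sum(self.method_probs) - 1.0) > 1e-9:
            raise ValueError("method_probs must sum to 1")
        self.params.validate()


@dataclass
class CovariateConfig:
    """Settings for the country-year covariate generator."""
    intake_obesity_corr: float = 0.30
    intake_sdi_corr: float = 0.20
    #: 'latent' keeps the availability series the truth was generated from;
    #: 'from_truth' rebuilds it as an affine function of the true country-year
    #: mean plus noise calibrated to ``availability_corr``.
    availability_mode: str = "latent"
    availability_corr: float = 0.9


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Priors, transformation and sampler settings of the intake model."""
    epsilon: float = 0.01               # log(x + epsilon) offset, servings/week
    prior_scale_fixed: float = 2.0
    # survey-instrument biases are modest multiplicative effects; N(0, 0.3)
    # on the log scale spans roughly -45%..+35%
    prior_scale_bias: float = 0.3
    prior_scale_sd: float = 1.0         # half-normal scale for all SD parameters
    age_smooth_sd: float = 0.30         # random-walk prior SD between adjacent age bins
    include_country_year: bool = True
    overdispersion_mode: str = "single"   # 'single' or 'per_flag'
    chains: int = 4
    warmup: int = 500
    draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.05

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.draws < 1 or self.chains < 1 or self.warmup < 0:
            raise ValueError("invalid sampler settings")
        if self.overdispersion_mode not in ("single", "per_flag"):
            raise ValueError("overdispersion_mode must be 'single' or 'per_flag'")


@dataclass
class TrendSpec:
    """Priors and sampler settings of the varying-slopes trend model."""
    mu_prior_mean: tuple[float, float] = (0.0, 0.0)
    mu_prior_sd: tuple[float, float] = (5.0, 2.0)
    iw_df: float = 3.0
    iw_scale: float = 0.05              # scale matrix = iw_scale * I
    sigma_resid_prior_scale: float = 0.5
    chains: int = 4
    warmup: int = 500
    draws: int = 1000
    seed: int = 0
    combination_rule: str = "anchor_ratio"   # or 'log_blend'

    def validate(self) -> None:
        if self.iw_df <= 1.0 or self.iw_scale <= 0:
            raise ValueError("inverse-Wishart prior must have positive-definite support")
        if self.combination_rule not in ("anchor_ratio", "log_blend"):
            raise ValueError("combination_rule must be 'anchor_ratio' or 'log_blend'")


@dataclass
class ValidationSpec:
    n_folds: int = 5
    n_repeats: int = 5
    implausible_lo: float = 0.0
    implausible_hi: float = 35.0
    max_ui_ratio: float | None = None


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings: stage toggles, seeds, constants, paths."""
    out_dir: str = "dietstrata_out"
    seed: int = 0
    n_draws: int = 200
    world: WorldConfig = field(default_factory=WorldConfig)
    covariates: CovariateConfig = field(default_factory=CovariateConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    trend: TrendSpec = field(default_factory=TrendSpec)
    validation: ValidationSpec = field(default_factory=ValidationSpec)
    serving_grams: float = SERVING_GRAMS
    threshold_servings_wk: float = HEADLINE_THRESHOLD
    change_periods: tuple[tuple[int, int], ...] = ((1990, 2005), (2005, 2018), (1990, 2018))
    stages: tuple[str, ...] = (
        "simulate", "harmonize", "fit", "trend", "aggregate", "validate",
    )

    def resolve_seeds(self) -> None:
        """Propagate the top-level seed and draw count into sub-configs."""
        self.world.seed = self.seed
        self.world.n_draws = self.n_draws
        self.model.seed = self.seed + 1
        self.trend.seed = self.seed + 2


def config_to_dict(cfg) -> dict:
    """Recursively convert a (possibly nested) config dataclass to plain dicts."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {k: config_to_dict(v) for k, v in dataclasses.asdict(cfg).items()}
    if isinstance(cfg, np.ndarray):
        return cfg.tolist()
    if isinstance(cfg, dict):
        return {k: config_to_dict(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return [config_to_dict(v) for v in cfg]
    return cfg


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain (e.g. YAML-loaded) dict."""
    d = dict(d)

    def _build(cls, sub: dict):
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(sub) - fields
        if unknown:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
        return cls(**sub)

    kwargs: dict = {}
    if "world" in d:
        w = dict(d.pop("world"))
        if "params" in w:
            p = dict(w["params"])
            if "age_effects" in p:
                p["age_effects"] = np.asarray(p["age_effects"], dtype=float)
            if "education_effects" in p:
                p["education_effects"] = tuple(p["education_effects"])
            w["params"] = _build(TrueParams, p)
        if "years" in w:
            w["years"] = tuple(w["years"])
        kwargs["world"] = _build(WorldConfig, w)
    for key, cls in (("covariates", CovariateConfig), ("model", ModelSpec),
                     ("trend", TrendSpec), ("validation", ValidationSpec)):
        if key in d:
            kwargs[key] = _build(cls, dict(d.pop(key)))
    if "change_periods" in d:
        d["change_periods"] = tuple(tuple(p) for p in d["change_periods"])
    if "stages" in d:
        d["stages"] = tuple(d["stages"])
    kwargs.update(d)
    return _build(PipelineConfig, {**kwargs})
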
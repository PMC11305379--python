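"""Hierarchical Bayesian model for stratum-level mean intakes.

The model estimates mean intake (servings/week) for each of the 264
demographic strata per country-year from sparse, biased, heteroscedastic
survey observations.  Likelihood, on the log scale with offset ``epsilon``::

    log(y_i + eps) ~ Normal(eta_i, s_i^2 + sigma^2 + tau^2 * od_i)

    eta_i = x_i' beta  +  b_i' gamma  +  v_{r(i)}  +  u_{c(i)}  +  w_{cy(i)}

where ``x_i`` holds the demographic and country-year prediction covariates
(age, sex, education, residence, food availability), ``b_i`` the
survey-bias covariates (assessment method, metric type, representativeness)
that are set to their reference levels at prediction time, ``v``/``u`` are
region and nested country random intercepts, ``w`` an optional country-year
random effect, ``s_i`` the delta-method sampling SE of the log observation,
and ``od_i`` flags surveys that are non-representative or coarsely
stratified (overdispersion).  Coarse observations covering several
elementary strata enter through population-weighted averages of the
elementary design rows.

Inference is by a blocked Gibbs sampler: all linear coefficients (fixed,
bias, and random effects) are drawn jointly from their exact Gaussian
conditional given the variance parameters; the five variance parameters are
updated by adaptive random-walk Metropolis steps on the log scale with
half-normal priors.  Age coefficients carry a first-difference (random-walk)
smoothing prior.  Convergence is reported as split-R-hat over chains.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .config import (
    AGE_BINS, EDUCATION_LEVELS, REFERENCE_METHOD,
    RESIDENCE_LEVELS, SEXES, STRATUM_COLS, DrawArray, ModelSpec, stratum_grid,
)

log = logging.getLogger(__name__)

__all__ = ["build_design", "fit_intake_model", "predict_strata",
           "predict_observations", "Design", "IntakePosterior"]

_REFERENCE_METRIC = "mean_daily_grams"


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _demo_dummies(grid: pd.DataFrame) -> np.ndarray:
    """Demographic design block (no intercept/availability): 25 columns."""
    n = len(grid)
    cols = []
    for a in AGE_BINS[1:]:
        cols.append((grid["age_bin"] == a).to_numpy(float))
    cols.append((grid["sex"] == "male").to_numpy(float))
    for e in EDUCATION_LEVELS[1:]:
        cols.append((grid["education"] == e).to_numpy(float))
    cols.append((grid["residence"] == "urban").to_numpy(float))
    return np.column_stack(cols) if n else np.empty((0, len(AGE_BINS) + 3))


_DEMO_NAMES = ([f"age[{a}]" for a in AGE_BINS[1:]] + ["sex[male]"]
               + [f"edu[{e}]" for e in EDUCATION_LEVELS[1:]] + ["res[urban]"])


@dataclass
class _Builder:
    """Turns observations or prediction grids into design rows."""
    countries: list[str]
    regions: list[str]
    country_region: dict[str, str]
    avail_lookup: dict[tuple[str, int], float]
    avail_mean: float
    avail_sd: float
    bias_methods: list[str] = field(default_factory=list)
    bias_metrics: list[str] = field(default_factory=list)
    cy_keys: list[tuple[str, int]] = field(default_factory=list)

    _grid: pd.DataFrame | None = None
    _grid_demo: np.ndarray | None = None
    _masks: dict | None = None
    _pop_vectors: dict = field(default_factory=dict)

    def grid_demo(self) -> tuple[pd.DataFrame, np.ndarray]:
        if self._grid is None:
            self._grid = stratum_grid()
            self._grid_demo = _demo_dummies(self._grid)
            self._masks = {
                col: {val: (self._grid[col] == val).to_numpy()
                      for val in self._grid[col].unique()}
                for col in STRATUM_COLS
            }
        return self._grid, self._grid_demo

    def set_populations(self, populations: pd.DataFrame | None) -> None:
        """Cache per-country-year population vectors in canonical grid order."""
        self._pop_vectors = {}
        if populations is None:
            return
        grid, _ = self.grid_demo()
        key = pd.MultiIndex.from_frame(grid[STRATUM_COLS])
        for (country, year), sub in populations.groupby(["country", "year"]):
            v = sub.set_index(STRATUM_COLS)["population"].reindex(key)
            self._pop_vectors[(country, int(year))] = np.maximum(
                v.to_numpy(dtype=float), 0.0)

    @property
    def fixed_names(self) -> list[str]:
        return ["intercept", *_DEMO_NAMES, "avail"]

    @property
    def bias_names(self) -> list[str]:
        return ([f"method[{m}]" for m in self.bias_methods]
                + [f"metric[{m}]" for m in self.bias_metrics] + ["nonrep"])

    def avail_z(self, country: str, year: int) -> float:
        key = (country, int(year))
        if key not in self.avail_lookup:
            raise KeyError(f"no availability covariate for country-year {key}")
        return (self.avail_lookup[key] - self.avail_mean) / self.avail_sd

    def demo_row(self, age_bin: str, sex: str, education: str, residence: str,
                 country: str, year: int) -> np.ndarray:
        """One observation's demographic row; coarse cells ('all' labels) are
        population-weighted averages of their elementary rows."""
        grid, demo = self.grid_demo()
        mask = np.ones(len(grid), dtype=bool)
        for col, val in zip(STRATUM_COLS, (age_bin, sex, education, residence)):
            if val != "all":
                try:
                    mask &= self._masks[col][val]
                except KeyError:
                    raise ValueError(
                        f"unknown stratum cell ({age_bin}, {sex}, {education}, "
                        f"{residence})") from None
        n_cells = int(mask.sum())
        if n_cells == 1:
            return demo[mask][0]
        pv = self._pop_vectors.get((country, int(year)))
        if pv is not None:
            w = pv[mask]
            if np.isnan(w).any():
                raise ValueError(
                    f"population weights missing for cells of ({country}, {year})")
            w = w if w.sum() > 0 else np.ones(n_cells)
        else:
            w = np.ones(n_cells)
        return np.average(demo[mask], axis=0, weights=w)


@dataclass
class Design:
    """Assembled regression design: sparse matrix plus response and metadata."""
    X: sp.csr_matrix
    ylog: np.ndarray
    s_log: np.ndarray              # delta-method sampling SE on the log scale
    od_flag: np.ndarray            # overdispersion indicator per row
    row_meta: pd.DataFrame
    builder: _Builder
    spec: ModelSpec
    blocks: dict                   # name -> slice into the coefficient vector

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    @property
    def col_names(self) -> list[str]:
        b = self.builder
        return (b.fixed_names + b.bias_names
                + [f"region[{r}]" for r in b.regions]
                + [f"country[{c}]" for c in b.countries]
                + [f"cy[{c}:{y}]" for c, y in b.cy_keys])


def _validate_observations(obs: pd.DataFrame, covariates: pd.DataFrame) -> None:
    known_countries = set(covariates["country"])
    bad_rows = []
    valid = {
        "age_bin": set(AGE_BINS) | {"all"},
        "sex": set(SEXES) | {"all"},
        "education": set(EDUCATION_LEVELS) | {"all"},
        "residence": set(RESIDENCE_LEVELS) | {"all"},
    }
    for i, row in obs.iterrows():
        if row["country"] not in known_countries:
            bad_rows.append((i, f"unknown country {row['country']!r}"))
        for col, ok in valid.items():
            if row[col] not in ok:
                bad_rows.append((i, f"unknown {col} {row[col]!r}"))
    if bad_rows:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise ValueError(f"invalid observations ({len(bad_rows)} problems): {listing}")


def build_design(observations: pd.DataFrame, covariates: pd.DataFrame,
                 spec: ModelSpec | None = None,
                 populations: pd.DataFrame | None = None) -> Design:
    """Assemble the regression design from harmonized observations.

    ``observations`` columns: survey_id, country, year, the four stratum
    columns (with ``"all"`` marking collapsed dimensions), method,
    representative, metric_type, servings_wk, se_servings_wk.
    ``covariates`` supplies region membership and the availability series
    (standardized internally); ``populations`` supplies the weights used to
    average elementary design rows under coarse observations.
    """
    spec = spec or ModelSpec()
    spec.validate()
    if len(observations) == 0:
        raise ValueError("no observations to fit")
    _validate_observations(observations, covariates)

    countries_in_data = sorted(observations["country"].unique())
    region_map = dict(zip(covariates["country"], covariates["region"]))
    regions = sorted({region_map[c] for c in countries_in_data})
    avail_lookup = {(c, int(y)): float(a) for c, y, a in
                    zip(covariates["country"], covariates["year"], covariates["availability"])}
    av = covariates["availability"].to_numpy(dtype=float)
    builder = _Builder(
        countries=countries_in_data, regions=regions,
        country_region={c: region_map[c] for c in region_map},
        avail_lookup=avail_lookup,
        avail_mean=float(av.mean()), avail_sd=float(av.std(ddof=0) or 1.0),
    )
    builder.set_populations(populations)
    builder.bias_methods = sorted(set(observations["method"]) - {REFERENCE_METHOD})
    builder.bias_metrics = sorted(set(observations.get(
        "metric_type", pd.Series(dtype=str))) - {_REFERENCE_METRIC})
    cy = observations[["country", "year"]].drop_duplicates()
    builder.cy_keys = sorted((c, int(y)) for c, y in cy.itertuples(index=False))

    X_rows, region_idx, country_idx, cy_idx = [], [], [], []
    coarse = np.zeros(len(observations), dtype=bool)
    obs = observations.reset_index(drop=True)
    cy_pos = {k: j for j, k in enumerate(builder.cy_keys)}
    c_pos = {c: j for j, c in enumerate(builder.countries)}
    r_pos = {r: j for j, r in enumerate(builder.regions)}
    for i, row in obs.iterrows():
        demo = builder.demo_row(row["age_bin"], row["sex"], row["education"],
                                row["residence"], row["country"], int(row["year"]))
        bias = [1.0 if row["method"] == m else 0.0 for m in builder.bias_methods]
        bias += [1.0 if row.get("metric_type", _REFERENCE_METRIC) == m else 0.0
                 for m in builder.bias_metrics]
        bias.append(0.0 if bool(row["representative"]) else 1.0)
        x = np.concatenate((
            [1.0], demo, [builder.avail_z(row["country"], int(row["year"]))], bias))
        X_rows.append(x)
        region_idx.append(r_pos[builder.country_region[row["country"]]])
        country_idx.append(c_pos[row["country"]])
        cy_idx.append(cy_pos[(row["country"], int(row["year"]))])
        coarse[i] = any(row[c] == "all" for c in STRATUM_COLS)

    n = len(obs)
    Xf = np.asarray(X_rows)
    n_fixed_bias = Xf.shape[1]
    parts = [sp.csr_matrix(Xf)]
    ones = np.ones(n)
    parts.append(sp.csr_matrix((ones, (np.arange(n), region_idx)),
                               shape=(n, len(builder.regions))))
    parts.append(sp.csr_matrix((ones, (np.arange(n), country_idx)),
                               shape=(n, len(builder.countries))))
    n_cy = len(builder.cy_keys) if spec.include_country_year else 0
    if spec.include_country_year:
        parts.append(sp.csr_matrix((ones, (np.arange(n), cy_idx)), shape=(n, n_cy)))
    X = sp.hstack(parts, format="csr")

    eps = spec.epsilon
    y = obs["servings_wk"].to_numpy(dtype=float)
    se = obs["se_servings_wk"].to_numpy(dtype=float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("se_servings_wk must be finite and > 0")
    ylog = np.log(y + eps)
    s_log = np.maximum(se / (y + eps), 1e-8)
    od_flag = (~obs["representative"].astype(bool).to_numpy()) | coarse

    nf = len(builder.fixed_names)
    blocks = {
        "fixed": slice(0, nf),
        "bias": slice(nf, n_fixed_bias),
        "region": slice(n_fixed_bias, n_fixed_bias + len(builder.regions)),
        "country": slice(n_fixed_bias + len(builder.regions),
                         n_fixed_bias + len(builder.regions) + len(builder.countries)),
        "cy": slice(n_fixed_bias + len(builder.regions) + len(builder.countries),
                    n_fixed_bias + len(builder.regions) + len(builder.countries) + n_cy),
        "age": slice(1, 1 + len(AGE_BINS) - 1),
        "avail": slice(nf - 1, nf),
    }
    meta = obs[["survey_id", "country", "year", *STRATUM_COLS]].copy()
    meta["representative"] = obs["representative"].astype(bool)
    meta["coarse"] = coarse
    meta["od_flag"] = od_flag
    return Design(X=X, ylog=ylog, s_log=s_log, od_flag=od_flag, row_meta=meta,
                  builder=builder, spec=spec, blocks=blocks)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _prior_precision(design: Design, sd_region: float, sd_country: float,
                     sd_cy: float) -> np.ndarray:
    spec, blocks = design.spec, design.blocks
    p = design.n_params
    P = np.zeros((p, p))
    ridge = 1.0 / spec.prior_scale_fixed ** 2
    np.fill_diagonal(P, ridge)
    # random-walk smoothing prior on the age coefficients (first bin fixed at 0)
    a = blocks["age"]
    k = a.stop - a.start
    D = np.eye(k) - np.eye(k, k=-1)
    P[a, a] += (D.T @ D) / spec.age_smooth_sd ** 2
    b = blocks["bias"]
    P[b, b] = np.eye(b.stop - b.start) / spec.prior_scale_bias ** 2
    for name, sd in (("region", sd_region), ("country", sd_country), ("cy", sd_cy)):
        s = blocks[name]
        if s.stop > s.start:
            P[s, s] = np.eye(s.stop - s.start) / max(sd, 1e-6) ** 2
    return P


def _total_var(design: Design, sigma: float, taus: np.ndarray) -> np.ndarray:
    v = design.s_log ** 2 + sigma ** 2
    if design.spec.overdispersion_mode == "single":
        v = v + taus[0] ** 2 * design.od_flag
    else:
        nonrep = ~design.row_meta["representative"].to_numpy(bool) \
            if "representative" in design.row_meta else design.od_flag
        coarse = design.row_meta["coarse"].to_numpy(bool)
        v = v + taus[0] ** 2 * nonrep + taus[1] ** 2 * coarse
    return v


def _halfnormal_logpdf(x: float, scale: float) -> float:
    return -0.5 * (x / scale) ** 2


@dataclass
class IntakePosterior:
    """Posterior samples and everything needed to predict from them."""
    design: Design
    theta: np.ndarray              # (chains, kept, p)
    sigma: np.ndarray              # (chains, kept)
    taus: np.ndarray               # (chains, kept, n_tau)
    sd_region: np.ndarray
    sd_country: np.ndarray
    sd_cy: np.ndarray
    diagnostics: dict

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    @property
    def n_total(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((self.n_total,) + arr.shape[2:])

    def draw_indices(self, n_draws: int | None) -> np.ndarray:
        """Deterministic selection of parameter draws, shared by all
        prediction calls so that draw d means the same parameters everywhere."""
        total = self.n_total
        if n_draws is None or n_draws == total:
            return np.arange(total)
        if n_draws <= total:
            return (np.arange(n_draws) * total) // n_draws
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.spec.seed, spawn_key=(17,)))
        return rng.integers(0, total, size=n_draws)

    def coef_mean(self, name: str) -> float:
        """Posterior mean of a named coefficient (e.g. ``'res[urban]'``)."""
        names = self.design.col_names
        j = names.index(name)
        return float(self.flat(self.theta)[:, j].mean())


class _MarginalState:
    """Marginal likelihood (coefficients integrated out) at one variance state.

    With ``y ~ N(X theta, V)`` and ``theta ~ N(0, P^{-1})``, the marginal is
    ``y ~ N(0, V + X P^{-1} X')`` whose log-density is computed through the
    normal equations already needed for the coefficient draw::

        A = P + X' V^{-1} X,    b = X' V^{-1} y
        log|V + X P^{-1} X'| = log|V| + log|A| - log|P|
        y' (V + X P^{-1} X')^{-1} y = y' V^{-1} y - b' A^{-1} b
    """

    def __init__(self, design: Design, sigma: float, taus: np.ndarray,
                 sd_r: float, sd_c: float, sd_w: float,
                 noise_cache: tuple | None = None):
        X, ylog = design.X, design.ylog
        # the noise-dependent pieces are reusable across proposals that only
        # move a random-effect SD (they change the prior precision only)
        key = (sigma, tuple(taus))
        if noise_cache is not None and noise_cache[0] == key:
            XtWX, b, yWy, logdet_V = noise_cache[1]
        else:
            var = _total_var(design, sigma, taus)
            w = 1.0 / var
            XtWX = (X.T @ X.multiply(w[:, None])).toarray()
            b = X.T @ (w * ylog)
            yWy = float(np.sum(w * ylog ** 2))
            logdet_V = float(np.sum(np.log(var)))
        self.noise_cache = (key, (XtWX, b, yWy, logdet_V))
        P = _prior_precision(design, sd_r, sd_c, sd_w)
        A = XtWX + P
        self.chol = sla.cho_factor(A, lower=True)
        self.mean = sla.cho_solve(self.chol, b)
        quad = yWy - float(b @ self.mean)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(self.chol[0]))))
        # variable part of log|P|: the random-effect blocks are diagonal and
        # the fixed/bias block does not depend on the variance parameters
        blocks = design.blocks
        logdet_P = 0.0
        for name, sd in (("region", sd_r), ("country", sd_c), ("cy", sd_w)):
            s = blocks[name]
            logdet_P += -2.0 * (s.stop - s.start) * np.log(max(sd, 1e-6))
        self.loglik = -0.5 * (logdet_V + logdet_A - logdet_P + quad)

    def draw_theta(self, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(len(self.mean))
        return self.mean + sla.solve_triangular(self.chol[0], z, lower=True,
                                                trans="T")


def _run_chain(design: Design, spec: ModelSpec, rng: np.random.Generator):
    """Collapsed sampler: random-walk Metropolis on the log variance
    parameters under the marginal likelihood (all linear coefficients
    integrated out), then an exact Gaussian draw of the coefficients.
    Marginalization avoids the funnel pathology that traps centered
    Gibbs updates of hierarchical SDs near zero."""
    n_tau = 1 if spec.overdispersion_mode == "single" else 2
    any_od = bool(design.od_flag.any())
    blocks = design.blocks
    has_cy = blocks["cy"].stop > blocks["cy"].start
    ps = spec.prior_scale_sd

    # phi layout: [log sigma, log taus..., log sd_r, log sd_c, log sd_w];
    # unidentified coordinates are masked out of the random walk
    inits = np.log([0.2] + [0.2] * n_tau + [0.3, 0.3, 0.2])
    phi = inits + 0.3 * rng.standard_normal(len(inits))
    active = np.ones(len(phi), dtype=bool)
    if not any_od:
        phi[1:1 + n_tau] = -np.inf      # tau fixed at zero: unidentified
        active[1:1 + n_tau] = False
    if not has_cy:
        phi[-1] = np.log(0.2)
        active[-1] = False

    def unpack(p):
        sigma = float(np.exp(p[0]))
        taus = np.exp(p[1:1 + n_tau])
        taus = np.where(np.isfinite(taus), taus, 0.0)
        return sigma, taus, float(np.exp(p[-3])), float(np.exp(p[-2])), \
            float(np.exp(p[-1]))

    def log_prior(p):
        vals = np.exp(p[active])
        # half-normal priors plus the log-scale Jacobian
        return float(np.sum([-0.5 * (v / ps) ** 2 + np.log(v) for v in vals]))

    state = _MarginalState(design, *unpack(phi))
    lp = state.loglik + log_prior(phi)
    coords = np.flatnonzero(active)
    steps = np.full(len(phi), 0.4)

    kept_theta = np.empty((spec.draws, design.n_params))
    kept_scal = np.empty((spec.draws, 3 + n_tau + 1))
    for it in range(spec.warmup + spec.draws):
        # one sweep: update each variance coordinate by 1-D marginal Metropolis
        for j in coords:
            prop = phi.copy()
            prop[j] = phi[j] + steps[j] * rng.standard_normal()
            try:
                prop_state = _MarginalState(design, *unpack(prop),
                                            noise_cache=state.noise_cache)
                lp_prop = prop_state.loglik + log_prior(prop)
            except np.linalg.LinAlgError:
                lp_prop = -np.inf
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                phi, state, lp = prop, prop_state, lp_prop
            if it < spec.warmup:
                # multiplicative adaptation toward ~0.44 acceptance
                steps[j] = float(np.clip(steps[j] * (1.05 if accept else 0.96),
                                         1e-3, 3.0))
        if it >= spec.warmup:
            k = it - spec.warmup
            sigma, taus, sd_r, sd_c, sd_w = unpack(phi)
            kept_theta[k] = state.draw_theta(rng)
            kept_scal[k] = [sigma, *taus, sd_r, sd_c, sd_w if has_cy else 0.0]
    return kept_theta, kept_scal


def fit_intake_model(observations: pd.DataFrame, covariates: pd.DataFrame,
                     spec: ModelSpec | None = None,
                     populations: pd.DataFrame | None = None) -> IntakePosterior:
    """Fit the hierarchical intake model by blocked Gibbs sampling.

    Runs ``spec.chains`` independent chains (seeded from ``spec.seed``),
    discards ``spec.warmup`` adaptation iterations each, keeps
    ``spec.draws`` per chain, and reports split-R-hat diagnostics for the
    variance parameters and key fixed effects.  Non-convergence
    (R-hat above ``spec.rhat_threshold``) logs a warning, never fails
    silently.
    """
    spec = spec or ModelSpec()
    design = build_design(observations, covariates, spec, populations)
    n_tau = 1 if spec.overdispersion_mode == "single" else 2
    thetas, scals = [], []
    for chain in range(spec.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(chain,)))
        kt, ks = _run_chain(design, spec, rng)
        thetas.append(kt)
        scals.append(ks)
    theta = np.stack(thetas)                      # (chains, kept, p)
    scal = np.stack(scals)
    sigma = scal[:, :, 0]
    taus = scal[:, :, 1:1 + n_tau]
    sd_region = scal[:, :, 1 + n_tau]
    sd_country = scal[:, :, 2 + n_tau]
    sd_cy = scal[:, :, 3 + n_tau]

    diag = _diagnostics(design, theta, sigma, taus, sd_region, sd_country, sd_cy, spec)
    if not diag["converged"]:
        log.warning("intake model convergence warning: max split-R-hat = %.3f "
                    "(threshold %.2f); worst parameters: %s",
                    diag["max_rhat"], spec.rhat_threshold, diag["worst_params"])
    return IntakePosterior(design=design, theta=theta, sigma=sigma, taus=taus,
                           sd_region=sd_region, sd_country=sd_country,
                           sd_cy=sd_cy, diagnostics=diag)


def _diagnostics(design, theta, sigma, taus, sd_region, sd_country, sd_cy, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az
    names = design.col_names
    track = {"sigma": sigma, "sd_region": sd_region, "sd_country": sd_country}
    if design.blocks["cy"].stop > design.blocks["cy"].start:
        track["sd_cy"] = sd_cy
    if design.od_flag.any():
        for j in range(taus.shape[2]):
            track[f"tau{j}"] = taus[:, :, j]
    for key in ("intercept", "res[urban]", "sex[male]", "avail"):
        if key in names:
            track[key] = theta[:, :, names.index(key)]
    rhats = {}
    if theta.shape[0] >= 2 and theta.shape[1] >= 4:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = az.from_dict(posterior={k: v for k, v in track.items()})
            r = az.rhat(ds)
            rhats = {k: float(r[k].values) for k in track}
    max_rhat = max(rhats.values()) if rhats else float("nan")
    worst = sorted(rhats, key=rhats.get, reverse=True)[:3] if rhats else []
    return {
        "rhat": rhats,
        "max_rhat": max_rhat,
        "worst_params": worst,
        "converged": (not rhats) or max_rhat <= spec.rhat_threshold,
        "n_observations": int(len(design.ylog)),
        "n_parameters": int(design.n_params),
        "chains": int(theta.shape[0]),
        "draws_per_chain": int(theta.shape[1]),
    }


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _fresh_effect(posterior: IntakePosterior, sd_draws: np.ndarray,
                  kind: int, *key_parts: int) -> np.ndarray:
    """Deterministic fresh random-effect draws for entities absent from the
    fit (new country, or a country-year without surveys)."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=posterior.spec.seed, spawn_key=(100 + kind, *key_parts)))
    return sd_draws * rng.standard_normal(len(sd_draws))


def predict_strata(posterior: IntakePosterior, country: str, year: int,
                   n_draws: int | None = None) -> DrawArray:
    """Posterior draws of the 264 stratum means for one country-year.

    Survey-bias covariates are held at their reference levels (24-hour
    recall, reference metric, nationally representative).  For a country
    with no training surveys the country effect is drawn from its
    population distribution per draw (flag ``no-country-data``); likewise
    the country-year effect for unsurveyed years.  Back-transformation is
    ``max(exp(eta) - epsilon, 0)``, so all values are nonnegative.
    """
    b = posterior.design.builder
    blocks = posterior.design.blocks
    idx = posterior.draw_indices(n_draws)
    theta = posterior.flat(posterior.theta)[idx]          # (D, p)
    grid, demo = b.grid_demo()
    az_val = b.avail_z(country, int(year))
    Xf = np.hstack([np.ones((len(grid), 1)), demo,
                    np.full((len(grid), 1), az_val)])     # (264, n_fixed)
    eta = Xf @ theta[:, blocks["fixed"]].T                # (264, D)

    flags: dict = {}
    region = b.country_region.get(country)
    if region is None:
        raise KeyError(f"country {country!r} absent from the covariate table")
    if region in b.regions:
        eta += theta[:, blocks["region"].start + b.regions.index(region)][None, :]
    else:
        sd_r = posterior.flat(posterior.sd_region)[idx]
        eta += _fresh_effect(posterior, sd_r, 0, _stable_key(region))[None, :]
        flags["no-region-data"] = True
    if country in b.countries:
        eta += theta[:, blocks["country"].start + b.countries.index(country)][None, :]
    else:
        sd_c = posterior.flat(posterior.sd_country)[idx]
        eta += _fresh_effect(posterior, sd_c, 1, _stable_key(country))[None, :]
        flags["no-country-data"] = True
    if blocks["cy"].stop > blocks["cy"].start:
        key = (country, int(year))
        if key in b.cy_keys:
            eta += theta[:, blocks["cy"].start + b.cy_keys.index(key)][None, :]
        else:
            sd_w = posterior.flat(posterior.sd_cy)[idx]
            eta += _fresh_effect(posterior, sd_w, 2, _stable_key(country),
                                 int(year))[None, :]
            flags["no-survey-this-year"] = True

    values = np.maximum(np.exp(eta) - posterior.spec.epsilon, 0.0)
    index = stratum_grid(country=country, year=int(year))
    return DrawArray(index=index, values=values, flags=flags)


def _stable_key(s: str) -> int:
    # deterministic non-negative 31-bit key from a label (hash() is salted)
    h = 0
    for ch in str(s):
        h = (h * 131 + ord(ch)) % (2 ** 31 - 1)
    return h


def predict_observations(posterior: IntakePosterior, observations: pd.DataFrame,
                         populations: pd.DataFrame | None = None,
                         n_draws: int | None = None,
                         include_noise_sd: bool = False):
    """Posterior draws of the *observed* log means for arbitrary survey rows.

    Unlike :func:`predict_strata` this includes each row's survey-bias
    covariates, so it predicts what the (biased) survey would report — the
    right target for cross-validation against held-out observations.
    Returns an (n_rows, n_draws) array of log-scale linear predictors, plus,
    when ``include_noise_sd``, the matching total observation SD (sampling
    + residual + overdispersion) per row and draw.
    """
    b = posterior.design.builder
    blocks = posterior.design.blocks
    idx = posterior.draw_indices(n_draws)
    theta = posterior.flat(posterior.theta)[idx]
    obs = observations.reset_index(drop=True)
    n = len(obs)
    eta = np.zeros((n, len(idx)))
    coarse = np.zeros(n, dtype=bool)
    if populations is not None:
        b.set_populations(populations)
    for i, row in obs.iterrows():
        demo = b.demo_row(row["age_bin"], row["sex"], row["education"],
                          row["residence"], row["country"], int(row["year"]))
        bias = [1.0 if row["method"] == m else 0.0 for m in b.bias_methods]
        bias += [1.0 if row.get("metric_type", _REFERENCE_METRIC) == m else 0.0
                 for m in b.bias_metrics]
        bias.append(0.0 if bool(row["representative"]) else 1.0)
        x = np.concatenate(([1.0], demo,
                            [b.avail_z(row["country"], int(row["year"]))], bias))
        e = x @ theta[:, :blocks["bias"].stop].T
        region = b.country_region[row["country"]]
        if region in b.regions:
            e = e + theta[:, blocks["region"].start + b.regions.index(region)]
        else:
            e = e + _fresh_effect(posterior, posterior.flat(posterior.sd_region)[idx],
                                  0, _stable_key(region))
        if row["country"] in b.countries:
            e = e + theta[:, blocks["country"].start + b.countries.index(row["country"])]
        else:
            e = e + _fresh_effect(posterior, posterior.flat(posterior.sd_country)[idx],
                                  1, _stable_key(row["country"]))
        if blocks["cy"].stop > blocks["cy"].start:
            key = (row["country"], int(row["year"]))
            if key in b.cy_keys:
                e = e + theta[:, blocks["cy"].start + b.cy_keys.index(key)]
            else:
                e = e + _fresh_effect(posterior, posterior.flat(posterior.sd_cy)[idx],
                                      2, _stable_key(row["country"]), int(row["year"]))
        eta[i] = e
        coarse[i] = any(row[c] == "all" for c in STRATUM_COLS)
    if not include_noise_sd:
        return eta
    eps = posterior.spec.epsilon
    y = obs["servings_wk"].to_numpy(dtype=float)
    se = obs["se_servings_wk"].to_numpy(dtype=float)
    s_log = np.maximum(se / (y + eps), 1e-8)
    od = (~obs["representative"].astype(bool).to_numpy()) | coarse
    sig = posterior.flat(posterior.sigma)[idx]
    taus = posterior.flat(posterior.taus)[idx]
    if posterior.spec.overdispersion_mode == "single":
        od_var = np.outer(od, taus[:, 0] ** 2)
    else:
        nonrep = ~obs["representative"].astype(bool).to_numpy()
        od_var = np.outer(nonrep, taus[:, 0] ** 2) + np.outer(coarse, taus[:, 1] ** 2)
    total_sd = np.sqrt(s_log[:, None] ** 2 + sig[None, :] ** 2 + od_var)
    return eta, total_sd
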
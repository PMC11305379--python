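"""Varying-slopes trend model and model combination.

The trend model regresses log country-mean intake on the (per-country
centered) food-availability covariate with country-specific intercepts and
slopes drawn from a common bivariate normal — two-dimensional partial
pooling with an estimated intercept-slope correlation.  No calendar-time
term appears; time enters only through the time variation of the
availability series.

Inference is a conjugate Gibbs sampler: country (alpha_c, beta_c) pairs,
the population mean vector, and the 2x2 covariance (inverse-Wishart) all
have closed-form conditionals; the residual SD takes an adaptive
random-walk Metropolis step.  Observation variances combine the
draw-level SE of each country-year's intake-model mean with the residual
variance.

Model combination rescales all 264 stratum draws of a country-year by the
per-draw trend ratio between the target year and that country's nearest
survey-informed (anchor) year, preserving within-country demographic
contrasts and collapsing to the intake model exactly at anchor years.  An
inverse-variance log-scale blend is available as an alternative rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DrawArray, TrendSpec
from .aggregate import group_draws

log = logging.getLogger(__name__)

__all__ = ["build_trajectories", "fit_trend_model", "combine_models",
           "nearest_anchor_years", "TrendPosterior"]


def build_trajectories(draws_by_cy: dict[tuple[str, int], DrawArray],
                       populations: pd.DataFrame,
                       covariates: pd.DataFrame,
                       epsilon: float = 0.01) -> pd.DataFrame:
    """Country-year trajectories of log mean intake with draw-level SEs.

    For each country-year draw array, the population-weighted country mean
    is computed per draw; the trajectory records the mean and SD across
    draws of ``log(mean + epsilon)`` together with the availability
    covariate and a flag marking survey-informed (anchor-eligible) years.
    """
    av = {(c, int(y)): float(a) for c, y, a in
          zip(covariates["country"], covariates["year"], covariates["availability"])}
    rows = []
    for (country, year), da in sorted(draws_by_cy.items()):
        w = populations[(populations["country"] == country)
                        & (populations["year"] == year)]
        _, means, _ = group_draws(da, w, by=None)
        zdraws = np.log(means[0] + epsilon)
        rows.append({
            "country": country, "year": int(year),
            "z": float(zdraws.mean()), "se_z": float(max(zdraws.std(ddof=0), 1e-4)),
            "availability": av[(country, int(year))],
            "survey_informed": not da.flags.get("no-survey-this-year", False),
        })
    traj = pd.DataFrame(rows)
    # center availability within country; a single-year country centers to 0
    # and therefore informs only its intercept
    traj["avail_c"] = traj.groupby("country")["availability"].transform(
        lambda a: a - a.mean())
    return traj


@dataclass
class TrendPosterior:
    """Posterior of the varying-slopes model."""
    countries: list[str]
    alpha: np.ndarray              # (chains, kept, C)
    beta: np.ndarray               # (chains, kept, C)
    mu: np.ndarray                 # (chains, kept, 2)
    Sigma: np.ndarray              # (chains, kept, 2, 2)
    sigma_resid: np.ndarray        # (chains, kept)
    avail_center: dict             # country -> mean availability used to center
    spec: TrendSpec
    diagnostics: dict

    @property
    def n_total(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((self.n_total,) + arr.shape[2:])

    def correlation_draws(self) -> np.ndarray:
        S = self.flat(self.Sigma)
        return S[:, 0, 1] / np.sqrt(S[:, 0, 0] * S[:, 1, 1])

    def draw_indices(self, n_draws: int | None) -> np.ndarray:
        total = self.n_total
        if n_draws is None or n_draws == total:
            return np.arange(total)
        if n_draws <= total:
            return (np.arange(n_draws) * total) // n_draws
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.spec.seed, spawn_key=(23,)))
        return rng.integers(0, total, size=n_draws)


def fit_trend_model(trajectories: pd.DataFrame,
                    spec: TrendSpec | None = None) -> TrendPosterior:
    """Fit the varying-slopes model by conjugate Gibbs sampling.

    Requires at least three countries with at least two years each (a
    single-year country is allowed and contributes to its intercept only).
    Raises on a degenerate (non-positive-definite) covariance state.
    """
    spec = spec or TrendSpec()
    spec.validate()
    traj = trajectories
    counts = traj.groupby("country")["year"].nunique()
    if (counts >= 2).sum() < 3:
        raise ValueError("need >= 3 countries with >= 2 years each")
    countries = sorted(traj["country"].unique())
    C = len(countries)
    ydat, Xdat, vdat = [], [], []
    for c in countries:
        sub = traj[traj["country"] == c].sort_values("year")
        ydat.append(sub["z"].to_numpy(dtype=float))
        Xdat.append(np.column_stack([np.ones(len(sub)),
                                     sub["avail_c"].to_numpy(dtype=float)]))
        vdat.append(sub["se_z"].to_numpy(dtype=float) ** 2)
    avail_center = traj.groupby("country")["availability"].mean().to_dict()

    m0 = np.asarray(spec.mu_prior_mean, dtype=float)
    S0inv = np.diag(1.0 / np.asarray(spec.mu_prior_sd, dtype=float) ** 2)
    Psi0 = spec.iw_scale * np.eye(2)
    nu0 = spec.iw_df

    out_a = np.empty((spec.chains, spec.draws, C))
    out_b = np.empty((spec.chains, spec.draws, C))
    out_mu = np.empty((spec.chains, spec.draws, 2))
    out_S = np.empty((spec.chains, spec.draws, 2, 2))
    out_sr = np.empty((spec.chains, spec.draws))

    for chain in range(spec.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(chain,)))
        mu = m0 + rng.normal(0, 0.1, size=2)
        Sigma = 0.2 * np.eye(2)
        sig_r = 0.1 * np.exp(0.3 * rng.normal())
        mh_step = 0.3
        params = np.zeros((C, 2))
        for it in range(spec.warmup + spec.draws):
            adapt = it < spec.warmup
            try:
                Sinv = np.linalg.inv(Sigma)
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"degenerate covariance state: {Sigma!r}") from exc
            # country-level (alpha, beta): exact Gaussian conditional
            for ci in range(C):
                V = vdat[ci] + sig_r ** 2
                Xc, yc = Xdat[ci], ydat[ci]
                prec = Xc.T @ (Xc / V[:, None]) + Sinv
                mean = np.linalg.solve(prec, Xc.T @ (yc / V) + Sinv @ mu)
                L = np.linalg.cholesky(np.linalg.inv(prec))
                params[ci] = mean + L @ rng.standard_normal(2)
            # population mean
            prec_mu = C * Sinv + S0inv
            mean_mu = np.linalg.solve(prec_mu, Sinv @ params.sum(axis=0) + S0inv @ m0)
            Lmu = np.linalg.cholesky(np.linalg.inv(prec_mu))
            mu = mean_mu + Lmu @ rng.standard_normal(2)
            # covariance: conjugate inverse-Wishart
            D = params - mu
            Psi = Psi0 + D.T @ D
            Sigma = stats.invwishart.rvs(df=nu0 + C, scale=Psi, random_state=rng)
            if np.linalg.det(Sigma) <= 0:
                raise ValueError(f"degenerate covariance draw: {Sigma!r}")
            # residual SD: adaptive MH on the log scale
            resid_sq, vlist = [], []
            for ci in range(C):
                r = ydat[ci] - Xdat[ci] @ params[ci]
                resid_sq.append(r ** 2)
                vlist.append(vdat[ci])
            r2 = np.concatenate(resid_sq)
            v0 = np.concatenate(vlist)

            cur = np.log(sig_r)
            prop = cur + mh_step * rng.normal()

            def lp(ls):
                s2 = np.exp(2 * ls)
                v = v0 + s2
                return (-0.5 * np.sum(np.log(v) + r2 / v)
                        - 0.5 * (np.exp(ls) / spec.sigma_resid_prior_scale) ** 2 + ls)
            accept = np.log(rng.random()) < lp(prop) - lp(cur)
            if accept:
                sig_r = float(np.exp(prop))
            if adapt:
                mh_step = float(np.clip(mh_step * (1.05 if accept else 0.97),
                                        1e-3, 2.0))
            if not adapt:
                k = it - spec.warmup
                out_a[chain, k] = params[:, 0]
                out_b[chain, k] = params[:, 1]
                out_mu[chain, k] = mu
                out_S[chain, k] = Sigma
                out_sr[chain, k] = sig_r

    corr = out_S[:, :, 0, 1] / np.sqrt(out_S[:, :, 0, 0] * out_S[:, :, 1, 1])
    diag = {
        "mean_correlation": float(corr.mean()),
        "mean_slope": float(out_mu[:, :, 1].mean()),
        "mean_sigma_resid": float(out_sr.mean()),
        "n_countries": C,
    }
    return TrendPosterior(countries=countries, alpha=out_a, beta=out_b,
                          mu=out_mu, Sigma=out_S, sigma_resid=out_sr,
                          avail_center=avail_center, spec=spec, diagnostics=diag)


def nearest_anchor_years(trajectories: pd.DataFrame) -> dict[str, dict[int, int]]:
    """For each country, map every year to its nearest survey-informed year.

    Ties in distance resolve to the later year.  Countries with no
    survey-informed year are absent from the result (their draws pass
    through uncombined).
    """
    anchors: dict[str, dict[int, int]] = {}
    for country, sub in trajectories.groupby("country"):
        informed = sorted(sub.loc[sub["survey_informed"], "year"])
        if not informed:
            continue
        anchors[country] = {
            int(y): int(min(informed, key=lambda a: (abs(a - y), -a)))
            for y in sub["year"]
        }
    return anchors


def combine_models(draws_by_cy: dict[tuple[str, int], DrawArray],
                   trend: TrendPosterior,
                   trajectories: pd.DataFrame,
                   spec: TrendSpec | None = None,
                   ) -> dict[tuple[str, int], DrawArray]:
    """Combine intake-model stratum draws with the trend model.

    Under the default anchor-ratio rule, draw d of every stratum in country
    c, year y is multiplied by::

        exp( beta_{c,d} * (avail_{c,y} - avail_{c,anchor(c,y)}) )

    the trend model's ratio between target and anchor year (intercepts
    cancel).  Stratum-to-stratum ratios within a country-year are exactly
    preserved and anchor years are returned unchanged.  Countries without a
    trend fit or anchor pass through with flag ``uncombined``.  The
    ``log_blend`` rule instead shifts each year's log country level to an
    inverse-variance-weighted blend of the intake-model level and the trend
    line.
    """
    spec = spec or trend.spec
    anchors = nearest_anchor_years(trajectories)
    av = {(c, int(y)): float(a) for c, y, a in
          zip(trajectories["country"], trajectories["year"],
              trajectories["availability"])}
    zmap = {(c, int(y)): (float(z), float(s)) for c, y, z, s in
            zip(trajectories["country"], trajectories["year"],
                trajectories["z"], trajectories["se_z"])}
    some = next(iter(draws_by_cy.values()))
    idx = trend.draw_indices(some.n_draws)
    beta_flat = trend.flat(trend.beta)[idx]      # (D, C)
    alpha_flat = trend.flat(trend.alpha)[idx]
    combined: dict[tuple[str, int], DrawArray] = {}
    for (country, year), da in draws_by_cy.items():
        out = da.copy()
        if country not in trend.countries or country not in anchors:
            out.flags["uncombined"] = True
            combined[(country, year)] = out
            continue
        ci = trend.countries.index(country)
        beta_d = beta_flat[:, ci]
        if spec.combination_rule == "anchor_ratio":
            anchor = anchors[country][int(year)]
            delta_a = av[(country, int(year))] - av[(country, anchor)]
            factor = np.exp(beta_d * delta_a)
            out.flags["anchor_year"] = anchor
        else:  # log_blend
            a_c = av[(country, int(year))] - trend.avail_center[country]
            trend_line = alpha_flat[:, ci] + beta_d * a_c
            z, se_z = zmap[(country, int(year))]
            var_t = max(trend_line.var(), 1e-8)
            w_i = 1.0 / max(se_z ** 2, 1e-8)
            w_t = 1.0 / var_t
            blend = (w_i * z + w_t * trend_line) / (w_i + w_t)
            factor = np.exp(blend - z)
        out.values = out.values * factor[None, :]
        combined[(country, year)] = out
    return combined
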
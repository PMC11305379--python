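"""Model validation: repeated five-fold cross-validation and plausibility checks.

Cross-validation randomly omits 20% of the survey data at the stratum-row
level, refits the intake model on the remainder, and predicts the held-out
rows *including* their survey-bias covariates — the held-out observation,
biases and all, is the only observable target.  Metrics (log-scale R²,
mean bias, RMSE, and empirical coverage of the 95% predictive interval)
are reported per fold and pooled, and the whole procedure repeats with
fresh partitions.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ModelSpec
from .intake_model import fit_intake_model, predict_observations

log = logging.getLogger(__name__)

__all__ = ["cross_validate", "flag_implausible", "assign_folds"]


def assign_folds(n_rows: int, n_folds: int, rng: np.random.Generator,
                 max_redraws: int = 20) -> np.ndarray:
    """Random fold labels 0..n_folds-1; re-draws if any fold is empty."""
    for _ in range(max_redraws):
        perm = rng.permutation(n_rows)
        folds = np.empty(n_rows, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            folds[chunk] = f
        if all((folds == f).any() for f in range(n_folds)):
            return folds
        log.info("empty fold drawn; re-drawing partition")
    raise ValueError(f"cannot form {n_folds} nonempty folds from {n_rows} rows")


def _fold_metrics(obs: pd.DataFrame, eta: np.ndarray, total_sd: np.ndarray,
                  epsilon: float, rng: np.random.Generator) -> dict:
    ylog = np.log(obs["servings_wk"].to_numpy(dtype=float) + epsilon)
    pred = eta.mean(axis=1)
    resid = pred - ylog
    sst = float(np.sum((ylog - ylog.mean()) ** 2))
    ssr = float(np.sum(resid ** 2))
    draws = eta + total_sd * rng.standard_normal(eta.shape)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=1)
    covered = (ylog >= lo) & (ylog <= hi)
    return {
        "n": len(obs),
        "r2": 1.0 - ssr / sst if sst > 0 else float("nan"),
        "bias": float(resid.mean()),
        "rmse": float(np.sqrt(ssr / len(obs))),
        "coverage": float(covered.mean()),
        "_ylog": ylog, "_pred": pred, "_covered": covered,
    }


def cross_validate(observations: pd.DataFrame, covariates: pd.DataFrame,
                   spec: ModelSpec, seed: int,
                   populations: pd.DataFrame | None = None,
                   n_folds: int = 5, n_repeats: int = 5,
                   n_draws: int | None = None) -> pd.DataFrame:
    """Repeated k-fold cross-validation of the intake model.

    Returns one row per (repeat, fold) plus one pooled row per repeat
    (``fold = -1``) with columns ``n``, ``r2``, ``bias``, ``rmse``,
    ``coverage``.  Deterministic given ``seed``; fold assignment never
    leaks a held-out row into its own training set.
    """
    obs = observations.reset_index(drop=True)
    if len(obs) < n_folds:
        raise ValueError("not enough observations for the requested folds")
    master = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,)))
        folds = assign_folds(len(obs), n_folds, rng)
        pooled_ylog, pooled_pred, pooled_cov = [], [], []
        for f in range(n_folds):
            hold = folds == f
            train, test = obs[~hold], obs[hold]
            assert not set(test.index) & set(train.index)
            fold_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + 1000 * rep + f})
            post = fit_intake_model(train, covariates, fold_spec, populations)
            eta, sd = predict_observations(post, test, populations,
                                           n_draws=n_draws, include_noise_sd=True)
            m = _fold_metrics(test, eta, sd, fold_spec.epsilon, master)
            pooled_ylog.append(m.pop("_ylog"))
            pooled_pred.append(m.pop("_pred"))
            pooled_cov.append(m.pop("_covered"))
            rows.append({"repeat": rep, "fold": f, **m})
        ylog = np.concatenate(pooled_ylog)
        pred = np.concatenate(pooled_pred)
        cov = np.concatenate(pooled_cov)
        resid = pred - ylog
        sst = float(np.sum((ylog - ylog.mean()) ** 2))
        rows.append({
            "repeat": rep, "fold": -1, "n": len(ylog),
            "r2": 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else float("nan"),
            "bias": float(resid.mean()),
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
            "coverage": float(cov.mean()),
        })
    return pd.DataFrame(rows)


def flag_implausible(estimates: pd.DataFrame, lo: float = 0.0, hi: float = 35.0,
                     max_ui_ratio: float | None = None) -> pd.DataFrame:
    """Flag estimate rows outside plausibility bounds.

    A row is flagged when its ``median`` lies outside [lo, hi] servings/week
    or, when ``max_ui_ratio`` is set, when ``hi95 / lo95`` exceeds that
    factor (rows with nonpositive ``lo95`` count as exceeding it).  Returns
    the flagged rows with a ``reason`` column; empty when all are plausible.
    """
    df = estimates.reset_index(drop=True)
    reasons = []
    for _, row in df.iterrows():
        r = []
        if not (lo <= row["median"] <= hi):
            r.append("median_out_of_bounds")
        if max_ui_ratio is not None:
            if row["lo95"] <= 0 or row["hi95"] / row["lo95"] > max_ui_ratio:
                r.append("ui_ratio_exceeded")
        reasons.append(";".join(r))
    out = df[[bool(r) for r in reasons]].copy()
    out["reason"] = [r for r in reasons if r]
    return out
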
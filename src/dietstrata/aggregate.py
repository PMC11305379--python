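"""Draw-level population-weighted aggregation and summary statistics.

Every aggregate (subgroup, country, region, global) is computed draw by
draw: for each posterior draw the group mean is the population-weighted
average of its member strata, and the median and 95% uncertainty interval
are then the 50th, 2.5th and 97.5th percentiles across draws (linear
interpolation between closest ranks, numpy's default percentile rule).
Because per-draw aggregation is linear, region-then-global aggregation is
exactly equal to direct global aggregation.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import CHILD_AGE_BINS, DrawArray, EstimateSummary, STRATUM_COLS

__all__ = [
    "summarize_draws", "group_draws", "weighted_aggregate",
    "change_between_years", "threshold_count", "correlate_index",
    "restrict_to_children",
]

_PCTS = (50.0, 2.5, 97.5)


def summarize_draws(draws: np.ndarray, population: float = float("nan")) -> EstimateSummary:
    """Median and 95% UI of a draw vector (percentiles 50 / 2.5 / 97.5)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size < 1:
        raise ValueError("need at least one draw")
    med, lo, hi = np.percentile(draws, _PCTS)
    return EstimateSummary(median=float(med), lo95=float(lo), hi95=float(hi),
                           population=population)


def _merge_weights(index: pd.DataFrame, weights: pd.DataFrame) -> np.ndarray:
    """Align a population-weight table onto a draw index; zero weights allowed."""
    keys = [c for c in ("country", "year", *STRATUM_COLS) if c in index.columns
            and c in weights.columns]
    if not keys:
        raise ValueError("no common key columns between draws and weights")
    merged = index.merge(weights[keys + ["population"]], on=keys, how="left",
                         validate="many_to_one")
    if merged["population"].isna().any():
        missing = merged.loc[merged["population"].isna(), keys].drop_duplicates()
        raise ValueError(
            f"weights do not cover every stratum; first missing rows:\n{missing.head()}"
        )
    return merged["population"].to_numpy(dtype=float)


def group_draws(draws: DrawArray, weights: pd.DataFrame,
                by: list[str] | None = None) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Population-weighted per-draw group means.

    Returns ``(group_index, means, group_population)`` where ``means`` has
    one row per group and one column per draw.  ``by=None`` (or ``[]``)
    aggregates everything into a single group.  Groups whose total weight is
    zero raise an "empty group" error.
    """
    w = _merge_weights(draws.index, weights)
    x = draws.values
    if by:
        codes, groups = pd.factorize(pd.MultiIndex.from_frame(draws.index[by]))
        g_index = pd.DataFrame(list(groups), columns=by)
    else:
        codes = np.zeros(len(draws.index), dtype=int)
        g_index = pd.DataFrame({"group": ["all"]})
    n_groups = len(g_index)
    w_tot = np.bincount(codes, weights=w, minlength=n_groups)
    if np.any(w_tot <= 0):
        empty = g_index[w_tot <= 0]
        raise ValueError(f"empty group (total population weight 0):\n{empty}")
    wx = x * w[:, None]
    sums = np.zeros((n_groups, x.shape[1]))
    np.add.at(sums, codes, wx)
    means = sums / w_tot[:, None]
    return g_index, means, w_tot


def weighted_aggregate(draws: DrawArray, weights: pd.DataFrame,
                       by: list[str] | None = None) -> pd.DataFrame:
    """Summarize population-weighted group means across draws.

    Returns one row per group with ``median``, ``lo95``, ``hi95``, ``mean``
    (mean of draws, emitted alongside the primary median), and ``population``.
    """
    g_index, means, w_tot = group_draws(draws, weights, by)
    med, lo, hi = np.percentile(means, _PCTS, axis=1)
    out = g_index.copy()
    out["median"] = med
    out["lo95"] = lo
    out["hi95"] = hi
    out["mean"] = means.mean(axis=1)
    out["population"] = w_tot
    return out


def change_between_years(draws_y1: DrawArray, draws_y2: DrawArray,
                         weights_std: pd.DataFrame,
                         by: list[str] | None = None,
                         period: tuple[int, int] | None = None) -> pd.DataFrame:
    """Standardized absolute and percent change between two years.

    Both years are aggregated with the *same* standardization weights
    (by convention the 2018 stratum proportions), per draw::

        A_d = mean_w(y2, d) - mean_w(y1, d)
        P_d = 100 * A_d / mean_w(y1, d)

    and summarized by percentiles across draws.  Draws with a zero baseline
    mean are excluded from the percent summary and counted in
    ``excluded_draws``.
    """
    if draws_y1.n_draws != draws_y2.n_draws:
        raise ValueError("draw counts differ between years")
    idx_cols = STRATUM_COLS if "country" not in draws_y1.index.columns else \
        ["country", *STRATUM_COLS]
    a1 = draws_y1.index[idx_cols].reset_index(drop=True)
    a2 = draws_y2.index[idx_cols].reset_index(drop=True)
    if not a1.equals(a2):
        raise ValueError("stratum indexes are not aligned between years")
    g_index, m1, _ = group_draws(draws_y1, weights_std, by)
    _, m2, w_tot = group_draws(draws_y2, weights_std, by)
    abs_d = m2 - m1
    rows = []
    for gi in range(len(g_index)):
        a = summarize_draws(abs_d[gi])
        base = m1[gi]
        ok = base != 0
        pct_draws = 100.0 * abs_d[gi][ok] / base[ok]
        p = summarize_draws(pct_draws) if ok.any() else None
        rows.append({
            "abs_median": a.median, "abs_lo95": a.lo95, "abs_hi95": a.hi95,
            "pct_median": p.median if p else np.nan,
            "pct_lo95": p.lo95 if p else np.nan,
            "pct_hi95": p.hi95 if p else np.nan,
            "excluded_draws": int((~ok).sum()),
            "population": w_tot[gi],
        })
    out = pd.concat([g_index.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    if period is not None:
        out.insert(len(by or []), "y1", period[0])
        out.insert(len(by or []) + 1, "y2", period[1])
    return out


def threshold_count(national: pd.DataFrame, threshold: float,
                    value_col: str = "median",
                    population_col: str = "population") -> dict:
    """Count countries at or above a national mean-intake threshold.

    ``national`` holds one summary row per country.  Returns the count, the
    percent of all countries, and the summed population of qualifying
    countries (NaN populations contribute 0).
    """
    if national["country"].duplicated().any():
        raise ValueError("expected exactly one summary row per country")
    qualifying = national[national[value_col] >= threshold]
    n_total = len(national)
    pop = float(np.nansum(qualifying[population_col].to_numpy(dtype=float))) \
        if population_col in national.columns else float("nan")
    return {
        "count": int(len(qualifying)),
        "n_countries": n_total,
        "percent": 100.0 * len(qualifying) / n_total if n_total else float("nan"),
        "population": pop,
    }


def correlate_index(national_means: np.ndarray, index_values: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between national means and an index."""
    x = np.asarray(national_means, dtype=float)
    y = np.asarray(index_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def restrict_to_children(draws: DrawArray) -> DrawArray:
    """Restrict a draw array to the child/adolescent age bins (ages 3-19)."""
    mask = draws.index["age_bin"].isin(CHILD_AGE_BINS).to_numpy()
    return DrawArray(draws.index[mask].reset_index(drop=True),
                     draws.values[mask], dict(draws.flags))
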
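"""Standardization of raw survey intake records to analysis units.

Three small, pure operations: beverage classification under the
added-sugar/energy-density definition of a sugar-sweetened beverage,
ratio-based energy adjustment to age-specific daily energy targets, and
conversion of grams/day to standardized 248 g servings/week.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    DAYS_PER_WEEK, ENERGY_TARGET_KCAL, SERVING_GRAMS, SSB_CATEGORIES,
    SSB_EXCLUDED_CATEGORIES, SSB_MIN_KCAL_PER_SERVING, STRATUM_COLS,
)

log = logging.getLogger(__name__)

__all__ = [
    "BeverageRecord", "UnclassifiableBeverage", "classify_ssb",
    "adjust_energy", "to_servings_per_week", "from_servings_per_week",
    "harmonize_surveys",
]


@dataclass(frozen=True)
class BeverageRecord:
    name: str
    kcal_per_237g: float
    added_sugar_flag: bool | None
    category: str

    def __post_init__(self):
        if self.kcal_per_237g < 0:
            raise ValueError("kcal_per_237g must be >= 0")
        if self.category not in SSB_CATEGORIES:
            raise ValueError(f"unknown beverage category {self.category!r}")


class UnclassifiableBeverage(ValueError):
    """Raised when a record lacks the information needed to classify it."""


def classify_ssb(record: BeverageRecord) -> bool:
    """Is this beverage a sugar-sweetened beverage?

    True iff it has added sugars AND provides at least 50 kcal per 237 g
    serving AND is not in an excluded category (100% juices, non-caloric
    artificially sweetened drinks, sweetened milk, tea, coffee).  A missing
    added-sugar flag raises :class:`UnclassifiableBeverage` rather than
    silently classifying as non-SSB.
    """
    if record.added_sugar_flag is None:
        raise UnclassifiableBeverage(
            f"beverage {record.name!r}: added_sugar_flag is missing"
        )
    if record.category in SSB_EXCLUDED_CATEGORIES:
        return False
    return bool(record.added_sugar_flag) and record.kcal_per_237g >= SSB_MIN_KCAL_PER_SERVING


def adjust_energy(grams_per_day: float, age_bin: str,
                  reported_energy_kcal: float | None) -> float:
    """Ratio energy adjustment to the age-specific daily energy target.

    ``adjusted = grams_per_day * target(age_bin) / reported_energy``.
    Targets: 1300 kcal/day for the youngest bins (ages 3-5 band), 1700 for
    the 5-9 bin, 2000 from age 10 upward.  With missing reported energy the
    intake passes through unchanged and an "unadjusted" warning is logged.
    """
    if grams_per_day < 0:
        raise ValueError("grams_per_day must be >= 0")
    if age_bin not in ENERGY_TARGET_KCAL and age_bin != "all":
        raise ValueError(f"unknown age bin {age_bin!r}")
    if reported_energy_kcal is None or (isinstance(reported_energy_kcal, float)
                                        and np.isnan(reported_energy_kcal)):
        log.warning("missing reported energy for age bin %s: intake left unadjusted",
                    age_bin)
        return float(grams_per_day)
    if reported_energy_kcal <= 0:
        raise ValueError("reported_energy_kcal must be > 0")
    target = ENERGY_TARGET_KCAL.get(age_bin, 2000.0)
    return float(grams_per_day) * target / float(reported_energy_kcal)


def to_servings_per_week(grams_per_day) -> float | np.ndarray:
    """Convert grams/day to standardized 248 g servings/week (linear)."""
    g = np.asarray(grams_per_day, dtype=float)
    if np.any(g < 0):
        raise ValueError("grams_per_day must be >= 0")
    out = g * DAYS_PER_WEEK / SERVING_GRAMS
    return float(out) if out.ndim == 0 else out


def from_servings_per_week(servings_wk) -> float | np.ndarray:
    """Inverse of :func:`to_servings_per_week`."""
    s = np.asarray(servings_wk, dtype=float)
    out = s * SERVING_GRAMS / DAYS_PER_WEEK
    return float(out) if out.ndim == 0 else out


def harmonize_surveys(raw: pd.DataFrame) -> pd.DataFrame:
    """Harmonize a raw survey table to analysis units.

    Input columns: ``grams_per_day``, ``sd_grams_per_day``, ``sample_n``,
    ``energy_kcal_per_day``, plus identifiers and stratum labels.  Output
    adds ``servings_wk`` (energy-adjusted) and ``se_servings_wk``
    (= SD / sqrt(n), converted), dropping the raw unit columns.
    """
    required = {"grams_per_day", "sd_grams_per_day", "sample_n",
                "energy_kcal_per_day", "age_bin"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw survey table missing columns: {sorted(missing)}")
    df = raw.copy()
    adj = np.array([
        adjust_energy(g, a, e) for g, a, e in
        zip(df["grams_per_day"], df["age_bin"], df["energy_kcal_per_day"])
    ])
    scale = np.divide(adj, df["grams_per_day"].to_numpy(),
                      out=np.ones(len(df)), where=df["grams_per_day"].to_numpy() > 0)
    df["servings_wk"] = to_servings_per_week(adj)
    sd_adj = df["sd_grams_per_day"].to_numpy() * scale
    se_grams = sd_adj / np.sqrt(np.maximum(df["sample_n"].to_numpy(), 1))
    df["se_servings_wk"] = to_servings_per_week(se_grams)
    keep_ids = [c for c in ("survey_id", "country", "year") if c in df.columns]
    keep_meta = [c for c in ("method", "representative", "metric_type", "sample_n")
                 if c in df.columns]
    return df[keep_ids + STRATUM_COLS + keep_meta + ["servings_wk", "se_servings_wk"]]
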
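"""End-to-end pipeline orchestration and file contracts.

Stages: ``simulate -> harmonize -> fit -> trend -> aggregate -> validate``.
Every stage reads CSVs written by earlier stages, writes its own outputs
into the run directory, and records them (with SHA-256 checksums, seed and
timing) in ``manifest.json``.  Re-running with an identical configuration
reproduces identical numeric outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_world as sw
from .aggregate import (
    change_between_years, correlate_index, restrict_to_children,
    threshold_count, weighted_aggregate,
)
from .config import (
    STRATUM_COLS, DrawArray, PipelineConfig, config_to_dict,
    pipeline_config_from_dict,
)
from .harmonize import harmonize_surveys
from .intake_model import fit_intake_model, predict_strata
from .trend_model import build_trajectories, combine_models, fit_trend_model
from .validate import cross_validate, flag_implausible

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_stage", "PipelineError", "load_config",
           "write_draws", "read_draws"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the machine-readable record is in ``error.json``."""


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a pipeline config from YAML (or defaults), applying overrides."""
    if path is not None:
        with open(path) as fh:
            cfg = pipeline_config_from_dict(yaml.safe_load(fh) or {})
    else:
        cfg = PipelineConfig()
    for key, val in overrides.items():
        if val is not None:
            setattr(cfg, key, val)
    cfg.resolve_seeds()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _require(out_dir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = out_dir / name
        if not p.exists():
            raise FileNotFoundError(f"missing required input file: {p}")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Draw-file round trip
# ---------------------------------------------------------------------------

def write_draws(draws_by_cy: dict[tuple[str, int], DrawArray], path: Path) -> None:
    frames = []
    for (country, year), da in sorted(draws_by_cy.items()):
        df = da.index.copy()
        if "country" not in df.columns:
            df.insert(0, "country", country)
        if "year" not in df.columns:
            df.insert(1, "year", year)
        df["_flags"] = json.dumps(da.flags)
        for d in range(da.n_draws):
            df[f"d{d}"] = da.values[:, d]
        frames.append(df)
    _write_csv(pd.concat(frames, ignore_index=True), path)


def read_draws(path: Path) -> dict[tuple[str, int], DrawArray]:
    df = pd.read_csv(path)
    dcols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    out = {}
    for (country, year), sub in df.groupby(["country", "year"], sort=False):
        flags = json.loads(sub["_flags"].iloc[0]) if "_flags" in sub else {}
        idx = sub[["country", "year", *STRATUM_COLS]].reset_index(drop=True)
        out[(country, int(year))] = DrawArray(
            index=idx, values=sub[dcols].to_numpy(dtype=float), flags=flags)
    return out


def _concat_draws(draws_by_cy: dict, year: int) -> DrawArray:
    """Stack all countries' draw arrays for one year into a single array."""
    keys = sorted(k for k in draws_by_cy if k[1] == year)
    if not keys:
        raise ValueError(f"no draw arrays for year {year}")
    idx = pd.concat([draws_by_cy[k].index for k in keys], ignore_index=True)
    vals = np.vstack([draws_by_cy[k].values for k in keys])
    return DrawArray(index=idx, values=vals)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    world = sw.generate_world(cfg.world)
    pops = sw.generate_populations(world)
    surveys_raw = sw.simulate_surveys(world, populations=pops)
    covariates = sw.generate_covariates(world, cov_config=cfg.covariates)
    _write_csv(world.truth, out / "world_truth.csv")
    _write_csv(surveys_raw, out / "surveys_raw.csv")
    _write_csv(covariates, out / "covariates.csv")
    _write_csv(pops, out / "populations.csv")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
    return {"n_surveys": int(surveys_raw["survey_id"].nunique()) if len(surveys_raw) else 0,
            "n_rows": len(surveys_raw)}


def _stage_harmonize(cfg: PipelineConfig, out: Path) -> dict:
    (raw_path,) = _require(out, "surveys_raw.csv")
    raw = pd.read_csv(raw_path)
    surveys = harmonize_surveys(raw)
    _write_csv(surveys, out / "surveys.csv")
    return {"n_rows": len(surveys)}


def _stage_fit(cfg: PipelineConfig, out: Path) -> dict:
    s_path, c_path, p_path = _require(out, "surveys.csv", "covariates.csv",
                                      "populations.csv")
    surveys = pd.read_csv(s_path)
    covariates = pd.read_csv(c_path)
    pops = pd.read_csv(p_path)
    posterior = fit_intake_model(surveys, covariates, cfg.model, pops)
    draws = {}
    for country, year in covariates[["country", "year"]].itertuples(index=False):
        draws[(country, int(year))] = predict_strata(
            posterior, country, int(year), n_draws=cfg.n_draws)
    write_draws(draws, out / "draws.csv")
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(posterior.diagnostics, fh, indent=2)
    return {"n_country_years": len(draws), **{
        k: posterior.diagnostics[k] for k in ("max_rhat", "converged")}}


def _stage_trend(cfg: PipelineConfig, out: Path) -> dict:
    d_path, c_path, p_path = _require(out, "draws.csv", "covariates.csv",
                                      "populations.csv")
    draws = read_draws(d_path)
    covariates = pd.read_csv(c_path)
    pops = pd.read_csv(p_path)
    traj = build_trajectories(draws, pops, covariates, epsilon=cfg.model.epsilon)
    trend = fit_trend_model(traj, cfg.trend)
    combined = combine_models(draws, trend, traj, cfg.trend)
    _write_csv(traj, out / "trajectories.csv")
    write_draws(combined, out / "combined_draws.csv")
    with open(out / "trend_diagnostics.json", "w") as fh:
        json.dump(trend.diagnostics, fh, indent=2)
    return dict(trend.diagnostics)


def _aggregate_year(draws, pops, year):
    year_draws = restrict_to_children(_concat_draws(draws, year))
    w = pops[pops["year"] == year]
    by_stratum = weighted_aggregate(year_draws, w, by=["country", *STRATUM_COLS])
    by_country = weighted_aggregate(year_draws, w, by=["country"])
    return year_draws, w, by_stratum, by_country


def _stage_aggregate(cfg: PipelineConfig, out: Path) -> dict:
    d_path, c_path, p_path = _require(out, "combined_draws.csv", "covariates.csv",
                                      "populations.csv")
    draws = read_draws(d_path)
    covariates = pd.read_csv(c_path)
    pops = pd.read_csv(p_path)
    region_map = covariates[["country", "region"]].drop_duplicates()
    years = sorted({y for _, y in draws})
    std_year = max(years)

    all_stratum, all_country, all_region, all_global = [], [], [], []
    per_year = {}
    for year in years:
        year_draws, w, by_stratum, by_country = _aggregate_year(draws, pops, year)
        rdraws = DrawArray(year_draws.index.merge(region_map, on="country"),
                           year_draws.values)
        by_region = weighted_aggregate(rdraws, w, by=["region"])
        by_global = weighted_aggregate(year_draws, w, by=None)
        for df in (by_stratum, by_country, by_region, by_global):
            df.insert(0, "year", year)
        all_stratum.append(by_stratum)
        all_country.append(by_country)
        all_region.append(by_region)
        all_global.append(by_global)
        per_year[year] = (year_draws, w)

    _write_csv(pd.concat(all_stratum, ignore_index=True), out / "estimates_by_stratum.csv")
    country_df = pd.concat(all_country, ignore_index=True)
    _write_csv(country_df, out / "estimates_by_country.csv")
    _write_csv(pd.concat(all_region, ignore_index=True), out / "estimates_by_region.csv")
    _write_csv(pd.concat(all_global, ignore_index=True), out / "estimates_global.csv")

    # standardized changes (both years weighted with the std-year proportions)
    w_std = per_year[std_year][1].drop(columns=["year"])
    changes = []
    for y1, y2 in cfg.change_periods:
        if y1 not in per_year or y2 not in per_year:
            continue
        for by in (None, ["region"]):
            d1, d2 = per_year[y1][0], per_year[y2][0]
            if by == ["region"]:
                d1 = DrawArray(d1.index.merge(region_map, on="country"), d1.values)
                d2 = DrawArray(d2.index.merge(region_map, on="country"), d2.values)
            ch = change_between_years(d1, d2, w_std, by=by, period=(y1, y2))
            if by is None:
                ch.insert(0, "region", "global")
            changes.append(ch)
    if changes:
        _write_csv(pd.concat(changes, ignore_index=True), out / "changes.csv")

    # headline summary: threshold count and index correlations at std year
    national = country_df[country_df["year"] == std_year]
    thr = threshold_count(national, cfg.threshold_servings_wk)
    cov_std = covariates[covariates["year"] == std_year]
    merged = national.merge(cov_std[["country", "sdi", "obesity_prev"]], on="country")
    r_sdi, p_sdi = correlate_index(merged["median"], merged["sdi"])
    r_ob, p_ob = correlate_index(merged["median"], merged["obesity_prev"])
    summary = {
        "std_year": std_year,
        "threshold_servings_wk": cfg.threshold_servings_wk,
        "threshold_count": thr,
        "corr_sdi": {"r": r_sdi, "p": p_sdi},
        "corr_obesity": {"r": r_ob, "p": p_ob},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"std_year": std_year, "countries_over_threshold": thr["count"]}


def _stage_validate(cfg: PipelineConfig, out: Path) -> dict:
    s_path, c_path, p_path, e_path = _require(
        out, "surveys.csv", "covariates.csv", "populations.csv",
        "estimates_by_country.csv")
    surveys = pd.read_csv(s_path)
    covariates = pd.read_csv(c_path)
    pops = pd.read_csv(p_path)
    v = cfg.validation
    report = cross_validate(surveys, covariates, cfg.model, seed=cfg.seed + 7,
                            populations=pops, n_folds=v.n_folds,
                            n_repeats=v.n_repeats, n_draws=cfg.n_draws)
    _write_csv(report, out / "cv_report.csv")
    estimates = pd.read_csv(e_path)
    flags = flag_implausible(estimates, lo=v.implausible_lo, hi=v.implausible_hi,
                             max_ui_ratio=v.max_ui_ratio)
    _write_csv(flags, out / "flags.csv")
    pooled = report[report["fold"] == -1]
    return {"pooled_r2": float(pooled["r2"].mean()),
            "pooled_coverage": float(pooled["coverage"].mean()),
            "n_flags": len(flags)}


_STAGES = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "fit": _stage_fit,
    "trend": _stage_trend,
    "aggregate": _stage_aggregate,
    "validate": _stage_validate,
}


def run_stage(cfg: PipelineConfig, stage: str, out_dir: str | Path | None = None) -> dict:
    """Run one named stage, updating the run manifest."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(_STAGES)}")
    before = {p.name for p in out.iterdir()}
    t0 = time.perf_counter()
    try:
        info = _STAGES[stage](cfg, out)
    except Exception as exc:
        record = {"stage": stage, "error_type": type(exc).__name__,
                  "message": str(exc)}
        with open(out / "error.json", "w") as fh:
            json.dump(record, fh, indent=2)
        raise
    elapsed = time.perf_counter() - t0
    new_files = sorted({p.name for p in out.iterdir()} - before
                       | _known_outputs(stage))
    outputs = {name: _sha256(out / name) for name in new_files
               if (out / name).exists() and name not in ("manifest.json", "error.json")}
    manifest_path = out / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest[stage] = {"seed": cfg.seed, "elapsed_s": round(elapsed, 3),
                       "outputs": outputs, **info}
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.info("stage %-9s done in %6.2fs  %s", stage, elapsed, info)
    return info


def _known_outputs(stage: str) -> set[str]:
    return {
        "simulate": {"world_truth.csv", "surveys_raw.csv", "covariates.csv",
                     "populations.csv", "config.yaml"},
        "harmonize": {"surveys.csv"},
        "fit": {"draws.csv", "diagnostics.json"},
        "trend": {"trajectories.csv", "combined_draws.csv", "trend_diagnostics.json"},
        "aggregate": {"estimates_by_stratum.csv", "estimates_by_country.csv",
                      "estimates_by_region.csv", "estimates_global.csv",
                      "changes.csv", "summary.json"},
        "validate": {"cv_report.csv", "flags.csv"},
    }[stage]


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Run all configured stages in order; returns the run directory."""
    out = Path(out_dir or cfg.out_dir)
    for stage in cfg.stages:
        run_stage(cfg, stage, out)
    return out
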
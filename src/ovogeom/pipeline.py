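"""End-to-end study runner: acquire profiles -> fit -> analyze -> report.

A run starts from one of three input modes — simulated cohorts, existing
coordinate CSVs, or silhouette images — fits every profile, derives the
geometry, and writes a reproducible report bundle: ``fits.csv`` (one row
per fruit), regression and group-comparison tables, and a machine-readable
``summary.json``.  The exact configuration of a run is serialized next to
its outputs; re-running the same config reproduces every file
bit-for-bit (CSV floats are fixed at 6 significant digits).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .epe_fitting import GOOD_FIT_THRESHOLD, FitOptions, fit_epe
from .geometry import shape_metrics
from .profile_pipeline import (calibrate_scale, extract_boundary,
                               read_binary_image, read_profile_csv,
                               standardize_profile, write_profile_csv)
from .scaling_analysis import (FruitRecord, allometric_fits, group_compare,
                               records_to_frame, relative_error_summary,
                               revolution_test)
from .synthetic_data import PRESETS, generate_cohort

__all__ = ["RunConfig", "run_study", "fit_records", "analyze_frame",
           "digitize_manifest"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one study run."""

    mode: str = "simulate"              # simulate | coordinates | images
    out_dir: str = "ovogeom_run"
    presets: tuple = ("cherry", "qianxi", "truss")
    n_fruits: Optional[int] = None      # override preset cohort sizes
    seed: Optional[int] = None          # override preset seeds (offset per cohort)
    manifest: Optional[str] = None      # for coordinates / images modes
    n_points: int = 1000
    fit_seed: int = 20241106
    n_restarts: int = 4
    ci_level: float = 0.95
    revolution_band: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "coordinates", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode != "simulate" and not self.manifest:
            raise ValueError(f"mode {self.mode!r} requires a manifest CSV")


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.select_dtypes("number").columns:
        out[col] = out[col].map(lambda v: float(f"{v:.6g}") if np.isfinite(v) else v)
    return out


def digitize_manifest(manifest_path, out_dir, n_points: int = 1000) -> pd.DataFrame:
    """Digitize every silhouette listed in a batch manifest.

    The manifest needs columns image_path, fruit_id, cultivar,
    measured_length_cm and optionally v_obs_cm3; image paths are resolved
    relative to the manifest.  Writes one standardized coordinate CSV per
    fruit plus a derived manifest, and returns the derived manifest.
    """
    manifest_path = Path(manifest_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    batch = pd.read_csv(manifest_path)
    rows = []
    for rec in batch.itertuples(index=False):
        img = manifest_path.parent / rec.image_path
        mask = read_binary_image(img)
        boundary = calibrate_scale(extract_boundary(mask),
                                   float(rec.measured_length_cm))
        profile = standardize_profile(boundary, n_points)
        rel = f"{rec.fruit_id}.csv"
        write_profile_csv(profile, out / rel)
        row = {"fruit_id": rec.fruit_id, "cultivar": rec.cultivar,
               "profile_path": rel}
        if hasattr(rec, "v_obs_cm3"):
            row["v_obs_cm3"] = rec.v_obs_cm3
        rows.append(row)
        logger.info("digitize: %s -> %s", rec.fruit_id, rel)
    derived = pd.DataFrame(rows)
    derived.to_csv(out / "profiles_manifest.csv", index=False)
    return derived


def fit_records(entries, options: FitOptions) -> List[FruitRecord]:
    """Fit profiles and derive geometry for (fruit_id, cultivar, profile, v_obs)."""
    records = []
    for fruit_id, cultivar, profile, v_obs in entries:
        fit = fit_epe(profile, options)
        geom = shape_metrics(fit.params)
        records.append(FruitRecord(fruit_id=fruit_id, cultivar=cultivar,
                                   fit=fit, geometry=geom, v_obs=v_obs))
        logger.info("fit: %s rmse_adj=%.4g converged=%s",
                    fruit_id, fit.rmse_adj, fit.converged)
    return records


def analyze_frame(df: pd.DataFrame, ci_level: float = 0.95,
                  band: float = 0.1) -> dict:
    """Per-cultivar and cross-cultivar statistics on a fits table.

    Returns a JSON-serializable dict: RMSE_adj distribution per cultivar,
    geometry summaries, revolution-test verdicts, relative-error summaries
    and allometric exponents, plus Tukey group comparisons when more than
    one cultivar is present.  The volume comparisons are skipped with a
    warning when no observed volumes are available.
    """
    summary: dict = {"cultivars": {}, "group_comparisons": {}}
    has_vobs = df["v_obs"].notna().any()
    if not has_vobs:
        logger.warning("no observed volumes: revolution test and relative "
                       "errors skipped")
    for cultivar, sub in df.groupby("cultivar", sort=False):
        entry: dict = {
            "n": int(len(sub)),
            "rmse_adj": {
                "median": float(sub["rmse_adj"].median()),
                "cv_percent": float(100 * sub["rmse_adj"].std(ddof=1)
                                    / sub["rmse_adj"].mean()) if len(sub) > 1 else 0.0,
                "fraction_good_fit": float((sub["rmse_adj"]
                                            < GOOD_FIT_THRESHOLD).mean()),
            },
            "s_median_cm2": float(sub["s"].median()),
            "v_pred_median_cm3": float(sub["v_pred"].median()),
            "w_over_l_median": float(sub["w_over_l"].median()),
        }
        if has_vobs and sub["v_obs"].notna().sum() >= 3:
            verdict = revolution_test(sub, band=band, ci_level=ci_level)
            reg = verdict.regression
            entry["revolution_test"] = {
                "slope": reg.slope, "ci_low": reg.slope_ci_low,
                "ci_high": reg.slope_ci_high, "r_squared": reg.r_squared,
                "strict": verdict.strict, "banded": verdict.banded,
                "band": verdict.band,
            }
            entry["relative_error"] = relative_error_summary(sub).to_dict()
        fits = allometric_fits(sub, ci_level=ci_level)
        entry["allometry"] = {
            row.relation: {"exponent": row.exponent, "ci_low": row.ci_low,
                           "ci_high": row.ci_high, "r_squared": row.r_squared}
            for row in fits.itertuples(index=False)
        }
        summary["cultivars"][cultivar] = entry
    if df["cultivar"].nunique() >= 2:
        for response in ("rmse_adj", "s", "v_pred", "w_over_l"):
            gc = group_compare(df, response)
            summary["group_comparisons"][response] = {
                "anova_f": gc.anova_f, "anova_p": gc.anova_p,
                "letters": gc.letters, "cv_percent": gc.cv_percent,
            }
    return summary


def _acquire(config: RunConfig):
    """Produce (fruit_id, cultivar, profile, v_obs) entries and truth table."""
    if config.mode == "simulate":
        entries, truths = [], []
        for i, name in enumerate(config.presets):
            spec = PRESETS[name]
            if config.n_fruits is not None:
                spec = dataclasses.replace(spec, n_fruits=config.n_fruits)
            if config.seed is not None:
                spec = dataclasses.replace(spec, seed=config.seed + i)
            cohort = generate_cohort(spec, config.n_points)
            truths.append(cohort.truth)
            for row, prof in zip(cohort.truth.itertuples(index=False),
                                 cohort.profiles):
                entries.append((row.fruit_id, row.cultivar, prof, row.v_obs))
        return entries, pd.concat(truths, ignore_index=True)
    manifest_path = Path(config.manifest)
    if config.mode == "images":
        out = Path(config.out_dir) / "profiles"
        derived = digitize_manifest(manifest_path, out, config.n_points)
        base = out
    else:
        derived = pd.read_csv(manifest_path)
        base = manifest_path.parent
    entries = []
    for rec in derived.itertuples(index=False):
        profile = read_profile_csv(base / rec.profile_path)
        profile = standardize_profile(profile, config.n_points)
        v_obs = float(rec.v_obs_cm3) if hasattr(rec, "v_obs_cm3") else None
        entries.append((rec.fruit_id, rec.cultivar, profile, v_obs))
    return entries, None


def run_study(config: RunConfig) -> dict:
    """Execute a full study and write its report bundle.

    Returns the summary dict (also written as ``summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)

    entries, truth = _acquire(config)
    options = FitOptions(seed=config.fit_seed, n_restarts=config.n_restarts)
    records = fit_records(entries, options)
    df = records_to_frame(records)
    _fmt(df).to_csv(out / "fits.csv", index=False)
    if truth is not None:
        _fmt(truth).to_csv(out / "ground_truth.csv", index=False)

    summary = analyze_frame(df, ci_level=config.ci_level,
                            band=config.revolution_band)
    frames = []
    for cultivar, sub in df.groupby("cultivar", sort=False):
        tab = allometric_fits(sub, ci_level=config.ci_level)
        tab.insert(0, "cultivar", cultivar)
        frames.append(tab)
    _fmt(pd.concat(frames, ignore_index=True)).to_csv(
        out / "allometric_fits.csv", index=False)
    if df["cultivar"].nunique() >= 2:
        rows = []
        for response in ("rmse_adj", "s", "v_pred", "w_over_l"):
            gc = group_compare(df, response)
            for group in gc.letters:
                rows.append({"response": response, "cultivar": group,
                             "mean": gc.group_means[group],
                             "cv_percent": gc.cv_percent[group],
                             "letters": gc.letters[group],
                             "anova_p": gc.anova_p})
        _fmt(pd.DataFrame(rows)).to_csv(out / "group_comparisons.csv",
                                        index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
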
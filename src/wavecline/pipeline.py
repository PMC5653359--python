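"""End-to-end orchestration: simulate/load → geometry → traits → clines → stats.

One :func:`run_full_analysis` call takes either file paths or a simulation
config and produces the full report bundle: per-trait cline fits with
likelihood-ratio tests, a residual-correlation table against squared flow
resistance (the Table-1-style family, BH-corrected within it), the pairwise
trait-residual correlation matrix, fucoid coverage at every snail, optional
common-garden Kruskal–Wallis comparisons, and a run manifest.  Every random
draw descends from the single run seed, so a rerun with the same config
reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .associations import (kruskal_wallis, pairwise_residual_correlations,
                           residual_correlation_table)
from .cline import fit_cline, fit_null, likelihood_ratio_test
from .exposure import ExposureConfig, FucoidSurvey, coverage_table
from .geometry import path_from_points
from .simulate import ShoreData, ShoreSimConfig, simulate_shore
from .traits import FlumeConfig, derive_traits_table, filter_cohort, resistance_table

__all__ = ["RunConfig", "run_full_analysis", "load_shore", "read_s1_like_workbook"]

logger = logging.getLogger("wavecline")

DEFAULT_TRAITS = ("RFA", "ROA", "RIA", "S1", "S2", "SA")


@dataclass
class RunConfig:
    """Inputs and knobs for one full analysis run.

    Either ``sim`` (a :class:`ShoreSimConfig`) or the four input paths must
    be given.  Squared flow resistance (SFR) is always fitted — it is the
    response of the residual-correlation analysis.
    """

    sim: ShoreSimConfig | None = None
    coordinates_csv: str | Path | None = None
    morphometry_csv: str | Path | None = None
    trials_csv: str | Path | None = None
    fucoid_csv: str | Path | None = None
    common_garden_csv: str | Path | None = None
    traits: tuple[str, ...] = DEFAULT_TRAITS
    seed: int = 0
    out_dir: str | Path | None = None
    sd_model: str = "smooth"
    n_starts: int = 20
    n_control: int = 5
    alpha: float = 0.05
    flume: FlumeConfig = field(default_factory=FlumeConfig)
    exposure_radius_m: float = 4.0

    def __post_init__(self):
        if not self.traits:
            raise ValueError("trait list must be non-empty")


def load_shore(config: RunConfig) -> tuple[ShoreData | None, pd.DataFrame, pd.DataFrame,
                                           pd.DataFrame, pd.DataFrame | None]:
    """Resolve inputs to (sim bundle or None, coords, morph, trials, fucoid)."""
    if config.sim is not None:
        data = simulate_shore(config.sim)
        return data, data.coordinates, data.morphometry, data.trials, data.fucoid
    missing = [name for name, p in [("coordinates_csv", config.coordinates_csv),
                                    ("morphometry_csv", config.morphometry_csv),
                                    ("trials_csv", config.trials_csv)] if p is None]
    if missing:
        raise ValueError(f"missing inputs: {', '.join(missing)} (or provide sim=)")
    coords = pd.read_csv(config.coordinates_csv)
    morph = pd.read_csv(config.morphometry_csv)
    trials = pd.read_csv(config.trials_csv)
    fucoid = pd.read_csv(config.fucoid_csv) if config.fucoid_csv else None
    return None, coords, morph, trials, fucoid


def _require_columns(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table} is missing required columns: {', '.join(missing)}")


def read_s1_like_workbook(path, sheet_map: dict) -> dict[str, pd.DataFrame]:
    """Read a field-study spreadsheet into the pipeline's input tables.

    ``sheet_map`` maps each logical table ("coordinates", "morphometry",
    "trials", optionally "fucoid", "common_garden") to a dict with the sheet
    name under ``sheet`` and a ``columns`` dict renaming spreadsheet columns
    to the pipeline's names (snail_id, x_m, y_m, SA_mm2, ...).
    """
    out = {}
    for table, spec in sheet_map.items():
        df = pd.read_excel(path, sheet_name=spec["sheet"], engine="openpyxl")
        df = df.rename(columns=spec.get("columns", {}))
        out[table] = df
    return out


def _config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded)."""
    from dataclasses import replace

    payload = repr(replace(config, out_dir=None)).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole analysis; returns the report dict (and writes files).

    Report keys: "positions" (per-snail geometry + exposure), "fits"
    (per-trait cline parameters, lnL, chi2, df, p), "residuals" (wide
    table), "correlations" (Table-1-style family vs SFR), "pairwise"
    (trait-by-trait residual correlations), "kruskal_wallis" (per stage, if
    common-garden data present), "manifest".
    """
    rng_children = np.random.SeedSequence(config.seed).spawn(len(config.traits) + 1)
    sim_bundle, coords, morph, trials, fucoid = load_shore(config)

    _require_columns(coords, ["snail_id", "x_m", "y_m"], "coordinates")
    _require_columns(morph, ["snail_id", "SA_mm2", "OA_mm2", "IA_mm2",
                             "L1_mm", "W1_mm", "L2_mm", "W2_mm"], "morphometry")
    _require_columns(trials, ["snail_id", "round", "level", "flush", "dislodged"],
                     "trials")

    # --- geometry: one smooth path through the snail cloud, arc positions
    path = path_from_points(coords[["x_m", "y_m"]].to_numpy(), n_control=config.n_control)
    projections = path.project_many(coords[["x_m", "y_m"]].to_numpy())
    positions = coords[["snail_id", "x_m", "y_m"]].copy()
    positions["position_m"] = [pr.position for pr in projections]
    positions["offpath_distance_m"] = [pr.distance for pr in projections]
    if "attached" in coords.columns:
        positions["attached"] = coords["attached"].astype(bool)
    else:
        tested = set(trials["snail_id"])
        positions["attached"] = positions["snail_id"].isin(tested)

    # --- exposure index at every snail
    if fucoid is not None and len(fucoid):
        survey = FucoidSurvey.from_frame(fucoid)
        cov = coverage_table(survey, positions[["x_m", "y_m"]],
                             ExposureConfig(config.exposure_radius_m))
        positions["fucoid_coverage"] = cov["coverage"].to_numpy()

    # --- traits and resistance
    derived = derive_traits_table(morph)
    resist = resistance_table(trials, config.flume)
    table = positions.merge(derived, on="snail_id", how="left").merge(
        resist, on="snail_id", how="left")
    kept, excluded = filter_cohort(table)
    logger.info("cohort: %d kept, %d excluded (non-attachers)", len(kept), len(excluded))

    # --- cline fits: SFR plus every requested trait
    fits: dict[str, dict] = {}
    residual_cols: dict[str, pd.Series] = {}
    fit_targets = list(dict.fromkeys(list(config.traits) + ["SFR"]))
    for trait, child in zip(fit_targets, rng_children):
        sub = kept[["snail_id", "position_m", trait]].dropna()
        if len(sub) < 8 or np.ptp(sub[trait].to_numpy()) == 0:
            logger.warning("trait %s skipped: not enough usable values", trait)
            continue
        x = sub["position_m"].to_numpy()
        y = sub[trait].to_numpy()
        fit = fit_cline(x, y, n_starts=config.n_starts,
                        seed=np.random.default_rng(child), sd_model=config.sd_model)
        null = fit_null(x, y)
        lrt = likelihood_ratio_test(fit, null)
        fits[trait] = {
            "params": fit.params.as_dict(),
            "log_likelihood": fit.log_likelihood,
            "null_log_likelihood": null.log_likelihood,
            "chi2": lrt.chi2, "df": lrt.df, "p_value": lrt.p_value,
            "converged": fit.converged, "identifiable": fit.identifiable,
            "n_starts_used": fit.n_starts_used, "n": len(sub),
            "sd_model": fit.sd_model,
        }
        residual_cols[trait] = pd.Series(fit.residuals, index=sub["snail_id"].to_numpy())

    residual_table = pd.DataFrame(residual_cols)
    residual_table.index.name = "snail_id"

    # --- Table-1-style residual correlations vs SFR, BH within the trait family
    correlations = None
    if "SFR" in residual_table.columns and residual_table.shape[1] >= 2:
        fam = [t for t in config.traits if t in residual_table.columns] + ["SFR"]
        correlations = residual_correlation_table(residual_table[fam], response="SFR",
                                                  alpha=config.alpha)

    pairwise = None
    morph_cols = [t for t in config.traits if t in residual_table.columns]
    if len(morph_cols) >= 2:
        pairwise = pairwise_residual_correlations(residual_table[morph_cols],
                                                  alpha=config.alpha)

    # --- common garden
    kw_results = {}
    garden = pd.read_csv(config.common_garden_csv) if config.common_garden_csv else None
    if garden is not None:
        _require_columns(garden, ["ecotype", "stage", "max_velocity_ms"], "common_garden")
        for stage, sub in garden.groupby("stage"):
            groups = [g["max_velocity_ms"].to_numpy() for _, g in sub.groupby("ecotype")]
            if len(groups) >= 2 and all(len(g) for g in groups):
                kw = kruskal_wallis(groups)
                kw_results[stage] = {"chi_squared": kw.statistic, "df": kw.df,
                                     "p_value": kw.p_value,
                                     "n_per_group": [len(g) for g in groups]}

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "wavecline_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_snails_input": len(coords),
        "n_kept": len(kept),
        "n_excluded_non_attachers": len(excluded),
        "traits_fitted": sorted(fits),
        "sd_model": config.sd_model,
        "sfr_note": "max resisted velocity squared inside the pipeline (drag ~ v^2)",
        "path_control_points": path.to_json_list(),
        "path_length_m": path.total_length,
    }

    report = {
        "positions": positions,
        "analysis_table": kept,
        "excluded": excluded,
        "fits": fits,
        "residuals": residual_table,
        "correlations": correlations,
        "pairwise": pairwise,
        "kruskal_wallis": kw_results,
        "manifest": manifest,
    }
    if sim_bundle is not None:
        report["truth"] = sim_bundle.truth

    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report["positions"].to_csv(out / "positions.csv", index=False)
    report["analysis_table"].to_csv(out / "analysis_table.csv", index=False)
    report["residuals"].to_csv(out / "residuals.csv")
    (out / "fits.json").write_text(json.dumps(report["fits"], indent=2))
    if report["correlations"] is not None:
        report["correlations"].to_csv(out / "correlations.csv", index=False)
    if report["pairwise"] is not None:
        report["pairwise"]["coefficient"].to_csv(out / "pairwise_coefficient.csv")
        report["pairwise"]["p_value"].to_csv(out / "pairwise_p_value.csv")
        report["pairwise"]["method"].to_csv(out / "pairwise_method.csv")
    if report["kruskal_wallis"]:
        (out / "kruskal_wallis.json").write_text(
            json.dumps(report["kruskal_wallis"], indent=2))
    (out / "manifest.json").write_text(json.dumps(report["manifest"], indent=2))
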
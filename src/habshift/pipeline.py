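"""End-to-end orchestration: landscape → prep → screen → model → change → gap.

The pipeline is linear and desk-scale, driven by one flat configuration
mapping (JSON-serializable). Every stage writes its intermediate artifacts
under ``out_dir`` and the consolidated report (JSON + Markdown) embeds the
configuration hash and all seeds, so a run is reproducible and every
reported number is recomputable from the persisted intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import maxent_sdm, occurrence_prep, reserve_gap, variable_screen
from .grid_model import write_grid, write_points_csv
from .habitat_change import (
    binarize,
    classify_change,
    elevation_contrast,
    filter_patches,
    indicators,
    label_patches,
)
from .synthetic_landscape import (
    Landscape,
    ScenarioSpec,
    default_truth,
    make_landscape,
    make_reserves,
    sample_occurrences,
    true_suitability,
)

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": None,  # required
    # synthetic landscape
    "n_rows": 100,
    "n_cols": 100,
    "cell_size_km": 1.0,
    "n_climate_layers": 6,
    "autocorrelation_range_cells": 8.0,
    "temperature_delta": 1.5,
    "precipitation_scale": 0.9,
    "forest_fraction": 0.6,
    "n_decoy_layers": 0,
    # occurrences / background
    "n_occurrences": 273,
    "n_background": 10_000,
    # screening
    "correlation_cutoff": 0.8,
    "importance_cutoff_pct": 1.0,
    # model
    "n_replicates": 15,
    "train_frac": 0.75,
    "hinge_knots": 4,
    "beta_multiplier": 1.0,
    "max_iter": 5000,
    "tol": 1e-7,
    # habitat mapping
    "connectivity": 8,
    "min_patch_km2": 4.0,
    "max_gap_km": 0.5,
    "threshold": None,  # None → shared mean max-SSS threshold
    # reserves
    "n_reserves": 19,
    "reserve_cover_fraction": 0.3,
    "write_intermediates": True,
}

_RANGE_CHECKS = [
    ("train_frac", lambda v: 0.0 < v < 1.0, "must lie in (0, 1)"),
    ("correlation_cutoff", lambda v: 0.0 < v <= 1.0, "must lie in (0, 1]"),
    ("importance_cutoff_pct", lambda v: v >= 0.0, "must be >= 0"),
    ("n_replicates", lambda v: v >= 1, "must be >= 1"),
    ("n_rows", lambda v: v >= 1, "must be >= 1"),
    ("n_cols", lambda v: v >= 1, "must be >= 1"),
    ("cell_size_km", lambda v: v > 0, "must be positive"),
    ("n_occurrences", lambda v: v >= 4, "must be >= 4"),
    ("n_background", lambda v: v >= 1, "must be >= 1"),
    ("connectivity", lambda v: v in (4, 8), "must be 4 or 8"),
    ("min_patch_km2", lambda v: v >= 0, "must be >= 0"),
    ("max_gap_km", lambda v: v >= 0, "must be >= 0"),
    ("n_reserves", lambda v: v >= 1, "must be >= 1"),
    ("forest_fraction", lambda v: 0.0 < v < 1.0, "must lie in (0, 1)"),
    ("threshold", lambda v: v is None or 0.0 < v < 1.0, "must be None or in (0, 1)"),
]


def validate_config(config: dict[str, Any]) -> list[str]:
    """All detectable problems in a config, without side effects."""
    problems: list[str] = []
    merged = {**DEFAULT_CONFIG, **config}
    for key in config:
        if key not in DEFAULT_CONFIG:
            problems.append(f"unknown config key {key!r}")
    if merged.get("out_dir") is None:
        problems.append("out_dir is required")
    for key, ok, msg in _RANGE_CHECKS:
        val = merged[key]
        try:
            if not ok(val):
                problems.append(f"{key}={val!r} {msg}")
        except TypeError:
            problems.append(f"{key}={val!r} has the wrong type")
    return problems


def _config_hash(config: dict[str, Any]) -> str:
    # hash only the keys that influence the numbers, not where they land
    canon = json.dumps(
        {k: v for k, v in config.items() if k not in ("out_dir", "write_intermediates")},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run every stage on a synthetic landscape; returns the report dict.

    Writes intermediates and ``report.json`` / ``report.md`` under
    ``out_dir``. Identical config (including seed) ⇒ identical report.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    write = bool(cfg["write_intermediates"])

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    # --- landscape -------------------------------------------------------
    _stage("landscape")
    spec = ScenarioSpec(
        n_rows=cfg["n_rows"],
        n_cols=cfg["n_cols"],
        cell_size_km=cfg["cell_size_km"],
        n_climate_layers=cfg["n_climate_layers"],
        autocorrelation_range_cells=cfg["autocorrelation_range_cells"],
        temperature_delta=cfg["temperature_delta"],
        precipitation_scale=cfg["precipitation_scale"],
        forest_fraction=cfg["forest_fraction"],
        n_decoy_layers=cfg["n_decoy_layers"],
        seed=seed,
    )
    landscape: Landscape = make_landscape(spec)
    truth = default_truth(landscape)
    suit_true = true_suitability(landscape.current, truth, elevation=landscape.elevation)
    geom = landscape.current.geometry

    # --- occurrences and background -------------------------------------
    _stage("prep")
    occ_xy = sample_occurrences(
        suit_true, landscape.forest, int(cfg["n_occurrences"]), seed=seed + 1
    )
    occ = occurrence_prep.OccurrenceSet(points=occ_xy, provenance="synthetic")
    thinned = occurrence_prep.thin_one_per_cell(occ, geom, seed=seed + 3)
    background = occurrence_prep.sample_background(
        landscape.forest, n=int(cfg["n_background"]), seed=seed + 2
    )
    if write:
        write_points_csv(occ.points, out / "occurrences.csv")
        write_points_csv(thinned.points, out / "occurrences_thinned.csv")
        write_points_csv(background.points, out / "background.csv")

    # --- variable screening ----------------------------------------------
    _stage("screen")
    merged_points = np.vstack([thinned.points, background.points])
    corr = variable_screen.pairwise_correlation(landscape.current, merged_points)
    screen_cfg = variable_screen.ScreenConfig(
        correlation_cutoff=cfg["correlation_cutoff"],
        importance_cutoff_pct=cfg["importance_cutoff_pct"],
    )
    screen = variable_screen.eliminate_correlated(corr, screen_cfg)
    if write:
        corr.to_csv(out / "correlation_matrix.csv")

    # --- first model + importance refit ----------------------------------
    _stage("first_model")
    pres_df = variable_screen.extract_at_points(
        landscape.current.subset(screen.retained), thinned.points
    )
    bg_df = variable_screen.extract_at_points(
        landscape.current.subset(screen.retained), background.points
    )
    expansion = maxent_sdm.build_features(bg_df, hinge_knots=int(cfg["hinge_knots"]))
    first_model = maxent_sdm.fit(
        expansion.transform(pres_df),
        expansion.transform(bg_df),
        beta_multiplier=cfg["beta_multiplier"],
        max_iter=int(cfg["max_iter"]),
        tol=cfg["tol"],
        expansion=expansion,
    )
    importance_first = maxent_sdm.permutation_importance(
        first_model, pres_df, bg_df, seed=seed + 5
    )
    final_vars = variable_screen.refit_top_variables(importance_first, screen_cfg)

    # --- replicate ensemble on the final variables ------------------------
    _stage("replicates")
    ensemble = maxent_sdm.run_replicates(
        pres_df[final_vars],
        bg_df[final_vars],
        landscape.current.subset(final_vars),
        n_rep=int(cfg["n_replicates"]),
        train_frac=cfg["train_frac"],
        seed=seed + 4,
        hinge_knots=int(cfg["hinge_knots"]),
        beta_multiplier=cfg["beta_multiplier"],
        max_iter=int(cfg["max_iter"]),
        tol=cfg["tol"],
    )
    suit_current = ensemble.mean_suitability
    suit_future = maxent_sdm.ensemble_mean_logistic(
        ensemble.models, landscape.future.subset(final_vars)
    )
    final_importance = maxent_sdm.permutation_importance(
        ensemble.models[0], pres_df[final_vars], bg_df[final_vars], seed=seed + 5
    )
    if write:
        write_grid(suit_current, out / "suitability_current.asc")
        write_grid(suit_future, out / "suitability_future.asc")
        write_grid(suit_true, out / "suitability_true.asc")

    # --- habitat maps, patch filter, change, indicators -------------------
    _stage("change")
    threshold = cfg["threshold"]
    if threshold is None:
        threshold = ensemble.mean_threshold
    maps = {}
    patch_removed = {}
    for label, grid in (("current", suit_current), ("future", suit_future)):
        raw_map = binarize(grid, threshold, scenario_label=label)
        patches = label_patches(raw_map, connectivity=int(cfg["connectivity"]))
        filtered = filter_patches(
            patches,
            min_area_km2=cfg["min_patch_km2"],
            max_gap_km=cfg["max_gap_km"],
        )
        patch_removed[label] = int(raw_map.suitable.sum() - filtered.suitable.sum())
        maps[label] = filtered
    change = classify_change(maps["current"], maps["future"])
    vuln = indicators(change)
    elev_test = elevation_contrast(maps["current"], maps["future"], landscape.elevation)
    if write:
        change_grid = landscape.elevation.with_values(
            change.categories.astype(float), layer_name="change_categories"
        )
        write_grid(change_grid, out / "change_categories.asc")

    # --- reserves ---------------------------------------------------------
    _stage("gap")
    reserves_geojson = make_reserves(
        geom,
        n_reserves=int(cfg["n_reserves"]),
        seed=seed + 6,
        cover_fraction=cfg["reserve_cover_fraction"],
    )
    reserves = reserve_gap.load_reserves_geojson(reserves_geojson)
    gap = reserve_gap.build_reserve_report(reserves, maps["current"], maps["future"])
    if write:
        with open(out / "reserves.geojson", "w") as fh:
            json.dump(reserves_geojson, fh)
        gap.table.to_csv(out / "reserve_table.csv")

    # --- consolidated report ---------------------------------------------
    _stage("report")
    valid = suit_true.valid_mask & suit_current.valid_mask
    from scipy.stats import spearmanr

    rho = float(
        spearmanr(suit_true.values[valid], suit_current.values[valid]).statistic
    )
    report = {
        "config_hash": _config_hash(cfg),
        "config": {k: cfg[k] for k in sorted(cfg) if k != "out_dir"},
        "counts": {
            "occurrences": len(occ),
            "thinned_presences": len(thinned),
            "background": len(background),
            "cells_removed_by_patch_filter": patch_removed,
        },
        "screening": {
            "candidates": list(corr.columns),
            "eliminated": [list(pair) for pair in screen.eliminated],
            "retained_after_correlation": screen.retained,
            "first_model_importance_pct": importance_first,
            "final_variables": final_vars,
            "final_importance_pct": final_importance,
        },
        "model": {
            "auc_train_mean": ensemble.auc_train_mean,
            "auc_train_sd": ensemble.auc_train_sd,
            "auc_test_mean": ensemble.auc_test_mean,
            "auc_test_sd": ensemble.auc_test_sd,
            "mean_threshold": ensemble.mean_threshold,
            "threshold_used": threshold,
            "spearman_vs_truth": rho,
        },
        "habitat": {
            "area_current_km2": vuln.a_c_km2,
            "area_future_km2": vuln.a_f_km2,
            "area_overlap_km2": vuln.a_fc_km2,
            "ac_pct": vuln.ac_pct,
            "sh_c_pct": vuln.sh_c_pct,
            "sh_f_pct": vuln.sh_f_pct,
            "vulnerable_km2": vuln.vulnerable_km2,
            "new_km2": vuln.new_km2,
        },
        "elevation": {
            "mean_current_m": elev_test.mean1,
            "sd_current_m": elev_test.sd1,
            "mean_future_m": elev_test.mean2,
            "sd_future_m": elev_test.sd2,
            "mann_whitney_u": elev_test.u,
            "z": elev_test.z,
            "p": elev_test.p,
        },
        "reserves": {
            "table": {
                name: {
                    "current_km2": float(row["current_km2"]),
                    "future_km2": float(row["future_km2"]),
                    "ac_pct": None if np.isnan(row["ac_pct"]) else float(row["ac_pct"]),
                }
                for name, row in gap.table.iterrows()
            },
            "protected_current_pct": gap.protected_current_pct,
            "protected_future_pct": gap.protected_future_pct,
        },
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict[str, Any], path: Path) -> None:
    h = report["habitat"]
    m = report["model"]
    e = report["elevation"]
    r = report["reserves"]
    lines = [
        "# Habitat vulnerability report",
        "",
        f"Config hash: `{report['config_hash']}`",
        "",
        "## Model",
        f"- training AUC {m['auc_train_mean']:.3f} ± {m['auc_train_sd']:.3f}",
        f"- test AUC {m['auc_test_mean']:.3f} ± {m['auc_test_sd']:.3f}",
        f"- mean max-SSS threshold {m['mean_threshold']:.4f}"
        f" (used: {m['threshold_used']:.4f})",
        f"- Spearman rho vs true suitability {m['spearman_vs_truth']:.3f}",
        f"- final variables: {', '.join(report['screening']['final_variables'])}",
        "",
        "## Habitat change",
        f"- current suitable {h['area_current_km2']:.2f} km², future {h['area_future_km2']:.2f} km²",
        f"- overlap {h['area_overlap_km2']:.2f} km²; vulnerable {h['vulnerable_km2']:.2f} km²;"
        f" new {h['new_km2']:.2f} km²",
        f"- AC {h['ac_pct']:.2f}%  SH_c {h['sh_c_pct']:.2f}%  SH_f {h['sh_f_pct']:.2f}%"
        if h["ac_pct"] is not None
        else "- indicators undefined (empty current habitat)",
        "",
        "## Elevation contrast",
        f"- current {e['mean_current_m']:.1f} ± {e['sd_current_m']:.1f} m;"
        f" future {e['mean_future_m']:.1f} ± {e['sd_future_m']:.1f} m",
        f"- Mann–Whitney U = {e['mann_whitney_u']:.0f}, z = {e['z']:.3f}, p = {e['p']:.3g}",
        "",
        "## Reserve network",
        f"- protects {r['protected_current_pct']:.2f}% of current and"
        f" {r['protected_future_pct']:.2f}% of future suitable habitat",
        "",
        "| reserve | current km² | future km² | AC % |",
        "|---|---|---|---|",
    ]
    for name, row in r["table"].items():
        ac = "—" if row["ac_pct"] is None else f"{row['ac_pct']:.2f}"
        lines.append(
            f"| {name} | {row['current_km2']:.2f} | {row['future_km2']:.2f} | {ac} |"
        )
    path.write_text("\n".join(lines) + "\n")
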
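"""End-to-end orchestration: grid -> beta -> heterogeneity -> CAR -> diagnostics.

A run starts either from a synthetic :class:`~betascape.synth.ScenarioConfig`
or from in-memory landscape/presence objects, and executes the full chain for
every requested scale, emitting a regression-summary CSV (one row per taxon
and scale), per-cell CSVs, GeoJSON cell maps, drop logs and a machine-readable
manifest.  All randomness flows from one master seed through per-stage
derived seeds.  Scales are reported side by side but never pooled: models are
compared among taxa at the same scale only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .beta import beta_summary, cell_diversity
from .car import CARFit, fit_car, whiten_residuals
from .diagnostics import morans_mc, residual_normality
from .grid import NeighborGraph, apply_mask, build_grid, queen_graph
from .hetero import PREDICTOR_COLUMNS, heterogeneity_table
from .io import cell_id_str, cells_to_geojson, graph_to_edgelist
from .prep import assemble
from .synth import Landscape, PresenceStack, ScenarioConfig, generate_landscape, generate_species

__all__ = ["RunConfig", "run_analysis", "ingest_cell_table", "fit_summary_row", "SUMMARY_COLUMNS"]

DISPLAY_NAMES = {
    "CV_Tm": "CV Tm",
    "ROV_Pp": "ROV Pp",
    "CV_Pp": "CV Pp",
    "ROV_Tm": "ROV Tm",
    "CV_Elev": "CV Elev",
    "Veg_H": "Veg (H)",
    "Soil_H": "Soil (H)",
    "ROV_Elev": "ROV Elev",
}
SUMMARY_COLUMNS = [
    "Group", "Scale", "N", "R2", "Lambda", "Intercept",
    "CV Tm", "ROV Pp", "CV Pp", "ROV Tm", "CV Elev", "Veg (H)", "Soil (H)", "ROV Elev",
]


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    scenario: ScenarioConfig | None = None
    scales: tuple[float, ...] = (2.0, 1.0, 0.5, 0.25)
    collinearity_threshold: float = 0.8
    weight_mode: str = "intent"
    n_permutations: int = 999
    seed: int = 0
    outdir: str | Path | None = None
    car_style: str = "W"
    whiten_for_moran: bool = True
    include_empty_pixels: bool = True
    standardize_scope: str = "all"
    priority: list[str] | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")


def fit_summary_row(fit: CARFit, taxon: str, scale: float, dropped: list[dict]) -> dict:
    """One regression-table row: estimates with significance stars, '-' for
    variables eliminated in pre-processing."""
    row = {
        "Group": taxon,
        "Scale": scale,
        "N": fit.n,
        "R2": round(fit.nagelkerke, 4),
        "Lambda": round(fit.lam, 4),
    }
    dropped_names = {d["dropped"] for d in dropped}
    for internal, display in [("Intercept", "Intercept"), *DISPLAY_NAMES.items()]:
        if internal in fit.coefficients:
            row[display] = f"{fit.coefficients[internal]:.4g}{fit.significance(internal)}"
        elif internal in dropped_names:
            row[display] = "-"
        else:
            row[display] = ""
    return row


def _analyze_scale(
    landscape: Landscape,
    stack: PresenceStack,
    scale: float,
    cfg: RunConfig,
    moran_seed: int,
) -> dict:
    """Run one (taxon, scale) analysis; returns all intermediate products."""
    grid = build_grid(
        (
            landscape.transform.lon_min,
            landscape.transform.lat_max - landscape.shape[0] * landscape.transform.pixel_size,
            landscape.transform.lon_min + landscape.shape[1] * landscape.transform.pixel_size,
            landscape.transform.lat_max,
        ),
        scale,
    )
    cells = apply_mask(grid, landscape.mask, landscape.transform)
    graph = queen_graph(cells)
    div = cell_diversity(stack, cells, include_empty_pixels=cfg.include_empty_pixels)
    het = heterogeneity_table(landscape, cells)
    mm = assemble(
        div,
        het,
        graph,
        weight_mode=cfg.weight_mode,
        collinearity_threshold=cfg.collinearity_threshold,
        priority=cfg.priority,
        standardize_scope=cfg.standardize_scope,
    )
    fit = fit_car(mm, style=cfg.car_style)
    resid = whiten_residuals(mm, fit) if cfg.whiten_for_moran else fit.residuals
    moran = morans_mc(resid, mm.graph, cfg.n_permutations, seed=moran_seed)
    normality = residual_normality(fit.residuals) if fit.n >= 8 else None
    return {
        "cells": cells,
        "graph": graph,
        "diversity": div,
        "heterogeneity": het,
        "model_matrix": mm,
        "fit": fit,
        "moran": moran,
        "normality": normality,
    }


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline for every scale; optionally write a report
    bundle to ``config.outdir``.

    Returns ``{"summary": DataFrame, "scales": {scale: products}, "errors":
    {scale: message}}``.  Stage failures are reported per scale with the
    offending stage; partial results are preserved.
    """
    if config.scenario is None:
        raise ValueError("run_analysis currently requires a scenario configuration")
    ss = np.random.SeedSequence(config.seed)
    scenario_seed, *moran_seeds = [
        int(s.generate_state(1)[0]) for s in ss.spawn(1 + len(config.scales))
    ]
    scenario = ScenarioConfig(**{**_scenario_dict(config.scenario), "seed": scenario_seed})
    landscape = generate_landscape(scenario)
    stack = generate_species(scenario, landscape)
    if stack.empty_species:
        warnings.warn(f"{len(stack.empty_species)} species have empty ranges", stacklevel=2)

    results: dict[float, dict] = {}
    errors: dict[float, str] = {}
    rows = []
    for scale, mseed in zip(config.scales, moran_seeds):
        try:
            out = _analyze_scale(landscape, stack, scale, config, mseed)
        except Exception as exc:  # noqa: BLE001 - reported, run continues
            errors[scale] = f"{type(exc).__name__}: {exc}"
            continue
        results[scale] = out
        rows.append(
            fit_summary_row(out["fit"], stack.taxon, scale, out["model_matrix"].dropped_variables)
        )
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)

    bundle = {
        "summary": summary,
        "scales": results,
        "errors": errors,
        "beta_summary": beta_summary(
            pd.concat([r["diversity"] for r in results.values()], ignore_index=True)
        )
        if results
        else pd.DataFrame(),
    }
    if config.outdir is not None:
        _write_bundle(bundle, config, scenario, landscape, stack)
    return bundle


def _scenario_dict(sc: ScenarioConfig) -> dict:
    from dataclasses import asdict

    return asdict(sc)


def _write_bundle(bundle, config: RunConfig, scenario, landscape, stack) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["summary"].to_csv(outdir / "summary.csv", index=False)
    if len(bundle["beta_summary"]):
        bundle["beta_summary"].to_csv(outdir / "beta_summary.csv", index=False)
    diagnostics = {}
    for scale, out in bundle["scales"].items():
        tag = f"{scale:g}deg"
        cell_df = out["diversity"].merge(
            out["heterogeneity"], on=["cell_id", "scale"], how="inner"
        )
        cell_csv = cell_df.copy()
        cell_csv["cell_id"] = cell_csv["cell_id"].map(cell_id_str)
        cell_csv.to_csv(outdir / f"cells_{tag}.csv", index=False, float_format="%.8g")
        cells_to_geojson(out["cells"], cell_df, outdir / f"grid_{tag}.geojson")
        graph_to_edgelist(out["graph"], outdir / f"edges_{tag}.csv")
        fit, moran = out["fit"], out["moran"]
        diagnostics[tag] = {
            "lambda": fit.lam,
            "lambda_interval": list(fit.lambda_interval),
            "sigma2": fit.sigma2,
            "loglik": fit.loglik,
            "null_loglik": fit.null_loglik,
            "nagelkerke_r2": fit.nagelkerke,
            "lr_lambda_p": fit.lr_lambda_p,
            "boxcox_power": fit.boxcox_power,
            "coefficients": fit.coefficients,
            "p_values": fit.p_values,
            "moran_I": moran.I_observed,
            "moran_p": moran.p_value,
            "moran_permutations": moran.n_permutations,
            "normality": out["normality"],
            "dropped_variables": out["model_matrix"].dropped_variables,
        }
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=1, default=float))
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "scales": list(config.scales),
        "weight_mode": config.weight_mode,
        "collinearity_threshold": config.collinearity_threshold,
        "n_permutations": config.n_permutations,
        "car_style": config.car_style,
        "scenario": _scenario_dict(scenario),
        "errors": {f"{k:g}": v for k, v in bundle["errors"].items()},
        "empty_species": stack.empty_species,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))


def ingest_cell_table(
    path,
    schema: dict[str, str],
    scale: float,
    taxon: str = "ingested",
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[pd.DataFrame, pd.DataFrame, NeighborGraph]:
    """Load a pre-computed per-cell table and rebuild the Queen graph.

    ``schema`` maps canonical names to the file's column names.  Mandatory
    keys: ``beta_w``, ``gamma``, and either (``row``, ``col``) or (``lon``,
    ``lat``) cell coordinates.  Any of the eight predictor names present in
    the schema are carried into the heterogeneity table.  Rows violating
    beta_w >= 1 are rejected with a validation error.
    """
    df = pd.read_csv(path)
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise ValueError(f"cell table is missing mapped columns: {missing}")
    mandatory = {"beta_w", "gamma"}
    if not mandatory <= schema.keys():
        raise ValueError(f"schema must map {sorted(mandatory)}")
    has_rc = {"row", "col"} <= schema.keys()
    if not has_rc and not {"lon", "lat"} <= schema.keys():
        raise ValueError("schema must map either (row, col) or (lon, lat)")

    beta_w = df[schema["beta_w"]].to_numpy(dtype=float)
    bad = np.flatnonzero(beta_w < 1 - 1e-12)
    if bad.size:
        raise ValueError(f"beta_w < 1 at rows {bad.tolist()}: invalid diversity records")

    if has_rc:
        rows = df[schema["row"]].to_numpy(dtype=int)
        cols = df[schema["col"]].to_numpy(dtype=int)
    else:
        lon = df[schema["lon"]].to_numpy(dtype=float)
        lat = df[schema["lat"]].to_numpy(dtype=float)
        grid = build_grid(
            (lon.min() - scale, lat.min() - scale, lon.max() + scale, lat.max() + scale),
            scale,
            origin,
        )
        rows, cols = grid.cell_of(lon, lat)
    cell_ids = [(int(r), int(c)) for r, c in zip(rows, cols)]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell coordinates in the table")

    gamma = df[schema["gamma"]].to_numpy(dtype=float)
    div = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "taxon": taxon,
            "scale": scale,
            "n_pixels": df[schema["n_pixels"]] if "n_pixels" in schema else np.nan,
            "alpha_mean": gamma / beta_w,
            "gamma": gamma,
            "beta_w": beta_w,
            "flagged": gamma == 0,
        }
    )
    het = pd.DataFrame({"cell_id": cell_ids, "scale": scale})
    for name in PREDICTOR_COLUMNS:
        if name in schema:
            het[name] = df[schema[name]].to_numpy(dtype=float)
    graph = NeighborGraph.from_cells(cell_ids)
    return div, het, graph
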
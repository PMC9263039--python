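"""End-to-end assay orchestration: simulate → reconstruct → morphometry → dry mass.

`run_assay` executes the full workflow for a configured plate design and
returns per-FOV time series, per-FOV endpoints (12-h dry-mass increment and
fraction of rounded cells) and per-condition summaries with significance
annotation against the medium control. A two-"laboratory" replication mode
re-runs the assay under parameter perturbations (initial cell count, growth
rate, noise level) emulating an interlaboratory design.

Everything is deterministic given the config seed; wall-clock timings are
logged but never written into result files, so re-running a config reproduces
every output byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import AssayConfig, config_to_dict
from .drymass import aggregate, dmi, dry_mass, relative_dm, significance
from .morphometry import rounded_fraction, segment_cells
from .reconstruct import reconstruct_series
from .simulate import SimulationResult, render_series, simulate_population

__all__ = ["AssayResult", "run_assay", "run_interlab", "interlab_compare"]

logger = logging.getLogger("holoassay")


@dataclass
class AssayResult:
    timeseries: pd.DataFrame
    fov_summary: pd.DataFrame
    condition_summary: pd.DataFrame
    report: dict
    simulation: Optional[SimulationResult] = None


def _config_hash(config: AssayConfig) -> str:
    payload = config_to_dict(config)
    payload.pop("out_dir", None)  # execution detail, not part of the science
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def _process_fov(fov, config: AssayConfig, rendered_tp):
    """Reconstruct one FOV at the rendered timepoints; returns rows + endpoint."""
    optics = fov.optics
    ts_rows = []
    endpoint = {}
    for ti, t in enumerate(rendered_tp):
        phase_true = fov.phase_image(t)
        seed = int(
            np.random.default_rng(
                np.random.SeedSequence(entropy=fov.render_seed, spawn_key=(ti,))
            ).integers(0, 2**31)
        )
        holos = render_series(phase_true, optics, seed)
        qpi = reconstruct_series(
            holos,
            filter_radius_frac=config.filter_radius_frac,
            refocus=config.refocus,
            poly_order=config.poly_order,
        )
        dm_pg = dry_mass(qpi, config.drymass)
        ts_rows.append(
            {
                "experiment": fov.experiment,
                "condition": fov.condition.label,
                "agent": fov.condition.agent,
                "concentration_ug_ml": fov.condition.concentration_ug_ml,
                "fov": fov.fov_index,
                "time_h": t,
                "dm_pg": dm_pg,
            }
        )
        if ti == len(rendered_tp) - 1:
            _, regions = segment_cells(qpi, config.segmentation, config.drymass)
            stats = rounded_fraction(regions, config.segmentation.c_round)
            endpoint = {
                "n_rounded": stats.n_rounded,
                "n_cells": stats.n_total,
                "rounded_fraction": stats.fraction,
            }
    return ts_rows, endpoint


def run_assay(config: AssayConfig) -> AssayResult:
    """Run the complete simulated assay for one configuration.

    Per-FOV failures are logged with provenance and skipped; the report records
    completeness. Deterministic given ``config.seed`` (the population seed is
    overridden by it so one number controls the whole run).
    """
    t_start = time.perf_counter()
    config = replace(config, population=replace(config.population, seed=config.seed))
    rendered_tp = config.rendered_timepoints()
    sim = simulate_population(config.population, config.optics)

    ts_rows = []
    fov_rows = []
    failures = []
    for fov in sim.fovs:
        try:
            rows, endpoint = _process_fov(fov, config, rendered_tp)
        except Exception as exc:  # keep going over remaining FOVs
            logger.warning("FOV %s failed: %s", fov.fov_id, exc)
            failures.append({"fov_id": fov.fov_id, "error": str(exc)})
            continue
        ts_rows.extend(rows)
        times = [r["time_h"] for r in rows]
        dms = [r["dm_pg"] for r in rows]
        fov_rows.append(
            {
                "experiment": fov.experiment,
                "condition": fov.condition.label,
                "agent": fov.condition.agent,
                "concentration_ug_ml": fov.condition.concentration_ug_ml,
                "fov": fov.fov_index,
                "dmi_pg": dmi(times, dms),
                **endpoint,
            }
        )
    timeseries = pd.DataFrame(ts_rows)
    if len(timeseries):
        timeseries["dm_rel_pg"] = (
            timeseries.sort_values("time_h")
            .groupby(["experiment", "condition", "concentration_ug_ml", "fov"])
            ["dm_pg"]
            .transform(lambda s: s - s.iloc[0])
        )
    fov_summary = pd.DataFrame(fov_rows)
    condition_summary = aggregate(fov_summary) if len(fov_summary) else pd.DataFrame()
    if len(fov_summary) and (fov_summary["condition"] == "medium").any():
        sig = significance(fov_summary, control="medium")
        if len(sig):
            condition_summary = condition_summary.merge(
                sig, on=["condition", "concentration_ug_ml"], how="left"
            )
            condition_summary["stars"] = condition_summary["stars"].fillna("")

    report = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "n_fov_total": len(sim.fovs),
        "n_fov_completed": len(fov_rows),
        "failures": failures,
        "rendered_timepoints_h": list(rendered_tp),
    }
    logger.info("assay completed in %.1f s", time.perf_counter() - t_start)

    result = AssayResult(timeseries, fov_summary, condition_summary, report, sim)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: AssayResult, config: AssayConfig) -> None:
    from .io import write_manifest, write_plate_layout

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    result.timeseries.to_csv(out / "fov_timeseries.csv", index=False,
                             float_format=fmt)
    result.fov_summary.to_csv(out / "fov_summary.csv", index=False,
                              float_format=fmt)
    result.condition_summary.to_csv(out / "condition_summary.csv", index=False,
                                    float_format=fmt)
    (out / "run_report.json").write_text(json.dumps(result.report, sort_keys=True,
                                                    indent=2))
    write_plate_layout(out / "plate_layout.csv", config.population.conditions,
                       config.population.n_fov)
    if result.simulation is not None:
        write_manifest(out / "ground_truth.json", result.simulation.ground_truth)


def run_interlab(config: AssayConfig) -> dict:
    """Run the assay once per configured laboratory variant.

    Each "laboratory" perturbs the population and noise parameters and uses an
    independent seed stream, emulating independent execution of the shared SOP.
    """
    variants = config.lab_variants or []
    if not variants:
        raise ValueError("config.lab_variants is empty")
    results = {}
    for i, var in enumerate(variants):
        pop = config.population
        pop_v = replace(
            pop,
            initial_cell_count=max(1, int(round(pop.initial_cell_count
                                                * var.cell_count_multiplier))),
            growth_rate_per_h=pop.growth_rate_per_h * var.growth_multiplier,
        )
        optics_v = replace(
            config.optics,
            shot_noise_scale=config.optics.shot_noise_scale * var.noise_multiplier,
            parasitic_fringe_amplitude=(
                config.optics.parasitic_fringe_amplitude * var.noise_multiplier
            ),
        )
        seed_v = int(
            np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
            ).integers(0, 2**31)
        )
        out_dir = (
            str(Path(config.out_dir) / var.label) if config.out_dir else None
        )
        cfg_v = replace(config, population=pop_v, optics=optics_v, seed=seed_v,
                        lab_variants=None, out_dir=out_dir)
        results[var.label] = run_assay(cfg_v)
    return results


def interlab_compare(result_a: AssayResult, result_b: AssayResult) -> pd.DataFrame:
    """Per-condition differences in DMI and rounded fraction between two runs.

    Requires identical condition grids; comparing a result with itself yields
    exact zeros.
    """
    keys = ["condition", "concentration_ug_ml"]
    a = result_a.condition_summary.set_index(keys).sort_index()
    b = result_b.condition_summary.set_index(keys).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("condition grids differ between the two results")
    out = pd.DataFrame(index=a.index)
    out["dmi_mean_a_pg"] = a["dmi_mean_pg"]
    out["dmi_mean_b_pg"] = b["dmi_mean_pg"]
    out["dmi_diff_pg"] = b["dmi_mean_pg"] - a["dmi_mean_pg"]
    out["rounded_fraction_a"] = a["rounded_fraction"]
    out["rounded_fraction_b"] = b["rounded_fraction"]
    out["rounded_fraction_diff"] = b["rounded_fraction"] - a["rounded_fraction"]
    return out.reset_index()
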
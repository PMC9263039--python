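"""Validation studies: round-trip accuracy, parameter recovery, calibration.

These routines exercise the full pipeline against the simulator's ground
truth and are used both by the test suite and by the reproduction script.
Problem sizes default to a 512×384 sensor grid, which keeps a full recovery
study (six conditions × 20 FOVs) to a few minutes on one CPU while leaving
>500 pixels per cell for morphometry.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (AssayConfig, Condition, OpticsConfig, PopulationConfig,
                     SegmentationParams)
from .drymass import significance
from .fields import PhaseImage
from .pipeline import run_assay
from .reconstruct import reconstruct_series
from .simulate import cell_phase_footprint, render_series

__all__ = [
    "scaled_optics",
    "blob_phantom",
    "roundtrip_rms",
    "recovery_study",
    "recovery_metrics",
    "anova_null_calibration",
    "determinism_check",
    "smoke_config",
]


def scaled_optics(cols: int = 512, rows: int = 384, **kwargs) -> OpticsConfig:
    """Default optics on a coarser sensor grid (same physical FOV)."""
    return OpticsConfig(sensor_cols=cols, sensor_rows=rows, **kwargs)


def blob_phantom(optics: OpticsConfig, seed: int, n_blobs: int = 8,
                 peak_range=(0.8, 4.0)) -> PhaseImage:
    """Smooth band-limited phase phantom for round-trip validation.

    Compact soft-edged blobs (super-Gaussian, edge width ~20 µm) whose spatial
    spectrum lies inside the sideband filter passband, with peaks up to ~4 rad
    to exercise phase unwrapping. Sharper structure than the demodulation
    passband cannot be represented by any sideband method and is validated
    through integral (dry-mass) metrics instead.
    """
    rng = np.random.default_rng(seed)
    pitch = optics.pixel_pitch_um
    canvas = np.zeros((optics.sensor_rows, optics.sensor_cols))
    margin = 60.0
    for _ in range(n_blobs):
        radius = rng.uniform(25.0, 40.0)
        area = math.pi * radius**2
        peak = rng.uniform(*peak_range)
        # mass chosen to reach the requested peak given the soft profile
        patch = cell_phase_footprint(
            1.0, area, rng.uniform(1.0, 1.6), "spread", pitch,
            orientation=rng.uniform(0, math.pi), profile_power=2.0,
            wavelength_um=optics.wavelength_um,
        )
        patch *= peak / patch.max()
        x = rng.uniform(margin, optics.fov_width_um - margin)
        y = rng.uniform(margin, optics.fov_height_um - margin)
        half = patch.shape[0] // 2
        ri, ci = int(round(y / pitch)), int(round(x / pitch))
        r0, r1 = max(0, ri - half), min(canvas.shape[0], ri + half + 1)
        c0, c1 = max(0, ci - half), min(canvas.shape[1], ci + half + 1)
        pr0, pc0 = r0 - (ri - half), c0 - (ci - half)
        canvas[r0:r1, c0:c1] += patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]
    return PhaseImage(canvas, pitch, wavelength_um=optics.wavelength_um)


def focus_phantom(optics: OpticsConfig, seed: int, n_blobs: int = 50,
                  peak_range=(0.2, 0.6)) -> PhaseImage:
    """Weak-phase fine-grained phantom for refocusing tests.

    Small blobs near the demodulation resolution limit: defocus sensitivity
    scales inversely with the squared feature size, so the wide smooth blobs
    of :func:`blob_phantom` sit deep inside their own depth of field and give
    no usable focus cue at tens of micrometres. Peaks stay below ~0.6 rad
    because amplitude-based focus metrics are unbiased only in the weak-phase
    regime (strong phase objects shift the total-variation minimum by the
    interplay of defocus phase contrast with the band-limit amplitude rims).
    """
    rng = np.random.default_rng(seed)
    pitch = optics.pixel_pitch_um
    canvas = np.zeros((optics.sensor_rows, optics.sensor_cols))
    margin = 30.0
    for _ in range(n_blobs):
        radius = rng.uniform(5.0, 9.0)
        patch = cell_phase_footprint(
            1.0, math.pi * radius**2, rng.uniform(1.0, 1.4), "spread", pitch,
            profile_power=2.0, wavelength_um=optics.wavelength_um,
        )
        patch *= rng.uniform(*peak_range) / patch.max()
        x = rng.uniform(margin, optics.fov_width_um - margin)
        y = rng.uniform(margin, optics.fov_height_um - margin)
        half = patch.shape[0] // 2
        ri, ci = int(round(y / pitch)), int(round(x / pitch))
        r0, r1 = max(0, ri - half), min(canvas.shape[0], ri + half + 1)
        c0, c1 = max(0, ci - half), min(canvas.shape[1], ci + half + 1)
        pr0, pc0 = r0 - (ri - half), c0 - (ci - half)
        canvas[r0:r1, c0:c1] += patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]
    return PhaseImage(canvas, pitch, wavelength_um=optics.wavelength_um)


def _central_region(shape, frac: float = 0.9):
    r0 = int(shape[0] * (1 - frac) / 2)
    c0 = int(shape[1] * (1 - frac) / 2)
    return slice(r0, shape[0] - r0), slice(c0, shape[1] - c0)


def roundtrip_rms(optics: OpticsConfig, seed: int, refocus="off") -> float:
    """RMS phase error (rad) of the 7-frame render→reconstruct→average→compensate
    round trip over the central 90% of the FOV, for a known phantom."""
    truth = blob_phantom(optics, seed)
    holos = render_series(truth, optics, seed + 1)
    qpi = reconstruct_series(holos, refocus=refocus)
    rs, cs = _central_region(truth.shape)
    diff = qpi.phase[rs, cs] - truth.phase[rs, cs]
    diff -= np.median(diff)  # piston is not physical
    return float(np.sqrt(np.mean(diff**2)))


def _recovery_config(seed: int, n_fov: int, cols: int, rows: int) -> AssayConfig:
    conditions = [
        Condition("medium", "medium", 0.0),
        Condition("cytostatic_8", "cytostatic", 8.0),
        Condition("detergent_0.1", "detergent", 0.1),
        Condition("detergent_5.5", "detergent", 5.5),
        Condition("detergent_20", "detergent", 20.0),
        Condition("detergent_140", "detergent", 140.0),
    ]
    pop = PopulationConfig(conditions=conditions, n_fov=n_fov, n_experiments=1,
                           seed=seed)
    return AssayConfig(
        optics=scaled_optics(cols, rows),
        population=pop,
        seed=seed,
        render_timepoints_h=(0.0, 12.0),
    )


def recovery_study(seed: int, n_fov: int = 20, cols: int = 512,
                   rows: int = 384):
    """Run the full pipeline on control/cytostatic/detergent arms and pair the
    per-FOV pipeline readouts with the ground-truth manifest."""
    config = _recovery_config(seed, n_fov, cols, rows)
    result = run_assay(config)
    gt = result.simulation.ground_truth
    true_dmi = gt.fov_dmi_pg()
    true_rf = gt.rounded_fraction(12.0)
    merged = result.fov_summary.merge(
        true_dmi, on=["experiment", "condition", "concentration_ug_ml", "fov"]
    ).merge(
        true_rf.rename(columns={"n_rounded": "true_n_rounded",
                                "n_total": "true_n_total",
                                "rounded_fraction": "true_rounded_fraction"}),
        on=["experiment", "condition", "concentration_ug_ml", "fov"],
        how="left",
    )
    return merged, result


def recovery_metrics(merged: pd.DataFrame) -> pd.DataFrame:
    """Condition-level recovery summary: DMI bias (% of the true change) and
    pooled rounded-fraction error."""
    rows = []
    for (cond, conc), g in merged.groupby(["condition", "concentration_ug_ml"],
                                          sort=True):
        true_mean = g["true_dmi_pg"].mean()
        est_mean = g["dmi_pg"].mean()
        bias_pct = (100.0 * (est_mean - true_mean) / abs(true_mean)
                    if true_mean != 0 else float("nan"))
        n_r = g["n_rounded"].sum()
        n_c = g["n_cells"].sum()
        tn_r = g["true_n_rounded"].sum()
        tn_c = g["true_n_total"].sum()
        est_rf = n_r / n_c if n_c > 0 else float("nan")
        true_rf = tn_r / tn_c if tn_c > 0 else float("nan")
        rows.append(
            {
                "condition": cond,
                "concentration_ug_ml": conc,
                "n_fov": len(g),
                "true_dmi_mean_pg": true_mean,
                "est_dmi_mean_pg": est_mean,
                "dmi_bias_pct": bias_pct,
                "true_rounded_fraction": true_rf,
                "est_rounded_fraction": est_rf,
                "rounded_fraction_error": est_rf - true_rf,
            }
        )
    return pd.DataFrame(rows)


def anova_null_calibration(n_sim: int = 1000, seed: int = 0,
                           alpha: float = 0.05) -> float:
    """Type-I error rate of the significance stage under the null.

    Both groups are drawn from the same normal distribution (with shared
    experiment offsets) in the study's replicate structure (N = 3 experiments
    × n = 3 FOVs); returns the fraction of simulations rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        exp_offsets = rng.normal(0.0, 1.0, size=3)
        rows = []
        for cond in ("medium", "treated"):
            for e in range(3):
                for f in range(3):
                    rows.append(
                        {
                            "condition": cond,
                            "concentration_ug_ml": 0.0 if cond == "medium" else 1.0,
                            "experiment": e,
                            "fov": f,
                            "dmi_pg": exp_offsets[e] + rng.normal(0.0, 1.0),
                        }
                    )
        sig = significance(pd.DataFrame(rows), control="medium")
        if float(sig["p_value"].iloc[0]) < alpha:
            hits += 1
    return hits / n_sim


def smoke_config(seed: int = 0, out_dir=None) -> AssayConfig:
    """Small two-condition configuration for fast end-to-end runs."""
    conditions = [
        Condition("medium", "medium", 0.0),
        Condition("detergent_140", "detergent", 140.0),
    ]
    pop = PopulationConfig(
        conditions=conditions,
        initial_cell_count=14,
        n_fov=2,
        n_experiments=1,
        timepoints_h=(0.0, 6.0, 12.0),
        seed=seed,
        placement_margin_um=45.0,
    )
    return AssayConfig(
        optics=scaled_optics(256, 192),
        population=pop,
        seed=seed,
        out_dir=out_dir,
    )


def _hash_tree(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def determinism_check(seed: int, base_dir) -> bool:
    """Run the smoke assay twice with the same seed and compare every output byte."""
    base = Path(base_dir)
    digests = []
    for name in ("run_a", "run_b"):
        out = base / name
        run_assay(smoke_config(seed=seed, out_dir=str(out)))
        digests.append(_hash_tree(out))
    return digests[0] == digests[1]
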
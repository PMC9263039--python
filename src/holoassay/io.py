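"""File interfaces: multi-page TIFF hologram stacks, phase images, manifests.

Hologram stacks are written one file per FOV, pages ordered time-major then
frame 0–6, as 16-bit unsigned integers after a fixed linear scaling recorded
in the embedded JSON metadata. Phase images are written as 32-bit float TIFF
with a companion 8-bit quality mask.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fields import Hologram, PhaseImage

__all__ = [
    "write_hologram_stack",
    "read_hologram_stack",
    "write_phase_image",
    "read_phase_image",
    "write_manifest",
    "write_plate_layout",
]


def write_hologram_stack(path, holograms: Sequence[Sequence[Hologram]],
                         timepoints_h: Sequence[float],
                         extra_meta: Optional[dict] = None) -> None:
    """Write a per-FOV time-lapse stack (time-major, then frame index)."""
    path = Path(path)
    frames = [h for series in holograms for h in series]
    if not frames:
        raise ValueError("no holograms to write")
    pitch = frames[0].pixel_pitch_um
    wavelength = frames[0].wavelength_nm
    peak = max(float(h.intensity.max()) for h in frames)
    scale = 65535.0 / peak if peak > 0 else 1.0
    stack = np.stack(
        [np.clip(h.intensity * scale, 0, 65535).astype(np.uint16) for h in frames]
    )
    meta = {
        "pixel_pitch_um": pitch,
        "wavelength_nm": wavelength,
        "intensity_scale": scale,
        "n_frames": len(holograms[0]),
        "timepoints_h": [float(t) for t in timepoints_h],
        **(extra_meta or {}),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack, metadata=None,
                     description=json.dumps(meta, sort_keys=True))


def read_hologram_stack(path, sidecar: Optional[dict] = None):
    """Read a stack written by :func:`write_hologram_stack` (or any multi-page
    TIFF given a sidecar dict/YAML with pixel_pitch_um, wavelength_nm,
    n_frames, timepoints_h and optional intensity_scale)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = sidecar
        if meta is None:
            desc = tf.pages[0].description
            meta = json.loads(desc)
    if isinstance(meta, (str, Path)):
        with open(meta) as fh:
            meta = yaml.safe_load(fh)
    scale = float(meta.get("intensity_scale", 1.0))
    n_frames = int(meta["n_frames"])
    timepoints = [float(t) for t in meta["timepoints_h"]]
    if stack.ndim == 2:
        stack = stack[None]
    series = []
    for i, t in enumerate(timepoints):
        frames = []
        for k in range(n_frames):
            frames.append(
                Hologram(
                    stack[i * n_frames + k].astype(float) / scale,
                    float(meta["pixel_pitch_um"]),
                    float(meta["wavelength_nm"]),
                    time_h=t,
                    frame_index=k,
                )
            )
        series.append(frames)
    return series, meta


def write_phase_image(path, qpi: PhaseImage) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"pixel_pitch_um": qpi.pixel_pitch_um, "wavelength_um": qpi.wavelength_um}
    tifffile.imwrite(path, qpi.phase.astype(np.float32), metadata=None,
                     description=json.dumps(meta, sort_keys=True))
    tifffile.imwrite(path.with_suffix(".mask.tif"),
                     qpi.mask.astype(np.uint8), metadata=None)


def read_phase_image(path) -> PhaseImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        phase = tf.asarray().astype(float)
        meta = json.loads(tf.pages[0].description)
    mask_path = path.with_suffix(".mask.tif")
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return PhaseImage(phase, float(meta["pixel_pitch_um"]), mask=mask,
                      wavelength_um=meta.get("wavelength_um"))


def write_manifest(path, ground_truth) -> None:
    """Serialize the simulator ground truth as JSON (records orientation)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "cells": json.loads(ground_truth.cells.to_json(orient="records",
                                                       double_precision=10)),
        "fov_totals": json.loads(ground_truth.fov_totals.to_json(
            orient="records", double_precision=10)),
    }
    path.write_text(json.dumps(payload, sort_keys=True))


def write_plate_layout(path, conditions, n_fov: int) -> None:
    """Plate layout CSV: well, condition, agent, concentration."""
    rows = []
    well = 0
    for cond in conditions:
        for _ in range(n_fov):
            rows.append(
                {
                    "well": f"W{well:03d}",
                    "condition": cond.label,
                    "agent": cond.agent,
                    "concentration_ug_ml": cond.concentration_ug_ml,
                }
            )
            well += 1
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
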
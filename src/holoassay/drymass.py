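"""Population dry-mass analytics.

The population dry mass of a field of view follows from the mean phase shift,

    dm = λ / (2πα) · Δφ̄ · S,

with λ the illumination wavelength, α ≈ 0.19 µm³/pg the specific refractive
increment of cellular protein, Δφ̄ the mean phase over valid pixels and S the
corresponding area. With λ in µm, α in µm³/pg and S in µm² the result is in
picograms. Relative dry-mass development subtracts the t = 0 value, and the
12-h dry-mass increment is DMI = dm(12 h) − dm(0 h); DMI may legitimately be
negative when cells lyse.
"""
from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import DryMassParams
from .fields import PhaseImage

__all__ = ["dry_mass", "relative_dm", "dmi", "aggregate", "significance",
           "star_annotation"]


def dry_mass(qpi: PhaseImage, params: Optional[DryMassParams] = None,
             cell_mask: Optional[np.ndarray] = None) -> float:
    """Population dry mass (pg) of a background-compensated phase image.

    Δφ̄ is averaged over the valid pixels and multiplied by the matching valid
    area, so the product equals the phase integral; for a fully valid frame
    this is exactly Δφ̄·S_FOV. May be negative under background fluctuations.
    An optional ``cell_mask`` restricts the computation to segmented regions
    (sensitivity-analysis variant); the default uses the whole field of view.
    """
    params = params or DryMassParams()
    valid = qpi.mask
    if cell_mask is not None:
        valid = valid & np.asarray(cell_mask, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid < 0.5 * qpi.phase.size and cell_mask is None:
        raise ValueError("more than 50% of pixels invalid; cannot evaluate dry mass")
    if n_valid == 0:
        raise ValueError("no valid pixels")
    area = n_valid * qpi.pixel_pitch_um**2
    mean_phase = float(np.mean(qpi.phase[valid]))
    return params.wavelength_um / (2.0 * math.pi * params.alpha_um3_per_pg) \
        * mean_phase * area


def relative_dm(times_h: Sequence[float], dm_pg: Sequence[float],
                mode: str = "difference") -> np.ndarray:
    """Relative dry-mass development with respect to t = 0.

    Default convention is subtraction, DM(t) = dm(t) − dm(0), which preserves
    units (ng in plots) and makes DM(12 h) identical to the DMI; ``mode='ratio'``
    divides by dm(0) instead.
    """
    times = np.asarray(times_h, dtype=float)
    dm = np.asarray(dm_pg, dtype=float)
    if times.shape != dm.shape:
        raise ValueError("times and dm must have matching shapes")
    idx0 = np.flatnonzero(times == 0.0)
    if idx0.size == 0:
        raise ValueError("t = 0 measurement required for normalization")
    d0 = dm[idx0[0]]
    if mode == "difference":
        return dm - d0
    if mode == "ratio":
        if d0 == 0:
            raise ValueError("dm(0) = 0; ratio normalization undefined")
        return dm / d0
    raise ValueError("mode must be 'difference' or 'ratio'")


def dmi(times_h: Sequence[float], dm_pg: Sequence[float],
        t_end: Optional[float] = None) -> float:
    """Dry-mass increment dm(t_end) − dm(0); t_end defaults to the last timepoint."""
    times = np.asarray(times_h, dtype=float)
    dm = np.asarray(dm_pg, dtype=float)
    if t_end is None:
        t_end = float(times.max())
    i0 = np.flatnonzero(times == 0.0)
    i1 = np.flatnonzero(times == t_end)
    if i0.size == 0 or i1.size == 0:
        raise ValueError("both t = 0 and the endpoint must be present")
    return float(dm[i1[0]] - dm[i0[0]])


def aggregate(fov_summary: pd.DataFrame,
              group_cols: Sequence[str] = ("condition", "concentration_ug_ml"),
              ) -> pd.DataFrame:
    """Per-condition summary: DMI mean ± sample sd over FOVs, pooled rounded counts.

    The standard deviation uses the n−1 denominator and is reported as missing
    for single-FOV groups; rounded fractions are pooled as total rounded over
    total identified cells across FOVs.
    """
    rows = []
    for key, g in fov_summary.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(g)
        n_rounded = int(g["n_rounded"].sum()) if "n_rounded" in g else 0
        n_total = int(g["n_cells"].sum()) if "n_cells" in g else 0
        rows.append(
            {
                **dict(zip(group_cols, key)),
                "n_fov": n,
                "dmi_mean_pg": float(g["dmi_pg"].mean()),
                "dmi_sd_pg": float(g["dmi_pg"].std(ddof=1)) if n > 1 else float("nan"),
                "n_rounded": n_rounded,
                "n_cells": n_total,
                "rounded_fraction": (n_rounded / n_total) if n_total > 0
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def star_annotation(p: float) -> str:
    """Significance stars: p < 0.005 (***), p < 0.01 (**), p < 0.05 (*)."""
    if not np.isfinite(p):
        return ""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def significance(fov_summary: pd.DataFrame, control: str = "medium",
                 value_col: str = "dmi_pg",
                 group_cols: Sequence[str] = ("condition", "concentration_ug_ml"),
                 ) -> pd.DataFrame:
    """Two-factor ANOVA (condition, experiment) of each group against the control.

    Delegates the linear-model fit to statsmodels; each non-control group is
    compared with the medium control and the condition-factor p-value is
    annotated with the three-level star scheme. Degenerate (zero-variance)
    groups yield a missing p-value with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    ctrl = fov_summary[fov_summary["condition"] == control]
    if len(ctrl) == 0:
        raise ValueError(f"control condition {control!r} not found")
    rows = []
    for key, g in fov_summary.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if key[0] == control:
            continue
        if len(g) < 2 or len(ctrl) < 2:
            rows.append({**dict(zip(group_cols, key)), "p_value": float("nan"),
                         "stars": ""})
            continue
        data = pd.concat(
            [
                ctrl.assign(_grp="control"),
                g.assign(_grp="treated"),
            ],
            ignore_index=True,
        )[["_grp", "experiment", value_col]].rename(columns={value_col: "_y"})
        if float(np.var(data["_y"])) < 1e-30:
            warnings.warn("degenerate variance; p-value undefined", stacklevel=2)
            p = float("nan")
        else:
            formula = "_y ~ C(_grp)"
            if data["experiment"].nunique() > 1:
                formula += " + C(experiment)"
            model = smf.ols(formula, data=data).fit()
            table = sm.stats.anova_lm(model, typ=2)
            p = float(table.loc["C(_grp)", "PR(>F)"])
        rows.append({**dict(zip(group_cols, key)), "p_value": p,
                     "stars": star_annotation(p)})
    return pd.DataFrame(rows)
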
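"""Synthetic off-axis hologram generator with ground-truth manifest.

Emulates the study conditions of a label-free DHM cytotoxicity assay on
adherent epithelial cells: populations that proliferate (medium control),
round up and detach (cytostatic response) or lyse into sub-threshold debris
(detergent response) in a concentration-dependent manner, imaged as 7-frame
off-axis hologram series per field of view and time point.

Cell phase footprints are super-Gaussian profiles on elliptical supports with
optional low-order boundary lobes; each rendered footprint encodes exactly the
requested dry mass through the inverse of the phase/dry-mass relation
dm = λ/(2πα)·∫φ dA.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import Condition, OpticsConfig, PopulationConfig
from .fields import Hologram, PhaseImage

__all__ = [
    "hill_effect",
    "cell_phase_footprint",
    "shape_circularity",
    "simulate_population",
    "render_phase",
    "render_hologram",
    "render_series",
    "SimulatedFOV",
    "SimulationResult",
    "GroundTruth",
]

# default super-Gaussian edge steepness per cell state; higher = sharper edge.
# Rounded cells are smooth domes (softer edge) rather than hard discs.
PROFILE_POWER = {"spread": 8.0, "rounded": 6.0, "debris": 6.0}

_LN2 = math.log(2.0)


def hill_effect(concentration: float, ec50: float, hill: float) -> float:
    """Fractional effect c^h / (c^h + ec50^h), monotone nondecreasing in c."""
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill coefficient must be positive")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0.0:
        return 0.0
    # evaluate in log space for numerical robustness at extreme ratios
    z = hill * (math.log(concentration) - math.log(ec50))
    if z < -700.0:
        return 0.0
    if z > 700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-z))


def _boundary_radius(theta: np.ndarray, axis_ratio: float, orientation: float,
                     lobes: tuple) -> np.ndarray:
    """Unnormalized polar boundary: ellipse of axis ratio q times lobe modulation."""
    t = theta - orientation
    # ellipse with semi-axes (q, 1) before area scaling
    r = axis_ratio / np.sqrt((np.cos(t)) ** 2 * 1.0 + (axis_ratio * np.sin(t)) ** 2)
    mod = np.ones_like(r)
    for k, amp, ph in lobes:
        mod += amp * np.cos(k * theta + ph)
    return r * np.maximum(mod, 0.2)


def _boundary_scale(area_um2: float, axis_ratio: float, lobes: tuple) -> float:
    """Scale factor mapping the unnormalized boundary to the requested area."""
    theta = np.linspace(0.0, 2.0 * np.pi, 721)
    r = _boundary_radius(theta, axis_ratio, 0.0, lobes)
    raw_area = 0.5 * np.trapezoid(r**2, theta)
    return math.sqrt(area_um2 / raw_area)


def shape_circularity(axis_ratio: float, lobes: tuple = ()) -> float:
    """Circularity 4πA/P² of the model boundary, by quadrature.

    Scale-invariant, so it serves as the manifest ground truth for any cell
    with this shape family regardless of its area.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, 4097)
    r = _boundary_radius(theta, axis_ratio, 0.0, lobes)
    dr = np.gradient(r, theta)
    area = 0.5 * np.trapezoid(r**2, theta)
    perim = np.trapezoid(np.sqrt(r**2 + dr**2), theta)
    return min(1.0, 4.0 * np.pi * area / perim**2)


def cell_phase_footprint(
    dry_mass_pg: float,
    area_um2: float,
    eccentricity: float,
    state: str,
    pixel_pitch_um: float,
    *,
    orientation: float = 0.0,
    lobes: tuple = (),
    profile_power: Optional[float] = None,
    profile: str = "super_gaussian",
    alpha_um3_per_pg: float = 0.19,
    wavelength_um: float = 0.532,
) -> np.ndarray:
    """Render a single-cell phase patch (radians) encoding exactly ``dry_mass_pg``.

    The patch integral satisfies λ/(2πα) · Σφ · pixel_area = dry_mass_pg by
    construction (the profile is rescaled after rasterization). ``eccentricity``
    is the boundary axis ratio (>= 1); ``area_um2`` is the area enclosed by the
    half-maximum contour.
    """
    if dry_mass_pg < 0:
        raise ValueError("dry mass must be >= 0")
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if eccentricity < 1.0:
        raise ValueError("eccentricity (axis ratio) must be >= 1")
    if area_um2 < 4.0 * pixel_pitch_um**2:
        raise ValueError(
            f"area {area_um2:.1f} um2 smaller than 4 pixels at pitch "
            f"{pixel_pitch_um:.3f} um"
        )
    if profile_power is None:
        profile_power = PROFILE_POWER.get(state, 8.0)

    scale = _boundary_scale(area_um2, eccentricity, lobes)
    rmax = scale * eccentricity * (1.0 + sum(abs(a) for _, a, _ in lobes))
    half = int(math.ceil(1.4 * rmax / pixel_pitch_um)) + 1
    coords = (np.arange(2 * half + 1) - half) * pixel_pitch_um
    xx, yy = np.meshgrid(coords, coords)
    rr = np.hypot(xx, yy)
    theta = np.arctan2(yy, xx)
    rb = scale * _boundary_radius(theta, eccentricity, orientation, lobes)
    rho = rr / rb
    if profile == "disc":
        f = (rho <= 1.0).astype(float)
    elif profile == "super_gaussian":
        f = np.exp(-_LN2 * rho ** (2.0 * profile_power))
    else:
        raise ValueError(f"unknown profile {profile!r}")

    total = float(np.sum(f)) * pixel_pitch_um**2
    if dry_mass_pg == 0.0 or total == 0.0:
        return np.zeros_like(f)
    peak = dry_mass_pg * 2.0 * np.pi * alpha_um3_per_pg / (wavelength_um * total)
    if peak * float(f.max()) > 4.0 * np.pi:
        warnings.warn(
            f"requested peak phase {peak * f.max():.2f} rad exceeds 4π "
            "(unwrapping stress case)",
            stacklevel=2,
        )
    return peak * f


# ---------------------------------------------------------------------------
# population dynamics


@dataclass
class _Cell:
    cell_id: str
    state: str  # spread | rounded | debris | removed
    mass_pg: float
    x_um: float
    y_um: float
    area_um2: float
    axis_ratio: float
    orientation: float
    lobes: tuple
    profile_power: float
    circularity: float
    overlap: bool = False


def _sample_lobes(rng: np.random.Generator, amp_range: tuple, n: int = 3) -> tuple:
    ks = rng.choice(np.arange(3, 7), size=n, replace=False)
    return tuple(
        (int(k), float(rng.uniform(*amp_range)), float(rng.uniform(0, 2 * np.pi)))
        for k in ks
    )


def _spread_geometry(pop: PopulationConfig, rng: np.random.Generator,
                     mass_pg: float):
    # spread area tracks dry mass (approximately constant dry-mass surface
    # density), with a lognormal density jitter of spread_area_cv; this keeps
    # the phase plateau comparable across cells, as in adherent monolayers
    density = pop.mean_cell_dry_mass_pg / pop.mean_spread_area_um2
    sigma = math.sqrt(math.log(1.0 + pop.spread_area_cv**2))
    area = mass_pg / density * math.exp(rng.normal(-0.5 * sigma**2, sigma))
    area = max(area, pop.debris_area_threshold_um2 * 1.05)
    ratio = float(rng.uniform(*pop.spread_axis_ratio))
    lobes = _sample_lobes(rng, pop.spread_lobe_amp)
    return area, ratio, float(rng.uniform(0, np.pi)), lobes, PROFILE_POWER["spread"]


def _rounded_geometry(pop: PopulationConfig, rng: np.random.Generator):
    area = float(rng.uniform(*pop.rounded_area_um2))
    ratio = float(rng.uniform(*pop.rounded_axis_ratio))
    lobes = _sample_lobes(rng, (0.0, 0.015), n=2)
    return area, ratio, float(rng.uniform(0, np.pi)), lobes, PROFILE_POWER["rounded"]


def _semi_major(area: float, ratio: float) -> float:
    return math.sqrt(area * ratio / np.pi)


class SimulatedFOV:
    """One simulated field of view: per-timepoint cell snapshots plus rendering."""

    def __init__(self, experiment: int, condition: Condition, fov_index: int,
                 optics: OpticsConfig, timepoints_h: tuple, snapshots: list,
                 render_seed: int):
        self.experiment = experiment
        self.condition = condition
        self.fov_index = fov_index
        self.optics = optics
        self.timepoints_h = timepoints_h
        #: list (per timepoint) of snapshot dicts for all non-removed entities
        self.snapshots = snapshots
        self.render_seed = render_seed

    @property
    def fov_id(self) -> str:
        return f"e{self.experiment}_{self.condition.label}_f{self.fov_index}"

    def time_index(self, time_h: float) -> int:
        return self.timepoints_h.index(float(time_h))

    def population_dry_mass_pg(self, time_h: float) -> float:
        rows = self.snapshots[self.time_index(time_h)]
        return float(sum(r["dry_mass_pg"] for r in rows if r["state"] != "removed"))

    def phase_image(self, time_h: float) -> PhaseImage:
        return render_phase(self, time_h)


@dataclass
class GroundTruth:
    """Simulator manifest: per-cell per-timepoint truth and per-FOV totals."""

    cells: pd.DataFrame
    fov_totals: pd.DataFrame

    def fov_dmi_pg(self) -> pd.DataFrame:
        """True 12-h dry-mass change per FOV (last minus first timepoint)."""
        g = self.fov_totals.sort_values("time_h").groupby(
            ["experiment", "condition", "concentration_ug_ml", "fov"], sort=True
        )
        out = g["population_dry_mass_pg"].agg(lambda s: s.iloc[-1] - s.iloc[0])
        return out.reset_index(name="true_dmi_pg")

    def rounded_fraction(self, time_h: float, min_area_um2: float = 350.0) -> pd.DataFrame:
        """Manifest rounded fraction among countable cells (area above the
        debris threshold, not debris/removed) at one timepoint."""
        df = self.cells[
            (self.cells.time_h == time_h)
            & self.cells.state.isin(["spread", "rounded"])
            & (self.cells.area_um2 > min_area_um2)
        ]
        g = df.groupby(["experiment", "condition", "concentration_ug_ml", "fov"])
        out = g.apply(
            lambda d: pd.Series(
                {
                    "n_rounded": int((d.state == "rounded").sum()),
                    "n_total": int(len(d)),
                }
            ),
            include_groups=False,
        ).reset_index()
        out["rounded_fraction"] = out.n_rounded / out.n_total
        return out


@dataclass
class SimulationResult:
    fovs: list
    ground_truth: GroundTruth


def _snapshot_row(fov_meta: dict, time_h: float, cell: _Cell, display_state: str,
                  geom=None) -> dict:
    area, ratio, orient, lobes, power, circ = geom if geom is not None else (
        cell.area_um2, cell.axis_ratio, cell.orientation, cell.lobes,
        cell.profile_power, cell.circularity,
    )
    return {
        **fov_meta,
        "time_h": time_h,
        "cell_id": cell.cell_id,
        "state": display_state,
        "dry_mass_pg": cell.mass_pg,
        "x_um": cell.x_um,
        "y_um": cell.y_um,
        "area_um2": area,
        "axis_ratio": ratio,
        "orientation": orient,
        "lobes": lobes,
        "profile_power": power,
        "circularity": circ,
        "overlap": cell.overlap,
    }


def _place_cells(pop: PopulationConfig, optics: OpticsConfig, n: int,
                 rng: np.random.Generator) -> list:
    """Dart-throwing placement with a minimum centroid separation; after bounded
    retries a cell is placed anyway and flagged as overlapping."""
    cells = []
    m = pop.placement_margin_um
    w, h = optics.fov_width_um, optics.fov_height_um
    for i in range(n):
        sigma = math.sqrt(math.log(1.0 + pop.dry_mass_cv**2))
        mass = pop.mean_cell_dry_mass_pg * math.exp(rng.normal(-0.5 * sigma**2, sigma))
        area, ratio, orient, lobes, power = _spread_geometry(pop, rng, mass)
        a = _semi_major(area, ratio)
        placed = False
        overlap = False
        x = y = 0.0
        for _ in range(pop.placement_max_retries):
            x = rng.uniform(m, w - m)
            y = rng.uniform(m, h - m)
            ok = all(
                math.hypot(x - c.x_um, y - c.y_um)
                >= pop.min_separation_scale
                * (a + _semi_major(c.area_um2, c.axis_ratio))
                for c in cells
            )
            if ok:
                placed = True
                break
        if not placed:
            overlap = True
        cells.append(
            _Cell(
                cell_id=f"c{i}",
                state="spread",
                mass_pg=mass,
                x_um=x,
                y_um=y,
                area_um2=area,
                axis_ratio=ratio,
                orientation=orient,
                lobes=lobes,
                profile_power=power,
                circularity=shape_circularity(ratio, lobes),
                overlap=overlap,
            )
        )
    return cells


def _simulate_fov(pop: PopulationConfig, optics: OpticsConfig, condition: Condition,
                  experiment: int, fov_index: int, growth_factor: float,
                  count_factor: float) -> SimulatedFOV:
    key = [c.label for c in pop.conditions].index(condition.label)
    ss = np.random.SeedSequence(entropy=pop.seed, spawn_key=(experiment, key, fov_index))
    rng = np.random.default_rng(ss)
    render_seed = int(rng.integers(0, 2**31))

    resp = pop.dose_response[condition.agent]
    c = condition.concentration_ug_ml
    e_growth = resp.growth_inhibition.effect(c)
    e_round = resp.rounding.effect(c)
    e_lysis = resp.lysis.effect(c)

    n0 = max(1, int(round(pop.initial_cell_count * count_factor)))
    cells = _place_cells(pop, optics, n0, rng)
    frag_counter = 0

    fov_meta = {
        "experiment": experiment,
        "condition": condition.label,
        "agent": condition.agent,
        "concentration_ug_ml": c,
        "fov": fov_index,
    }
    snapshots = []
    tp = pop.timepoints_h
    for i, t in enumerate(tp):
        rows = []
        for cell in cells:
            if cell.state == "removed":
                continue
            if cell.state == "spread" and rng.random() < pop.baseline_rounding_prob:
                # transient mitotic rounding: displayed rounded at this
                # timepoint only, dry mass conserved
                area, ratio, orient, lobes, power = _rounded_geometry(pop, rng)
                geom = (area, ratio, orient, lobes, power,
                        shape_circularity(ratio, lobes))
                rows.append(_snapshot_row(fov_meta, t, cell, "rounded", geom))
            else:
                rows.append(_snapshot_row(fov_meta, t, cell, cell.state))
        snapshots.append(rows)

        if i == len(tp) - 1:
            break
        dt = tp[i + 1] - t
        new_fragments = []
        for cell in cells:
            if cell.state in ("removed", "debris"):
                continue
            hazard = pop.lysis_rate_per_h * e_lysis
            if cell.state == "rounded":
                hazard *= pop.rounded_lysis_factor
            if hazard > 0 and rng.random() < 1.0 - math.exp(-hazard * dt):
                retained = rng.uniform(*pop.debris_mass_fraction) * cell.mass_pg
                nfrag = int(rng.integers(pop.debris_fragment_count[0],
                                         pop.debris_fragment_count[1] + 1))
                weights = rng.dirichlet(np.ones(nfrag))
                for w in weights:
                    area = float(rng.uniform(*pop.debris_fragment_area_um2))
                    ratio = float(rng.uniform(1.0, 2.0))
                    lobes = _sample_lobes(rng, (0.05, 0.2), n=2)
                    new_fragments.append(
                        _Cell(
                            cell_id=f"{cell.cell_id}_d{frag_counter}",
                            state="debris",
                            mass_pg=float(w * retained),
                            x_um=float(np.clip(cell.x_um + rng.uniform(-15, 15),
                                               0, optics.fov_width_um)),
                            y_um=float(np.clip(cell.y_um + rng.uniform(-15, 15),
                                               0, optics.fov_height_um)),
                            area_um2=area,
                            axis_ratio=ratio,
                            orientation=float(rng.uniform(0, np.pi)),
                            lobes=lobes,
                            profile_power=PROFILE_POWER["debris"],
                            circularity=shape_circularity(ratio, lobes),
                        )
                    )
                    frag_counter += 1
                cell.state = "removed"
                continue
            if cell.state == "spread":
                p_round = 1.0 - math.exp(-pop.rounding_rate_per_h * e_round * dt)
                if rng.random() < p_round:
                    (cell.area_um2, cell.axis_ratio, cell.orientation,
                     cell.lobes, cell.profile_power) = _rounded_geometry(pop, rng)
                    cell.circularity = shape_circularity(cell.axis_ratio, cell.lobes)
                    cell.state = "rounded"
                else:
                    g = pop.growth_rate_per_h * growth_factor * (1.0 - e_growth)
                    factor = math.exp(g * dt)
                    cell.mass_pg *= factor
                    cell.area_um2 *= factor
        cells.extend(new_fragments)

    return SimulatedFOV(experiment, condition, fov_index, optics,
                        tp, snapshots, render_seed)


def simulate_population(pop: PopulationConfig, optics: OpticsConfig) -> SimulationResult:
    """Simulate all experiments × conditions × FOVs of the configured design.

    Returns lazily rendered per-FOV time-lapse stacks (``SimulatedFOV.phase_image``)
    together with the complete ground-truth manifest. All stochastic draws derive
    from ``pop.seed``; identical configs give bit-identical results.
    """
    fovs = []
    for e in range(pop.n_experiments):
        rng_e = np.random.default_rng(
            np.random.SeedSequence(entropy=pop.seed, spawn_key=(10_000 + e,))
        )
        growth_factor = float(np.exp(rng_e.normal(0.0, pop.experiment_growth_cv)))
        count_factor = float(np.exp(rng_e.normal(0.0, pop.experiment_count_cv)))
        for condition in pop.conditions:
            for f in range(pop.n_fov):
                fovs.append(
                    _simulate_fov(pop, optics, condition, e, f,
                                  growth_factor, count_factor)
                )
    cell_rows = []
    total_rows = []
    for fov in fovs:
        for t, rows in zip(fov.timepoints_h, fov.snapshots):
            for r in rows:
                cell_rows.append({k: v for k, v in r.items() if k != "lobes"})
            total_rows.append(
                {
                    "experiment": fov.experiment,
                    "condition": fov.condition.label,
                    "agent": fov.condition.agent,
                    "concentration_ug_ml": fov.condition.concentration_ug_ml,
                    "fov": fov.fov_index,
                    "time_h": t,
                    "population_dry_mass_pg": sum(
                        r["dry_mass_pg"] for r in rows if r["state"] != "removed"
                    ),
                }
            )
    gt = GroundTruth(pd.DataFrame(cell_rows), pd.DataFrame(total_rows))
    return SimulationResult(fovs, gt)


# ---------------------------------------------------------------------------
# rendering


def render_phase(fov: SimulatedFOV, time_h: float,
                 alpha_um3_per_pg: float = 0.19) -> PhaseImage:
    """Rasterize the true (noise-free) phase image of one FOV at one timepoint."""
    optics = fov.optics
    pitch = optics.pixel_pitch_um
    canvas = np.zeros((optics.sensor_rows, optics.sensor_cols))
    for r in fov.snapshots[fov.time_index(time_h)]:
        if r["state"] == "removed" or r["dry_mass_pg"] <= 0:
            continue
        patch = cell_phase_footprint(
            r["dry_mass_pg"], r["area_um2"], r["axis_ratio"], r["state"], pitch,
            orientation=r["orientation"], lobes=r["lobes"],
            profile_power=r["profile_power"],
            alpha_um3_per_pg=alpha_um3_per_pg,
            wavelength_um=optics.wavelength_um,
        )
        half = patch.shape[0] // 2
        ci = int(round(r["x_um"] / pitch))
        ri = int(round(r["y_um"] / pitch))
        r0, r1 = ri - half, ri + half + 1
        c0, c1 = ci - half, ci + half + 1
        pr0, pc0 = max(0, -r0), max(0, -c0)
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(canvas.shape[0], r1), min(canvas.shape[1], c1)
        if r1 <= r0 or c1 <= c0:
            continue
        canvas[r0:r1, c0:c1] += patch[pr0:pr0 + (r1 - r0), pc0:pc0 + (c1 - c0)]
    return PhaseImage(canvas, pitch, wavelength_um=optics.wavelength_um)


def sample_background_aberration(optics: OpticsConfig,
                                 rng: np.random.Generator) -> np.ndarray:
    """Smooth instrument phase background (tilt + curvature) for one timepoint."""
    rows, cols = optics.sensor_rows, optics.sensor_cols
    u = np.linspace(-1.0, 1.0, cols)
    v = np.linspace(-1.0, 1.0, rows)
    uu, vv = np.meshgrid(u, v)
    a = optics.background_aberration_rad
    coef = rng.normal(0.0, a, size=6)
    return (coef[0] * uu + coef[1] * vv + coef[2] * uu * vv
            + coef[3] * uu**2 + coef[4] * vv**2 + coef[5] * 0.0)


def render_hologram(phase: PhaseImage, optics: OpticsConfig, frame_index: int,
                    seed: int, background: Optional[np.ndarray] = None) -> Hologram:
    """Record one off-axis hologram of the given object phase.

    intensity = |reference + object|² with a tilted plane reference at the
    configured carrier frequency and an object wave exp(i(φ + background +
    parasitic)). The parasitic term is a low-frequency sinusoidal phase pattern
    whose orientation is fixed per frame index (emulating the decorrelation of
    coherence-induced disturbances under modulated illumination) and whose
    offset is drawn from ``seed``; shot noise is added last.
    """
    if not 0 <= frame_index <= 6:
        raise ValueError("frame_index must be in 0..6")
    fmag = optics.carrier_magnitude
    lo = 3.0 * optics.object_halfwidth_frac * optics.nyquist_cyc_um
    if not (lo < fmag < optics.nyquist_cyc_um):
        raise ValueError("carrier frequency violates the separability invariant")
    rng = np.random.default_rng(seed)
    rows, cols = phase.shape
    pitch = phase.pixel_pitch_um
    x = np.arange(cols) * pitch
    y = np.arange(rows) * pitch
    xx, yy = np.meshgrid(x, y)

    obj_phase = phase.phase.copy()
    if background is not None:
        obj_phase = obj_phase + background
    ang = np.pi * (frame_index + 0.5) / 7.0
    fpx = optics.parasitic_fringe_freq * math.cos(ang)
    fpy = optics.parasitic_fringe_freq * math.sin(ang)
    offset = rng.uniform(0.0, 2.0 * np.pi)
    obj_phase = obj_phase + optics.parasitic_fringe_amplitude * np.cos(
        2.0 * np.pi * (fpx * xx + fpy * yy) + offset
    )
    obj = np.exp(1j * obj_phase)
    if optics.defocus_um != 0.0:
        from .reconstruct import propagate
        from .fields import ComplexField

        obj = propagate(
            ComplexField(obj, pitch, optics.wavelength_um), optics.defocus_um
        ).data
    fx, fy = optics.carrier_freq
    ref = optics.reference_amplitude * np.exp(
        2j * np.pi * (fx * xx + fy * yy)
    )
    intensity = np.abs(obj + ref) ** 2
    if optics.shot_noise_scale > 0:
        intensity = intensity + rng.normal(size=intensity.shape) * (
            optics.shot_noise_scale * np.sqrt(intensity)
        )
        intensity = np.clip(intensity, 0.0, None)
    return Hologram(intensity, pitch, optics.wavelength_nm,
                    frame_index=frame_index)


def render_series(phase: PhaseImage, optics: OpticsConfig, seed: int,
                  n_frames: int = 7) -> list:
    """Render the per-timepoint series of holograms.

    All frames share the identical cell phase and instrument background but
    carry frame-specific parasitic patterns and independent shot noise, so
    averaging the reconstructed frames suppresses the coherent disturbances.
    """
    rng = np.random.default_rng(seed)
    background = sample_background_aberration(optics, rng)
    seeds = rng.integers(0, 2**31, size=n_frames)
    return [
        render_hologram(phase, optics, k, int(seeds[k]), background=background)
        for k in range(n_frames)
    ]
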
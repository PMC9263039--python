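"""Configuration objects for the simulated DHM cytotoxicity assay.

The defaults describe the acquisition geometry of the emulated instruments
(λ = 532 nm, 450 µm × 338 µm field of view, 7 off-axis holograms per position
and time point, images every 60 min for 12 h) and a plate layout with a medium
control, a detergent cytotoxicity control and particle-like agents on
four-point concentration grids, observed in n = 3 fields of view per condition
across N = 3 independent experiments.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "OpticsConfig",
    "HillCurve",
    "AgentResponse",
    "Condition",
    "PopulationConfig",
    "SegmentationParams",
    "DryMassParams",
    "LabVariant",
    "AssayConfig",
    "default_conditions",
    "default_dose_response",
    "load_config",
    "save_config",
]


@dataclass
class OpticsConfig:
    """Off-axis interferometer geometry and noise model.

    ``carrier_freq`` is the spatial frequency of the tilted reference in
    cycles/µm; the default places it on the diagonal at one third of the
    Nyquist frequency per axis, the standard compromise between sideband
    separability and spatial resolution.
    """

    wavelength_nm: float = 532.0
    fov_width_um: float = 450.0
    fov_height_um: float = 338.0
    sensor_cols: int = 1024
    sensor_rows: int = 770
    carrier_freq: Optional[tuple] = None  # (fx, fy) cycles/um; None -> diagonal Nyquist/3
    reference_amplitude: float = 2.0
    shot_noise_scale: float = 0.05
    parasitic_fringe_amplitude: float = 0.08  # rad, per-frame coherent disturbance
    parasitic_fringe_freq: float = 0.012  # cycles/um
    background_aberration_rad: float = 0.3  # peak scale of the smooth phase background
    defocus_um: float = 0.0
    #: nominal half-width of the object spectrum as a fraction of Nyquist,
    #: used only for the sideband-separability validity check
    object_halfwidth_frac: float = 0.12

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.fov_width_um <= 0 or self.fov_height_um <= 0:
            raise ValueError("FOV dimensions must be positive")
        px = self.fov_width_um / self.sensor_cols
        py = self.fov_height_um / self.sensor_rows
        if abs(px - py) / px > 0.01:
            raise ValueError(
                f"pixel pitch must be square within 1% (got {px:.4f} x {py:.4f} um)"
            )
        if self.carrier_freq is None:
            f = self.nyquist_cyc_um / 3.0
            self.carrier_freq = (f, f)
        else:
            self.carrier_freq = (float(self.carrier_freq[0]), float(self.carrier_freq[1]))
        fmag = float(np.hypot(*self.carrier_freq))
        lo = 3.0 * self.object_halfwidth_frac * self.nyquist_cyc_um
        if not (lo < fmag < self.nyquist_cyc_um):
            raise ValueError(
                f"carrier magnitude {fmag:.3f} cycles/um must lie strictly between "
                f"{lo:.3f} (3x object spectrum half-width) and the Nyquist limit "
                f"{self.nyquist_cyc_um:.3f}"
            )

    @property
    def pixel_pitch_um(self) -> float:
        return self.fov_width_um / self.sensor_cols

    @property
    def nyquist_cyc_um(self) -> float:
        return 1.0 / (2.0 * self.pixel_pitch_um)

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def carrier_magnitude(self) -> float:
        return float(np.hypot(*self.carrier_freq))


@dataclass
class HillCurve:
    """Sigmoidal dose–response: effect(c) = max_effect * c^h / (c^h + ec50^h)."""

    ec50_ug_ml: float = 1.0
    coef: float = 1.0
    max_effect: float = 0.0

    def effect(self, concentration: float) -> float:
        from .simulate import hill_effect

        if self.max_effect == 0.0:
            return 0.0
        return self.max_effect * hill_effect(concentration, self.ec50_ug_ml, self.coef)


@dataclass
class AgentResponse:
    """Per-agent dose–response shapes for the three modelled effects."""

    growth_inhibition: HillCurve = field(default_factory=HillCurve)
    rounding: HillCurve = field(default_factory=HillCurve)
    lysis: HillCurve = field(default_factory=HillCurve)


@dataclass
class Condition:
    label: str
    agent: str = "medium"  # medium | detergent | cytostatic | inert
    concentration_ug_ml: float = 0.0


def default_dose_response() -> dict:
    """Dose–response defaults for the four agent classes.

    detergent: cells round up early, then lyse with dry-mass loss (steep lysis
    curve so the highest grid concentration destroys most of the population);
    cytostatic: concentration-dependent rounding and growth arrest with
    conserved per-cell dry mass; inert: measurable rounding only near the top
    of the concentration grid; medium: no effect.
    """
    return {
        "medium": AgentResponse(),
        "detergent": AgentResponse(
            growth_inhibition=HillCurve(8.0, 1.5, 1.0),
            rounding=HillCurve(8.0, 1.5, 1.0),
            lysis=HillCurve(60.0, 3.0, 1.0),
        ),
        "cytostatic": AgentResponse(
            growth_inhibition=HillCurve(6.0, 1.3, 0.85),
            rounding=HillCurve(6.0, 1.3, 0.85),
        ),
        "inert": AgentResponse(
            growth_inhibition=HillCurve(300.0, 2.0, 0.3),
            rounding=HillCurve(150.0, 2.5, 0.7),
        ),
    }


def default_conditions() -> list:
    """Medium control, detergent control and two particle-like agents on the
    study's four-point concentration grids."""
    conds = [Condition("medium", "medium", 0.0)]
    conds += [
        Condition(f"detergent_{c:g}", "detergent", c) for c in (0.1, 5.5, 20.0, 140.0)
    ]
    conds += [Condition(f"particle_{c:g}", "inert", c) for c in (2.0, 8.0, 32.0, 128.0)]
    conds += [
        Condition(f"particle_drug_{c:g}", "cytostatic", c)
        for c in (2.0, 8.0, 32.0, 128.0)
    ]
    return conds


@dataclass
class PopulationConfig:
    """Simulated adherent epithelial cell population and its dynamics.

    Rates are per hour; probabilities per step are derived as 1 - exp(-rate*dt)
    and therefore always in [0, 1]. ``baseline_rounding_prob`` is the chance of
    a spread cell appearing transiently rounded (mitosis) at any one time point
    in untreated controls.
    """

    initial_cell_count: int = 50
    mean_cell_dry_mass_pg: float = 300.0
    dry_mass_cv: float = 0.20
    mean_spread_area_um2: float = 550.0
    #: lognormal jitter of the dry-mass surface density (area tracks mass)
    spread_area_cv: float = 0.10
    spread_axis_ratio: tuple = (2.6, 3.8)
    spread_lobe_amp: tuple = (0.04, 0.10)
    rounded_axis_ratio: tuple = (1.0, 1.08)
    rounded_area_um2: tuple = (360.0, 520.0)
    growth_rate_per_h: float = 0.03
    baseline_rounding_prob: float = 0.10
    rounding_rate_per_h: float = 0.35
    lysis_rate_per_h: float = 0.12
    #: hazard multiplier for rounded (dying) cells, which detach and lyse
    #: first; must dominate the spread-state decay rate at saturating doses
    #: so that the rounded pool itself drains into sub-threshold debris
    rounded_lysis_factor: float = 15.0
    debris_mass_fraction: tuple = (0.15, 0.35)
    debris_fragment_area_um2: tuple = (40.0, 200.0)
    debris_fragment_count: tuple = (2, 4)
    conditions: list = field(default_factory=default_conditions)
    dose_response: dict = field(default_factory=default_dose_response)
    timepoints_h: tuple = tuple(float(t) for t in range(13))
    n_fov: int = 3
    n_experiments: int = 3
    seed: int = 0
    placement_margin_um: float = 40.0
    min_separation_scale: float = 0.7  # of the sum of semi-major axes
    placement_max_retries: int = 50
    experiment_growth_cv: float = 0.12
    experiment_count_cv: float = 0.08
    debris_area_threshold_um2: float = 350.0

    def __post_init__(self) -> None:
        if self.initial_cell_count <= 0:
            raise ValueError("initial_cell_count must be positive")
        for name in ("growth_rate_per_h", "rounding_rate_per_h", "lysis_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.baseline_rounding_prob <= 1.0:
            raise ValueError("baseline_rounding_prob must be in [0, 1]")
        tp = tuple(float(t) for t in self.timepoints_h)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing with >= 2 entries")
        self.timepoints_h = tp
        if self.mean_spread_area_um2 <= self.debris_area_threshold_um2:
            raise ValueError(
                "mean_spread_area_um2 must exceed the debris area threshold so "
                "healthy cells are never filtered out"
            )
        if self.rounded_area_um2[0] <= self.debris_area_threshold_um2:
            raise ValueError("rounded cell areas must exceed the debris threshold")
        if self.debris_fragment_area_um2[1] >= self.debris_area_threshold_um2:
            raise ValueError("debris fragments must stay below the debris threshold")
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise ValueError("condition labels must be unique")


@dataclass
class SegmentationParams:
    """Threshold segmentation and circularity classification parameters.

    ``min_area_um2`` implements the debris filter S_cell > 350 µm²;
    ``c_round`` the rounded-cell rule C > 0.8.
    """

    threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold_rad: float = 0.5
    otsu_floor_rad: float = 0.15
    min_area_um2: float = 350.0
    fill_holes: bool = True
    c_round: float = 0.8
    exclude_border: bool = False
    #: dilation (µm) of the region footprint used only for the per-region
    #: dry-mass integral, capturing the soft phase skirt at the cell boundary;
    #: shape metrics always use the undilated mask
    mass_dilation_um: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")
        if not 0.0 < self.c_round < 1.0:
            raise ValueError("c_round must be in (0, 1)")


@dataclass
class DryMassParams:
    """Constants of the phase-to-dry-mass conversion dm = λ/(2πα)·Δφ̄·S_FOV."""

    alpha_um3_per_pg: float = 0.19
    wavelength_um: float = 0.532

    def __post_init__(self) -> None:
        if self.alpha_um3_per_pg <= 0 or self.wavelength_um <= 0:
            raise ValueError("alpha and wavelength must be positive")


@dataclass
class LabVariant:
    """Parameter perturbation emulating a second laboratory running the SOP."""

    label: str
    cell_count_multiplier: float = 1.0
    growth_multiplier: float = 1.0
    noise_multiplier: float = 1.0


@dataclass
class AssayConfig:
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    drymass: DryMassParams = field(default_factory=DryMassParams)
    lab_variants: Optional[list] = None
    out_dir: Optional[str] = None
    seed: int = 0
    #: subset of timepoints to image/reconstruct (None = all simulated timepoints)
    render_timepoints_h: Optional[tuple] = None
    refocus: str = "off"  # off | auto | "<distance in um>"
    filter_radius_frac: float = 0.75  # of the carrier magnitude (Hann rolloff)
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.lab_variants is not None:
            labels = [v.label for v in self.lab_variants]
            if len(labels) != len(set(labels)):
                raise ValueError("lab_variants must have distinct labels")

    def rendered_timepoints(self) -> tuple:
        if self.render_timepoints_h is None:
            return self.population.timepoints_h
        tp = tuple(float(t) for t in self.render_timepoints_h)
        missing = [t for t in tp if t not in self.population.timepoints_h]
        if missing:
            raise ValueError(f"render timepoints {missing} not in simulated timepoints")
        return tp


# ---------------------------------------------------------------------------
# (de)serialization


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config: AssayConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> AssayConfig:
    data = dict(data)
    pop = dict(data.get("population", {}))
    if "conditions" in pop:
        pop["conditions"] = [Condition(**c) for c in pop["conditions"]]
    if "dose_response" in pop:
        pop["dose_response"] = {
            agent: AgentResponse(**{k: HillCurve(**v) for k, v in resp.items()})
            for agent, resp in pop["dose_response"].items()
        }
    for key in ("timepoints_h",):
        if key in pop:
            pop[key] = tuple(pop[key])
    optics = dict(data.get("optics", {}))
    if optics.get("carrier_freq") is not None:
        optics["carrier_freq"] = tuple(optics["carrier_freq"])
    variants = data.get("lab_variants")
    return AssayConfig(
        optics=OpticsConfig(**optics),
        population=PopulationConfig(**pop),
        segmentation=SegmentationParams(**data.get("segmentation", {})),
        drymass=DryMassParams(**data.get("drymass", {})),
        lab_variants=[LabVariant(**v) for v in variants] if variants else None,
        out_dir=data.get("out_dir"),
        seed=int(data.get("seed", 0)),
        render_timepoints_h=(
            tuple(data["render_timepoints_h"])
            if data.get("render_timepoints_h") is not None
            else None
        ),
        refocus=data.get("refocus", "off"),
        filter_radius_frac=float(data.get("filter_radius_frac", 0.4)),
        poly_order=int(data.get("poly_order", 2)),
    )


def load_config(path) -> AssayConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: AssayConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
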
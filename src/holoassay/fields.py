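"""Core image/field containers shared by the simulator and the reconstruction stages.

All spatial quantities are in micrometres, phase in radians. Pixel grids are
row-major with the origin at the top-left corner (0-based indices); the x
coordinate runs along columns, y along rows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Hologram", "ComplexField", "PhaseImage"]

#: minimum sensor dimension accepted by the reconstruction stages
MIN_DIM = 64


@dataclass
class Hologram:
    """A recorded off-axis intensity image with pixel geometry and wavelength metadata."""

    intensity: np.ndarray
    pixel_pitch_um: float
    wavelength_nm: float
    fov_id: Optional[str] = None
    time_h: Optional[float] = None
    frame_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be a 2D array")
        if min(self.intensity.shape) < MIN_DIM:
            raise ValueError(
                f"hologram dimensions must be >= {MIN_DIM}, got {self.intensity.shape}"
            )
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")
        if self.pixel_pitch_um <= 0 or self.wavelength_nm <= 0:
            raise ValueError("pixel pitch and wavelength must be positive")

    @property
    def shape(self) -> tuple:
        return self.intensity.shape


@dataclass
class ComplexField:
    """A complex object wave sampled on the sensor grid (amplitude + phase)."""

    data: np.ndarray
    pixel_pitch_um: float
    wavelength_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("field must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field must be finite everywhere")
        if self.pixel_pitch_um <= 0 or self.wavelength_um <= 0:
            raise ValueError("pixel pitch and wavelength must be positive")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def power(self) -> float:
        """Total power (sum of squared magnitudes)."""
        return float(np.sum(np.abs(self.data) ** 2))


@dataclass
class PhaseImage:
    """An unwrapped (and, downstream, background-compensated) phase map in radians.

    The boolean ``mask`` marks valid pixels; invalid pixels (apodized border,
    unresolved unwrapping residues) are excluded from all statistics.
    """

    phase: np.ndarray
    pixel_pitch_um: float
    mask: Optional[np.ndarray] = None
    wavelength_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase must be a 2D array")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.mask is None:
            self.mask = np.ones(self.phase.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.phase.shape:
                raise ValueError("mask shape must match phase shape")

    @property
    def shape(self) -> tuple:
        return self.phase.shape

    @property
    def fov_area_um2(self) -> float:
        """S_FOV = rows * cols * pixel_pitch**2."""
        r, c = self.phase.shape
        return r * c * self.pixel_pitch_um**2

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.mask))

    def mean_phase(self) -> float:
        """Mean phase shift over valid pixels (the dry-mass formula input)."""
        return float(np.mean(self.phase[self.mask]))
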
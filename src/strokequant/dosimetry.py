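"""Electrode geometry and current dosimetry for epicranial direct-current
stimulation.

The stimulation dose is specified as a current density (A/m²) over a
saline-filled cylindrical electrode of known inner diameter; these helpers
convert between diameter, contact area and absolute current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Current densities (A/m²) of the four standard treatment arms:
#: sham plus three active anodal intensities.
STANDARD_DENSITIES = (0.0, 0.8, 31.8, 47.8)


@dataclass(frozen=True)
class StimulationProtocol:
    """One stimulation arm: dose, timing and electrode geometry.

    current_density in A/m², duration in minutes, ramp (up and down) in
    seconds, electrode inner diameter in mm. ``contact_area`` (mm²) is
    derived from the diameter unless given explicitly.
    """

    current_density: float
    duration_min: float = 20.0
    ramp_s: float = 1.0
    electrode_inner_diameter_mm: float = 4.0
    contact_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.current_density < 0:
            raise ValueError("current_density must be >= 0")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        area = self.contact_area_mm2
        if area is None:
            area = electrode_contact_area(self.electrode_inner_diameter_mm)
            object.__setattr__(self, "contact_area_mm2", area)
        if area <= 0:
            raise ValueError("contact_area must be positive")

    @property
    def current_uA(self) -> float:
        return current_for_density(self.current_density, self.contact_area_mm2)


def electrode_contact_area(inner_diameter_mm: float) -> float:
    """Contact area (mm²) of a circular electrode of given inner diameter (mm).

    >>> electrode_contact_area(4.0)  # doctest: +ELLIPSIS
    12.56637...
    """
    if inner_diameter_mm <= 0:
        raise ValueError("inner diameter must be positive")
    return math.pi * (inner_diameter_mm / 2.0) ** 2


def printed_contact_area(inner_diameter_mm: float) -> float:
    """Contact area truncated (not rounded) to two decimals, the convention
    used when such areas are reported (4 mm -> 12.56 mm²)."""
    return math.floor(electrode_contact_area(inner_diameter_mm) * 100) / 100


def current_for_density(density_A_per_m2: float, area_mm2: float) -> float:
    """Absolute current in µA delivering ``density`` (A/m²) over ``area`` (mm²).

    I = J * A; 1 mm² = 1e-6 m², 1 A = 1e6 µA, so numerically I[µA] =
    J[A/m²] * A[mm²].
    """
    if density_A_per_m2 < 0:
        raise ValueError("current density must be >= 0")
    if area_mm2 <= 0:
        raise ValueError("contact area must be positive")
    return density_A_per_m2 * area_mm2
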
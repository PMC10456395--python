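"""Pore-array geometry of ultra-thin microsieve membranes.

Silicon-nitride microsieves carry a hexagonal array of circular pores on a
square active area; a chip tiles many such membranes.  This module collects
the small geometric identities used to report a filter: hexagonal-lattice
porosity, porosity rescaling from designed to as-fabricated pore diameter
(photolithographic loading shrinks holes at fixed pitch), total active area,
and the pore aspect ratio (diameter over membrane thickness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HEX_PACKING",
    "hex_porosity",
    "pitch_for_porosity",
    "rescale_porosity",
    "total_active_area",
    "aspect_ratio",
    "PoreArrayGeometry",
]

#: Areal packing prefactor of a hexagonal lattice of circles, pi / (2 sqrt 3).
HEX_PACKING = math.pi / (2.0 * math.sqrt(3.0))


def hex_porosity(d_um: float, pitch_um: float) -> float:
    """Open-area fraction of a hexagonal pore array.

    porosity = (pi / (2 sqrt 3)) * (d / pitch)^2, maximal (~0.9069) as the
    pores touch.
    """
    if d_um <= 0:
        raise ValueError(f"pore diameter must be > 0, got {d_um}")
    if pitch_um <= d_um:
        raise ValueError(
            f"pitch ({pitch_um}) must exceed pore diameter ({d_um}); pores overlap"
        )
    return HEX_PACKING * (d_um / pitch_um) ** 2


def pitch_for_porosity(d_um: float, porosity: float) -> float:
    """Pitch giving a target porosity at pore diameter ``d_um`` (inverse of
    :func:`hex_porosity`)."""
    if d_um <= 0:
        raise ValueError(f"pore diameter must be > 0, got {d_um}")
    if not 0 < porosity < HEX_PACKING:
        raise ValueError(f"porosity must be in (0, {HEX_PACKING:.4f}), got {porosity}")
    return d_um * math.sqrt(HEX_PACKING / porosity)


def rescale_porosity(designed_porosity_pct: float, designed_d_um: float,
                     actual_d_um: float) -> float:
    """As-fabricated porosity from the designed one, assuming fixed pitch.

    Fabrication shrinks hole diameters but not the lattice pitch, so
    porosity scales as d^2: ``designed * (actual_d / designed_d)^2``.
    Returned in percent, rounded to 0.1.
    """
    if designed_d_um <= 0:
        raise ValueError(f"designed diameter must be > 0, got {designed_d_um}")
    if actual_d_um <= 0:
        raise ValueError(f"actual diameter must be > 0, got {actual_d_um}")
    if designed_porosity_pct <= 0:
        raise ValueError(f"designed porosity must be > 0, got {designed_porosity_pct}")
    return round(designed_porosity_pct * (actual_d_um / designed_d_um) ** 2, 1)


def total_active_area(membranes: int, side_mm: float) -> float:
    """Total patterned area (mm^2) of ``membranes`` square active windows."""
    if membranes < 0:
        raise ValueError(f"membrane count must be >= 0, got {membranes}")
    if side_mm <= 0:
        raise ValueError(f"active side must be > 0, got {side_mm}")
    return membranes * side_mm**2


def aspect_ratio(d_um: float, thickness_um: float) -> float:
    """Pore diameter over membrane thickness, rounded to 0.1.

    A high aspect ratio (pore much wider than the membrane is thick) keeps
    shear on passing cells short, minimizing damage.
    """
    if d_um <= 0 or thickness_um <= 0:
        raise ValueError("diameter and thickness must be > 0")
    return round(d_um / thickness_um, 1)


@dataclass(frozen=True)
class PoreArrayGeometry:
    """One microsieve design: pore array plus chip layout."""

    pore_diameter_um: float
    pitch_um: float
    thickness_um: float
    membranes: int
    membrane_active_side_mm: float

    def __post_init__(self) -> None:
        for name in ("pore_diameter_um", "pitch_um", "thickness_um",
                     "membrane_active_side_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pore_diameter_um >= self.pitch_um:
            raise ValueError("pore diameter must be smaller than the pitch")
        if self.membranes < 0:
            raise ValueError("membranes must be >= 0")

    @property
    def porosity(self) -> float:
        return hex_porosity(self.pore_diameter_um, self.pitch_um)

    @property
    def total_active_area_mm2(self) -> float:
        return total_active_area(self.membranes, self.membrane_active_side_mm)

    @property
    def aspect_ratio(self) -> float:
        return aspect_ratio(self.pore_diameter_um, self.thickness_um)

    def to_dict(self) -> dict:
        return {
            "pore_diameter_um": self.pore_diameter_um,
            "pitch_um": self.pitch_um,
            "thickness_um": self.thickness_um,
            "membranes": self.membranes,
            "membrane_active_side_mm": self.membrane_active_side_mm,
            "porosity_pct": round(100.0 * self.porosity, 1),
            "total_active_area_mm2": round(self.total_active_area_mm2, 1),
            "aspect_ratio": self.aspect_ratio,
        }
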
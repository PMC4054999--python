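"""Stereological and morphometric estimators for healing wounds.

The quantities, with the units they are conventionally reported in:

* percentage wound closure          %C  = (A0 - Ai)/A0 × 100
* wound volume                      V   = mean(six thicknesses) × traced area   [mm³]
* surface density of vessels        Sv  = 2·I / L_T                             [mm⁻¹]
* length density of vessels         Lv  = 2·I / (L_T · T_s)                     [mm⁻²]
* radial diffusion (Krogh) distance R   = 1/sqrt(π · Lv)                        [μm]
* vessel diameter                   d   = (Sv / (π · Lv)) × shrinkage           [μm]
* volume fraction (point counting)  Vv  = P_p / P_T                             [-]
* totals                            density × wound volume

``I`` is the intersection count of the appropriate cycloid system with vessel
profiles, ``L_T`` the total test-line length, ``T_s`` the section thickness
(5 μm), and the shrinkage factor (default 1.6) corrects vessel diameter for
tissue dimension loss during histological processing; densities and the
diffusion distance are reported uncorrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .counting import FieldCounts
from .errors import EstimationError, InvalidParameterError

__all__ = [
    "WoundMeasurement",
    "wound_closure",
    "surface_density",
    "length_density",
    "radial_diffusion",
    "vessel_diameter",
    "volume_fraction",
    "wound_volume",
    "totals",
    "epithelialization_percent",
    "estimate_wound",
    "MM_PER_UM",
    "UM_PER_MM",
]

MM_PER_UM = 1e-3
UM_PER_MM = 1e3

DEFAULT_SHRINKAGE = 1.6
DEFAULT_SECTION_THICKNESS_MM = 5e-3


@dataclass
class WoundMeasurement:
    """One wound's complete record: inputs, densities and derived totals.

    Areas in mm², thicknesses and volume in mm/mm³, Sv in mm⁻¹, Lv in mm⁻²,
    Rdiff and diameter in μm, Vv as a fraction.  ``epithelialization`` may be
    None when not measured; it is never imputed.
    """

    wound_id: str
    group: str
    A0: float
    A7: float
    thicknesses: tuple
    volume: float
    closure: float
    Sv: float
    Lv: float
    Rdiff: float
    diameter: float
    Vv: float
    surface_area_total: float
    length_total: float
    inflam_volume_total: float
    epithelialization: float | None = None

    def to_row(self) -> dict:
        return {
            "wound_id": self.wound_id,
            "group": self.group,
            "Percentage wound closure (%)": self.closure,
            "Wound volume (mm^3)": self.volume,
            "Total volume of inflammatory cells (mm^3)": self.inflam_volume_total,
            "Surface density of blood vessels in wound (mm^-1)": self.Sv,
            "Surface area of blood vessels (mm^2)": self.surface_area_total,
            "Length density of blood vessels in wound (mm^-2)": self.Lv,
            "Total length of blood vessels in wound (mm)": self.length_total,
            "Radial diffusion distance (um)": self.Rdiff,
            "Vessel diameter (um)": self.diameter,
            "Inflammatory cell volume fraction": self.Vv,
            "Percentage epithelialization (%)": self.epithelialization,
        }


def wound_closure(A0: float, Ai: float) -> float:
    """Percentage wound closure from day-0 and later traced areas (mm²)."""
    if A0 <= 0:
        raise InvalidParameterError("A0 must be > 0")
    if Ai < 0:
        raise InvalidParameterError("Ai must be >= 0")
    return (A0 - Ai) / A0 * 100.0


def surface_density(I: float, L_T: float) -> float:
    """Sv = 2I/L_T; with L_T in mm the result is mm⁻¹ (mm² surface per mm³)."""
    if L_T <= 0:
        raise InvalidParameterError("L_T must be > 0")
    if I < 0:
        raise InvalidParameterError("I must be >= 0")
    return 2.0 * I / L_T


def length_density(I: float, L_T: float, T_s: float = DEFAULT_SECTION_THICKNESS_MM) -> float:
    """Lv = 2I/(L_T·T_s): projected thick-section (Gokhale) length density.

    With L_T and T_s in mm the result is mm⁻² (mm of vessel per mm³).
    """
    if L_T <= 0 or T_s <= 0:
        raise InvalidParameterError("L_T and T_s must be > 0")
    if I < 0:
        raise InvalidParameterError("I must be >= 0")
    return 2.0 * I / (L_T * T_s)


def radial_diffusion(Lv: float) -> float:
    """Krogh radius 1/sqrt(π·Lv), returned in μm for Lv in mm⁻².

    The mean tissue radius served by one capillary; smaller means a more
    efficient vascular network.
    """
    if Lv <= 0:
        raise InvalidParameterError("Lv must be > 0")
    return 1.0 / math.sqrt(math.pi * Lv) * UM_PER_MM


def vessel_diameter(Sv: float, Lv: float, shrinkage: float = DEFAULT_SHRINKAGE) -> float:
    """Mean vessel diameter (Sv/(π·Lv)) × shrinkage, in μm for mm-based densities.

    For cylinders Sv = π·d·Lv exactly, so Sv/(π·Lv) recovers d; the shrinkage
    factor (default 1.6) compensates processing-induced tissue shrinkage.
    """
    if Lv <= 0:
        raise InvalidParameterError("Lv must be > 0")
    if shrinkage <= 0:
        raise InvalidParameterError("shrinkage must be > 0")
    return Sv / (Lv * math.pi) * shrinkage * UM_PER_MM


def volume_fraction(P_p: float, P_T: float) -> float:
    """Vv = P_p/P_T from point counting."""
    if P_T <= 0:
        raise EstimationError("P_T must be > 0: no tissue reference points")
    if not 0 <= P_p <= P_T:
        raise InvalidParameterError("need 0 <= P_p <= P_T")
    return P_p / P_T


def wound_volume(thicknesses: Sequence[float], traced_area: float) -> float:
    """Mean of six wound-thickness readings (mm) × traced wound area (mm²)."""
    th = tuple(float(t) for t in thicknesses)
    if len(th) != 6:
        raise InvalidParameterError(f"exactly six thickness readings required, got {len(th)}")
    if min(th) <= 0 or traced_area <= 0:
        raise InvalidParameterError("thicknesses and traced_area must be > 0")
    return float(np.mean(th)) * traced_area


def totals(density: float, volume: float) -> float:
    """Absolute amount: density (mm⁻¹, mm⁻² or fraction) × wound volume (mm³)."""
    if volume < 0:
        raise InvalidParameterError("volume must be >= 0")
    return density * volume


def epithelialization_percent(
    new_epithelium_lengths: Iterable[float], edge_to_edge_distance: float
) -> float:
    """Percentage of the wound span covered by newly formed epithelium."""
    lengths = [float(x) for x in new_epithelium_lengths]
    if edge_to_edge_distance <= 0:
        raise InvalidParameterError("edge_to_edge_distance must be > 0")
    if any(x < 0 for x in lengths):
        raise InvalidParameterError("epithelium lengths must be >= 0")
    total = sum(lengths)
    if total > edge_to_edge_distance * (1 + 1e-9):
        raise InvalidParameterError("epithelium cannot exceed the wound span")
    return total / edge_to_edge_distance * 100.0


def estimate_wound(
    fields: Sequence[FieldCounts],
    wound_id: str,
    group: str,
    A0: float,
    A7: float,
    thicknesses: Sequence[float],
    section_thickness_mm: float = DEFAULT_SECTION_THICKNESS_MM,
    shrinkage: float = DEFAULT_SHRINKAGE,
    aggregate: str = "ratio_of_sums",
    epithelialization: float | None = None,
) -> WoundMeasurement:
    """Pool field counts into one wound's full stereological record.

    Default aggregation pools raw counts across all fields and sections before
    applying the formulas (ratio of sums) — the standard design-based
    practice.  ``aggregate='per_field_mean'`` instead averages per-field
    density estimates (mean of ratios) for sensitivity analysis; fields with
    no valid reference points are skipped there.
    """
    fields = list(fields)
    if not fields or not any(f.P_T > 0 for f in fields):
        raise EstimationError("no usable fields (need at least one with P_T > 0)")
    if aggregate == "ratio_of_sums":
        I_s = sum(f.I_surface for f in fields)
        I_l = sum(f.I_length for f in fields)
        LT_s = sum(f.L_T_surface for f in fields) * MM_PER_UM
        LT_l = sum(f.L_T_length for f in fields) * MM_PER_UM
        P_p = sum(f.P_p for f in fields)
        P_T = sum(f.P_T for f in fields)
        Sv = surface_density(I_s, LT_s)
        Lv = length_density(I_l, LT_l, section_thickness_mm)
        Vv = volume_fraction(P_p, P_T)
    elif aggregate == "per_field_mean":
        svs = [surface_density(f.I_surface, f.L_T_surface * MM_PER_UM) for f in fields]
        lvs = [
            length_density(f.I_length, f.L_T_length * MM_PER_UM, section_thickness_mm)
            for f in fields
        ]
        vvs = [volume_fraction(f.P_p, f.P_T) for f in fields if f.P_T > 0]
        Sv, Lv, Vv = float(np.mean(svs)), float(np.mean(lvs)), float(np.mean(vvs))
    else:
        raise InvalidParameterError(f"unknown aggregate mode {aggregate!r}")
    volume = wound_volume(thicknesses, A7)
    closure = wound_closure(A0, A7)
    Rdiff = radial_diffusion(Lv) if Lv > 0 else float("inf")
    diameter = vessel_diameter(Sv, Lv, shrinkage) if Lv > 0 else float("nan")
    return WoundMeasurement(
        wound_id=wound_id,
        group=group,
        A0=A0,
        A7=A7,
        thicknesses=tuple(float(t) for t in thicknesses),
        volume=volume,
        closure=closure,
        Sv=Sv,
        Lv=Lv,
        Rdiff=Rdiff,
        diameter=diameter,
        Vv=Vv,
        surface_area_total=totals(Sv, volume),
        length_total=totals(Lv, volume),
        inflam_volume_total=totals(Vv, volume),
        epithelialization=epithelialization,
    )
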
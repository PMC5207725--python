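"""Intrinsic clearance scaling (IVIVE) for spheroid depletion rate constants.

A fitted depletion rate constant k (h⁻¹) is scaled to in vitro intrinsic
clearance Cl_int,in-vitro (mL h⁻¹ cell⁻¹) and extrapolated to intrinsic
hepatic clearance Cl_int,hepatic (mL h⁻¹ g liver⁻¹) via hepatocellularity
(hepatocytes per gram liver).  Two scaling modes are provided:

``paper_literal``
    k divided by total cell number per well — the published formula for this
    assay, dimensionally loose but kept as the default for fidelity to the
    original analysis.
``volume_corrected``
    k·V/N with V the well volume in mL — the standard substrate-depletion
    scaling that yields true volume-per-time-per-cell units.

Both modes are one flag apart and every output carries its mode so the two are
never silently mixed.  Literature clearance values reported per mg S9 protein
or per 10⁶ hepatocytes are converted onto the same per-gram-liver scale with
species-specific factors (human: 120×10⁶ hepatocytes/g, 50 mg S9 protein/g;
trout: the spheroid-derived 91×10⁶ hepatocytes/g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ScalingFactors",
    "ClearanceResult",
    "clint_in_vitro",
    "clint_hepatic",
    "convert_literature_clearance",
    "literature_from_hepatic",
    "MODES",
    "LITERATURE_UNITS",
]

MODES = ("paper_literal", "volume_corrected")

UNIT_S9 = "uL/min/mg_S9"
UNIT_HEPATOCYTES = "uL/min/1e6_hepatocytes"
UNIT_PER_G_LIVER = "mL/h/g_liver"
LITERATURE_UNITS = (UNIT_S9, UNIT_HEPATOCYTES, UNIT_PER_G_LIVER)

_MIN_PER_H_OVER_UL_PER_ML = 60.0 / 1000.0  # µL min⁻¹ → mL h⁻¹


@dataclass(frozen=True)
class ScalingFactors:
    """Cell, volume and hepatocellularity constants for clearance scaling.

    ``cells_per_well`` defaults to cells_per_spheroid × spheroids_per_well
    (500 × 100 = 50,000) when not overridden.
    """

    cells_per_spheroid: int = 500
    spheroids_per_well: int = 100
    cells_per_well: int | None = None
    well_volume_mL: float = 0.075
    trout_spheroid_hepatocellularity_per_g: float = 91e6
    human_hepatocellularity_per_g: float = 120e6
    human_s9_protein_mg_per_g: float = 50.0

    def __post_init__(self) -> None:
        if self.cells_per_well is None:
            object.__setattr__(
                self, "cells_per_well",
                self.cells_per_spheroid * self.spheroids_per_well,
            )
        for name in (
            "cells_per_spheroid", "spheroids_per_well", "cells_per_well",
            "well_volume_mL", "trout_spheroid_hepatocellularity_per_g",
            "human_hepatocellularity_per_g", "human_s9_protein_mg_per_g",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")

    def hepatocellularity(self, species: str) -> float:
        if species == "human":
            return self.human_hepatocellularity_per_g
        if species == "trout":
            return self.trout_spheroid_hepatocellularity_per_g
        raise ValueError(f"unknown species {species!r}; expected human or trout")


@dataclass(frozen=True)
class ClearanceResult:
    fish_id: str
    compound: str
    mode: str
    cl_int_in_vitro_mL_per_h_per_cell: float
    cl_int_hepatic_mL_per_h_per_g: float


def clint_in_vitro(
    k_h: float, factors: ScalingFactors, mode: str = "paper_literal"
) -> float:
    """In vitro intrinsic clearance (mL h⁻¹ cell⁻¹) from a rate constant."""
    if k_h < 0:
        raise ValueError("k must be non-negative")
    if mode == "paper_literal":
        return k_h / factors.cells_per_well
    if mode == "volume_corrected":
        return k_h * factors.well_volume_mL / factors.cells_per_well
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def clint_hepatic(cl_in_vitro: float, factors: ScalingFactors) -> float:
    """Hepatic intrinsic clearance (mL h⁻¹ g liver⁻¹): scale by trout
    spheroid-derived hepatocellularity."""
    if cl_in_vitro < 0:
        raise ValueError("clearance must be non-negative")
    return cl_in_vitro * factors.trout_spheroid_hepatocellularity_per_g


def scale_fit(
    fish_id: str,
    compound: str,
    k_h: float,
    factors: ScalingFactors,
    mode: str = "paper_literal",
) -> ClearanceResult:
    """Full chain k → Cl_int,in-vitro → Cl_int,hepatic for one fit."""
    cl_vitro = clint_in_vitro(k_h, factors, mode)
    return ClearanceResult(
        fish_id=fish_id,
        compound=compound,
        mode=mode,
        cl_int_in_vitro_mL_per_h_per_cell=cl_vitro,
        cl_int_hepatic_mL_per_h_per_g=clint_hepatic(cl_vitro, factors),
    )


def convert_literature_clearance(
    value: float,
    unit: str,
    factors: ScalingFactors,
    species: str = "human",
) -> float:
    """Convert a literature clearance value to mL h⁻¹ g liver⁻¹.

    S9 values (µL min⁻¹ mg⁻¹ protein) scale by 0.06 × mg protein per g liver;
    hepatocyte values (µL min⁻¹ per 10⁶ cells) by 0.06 × hepatocellularity/10⁶
    for the given species; per-gram values pass through unchanged.
    """
    if value < 0:
        raise ValueError("clearance value must be non-negative")
    if unit == UNIT_S9:
        return value * _MIN_PER_H_OVER_UL_PER_ML * factors.human_s9_protein_mg_per_g
    if unit == UNIT_HEPATOCYTES:
        return (
            value * _MIN_PER_H_OVER_UL_PER_ML * factors.hepatocellularity(species) / 1e6
        )
    if unit == UNIT_PER_G_LIVER:
        return value
    raise ValueError(
        f"unknown unit {unit!r}; accepted units: {', '.join(LITERATURE_UNITS)}"
    )


def literature_from_hepatic(
    value_mL_per_h_per_g: float,
    unit: str,
    factors: ScalingFactors,
    species: str = "human",
) -> float:
    """Inverse of :func:`convert_literature_clearance` (per-gram → assay units)."""
    if value_mL_per_h_per_g < 0:
        raise ValueError("clearance value must be non-negative")
    if unit == UNIT_S9:
        return value_mL_per_h_per_g / (
            _MIN_PER_H_OVER_UL_PER_ML * factors.human_s9_protein_mg_per_g
        )
    if unit == UNIT_HEPATOCYTES:
        return value_mL_per_h_per_g / (
            _MIN_PER_H_OVER_UL_PER_ML * factors.hepatocellularity(species) / 1e6
        )
    if unit == UNIT_PER_G_LIVER:
        return value_mL_per_h_per_g
    raise ValueError(
        f"unknown unit {unit!r}; accepted units: {', '.join(LITERATURE_UNITS)}"
    )
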
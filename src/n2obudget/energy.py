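"""Fuel-combustion and fugitive N2O for the eleven energy categories.

Combustion emissions are energy-based: activity in TJ (directly, or as fuel
mass x net calorific value) times an EF in kg N2O per TJ.  Fugitive
emissions use the activity in its native unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import EmissionEstimate
from .taxonomy import ENERGY_CATEGORIES
from .units import n2o_to_n2o_n, parse_activity_unit, UnitError

SECTOR = "energy"


@dataclass(frozen=True)
class FuelRecord:
    """Fuel consumed in one year x province x energy category."""

    year: int
    province: str
    category: str
    fuel: str
    quantity: float
    unit: str  # "TJ" or a mass unit like "kt"
    ncv: Optional[float] = None  # TJ per tonne, required for mass units

    def __post_init__(self) -> None:
        if self.category not in ENERGY_CATEGORIES:
            raise ValueError(
                f"unknown energy category {self.category!r}; "
                f"the category set is closed to the {len(ENERGY_CATEGORIES)} "
                "inventory rows"
            )
        if self.quantity < 0:
            raise ValueError("fuel quantity must be >= 0")
        if self.ncv is not None and self.ncv <= 0:
            raise ValueError("net calorific value must be > 0")

    def energy_tj(self) -> float:
        """Activity expressed in TJ."""
        if self.unit == "TJ":
            return self.quantity
        mult, kind = parse_activity_unit(self.unit)
        if kind in ("TJ", "head"):
            raise UnitError(f"unit {self.unit!r} is not a fuel mass or TJ")
        if self.ncv is None:
            raise UnitError(
                f"mass-based fuel record ({self.unit!r}) needs a net "
                "calorific value to convert to TJ"
            )
        mass_t = self.quantity * mult / 1e3  # kg -> t
        return mass_t * self.ncv


def combustion_emission(rec: FuelRecord, ef_kg_per_tj: float) -> EmissionEstimate:
    """Combustion N2O: (TJ burned) x EF [kg N2O / TJ], stored as N2O-N."""
    n2o_gg = rec.energy_tj() * ef_kg_per_tj / 1e6  # kg -> Gg
    return EmissionEstimate(
        year=rec.year,
        province=rec.province,
        sector=SECTOR,
        category=rec.category,
        n2o_n_gg=n2o_to_n2o_n(n2o_gg),
    )


def fugitive_emission(rec: FuelRecord, ef_kg_per_unit: float) -> EmissionEstimate:
    """Fugitive N2O: activity in native units x EF [kg N2O per unit]."""
    n2o_gg = rec.quantity * ef_kg_per_unit / 1e6
    return EmissionEstimate(
        year=rec.year,
        province=rec.province,
        sector=SECTOR,
        category=rec.category,
        n2o_n_gg=n2o_to_n2o_n(n2o_gg),
    )
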
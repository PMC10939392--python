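"""Adipic- and nitric-acid production N2O with plant-level abatement.

Unabated emission is production x EF; an installed abatement train removes
a fraction DF (destruction factor) of the N2O for the fraction UF of time
it operates, so the abated emission is P x EF x (1 - DF x UF).  Only two
Chinese adipic-acid plants registered abatement, credited during the
2008-2012 Kyoto first commitment period; whether they kept abating after
2012 is unresolved, so continuation is a scenario switch defaulting to off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import EmissionEstimate
from .units import n2o_to_n2o_n

SECTOR = "industry"

PRODUCTS = {"adipic": "Adipic acid production", "nitric": "Nitric acid production"}

# IPCC-style default EFs, kg N2O per tonne of product (config placeholders)
DEFAULT_EF = {"adipic": 300.0, "nitric": 9.0}


@dataclass(frozen=True)
class PlantRecord:
    """One plant-year (or province aggregate) of acid production."""

    year: int
    province: str
    product: str  # adipic | nitric
    production_kt: float
    abated: bool = False
    df: float = 0.0  # destruction factor
    uf: float = 0.0  # abatement utilization

    def __post_init__(self) -> None:
        if self.product not in PRODUCTS:
            raise ValueError(f"product must be adipic|nitric, got {self.product!r}")
        if self.production_kt < 0:
            raise ValueError("production must be >= 0")
        for name in ("df", "uf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def production_emission(rec: PlantRecord, ef_kg_per_t: float) -> EmissionEstimate:
    """P x EF x (1 - DF x UF) when abated, else P x EF; stored as N2O-N."""
    abatement = (1.0 - rec.df * rec.uf) if rec.abated else 1.0
    n2o_kg = rec.production_kt * 1e6 * ef_kg_per_t / 1e3  # kt -> t, x kg/t
    n2o_gg = n2o_kg * abatement / 1e6
    return EmissionEstimate(
        year=rec.year,
        province=rec.province,
        sector=SECTOR,
        category=PRODUCTS[rec.product],
        n2o_n_gg=n2o_to_n2o_n(n2o_gg),
    )


@dataclass(frozen=True)
class AbatedPlant:
    name: str
    province: str
    df: float
    uf: float
    active_from: int = 2008
    active_to: int = 2012


@dataclass
class AbatementRegistry:
    """The plants with registered N2O abatement and their active window.

    Defaults to the two adipic-acid plants credited under the Clean
    Development Mechanism, active 2008-2012; ``continue_after_window``
    keeps their abatement running after 2012 (a scenario, off by default).
    """

    plants: tuple[AbatedPlant, ...] = field(
        default_factory=lambda: (
            AbatedPlant("Henan Shenma Nylon Chemical", "Henan", df=0.9, uf=0.95),
            AbatedPlant(
                "PetroChina Liaoyang Petrochemical", "Liaoning", df=0.9, uf=0.95
            ),
        )
    )
    continue_after_window: bool = False

    def abatement_for(self, province: str, year: int) -> Optional[AbatedPlant]:
        for p in self.plants:
            if p.province != province:
                continue
            if p.active_from <= year <= p.active_to:
                return p
            if self.continue_after_window and year > p.active_to:
                return p
        return None
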
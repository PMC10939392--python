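"""Waste-sector N2O: wastewater (population-protein N load) and solid waste.

The wastewater pathway derives the nitrogen load in effluent from
population x protein intake x the N content of protein (0.16 kg N per kg
protein), scaled by non-consumed-protein and industrial co-discharge
multipliers, minus N removed with sludge; the load times an effluent EF
gives N2O-N.  Composting and incineration are per-mass EF pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .records import EmissionEstimate
from .units import n2o_to_n2o_n

SECTOR = "waste"
N_PER_PROTEIN = 0.16  # kg N per kg protein

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WastewaterRecord:
    year: int
    province: str
    population: float
    protein_kg: float  # per capita per year
    frac_npr: float = N_PER_PROTEIN
    mult_nonconsumed: float = 1.0
    mult_industrial: float = 1.0
    sludge_n_gg: float = 0.0

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")
        for name in ("protein_kg", "frac_npr", "mult_nonconsumed",
                     "mult_industrial", "sludge_n_gg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def n_load_gg(self) -> float:
        """Effluent N load (Gg N), floored at zero after sludge removal."""
        gross_kg = (
            self.population
            * self.protein_kg
            * self.frac_npr
            * self.mult_nonconsumed
            * self.mult_industrial
        )
        net = gross_kg / 1e6 - self.sludge_n_gg
        if net < 0:
            logger.warning(
                "sludge N (%.3f Gg) exceeds gross effluent N load (%.3f Gg) "
                "for %s %d; clamping to 0",
                self.sludge_n_gg, gross_kg / 1e6, self.province, self.year,
            )
            return 0.0
        return net


@dataclass(frozen=True)
class SolidWasteRecord:
    year: int
    province: str
    compost_kt: float = 0.0
    incin_kt: float = 0.0
    ef_compost_t_per_t: float = 0.0006  # t N2O per t treated
    ef_incin_t_per_t: float = 0.00005

    def __post_init__(self) -> None:
        for name in ("compost_kt", "incin_kt", "ef_compost_t_per_t",
                     "ef_incin_t_per_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def wastewater_emission(
    rec: WastewaterRecord, ef_effluent: float = 0.005
) -> EmissionEstimate:
    """Effluent N load x EF [kg N2O-N per kg N]."""
    mass = rec.n_load_gg() * ef_effluent
    return EmissionEstimate(
        year=rec.year,
        province=rec.province,
        sector=SECTOR,
        category="Wastewater treatment and discharge",
        n2o_n_gg=mass,
    )


def solid_waste_emission(rec: SolidWasteRecord) -> EmissionEstimate:
    """Composted mass x EF_compost + incinerated mass x EF_incin."""
    n2o_t = (
        rec.compost_kt * 1e3 * rec.ef_compost_t_per_t
        + rec.incin_kt * 1e3 * rec.ef_incin_t_per_t
    )
    return EmissionEstimate(
        year=rec.year,
        province=rec.province,
        sector=SECTOR,
        category="Biological treatment of solid waste and waste incineration",
        n2o_n_gg=n2o_to_n2o_n(n2o_t / 1e3),  # t -> Gg
    )
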
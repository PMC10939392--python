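"""Agricultural N2O: direct soil, indirect, manure, and burning pathways.

Nine sub-sources are computed so the inventory's agriculture rows are
individually recoverable:

* direct soil emissions from five N-input components (synthetic fertilizer,
  applied manure, crop residue, mineralized soil N, N deposition onto
  cropland), each F_i x EF1 with EF1 stratified by climate region and
  land type (upland vs paddy);
* indirect emissions via volatilization-redeposition (EF4 pathway) and via
  leaching/runoff (Frac_leach x EF5);
* manure management (per-system EF3 on excreted N) and manure left on
  pasture (group EF3), reported combined;
* pasture fertilization (EF1 on pasture N inputs) and crop-residue burning.

EF1 defaults follow a six-climate-region stratification: upland is high in
the humid East (0.0157 kg N2O-N kg^-1 N) and Northeast (0.0149) and lower
(0.0065-0.0093) elsewhere; paddy values sit in 0.0052-0.0161.  The
leaching-fraction defaults span 1.21-8.27 % (paddy) and 0.61-8.74 %
(upland), and EF5 defaults to 0.0065 kg N2O-N per kg N leached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .records import EmissionEstimate
from .taxonomy import RegionRegistry
from .units import n2o_to_n2o_n

SECTOR = "agriculture"

# pasture EF3 groups (kg N2O-N per kg N excreted on pasture)
PASTURE_GROUPS = ("cattle_swine_poultry", "sheep_other")

# default EF1 (kg N2O-N per kg N) by climate region x land type; editable.
# Upland anchors: subtropical_humid (East) 0.0157, temperate_humid
# (Northeast) 0.0149; remaining regions within 0.0065-0.0093.  Paddy values
# within 0.0052-0.0161.
DEFAULT_EF1 = {
    ("subtropical_humid", "upland"): 0.0157,
    ("temperate_humid", "upland"): 0.0149,
    ("warm_temperate", "upland"): 0.0093,
    ("temperate_arid", "upland"): 0.0065,
    ("tropical", "upland"): 0.0090,
    ("plateau", "upland"): 0.0070,
    ("subtropical_humid", "paddy"): 0.0052,
    ("temperate_humid", "paddy"): 0.0161,
    ("warm_temperate", "paddy"): 0.0080,
    ("temperate_arid", "paddy"): 0.0060,
    ("tropical", "paddy"): 0.0075,
    ("plateau", "paddy"): 0.0055,
}

# IPCC-2019-style tier-1 fallbacks when no climate stratum is configured
DEFAULT_EF1_BY_LAND_TYPE = {"upland": 0.01, "paddy": 0.004}

DEFAULT_FRAC_LEACH = {"paddy": 0.0474, "upland": 0.0468}  # mid-range defaults

FRAC_LEACH_RANGE = {"paddy": (0.0121, 0.0827), "upland": (0.0061, 0.0874)}


@dataclass(frozen=True)
class NInputBundle:
    """Annual N inputs to cropland soil for one province x land type (Gg N)."""

    year: int
    province: str
    land_type: str  # upland | paddy
    f_sn: float = 0.0  # synthetic fertilizer N
    f_on: float = 0.0  # applied manure N
    f_cr: float = 0.0  # crop-residue N
    f_som: float = 0.0  # mineralized soil organic N
    f_dep: float = 0.0  # deposited N reaching cropland

    def __post_init__(self) -> None:
        if self.land_type not in ("upland", "paddy"):
            raise ValueError(f"land type must be upland|paddy, got {self.land_type!r}")
        for name in ("f_sn", "f_on", "f_cr", "f_som", "f_dep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LivestockRecord:
    """One province x year x species herd with excretion and manure routing."""

    year: int
    province: str
    species: str
    headcount: float
    mass_kg: float
    excretion_rate: float  # kg N per 1000 kg animal mass per day
    frac_pasture: float
    frac_applied: float
    frac_mms: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.headcount < 0:
            raise ValueError("headcount must be >= 0")
        fracs = [self.frac_pasture, self.frac_applied, *self.frac_mms.values()]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("management fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(
                f"management fractions must sum to 1, got {sum(fracs)!r}"
            )


@dataclass
class AgEFSet:
    """Agricultural emission factors and N-transformation parameters."""

    ef1: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EF1)
    )
    ef1_by_land_type: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EF1_BY_LAND_TYPE)
    )
    ef3_mms: Mapping[str, float] = field(
        default_factory=lambda: {"liquid": 0.001, "solid": 0.005, "drylot": 0.02}
    )
    ef3_pasture: Mapping[str, float] = field(
        default_factory=lambda: {"cattle_swine_poultry": 0.004, "sheep_other": 0.003}
    )
    ef4: float = 0.01  # kg N2O-N per kg N volatilized-redeposited
    ef5: float = 0.0065  # kg N2O-N per kg N leached/run off
    frac_leach: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAC_LEACH)
    )
    frac_gasf: float = 0.11  # volatilized fraction, synthetic fertilizer
    frac_gasm: float = 0.21  # volatilized fraction, organic amendments
    burn_combustion_factor: float = 0.80
    ef_burn: float = 0.07  # kg N2O per t dry matter burned

    def ef1_lookup(self, climate_region: str, land_type: str) -> float:
        """(climate region, land type) exact match, else land-type default."""
        key = (climate_region, land_type)
        if key in self.ef1:
            return self.ef1[key]
        if land_type in self.ef1_by_land_type:
            return self.ef1_by_land_type[land_type]
        raise KeyError(
            f"no EF1 for climate region {climate_region!r}, land type {land_type!r}"
        )


_DIRECT_SUBSOURCES = {
    "f_sn": "Fertilizer application in cropland",
    "f_on": "Manure application in cropland",
    "f_cr": "Crop residue",
    "f_som": "Nitrogen mineralization",
    "f_dep": "Nitrogen deposition",
}


def direct_soil(
    bundle: NInputBundle, efs: AgEFSet, registry: RegionRegistry
) -> dict[str, EmissionEstimate]:
    """Direct soil N2O from each N-input component: F_i x EF1(region, land)."""
    climate = registry.climate_region_of(bundle.province)
    ef1 = efs.ef1_lookup(climate, bundle.land_type)
    out = {}
    for attr, category in _DIRECT_SUBSOURCES.items():
        mass = getattr(bundle, attr) * ef1
        out[category] = EmissionEstimate(
            year=bundle.year,
            province=bundle.province,
            sector=SECTOR,
            category=category,
            n2o_n_gg=mass,
        )
    return out


def indirect_leaching(
    n_applied: float,
    land_type: str,
    frac_leach: float,
    ef5: float,
    year: int = 1980,
    province: Optional[str] = None,
) -> EmissionEstimate:
    """Indirect N2O from the leaching/runoff pathway: N x Frac_leach x EF5."""
    if not 0.0 <= frac_leach <= 1.0:
        raise ValueError(f"frac_leach must lie in [0, 1], got {frac_leach}")
    if land_type not in ("upland", "paddy"):
        raise ValueError(f"land type must be upland|paddy, got {land_type!r}")
    mass = n_applied * frac_leach * ef5
    return EmissionEstimate(
        year=year,
        province=province,
        sector=SECTOR,
        category="Nitrogen leaching/runoff",
        n2o_n_gg=mass,
    )


def indirect_deposition(
    n_applied_syn: float,
    n_applied_org: float,
    frac_gasf: float,
    frac_gasm: float,
    ef4: float,
    year: int = 1980,
    province: Optional[str] = None,
) -> EmissionEstimate:
    """Indirect N2O from volatilization-redeposition:
    (F_SN x Frac_GASF + F_ON x Frac_GASM) x EF4."""
    for name, f in (("frac_gasf", frac_gasf), ("frac_gasm", frac_gasm)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    mass = (n_applied_syn * frac_gasf + n_applied_org * frac_gasm) * ef4
    return EmissionEstimate(
        year=year,
        province=province,
        sector=SECTOR,
        category="Nitrogen deposition",
        n2o_n_gg=mass,
    )


def excreted_n_gg(rec: LivestockRecord) -> float:
    """Annual excreted N (Gg): head x (mass/1000) x rate x 365 / 1e6."""
    kg_n = rec.headcount * (rec.mass_kg / 1000.0) * rec.excretion_rate * 365.0
    return kg_n / 1e6


def manure_management(
    rec: LivestockRecord, efs: AgEFSet
) -> tuple[float, dict[str, EmissionEstimate], dict[str, float]]:
    """Excretion and per-system managed-manure emissions.

    Returns (total excreted N in Gg, per-system estimates, routed N):
    ``routed['pasture']`` and ``routed['applied']`` are handed to the
    pasture-deposition and soil-application pathways and are not emitted
    here, so no N is double-counted.
    """
    n_ex = excreted_n_gg(rec)
    per_system: dict[str, EmissionEstimate] = {}
    for system, frac in rec.frac_mms.items():
        if system not in efs.ef3_mms:
            raise KeyError(
                f"no EF3 for manure management system {system!r}; "
                f"known: {sorted(efs.ef3_mms)}"
            )
        per_system[system] = EmissionEstimate(
            year=rec.year,
            province=rec.province,
            sector=SECTOR,
            category="Manure left on pasture and manure management",
            n2o_n_gg=n_ex * frac * efs.ef3_mms[system],
        )
    routed = {
        "pasture": n_ex * rec.frac_pasture,
        "applied": n_ex * rec.frac_applied,
    }
    return n_ex, per_system, routed


def pasture_group(species: str) -> str:
    """Map a species name to its pasture-EF3 group."""
    if species.lower() in ("cattle", "cows", "cow", "swine", "pig", "poultry"):
        return "cattle_swine_poultry"
    return "sheep_other"


def manure_pasture(
    n_deposited: float,
    species_group: str,
    efs: AgEFSet,
    year: int = 1980,
    province: Optional[str] = None,
) -> EmissionEstimate:
    """N2O from manure deposited on pasture: N x EF3(group)."""
    if species_group not in efs.ef3_pasture:
        raise KeyError(
            f"unknown pasture species group {species_group!r}; "
            f"known: {sorted(efs.ef3_pasture)}"
        )
    mass = n_deposited * efs.ef3_pasture[species_group]
    return EmissionEstimate(
        year=year,
        province=province,
        sector=SECTOR,
        category="Manure left on pasture and manure management",
        n2o_n_gg=mass,
    )


def pasture_fertilization(
    n_applied: float,
    ef1: float,
    year: int = 1980,
    province: Optional[str] = None,
) -> EmissionEstimate:
    """Direct N2O from fertilizer and manure applied to pasture."""
    return EmissionEstimate(
        year=year,
        province=province,
        sector=SECTOR,
        category="Fertilizer and manure application in pasture",
        n2o_n_gg=n_applied * ef1,
    )


def biomass_burning(
    residue_mass_gg_dm: float,
    combustion_factor: float,
    ef_burn_kg_per_t: float,
    year: int = 1980,
    province: Optional[str] = None,
) -> EmissionEstimate:
    """Crop-residue burning: mass x combustion factor x EF, as N2O-N.

    ``residue_mass_gg_dm`` is dry matter in Gg; the EF is kg N2O per tonne
    of dry matter burned.
    """
    if not 0.0 <= combustion_factor <= 1.0:
        raise ValueError(
            f"combustion factor must lie in [0, 1], got {combustion_factor}"
        )
    burned_t = residue_mass_gg_dm * combustion_factor * 1e3  # Gg dm -> t dm
    n2o_gg = burned_t * ef_burn_kg_per_t / 1e6  # kg -> Gg
    return EmissionEstimate(
        year=year,
        province=province,
        sector=SECTOR,
        category="Biomass burning",
        n2o_n_gg=n2o_to_n2o_n(n2o_gg),
    )
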
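"""End-to-end inventory assembly from activity tables.

Runs every sector engine over the activity tables (generated or loaded),
producing the long-format province-level inventory.  The mapping from
tables to categories follows the category taxonomy exactly, so the 24
anthropogenic rows aggregate to well-defined sector subtotals.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from . import agriculture as ag
from . import energy as en
from . import industry as ind
from . import waste as ws
from .records import EmissionEstimate, InventoryTable
from .taxonomy import RegionRegistry

# IPCC-default-style fuel EFs, kg N2O per TJ (config placeholders);
# the electricity value reflects the circulating-fluidized-bed coal share.
DEFAULT_ENERGY_EFS: dict[str, float] = {
    "Electricity generation": 3.0,
    "Heat plants": 1.5,
    "Petroleum refining": 0.6,
    "Manufacture of solid fuels": 1.5,
    "Other energy industries": 1.5,
    "Manufacturing industries and construction": 1.5,
    "Transport": 2.0,
    "Residential": 1.5,
    "Agriculture/forestry/fishing/fish farms": 1.5,
    "Non-specified": 1.5,
    "Fugitive emissions from fuels": 0.05,
}


def run_inventory(
    tables: Mapping[str, pd.DataFrame],
    registry: Optional[RegionRegistry] = None,
    ag_efs: Optional[ag.AgEFSet] = None,
    energy_efs: Optional[Mapping[str, float]] = None,
    abatement: Optional[ind.AbatementRegistry] = None,
    industry_efs: Optional[Mapping[str, float]] = None,
    wastewater_ef: float = 0.005,
) -> InventoryTable:
    """Compute the full anthropogenic inventory from activity tables.

    ``tables`` uses the keys produced by the synthetic generator
    (``n_inputs``, ``livestock``, ``fuels``, ``plants``, ``waste``).
    """
    registry = registry or RegionRegistry.default()
    ag_efs = ag_efs or ag.AgEFSet()
    energy_efs = energy_efs or DEFAULT_ENERGY_EFS
    abatement = abatement or ind.AbatementRegistry()
    industry_efs = industry_efs or ind.DEFAULT_EF
    estimates: list[EmissionEstimate] = []

    # --- agriculture ------------------------------------------------------
    for row in tables["n_inputs"].itertuples(index=False):
        bundle = ag.NInputBundle(
            year=row.year, province=row.province, land_type=row.land_type,
            f_sn=row.f_sn, f_on=row.f_on, f_cr=row.f_cr,
            f_som=row.f_som, f_dep=row.f_dep,
        )
        estimates.extend(ag.direct_soil(bundle, ag_efs, registry).values())
        estimates.append(ag.indirect_leaching(
            n_applied=row.f_sn + row.f_on,
            land_type=row.land_type,
            frac_leach=ag_efs.frac_leach[row.land_type],
            ef5=ag_efs.ef5,
            year=row.year, province=row.province,
        ))
        climate = registry.climate_region_of(row.province)
        estimates.append(ag.pasture_fertilization(
            n_applied=row.pasture_n,
            ef1=ag_efs.ef1_lookup(climate, "upland"),
            year=row.year, province=row.province,
        ))
        estimates.append(ag.biomass_burning(
            residue_mass_gg_dm=row.residue_dm_gg,
            combustion_factor=ag_efs.burn_combustion_factor,
            ef_burn_kg_per_t=ag_efs.ef_burn,
            year=row.year, province=row.province,
        ))

    for row in tables["livestock"].itertuples(index=False):
        rec = ag.LivestockRecord(
            year=row.year, province=row.province, species=row.species,
            headcount=row.headcount, mass_kg=row.mass_kg,
            excretion_rate=row.excretion_rate,
            frac_pasture=row.frac_pasture, frac_applied=row.frac_applied,
            frac_mms={"solid": row.frac_mms_solid,
                      "liquid": row.frac_mms_liquid},
        )
        _n_ex, per_system, routed = ag.manure_management(rec, ag_efs)
        estimates.extend(per_system.values())
        # N routed to applied-to-soil is already represented by the manure
        # component of the soil N-input table, so only pasture N is emitted
        # here.
        estimates.append(ag.manure_pasture(
            routed["pasture"], ag.pasture_group(row.species), ag_efs,
            year=row.year, province=row.province,
        ))

    # --- energy ------------------------------------------------------------
    for row in tables["fuels"].itertuples(index=False):
        rec = en.FuelRecord(
            year=row.year, province=row.province, category=row.category,
            fuel=row.fuel, quantity=row.quantity, unit=row.unit,
            ncv=None if pd.isna(row.ncv) else row.ncv,
        )
        ef = energy_efs[row.category]
        if row.category == "Fugitive emissions from fuels":
            estimates.append(en.fugitive_emission(rec, ef))
        else:
            estimates.append(en.combustion_emission(rec, ef))

    # --- industry -----------------------------------------------------------
    for row in tables["plants"].itertuples(index=False):
        plant = abatement.abatement_for(row.province, row.year)
        abated = plant is not None and row.product == "adipic"
        rec = ind.PlantRecord(
            year=row.year, province=row.province, product=row.product,
            production_kt=row.production_kt,
            abated=abated,
            df=plant.df if abated else 0.0,
            uf=plant.uf if abated else 0.0,
        )
        estimates.append(ind.production_emission(rec, industry_efs[row.product]))

    # --- waste ---------------------------------------------------------------
    for row in tables["waste"].itertuples(index=False):
        ww = ws.WastewaterRecord(
            year=row.year, province=row.province,
            population=row.population, protein_kg=row.protein_kg,
        )
        estimates.append(ws.wastewater_emission(ww, wastewater_ef))
        sw = ws.SolidWasteRecord(
            year=row.year, province=row.province,
            compost_kt=row.compost_kt, incin_kt=row.incin_kt,
        )
        estimates.append(ws.solid_waste_emission(sw))

    table = InventoryTable.from_estimates(estimates, registry=registry)
    table.validate_categories()
    return table


def line_items(table: InventoryTable) -> pd.DataFrame:
    """Collapse an inventory to (year, province, sector, category) line
    items for Monte Carlo propagation."""
    return (
        table.df.groupby(
            ["year", "province", "sector", "category"], as_index=False
        )["n2o_n_gg"].sum()
    )
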
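"""Published snapshot inventory fixture: sub-source N2O emissions for
1980/1990/2000/2010/2020 (Gg N2O yr^-1).

Only line items (sub-source rows) are stored as data; subtotal and total
rows are recomputed by aggregation.  Because each printed row was rounded
independently, recomputed subtotals can differ from the printed ones by up
to ~0.2 Gg; the printed subtotals are therefore also carried as reference
metadata (not as table rows) for exact cross-checks.

Snapshot substitutions in the source table (energy 1980/1990 use 1985/1995
values, industry 2000 uses 2002, waste 1980/2020 use 1981/2019) are
flagged ``substituted`` on the affected rows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import EmissionEstimate, InventoryTable
from .units import n2o_to_n2o_n

FIXTURE_YEARS = (1980, 1990, 2000, 2010, 2020)

# sector -> category -> {year: Gg N2O}; missing years were not reported
LINE_ITEMS: dict[str, dict[str, dict[int, float]]] = {
    "natural": {
        "Forest": {1980: 247.9, 1990: 291.1, 2000: 296.5, 2010: 298.9, 2020: 303.0},
        "Grassland": {1980: 69.4, 1990: 76.2, 2000: 69.5, 2010: 68.8, 2020: 73.3},
    },
    "energy": {
        "Electricity generation": {1980: 19.2, 1990: 52.4, 2000: 61.8, 2010: 185.9, 2020: 241.1},
        "Heat plants": {1980: 0.5, 1990: 2.4, 2000: 3.1, 2010: 10.2, 2020: 19.8},
        "Petroleum refining": {1980: 0.5, 1990: 0.1, 2000: 0.2, 2010: 0.9, 2020: 3.4},
        "Manufacture of solid fuels": {1980: 1.0, 1990: 2.2, 2000: 1.8, 2010: 5.9, 2020: 7.2},
        "Other energy industries": {1980: 0.1, 1990: 0.4, 2000: 0.6, 2010: 0.3, 2020: 1.3},
        "Manufacturing industries and construction": {1980: 15.1, 1990: 24.7, 2000: 23.9, 2010: 45.5, 2020: 36.6},
        "Transport": {1980: 4.1, 1990: 4.2, 2000: 5.3, 2010: 17.1, 2020: 20.0},
        "Residential": {1980: 4.3, 1990: 5.7, 2000: 4.3, 2010: 5.6, 2020: 4.5},
        "Agriculture/forestry/fishing/fish farms": {1980: 0.9, 1990: 1.1, 2000: 1.2, 2010: 1.4, 2020: 1.7},
        "Non-specified": {1980: 0.2, 1990: 1.0, 2000: 0.9, 2010: 2.0, 2020: 0.8},
        "Fugitive emissions from fuels": {1980: 0.6, 1990: 0.3, 2000: 0.3, 2010: 0.1, 2020: 0.0},
    },
    "industry": {
        "Nitric acid production": {2000: 10.6, 2010: 38.3, 2020: 38.7},
        "Adipic acid production": {2000: 34.5, 2010: 129.8, 2020: 468.0},
    },
    "agriculture": {
        "Fertilizer application in cropland": {1980: 197.7, 1990: 305.4, 2000: 356.8, 2010: 479.5, 2020: 413.1},
        "Nitrogen mineralization": {1980: 82.1, 1990: 122.6, 2000: 124.7, 2010: 124.3, 2020: 170.0},
        "Manure left on pasture and manure management": {1980: 79.7, 1990: 99.7, 2000: 119.3, 2010: 91.4, 2020: 91.7},
        "Manure application in cropland": {1980: 39.0, 1990: 49.7, 2000: 71.7, 2010: 78.5, 2020: 64.9},
        "Crop residue": {1980: 30.8, 1990: 49.1, 2000: 49.6, 2010: 59.5, 2020: 70.6},
        "Nitrogen deposition": {1980: 31.7, 1990: 46.1, 2000: 49.8, 2010: 56.8, 2020: 81.5},
        "Fertilizer and manure application in pasture": {1980: 7.7, 1990: 14.3, 2000: 20.8, 2010: 30.4, 2020: 25.9},
        "Nitrogen leaching/runoff": {1980: 10.7, 1990: 17.9, 2000: 21.6, 2010: 25.1, 2020: 23.5},
        "Biomass burning": {1980: 2.3, 1990: 3.6, 2000: 3.8, 2010: 4.5, 2020: 5.3},
    },
    "waste": {
        "Biological treatment of solid waste and waste incineration": {2000: 0.1, 2010: 2.0, 2020: 10.1},
        "Wastewater treatment and discharge": {1980: 44.2, 1990: 59.5, 2000: 85.3, 2010: 102.1, 2020: 118.8},
    },
}

# printed sector subtotals (Gg N2O), carried as reference metadata only
PRINTED_SUBTOTALS: dict[str, dict[int, float]] = {
    "natural": {1980: 317.3, 1990: 367.2, 2000: 366.0, 2010: 367.7, 2020: 376.2},
    "energy": {1980: 46.5, 1990: 94.6, 2000: 103.4, 2010: 274.8, 2020: 336.6},
    "industry": {2000: 45.1, 2010: 168.1, 2020: 506.7},
    "agriculture": {1980: 481.5, 1990: 708.4, 2000: 818.1, 2010: 950.1, 2020: 946.6},
    "waste": {1980: 44.2, 1990: 59.5, 2000: 85.5, 2010: 104.0, 2020: 128.9},
}

PRINTED_ANTHROPOGENIC = {1980: 572.2, 1990: 862.6, 2000: 1052.1, 2010: 1497.1, 2020: 1918.8}
PRINTED_TOTAL = {1980: 889.6, 1990: 1229.8, 2000: 1418.0, 2010: 1864.8, 2020: 2295.0}

# (sector, year) cells the source table filled from a neighbouring year
SUBSTITUTED_CELLS = {
    ("energy", 1980): 1985,
    ("energy", 1990): 1995,
    ("industry", 2000): 2002,
    ("waste", 1980): 1981,
    ("waste", 2020): 2019,
}


@dataclass(frozen=True)
class Table1Fixture:
    """The snapshot inventory as line items plus printed reference values."""

    table: InventoryTable

    @property
    def printed_subtotals(self):
        return PRINTED_SUBTOTALS

    @property
    def printed_anthropogenic(self):
        return PRINTED_ANTHROPOGENIC

    @property
    def printed_total(self):
        return PRINTED_TOTAL

    def recomputed_subtotal(self, sector: str, year: int) -> float:
        return self.table.total_n2o_gg(sector=sector, year=year)

    def recomputed_total(self, year: int, anthropogenic_only: bool = False) -> float:
        df = self.table.df[self.table.df["year"] == year]
        if anthropogenic_only:
            df = df[df["sector"] != "natural"]
        from .units import N2O_N_TO_N2O

        return float(df["n2o_n_gg"].sum()) * N2O_N_TO_N2O


def load_table1_fixture() -> Table1Fixture:
    """Build the national-level inventory table from the printed line items."""
    estimates = []
    for sector, cats in LINE_ITEMS.items():
        for category, by_year in cats.items():
            for year, n2o_gg in by_year.items():
                estimates.append(
                    EmissionEstimate(
                        year=year,
                        province=None,
                        sector=sector,
                        category=category,
                        n2o_n_gg=n2o_to_n2o_n(n2o_gg),
                        substituted=(sector, year) in SUBSTITUTED_CELLS,
                    )
                )
    return Table1Fixture(InventoryTable.from_estimates(estimates))
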
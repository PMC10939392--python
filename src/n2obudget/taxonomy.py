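"""Source taxonomy and regional registries.

The inventory covers five closed sectors.  The four anthropogenic sectors
contain exactly 24 categories (11 energy, 2 industry, 9 agriculture,
2 waste); the natural sector holds forest and grassland soil emissions.

Provinces (31 mainland units) map to seven reporting regions and to six
climate regions; the climate regions stratify the direct soil emission
factor EF1.  Both maps ship as editable defaults and can be loaded from a
``region_map.csv`` with columns province, region, climate_region.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SECTORS = ("natural", "energy", "industry", "agriculture", "waste")

REGIONS = (
    "Northwest",
    "Southwest",
    "South",
    "East",
    "Central",
    "North",
    "Northeast",
)

CLIMATE_REGIONS = (
    "temperate_humid",
    "temperate_arid",
    "warm_temperate",
    "subtropical_humid",
    "tropical",
    "plateau",
)

ENERGY_CATEGORIES = (
    "Electricity generation",
    "Heat plants",
    "Petroleum refining",
    "Manufacture of solid fuels",
    "Other energy industries",
    "Manufacturing industries and construction",
    "Transport",
    "Residential",
    "Agriculture/forestry/fishing/fish farms",
    "Non-specified",
    "Fugitive emissions from fuels",
)

INDUSTRY_CATEGORIES = (
    "Nitric acid production",
    "Adipic acid production",
)

AGRICULTURE_CATEGORIES = (
    "Fertilizer application in cropland",
    "Nitrogen mineralization",
    "Manure left on pasture and manure management",
    "Manure application in cropland",
    "Crop residue",
    "Nitrogen deposition",
    "Fertilizer and manure application in pasture",
    "Nitrogen leaching/runoff",
    "Biomass burning",
)

WASTE_CATEGORIES = (
    "Biological treatment of solid waste and waste incineration",
    "Wastewater treatment and discharge",
)

NATURAL_CATEGORIES = ("Forest", "Grassland")

_SECTOR_CATEGORIES = {
    "energy": ENERGY_CATEGORIES,
    "industry": INDUSTRY_CATEGORIES,
    "agriculture": AGRICULTURE_CATEGORIES,
    "waste": WASTE_CATEGORIES,
    "natural": NATURAL_CATEGORIES,
}


class CategoryTaxonomy:
    """Closed registry of emission categories and their sectors."""

    def __init__(self) -> None:
        self._sector_of: dict[str, str] = {}
        for sector, cats in _SECTOR_CATEGORIES.items():
            for cat in cats:
                if cat in self._sector_of:
                    raise ValueError(f"category {cat!r} registered twice")
                self._sector_of[cat] = sector
        n_anthro = len(self.anthropogenic_categories())
        if n_anthro != 24:
            raise AssertionError(
                f"taxonomy must register 24 anthropogenic categories, got {n_anthro}"
            )

    def sector_of(self, category: str) -> str:
        try:
            return self._sector_of[category]
        except KeyError:
            raise KeyError(f"unknown category {category!r}") from None

    def categories(self, sector: str) -> tuple[str, ...]:
        if sector not in SECTORS:
            raise KeyError(f"unknown sector {sector!r}; sectors are {SECTORS}")
        return _SECTOR_CATEGORIES[sector]

    def anthropogenic_categories(self) -> tuple[str, ...]:
        return tuple(
            c for c, s in self._sector_of.items() if s != "natural"
        )

    def all_categories(self) -> tuple[str, ...]:
        return tuple(self._sector_of)


TAXONOMY = CategoryTaxonomy()

# province -> (reporting region, climate region); standard administrative
# grouping of the 31 mainland provinces, municipalities and autonomous
# regions.  The climate assignment is an editable default: a temperate-humid
# Northeast, arid/semi-arid Northwest belt, the warm-temperate North China
# Plain, the humid subtropics, the tropical far South and the high plateau.
_DEFAULT_PROVINCES: dict[str, tuple[str, str]] = {
    "Heilongjiang": ("Northeast", "temperate_humid"),
    "Jilin": ("Northeast", "temperate_humid"),
    "Liaoning": ("Northeast", "temperate_humid"),
    "Beijing": ("North", "warm_temperate"),
    "Tianjin": ("North", "warm_temperate"),
    "Hebei": ("North", "warm_temperate"),
    "Shanxi": ("North", "warm_temperate"),
    "Inner Mongolia": ("North", "temperate_arid"),
    "Shanghai": ("East", "subtropical_humid"),
    "Jiangsu": ("East", "subtropical_humid"),
    "Zhejiang": ("East", "subtropical_humid"),
    "Anhui": ("East", "subtropical_humid"),
    "Fujian": ("East", "subtropical_humid"),
    "Jiangxi": ("East", "subtropical_humid"),
    "Shandong": ("East", "warm_temperate"),
    "Henan": ("Central", "warm_temperate"),
    "Hubei": ("Central", "subtropical_humid"),
    "Hunan": ("Central", "subtropical_humid"),
    "Guangdong": ("South", "tropical"),
    "Guangxi": ("South", "tropical"),
    "Hainan": ("South", "tropical"),
    "Chongqing": ("Southwest", "subtropical_humid"),
    "Sichuan": ("Southwest", "subtropical_humid"),
    "Guizhou": ("Southwest", "subtropical_humid"),
    "Yunnan": ("Southwest", "subtropical_humid"),
    "Tibet": ("Southwest", "plateau"),
    "Shaanxi": ("Northwest", "warm_temperate"),
    "Gansu": ("Northwest", "temperate_arid"),
    "Qinghai": ("Northwest", "plateau"),
    "Ningxia": ("Northwest", "temperate_arid"),
    "Xinjiang": ("Northwest", "temperate_arid"),
}


@dataclass(frozen=True)
class RegionRegistry:
    """Province -> reporting-region and climate-region lookup."""

    table: pd.DataFrame  # columns: province, region, climate_region

    def __post_init__(self) -> None:
        t = self.table
        required = {"province", "region", "climate_region"}
        if not required.issubset(t.columns):
            raise ValueError(f"region map needs columns {sorted(required)}")
        if t["province"].duplicated().any():
            dups = t.loc[t["province"].duplicated(), "province"].tolist()
            raise ValueError(f"provinces mapped more than once: {dups}")
        bad_r = set(t["region"]) - set(REGIONS)
        if bad_r:
            raise ValueError(f"unknown regions {sorted(bad_r)}; valid: {REGIONS}")
        bad_c = set(t["climate_region"]) - set(CLIMATE_REGIONS)
        if bad_c:
            raise ValueError(f"unknown climate regions {sorted(bad_c)}")

    @classmethod
    def default(cls) -> "RegionRegistry":
        rows = [
            {"province": p, "region": r, "climate_region": c}
            for p, (r, c) in _DEFAULT_PROVINCES.items()
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "RegionRegistry":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(self.table["province"])

    def region_of(self, province: str) -> str:
        return self._lookup(province, "region")

    def climate_region_of(self, province: str) -> str:
        return self._lookup(province, "climate_region")

    def _lookup(self, province: str, col: str) -> str:
        hit = self.table.loc[self.table["province"] == province, col]
        if hit.empty:
            raise KeyError(f"province {province!r} not in region map")
        return hit.iloc[0]
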
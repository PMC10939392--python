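"""Synthetic province-level activity data and model forcings.

The generator emulates the statistical structure of four decades of
Chinese activity trajectories without reproducing any real provincial
statistics:

* synthetic-fertilizer N rises roughly threefold from 1980, peaks in 2016
  at the national anchor of 35.4 Tg N, and declines to 30.6 Tg N by 2020
  (the two anchors are exact by construction; everything else is shape);
* adipic-acid production is negligible before the late 1990s and grows
  steeply after 2005; nitric acid grows steadily;
* fuel combustion (coal-dominated electricity) grows fastest in the 2000s;
* population growth decelerates from ~15.5 to ~7.5 million persons per
  year between the 1980s and the 2010s;
* atmospheric CO2 rises ~339 -> 412 ppm; N deposition rises to 2000 and
  then plateaus; temperature carries a warming trend plus interannual
  noise; WFPS is stationary noise.

Provincial disaggregation uses seeded Dirichlet shares with multiplicative
lognormal noise, renormalized each year so national totals are preserved.
All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .natural_soil import GridSpec, LC_FOREST, LC_GRASSLAND, LC_NONE
from .table1 import Table1Fixture, load_table1_fixture  # noqa: F401  (re-export)
from .taxonomy import ENERGY_CATEGORIES, RegionRegistry

YEARS = tuple(range(1980, 2021))

SPECIES = ("cattle", "swine", "poultry", "goat", "sheep", "other")

# typical animal mass (kg) and N excretion rate (kg N / 1000 kg mass / day)
SPECIES_PARAMS = {
    "cattle": (400.0, 0.35),
    "swine": (80.0, 0.50),
    "poultry": (1.5, 0.82),
    "goat": (40.0, 0.34),
    "sheep": (45.0, 0.32),
    "other": (200.0, 0.35),
}


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    n_provinces: int = 31
    years: tuple[int, ...] = YEARS
    noise_cv: float = 0.05
    fertilizer_start_gg: float = 12000.0   # ~1/3 of the 2016 peak
    fertilizer_2016_gg: float = 35400.0    # national calibration anchors
    fertilizer_2020_gg: float = 30600.0
    population_1980: float = 987e6
    pop_growth_1980s: float = 15.5e6       # persons per year, 1980s mean
    pop_growth_2010s: float = 7.5e6        # persons per year, 2010s mean

    def validate(self) -> None:
        if self.n_provinces < 1:
            raise ValueError("need at least one province")
        if not (0 < self.fertilizer_start_gg < self.fertilizer_2016_gg):
            raise ValueError(
                "infeasible fertilizer calibration: start must be positive "
                "and below the 2016 peak"
            )
        if self.fertilizer_2020_gg > self.fertilizer_2016_gg:
            raise ValueError(
                "infeasible fertilizer calibration: 2020 must not exceed "
                "the 2016 peak"
            )


def _provinces(config: ScenarioConfig) -> list[str]:
    defaults = RegionRegistry.default().provinces
    if config.n_provinces <= len(defaults):
        return list(defaults[: config.n_provinces])
    extra = [f"Province{i:02d}" for i in range(len(defaults), config.n_provinces)]
    return list(defaults) + extra


def _disaggregate(
    national: np.ndarray,
    shares: np.ndarray,
    rng: np.random.Generator,
    cv: float,
) -> np.ndarray:
    """(n_years,) national series -> (n_years, n_prov) with noisy shares
    renormalized so each year sums exactly to the national value."""
    n_years = len(national)
    n_prov = len(shares)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    noise = rng.lognormal(0.0, sigma, (n_years, n_prov)) if cv > 0 else 1.0
    w = shares[None, :] * noise
    w = w / w.sum(axis=1, keepdims=True)
    return national[:, None] * w


def national_fertilizer_series(config: ScenarioConfig) -> pd.Series:
    """National synthetic-fertilizer N (Gg N): smooth rise to the 2016 peak
    then linear decline to the 2020 anchor."""
    config.validate()
    years = np.asarray(config.years)
    out = np.empty(len(years), dtype=float)
    f0, fpeak, fend = (
        config.fertilizer_start_gg,
        config.fertilizer_2016_gg,
        config.fertilizer_2020_gg,
    )
    for i, y in enumerate(years):
        if y <= 2016:
            x = (y - 1980) / (2016 - 1980)
            out[i] = f0 + (fpeak - f0) * np.sin(0.5 * np.pi * x) ** 1.5
        else:
            out[i] = fpeak + (fend - fpeak) * (y - 2016) / (2020 - 2016)
    return pd.Series(out, index=years)


def _logistic(years: np.ndarray, level: float, center: float, width: float,
              floor: float = 0.0) -> np.ndarray:
    return floor + level / (1.0 + np.exp(-(years - center) / width))


def generate_activity(config: ScenarioConfig) -> dict[str, pd.DataFrame]:
    """Generate all activity tables keyed by sector input file."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    provinces = _provinces(config)
    years = np.asarray(config.years)
    n_prov = len(provinces)

    shares = rng.dirichlet(np.full(n_prov, 3.0))

    # --- agriculture: N inputs to soil -----------------------------------
    fert = national_fertilizer_series(config).to_numpy()
    fert_pv = _disaggregate(fert, shares, rng, config.noise_cv)
    paddy_frac = rng.uniform(0.10, 0.50, n_prov)
    ratios = {"f_on": 0.18, "f_cr": 0.12, "f_som": 0.35, "f_dep": 0.15}
    rows = []
    for j, prov in enumerate(provinces):
        for i, y in enumerate(years):
            for land, lfrac in (("upland", 1 - paddy_frac[j]),
                                ("paddy", paddy_frac[j])):
                f_sn = fert_pv[i, j] * lfrac
                row = {
                    "year": int(y), "province": prov, "land_type": land,
                    "f_sn": f_sn,
                }
                for k, r in ratios.items():
                    row[k] = f_sn * r
                row["pasture_n"] = f_sn * 0.06
                row["residue_dm_gg"] = f_sn * 2.5  # dry matter available
                rows.append(row)
    n_inputs = pd.DataFrame(rows)

    # --- livestock --------------------------------------------------------
    head_1980 = {"cattle": 70e6, "swine": 300e6, "poultry": 1.5e9,
                 "goat": 80e6, "sheep": 100e6, "other": 20e6}
    rows = []
    for sp in SPECIES:
        growth = _logistic(years, 1.0, 1998.0, 8.0, floor=0.6)
        nat = head_1980[sp] * growth / growth[0]
        pv = _disaggregate(nat, shares, rng, config.noise_cv)
        mass, rate = SPECIES_PARAMS[sp]
        grazing = sp in ("cattle", "goat", "sheep", "other")
        frac_pasture = 0.30 if grazing else 0.05
        frac_applied = 0.40
        frac_solid = 0.20 if grazing else 0.30
        frac_liquid = 1.0 - frac_pasture - frac_applied - frac_solid
        for j, prov in enumerate(provinces):
            for i, y in enumerate(years):
                rows.append({
                    "year": int(y), "province": prov, "species": sp,
                    "headcount": pv[i, j], "mass_kg": mass,
                    "excretion_rate": rate,
                    "frac_pasture": frac_pasture,
                    "frac_applied": frac_applied,
                    "frac_mms_solid": frac_solid,
                    "frac_mms_liquid": frac_liquid,
                })
    livestock = pd.DataFrame(rows)

    # --- energy: fuel combusted (TJ) -------------------------------------
    # coal-heavy categories grow fastest through the 2000s
    cat_scale = {
        "Electricity generation": (6.3e7, 2006.0, 5.0, 2.8e6),
        "Heat plants": (4.2e6, 2008.0, 6.0, 1.4e5),
        "Petroleum refining": (7.7e5, 2010.0, 6.0, 5.6e4),
        "Manufacture of solid fuels": (1.7e6, 2006.0, 6.0, 1.4e5),
        "Other energy industries": (2.8e5, 2008.0, 6.0, 2.1e4),
        "Manufacturing industries and construction": (1.05e7, 2004.0, 7.0, 2.8e6),
        "Transport": (4.9e6, 2008.0, 6.0, 7e5),
        "Residential": (1.1e6, 2000.0, 10.0, 7.7e5),
        "Agriculture/forestry/fishing/fish farms": (2.8e5, 2000.0, 10.0, 1.7e5),
        "Non-specified": (2.8e5, 2005.0, 8.0, 4.2e4),
    }
    rows = []
    for cat, (level, center, width, floor) in cat_scale.items():
        nat = _logistic(years, level, center, width, floor)
        pv = _disaggregate(nat, shares, rng, config.noise_cv)
        for j, prov in enumerate(provinces):
            for i, y in enumerate(years):
                rows.append({
                    "year": int(y), "province": prov, "category": cat,
                    "fuel": "coal", "quantity": pv[i, j], "unit": "TJ",
                    "ncv": np.nan,
                })
    # fugitive: small and declining, native units (Mm3 gas handled)
    nat = 12.0 * np.exp(-0.09 * (years - 1980))
    pv = _disaggregate(nat, shares, rng, config.noise_cv)
    for j, prov in enumerate(provinces):
        for i, y in enumerate(years):
            rows.append({
                "year": int(y), "province": prov,
                "category": "Fugitive emissions from fuels",
                "fuel": "gas", "quantity": pv[i, j], "unit": "TJ",
                "ncv": np.nan,
            })
    fuels = pd.DataFrame(rows)
    assert set(fuels["category"]) == set(ENERGY_CATEGORIES)

    # --- industry: acid production (kt) -----------------------------------
    adipic_nat = np.where(
        years < 1995, 0.0,
        _logistic(years, 2600.0, 2012.0, 3.5) - _logistic(
            np.asarray([1995.0]), 2600.0, 2012.0, 3.5)[0],
    )
    adipic_nat = np.maximum(adipic_nat, 0.0)
    nitric_nat = 300.0 + 30.0 * (years - 1980)
    adipic_provs = ["Henan", "Liaoning", "Shandong", "Jiangsu"]
    adipic_shares = np.array([0.35, 0.25, 0.25, 0.15])
    rows = []
    for j, prov in enumerate(adipic_provs):
        for i, y in enumerate(years):
            rows.append({
                "year": int(y), "province": prov, "product": "adipic",
                "production_kt": adipic_nat[i] * adipic_shares[j],
            })
    nitric_pv = _disaggregate(nitric_nat, shares, rng, config.noise_cv)
    for j, prov in enumerate(provinces):
        for i, y in enumerate(years):
            rows.append({
                "year": int(y), "province": prov, "product": "nitric",
                "production_kt": nitric_pv[i, j],
            })
    plants = pd.DataFrame(rows)

    # --- waste -------------------------------------------------------------
    # decelerating population growth (linear decline in annual increments)
    inc_slope = (config.pop_growth_2010s - config.pop_growth_1980s) / 31.0
    inc_at_1980 = config.pop_growth_1980s - inc_slope * 4.5
    pop_nat = np.empty(len(years))
    pop_nat[0] = config.population_1980
    for i in range(1, len(years)):
        pop_nat[i] = pop_nat[i - 1] + inc_at_1980 + inc_slope * (years[i] - 1980)
    pop_pv = _disaggregate(pop_nat, shares, rng, 0.0)  # shares fixed in time
    protein = 25.0 + 10.0 * (years - 1980) / 40.0
    compost_nat = _logistic(years, 3000.0, 2012.0, 4.0)
    incin_nat = _logistic(years, 8000.0, 2013.0, 4.0)
    compost_pv = _disaggregate(compost_nat, shares, rng, config.noise_cv)
    incin_pv = _disaggregate(incin_nat, shares, rng, config.noise_cv)
    rows = []
    for j, prov in enumerate(provinces):
        for i, y in enumerate(years):
            rows.append({
                "year": int(y), "province": prov,
                "population": pop_pv[i, j],
                "protein_kg": protein[i],
                "compost_kt": compost_pv[i, j],
                "incin_kt": incin_pv[i, j],
            })
    waste = pd.DataFrame(rows)

    return {
        "n_inputs": n_inputs,
        "livestock": livestock,
        "fuels": fuels,
        "plants": plants,
        "waste": waste,
    }


# ---------------------------------------------------------------------------
# natural-model grid and forcings
# ---------------------------------------------------------------------------

def default_grid(config: ScenarioConfig, ny: int = 100, nx: int = 100) -> GridSpec:
    """Equal-area 25-km lattice whose forest/grassland cell counts give
    areas of the order of the real forest (~2.2 Mkm2) and grassland
    (~3.9 Mkm2) extents."""
    rng = np.random.default_rng(config.seed + 1)
    n_cells = ny * nx
    # cover fractions chosen so the full 100x100 lattice matches the real
    # forest (~2.2 Mkm2) and grassland (~3.9 Mkm2) extents at 25 km
    n_forest = int(round(0.352 * n_cells))
    n_grass = int(round(0.624 * n_cells))
    if n_forest + n_grass > n_cells:
        raise ValueError("grid too small for the default landcover extents")
    codes = np.full(n_cells, LC_NONE, dtype=int)
    codes[:n_forest] = LC_FOREST
    codes[n_forest:n_forest + n_grass] = LC_GRASSLAND
    rng.shuffle(codes)
    return GridSpec(landcover=codes.reshape(ny, nx))


def generate_forcings(config: ScenarioConfig, grid: GridSpec) -> xr.Dataset:
    """Annual gridded forcings 1980-2020, deterministic given the seed."""
    rng = np.random.default_rng(config.seed + 2)
    years = np.asarray(config.years)
    t_idx = years - years[0]
    ny, nx = grid.shape
    lc = np.asarray(grid.landcover)

    co2 = 338.7 + 1.2 * t_idx + 0.0158 * t_idx**2  # ppm, strictly increasing

    temp_base = np.where(lc == LC_FOREST, 12.0, 8.0) + rng.normal(0, 2.0, (ny, nx))
    temp_anom = 0.03 * t_idx + rng.normal(0, 0.3, len(years))
    temp = temp_base[None, :, :] + temp_anom[:, None, None]

    wfps_base = np.where(lc == LC_FOREST, 0.62, 0.45) + rng.normal(0, 0.05, (ny, nx))
    wfps = np.clip(
        wfps_base[None, :, :] + rng.normal(0, 0.03, len(years))[:, None, None],
        0.05, 0.95,
    )

    ndep_base = np.where(lc == LC_FOREST, 1.5, 1.0) * rng.lognormal(
        0, 0.2, (ny, nx))
    # rises ~60% to 2000, then stable
    ramp = np.where(years <= 2000, 1.0 + 0.6 * (years - 1980) / 20.0, 1.6)
    ramp = ramp * (1.0 + rng.normal(0, 0.005, len(years)))
    ndep = ndep_base[None, :, :] * ramp[:, None, None]

    return xr.Dataset(
        {
            "t": (("year", "y", "x"), temp),
            "wfps": (("year", "y", "x"), wfps),
            "ndep": (("year", "y", "x"), ndep),
            "co2": (("year",), co2),
        },
        coords={"year": years},
        attrs={"units": "t: degC; wfps: fraction; ndep: g N m-2 yr-1; co2: ppm"},
    )


def write_activity_csvs(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
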
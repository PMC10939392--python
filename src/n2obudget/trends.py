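"""Trend statistics, shares, and dataset export.

Decadal rates are endpoint ratios (value change between two inventory
years over the start value), matching how multi-year percent changes are
conventionally quoted from snapshot tables.  Accumulated changes over the
1980-2020 window use the OLS slope multiplied by 41 years (the number of
annual values in the window).  Monotonic trends are tested with the
Mann-Kendall statistic using the tie-corrected normal approximation,
without pre-whitening.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .records import InventoryTable
from .taxonomy import SECTORS

WINDOW_YEARS = 41  # 1980-2020 inclusive


def _as_series(series) -> pd.Series:
    s = pd.Series(series) if not isinstance(series, pd.Series) else series
    s = s.sort_index()
    if not np.isfinite(s.to_numpy(dtype=float)).all():
        raise ValueError("series contains non-finite values")
    return s


def decadal_change_pct(series, y0: int, y1: int) -> float:
    """Endpoint percent change 100 x (v(y1) - v(y0)) / v(y0), one decimal."""
    s = _as_series(series)
    for y in (y0, y1):
        if y not in s.index:
            raise KeyError(f"year {y} not in series")
    if s[y0] == 0:
        raise ZeroDivisionError(f"change from a zero value at {y0} is undefined")
    return float(round(100.0 * (s[y1] - s[y0]) / s[y0], 1))


def contribution_pct(component, total, y0: int, y1: int) -> tuple[float, float]:
    """A component's growth relative to the total.

    Returns (100 x dComp / total(y0), 100 x dComp / dTotal): the component's
    change as a percent of the starting total, and its share of the total
    increase.  Both rounded to one decimal.
    """
    c = _as_series(component)
    t = _as_series(total)
    for s, lbl in ((c, "component"), (t, "total")):
        for y in (y0, y1):
            if y not in s.index:
                raise KeyError(f"year {y} not in {lbl} series")
    if t[y0] == 0:
        raise ZeroDivisionError("contribution relative to a zero total")
    d_total = t[y1] - t[y0]
    if d_total == 0:
        raise ZeroDivisionError("share of a zero total increase is undefined")
    d_comp = c[y1] - c[y0]
    return (
        float(round(100.0 * d_comp / t[y0], 1)),
        float(round(100.0 * d_comp / d_total, 1)),
    )


def sector_share(
    table: InventoryTable, year: int, basis: str = "anthropogenic"
) -> dict[str, float]:
    """Percent share of each sector in the chosen basis for one year.

    ``basis='anthropogenic'`` excludes the natural sector from both the
    numerators and the denominator; ``basis='total'`` includes it.
    Shares are rounded to one decimal and sum to 100 within rounding.
    """
    if basis not in ("total", "anthropogenic"):
        raise ValueError("basis must be 'total' or 'anthropogenic'")
    df = table.df[table.df["year"] == year]
    sums = df.groupby("sector")["n2o_n_gg"].sum()
    sectors = [s for s in SECTORS if basis == "total" or s != "natural"]
    present = [s for s in sectors if s in sums.index]
    missing = [
        s for s in sectors
        if s not in sums.index and s in set(table.df["sector"])
    ]
    if missing:
        raise KeyError(f"sectors {missing} have no rows for year {year}")
    denom = sums[present].sum()
    if denom == 0:
        raise ZeroDivisionError(f"no emissions in year {year}")
    return {s: float(round(100.0 * sums[s] / denom, 1)) for s in present}


def linear_trend(series, window_years: int = WINDOW_YEARS) -> tuple[float, float]:
    """OLS slope (Gg yr^-1) and accumulated change (slope x window)."""
    s = _as_series(series)
    if len(s) < 3:
        raise ValueError(f"need >= 3 points for a trend, got {len(s)}")
    res = stats.linregress(s.index.to_numpy(dtype=float), s.to_numpy(dtype=float))
    return float(res.slope), float(res.slope) * window_years


@dataclass(frozen=True)
class MKResult:
    s: int
    tau: float
    p: float
    increasing: bool


def mann_kendall(series, alpha: float = 0.05) -> MKResult:
    """Mann-Kendall monotonic-trend test.

    S is the sum of signs over all ordered pairs; the p-value uses the
    tie-corrected normal approximation with continuity correction; tau is
    the tau-b normalization.  An all-identical series yields tau 0, p 1.
    """
    s_ = _as_series(series)
    x = s_.to_numpy(dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 points for the Mann-Kendall test, got {n}")
    diff_signs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff_signs, 1).sum())
    ties = Counter(x)
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in ties.values() if t > 1)
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0
    d = n * (n - 1) / 2.0
    tie_pairs = sum(t * (t - 1) / 2.0 for t in ties.values() if t > 1)
    denom = np.sqrt(d * (d - tie_pairs))
    tau = s / denom if denom > 0 else 0.0
    if var_s == 0 or s == 0:
        z = 0.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)
    p = 2.0 * stats.norm.sf(abs(z))
    return MKResult(s=s, tau=float(tau), p=float(p),
                    increasing=bool(p < alpha and s > 0))


def mann_kendall_s_bruteforce(series) -> int:
    """Independent S by explicit pair enumeration (cross-check oracle)."""
    x = _as_series(series).to_numpy(dtype=float)
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            s += int(x[j] > x[i]) - int(x[j] < x[i])
    return s


# ---------------------------------------------------------------------------
# full-annual-dataset export
# ---------------------------------------------------------------------------

def export_fan(
    table: InventoryTable,
    out_dir,
    natural_grid: xr.Dataset | None = None,
) -> dict[str, Path]:
    """Write the full-scale annual dataset: a province-level inventory CSV
    and, when supplied, the annual 25-km natural-flux grid as NetCDF.

    Re-reading the CSV with :func:`read_fan` reproduces the table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    csv_path = out_dir / "fan_inventory.csv"
    try:
        table.to_csv(csv_path)
    except OSError as exc:
        raise OSError(f"could not write inventory to {csv_path}: {exc}") from exc
    paths["inventory"] = csv_path
    if natural_grid is not None:
        nc_path = out_dir / "fan_natural.nc"
        try:
            natural_grid.to_netcdf(nc_path, engine="scipy")
        except OSError as exc:
            raise OSError(f"could not write grid to {nc_path}: {exc}") from exc
        paths["natural"] = nc_path
    return paths


def read_fan(path) -> InventoryTable:
    return InventoryTable.read_csv(path)
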
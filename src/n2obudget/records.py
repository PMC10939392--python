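"""Core domain records: activity data, emission factors, emission estimates,
and the long-format inventory table they aggregate into.

Masses are stored internally on the N2O-N basis (Gg N2O-N yr^-1); the
reporting layer converts to Gg N2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .taxonomy import TAXONOMY, RegionRegistry
from .units import N2O_N_TO_N2O

DISTRIBUTIONS = ("normal", "lognormal", "uniform", "triangular")

YEAR_RANGE = (1980, 2020)


@dataclass(frozen=True)
class ActivityRecord:
    """One activity observation (year x province x category x variable)."""

    year: int
    province: str
    category: str
    variable: str
    value: float
    unit: str
    strata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"activity value must be >= 0, got {self.value}")
        lo, hi = YEAR_RANGE
        if not lo <= self.year <= hi:
            raise ValueError(f"year {self.year} outside {lo}-{hi}")


@dataclass(frozen=True)
class EmissionFactor:
    """Stratified emission factor or N-transformation parameter."""

    category: str
    value: float
    unit: str
    strata: Mapping[str, str] = field(default_factory=dict)
    low: Optional[float] = None
    high: Optional[float] = None
    distribution: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"EF value must be >= 0, got {self.value}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.value <= self.high):
                raise ValueError(
                    f"EF bounds violated: {self.low} <= {self.value} <= {self.high}"
                )
        if self.distribution is not None and self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class EmissionEstimate:
    """Computed N2O mass for one year/province/category (Gg N2O-N yr^-1)."""

    year: int
    province: Optional[str]
    sector: str
    category: str
    n2o_n_gg: float
    low: Optional[float] = None
    high: Optional[float] = None
    substituted: bool = False

    def __post_init__(self) -> None:
        if self.n2o_n_gg < 0:
            raise ValueError(f"emission mass must be >= 0, got {self.n2o_n_gg}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.n2o_n_gg <= self.high):
                raise ValueError("interval must bracket the central value")

    @property
    def n2o_gg(self) -> float:
        return self.n2o_n_gg * N2O_N_TO_N2O


_COLUMNS = [
    "year",
    "province",
    "region",
    "sector",
    "category",
    "n2o_n_gg",
    "ci_low",
    "ci_high",
    "substituted",
]


class InventoryTable:
    """Long-format collection of emission estimates.

    Thin wrapper over a :class:`pandas.DataFrame` with a fixed schema;
    supports grouping/aggregation, unit conversion to Gg N2O on export,
    and round-trippable CSV I/O.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"inventory table missing columns {missing}")
        df = df[_COLUMNS].reset_index(drop=True)
        for col in ("n2o_n_gg", "ci_low", "ci_high"):
            df[col] = pd.to_numeric(df[col])
        self.df = df

    # -- construction -----------------------------------------------------
    @classmethod
    def from_estimates(
        cls,
        estimates: Iterable[EmissionEstimate],
        registry: Optional[RegionRegistry] = None,
    ) -> "InventoryTable":
        rows = []
        for e in estimates:
            region = None
            if registry is not None and e.province is not None:
                region = registry.region_of(e.province)
            rows.append(
                {
                    "year": e.year,
                    "province": e.province,
                    "region": region,
                    "sector": e.sector,
                    "category": e.category,
                    "n2o_n_gg": e.n2o_n_gg,
                    "ci_low": e.low,
                    "ci_high": e.high,
                    "substituted": e.substituted,
                }
            )
        if not rows:
            return cls(pd.DataFrame(columns=_COLUMNS))
        return cls(pd.DataFrame(rows))

    @classmethod
    def empty(cls) -> "InventoryTable":
        return cls(pd.DataFrame(columns=_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    # -- aggregation ------------------------------------------------------
    def aggregate(self, by: Sequence[str]) -> pd.DataFrame:
        """Sum N2O-N masses over groups; returns a frame with an added
        ``n2o_gg`` reporting column (Gg N2O).

        Empty table -> empty frame (a sum over no rows is 0 by convention
        and appears as no groups).
        """
        valid = {"year", "province", "region", "sector", "category"}
        bad = [k for k in by if k not in valid]
        if bad:
            raise KeyError(f"unknown grouping keys {bad}; valid: {sorted(valid)}")
        if len(self.df) == 0:
            out = pd.DataFrame(columns=[*by, "n2o_n_gg", "n2o_gg"])
            return out
        if not by:
            total = float(self.df["n2o_n_gg"].sum())
            return pd.DataFrame({"n2o_n_gg": [total], "n2o_gg": [total * N2O_N_TO_N2O]})
        g = self.df.groupby(list(by), dropna=False)["n2o_n_gg"].sum().reset_index()
        g["n2o_gg"] = g["n2o_n_gg"] * N2O_N_TO_N2O
        return g

    def total_n2o_gg(self, **filters) -> float:
        """Total mass in Gg N2O over rows matching the given column filters."""
        df = self.df
        for col, val in filters.items():
            df = df[df[col] == val]
        return float(df["n2o_n_gg"].sum()) * N2O_N_TO_N2O

    def series(self, **filters) -> pd.Series:
        """Annual national series (Gg N2O) over rows matching filters."""
        df = self.df
        for col, val in filters.items():
            df = df[df[col] == val]
        s = df.groupby("year")["n2o_n_gg"].sum() * N2O_N_TO_N2O
        return s.sort_index()

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["n2o_gg"] = out["n2o_n_gg"] * N2O_N_TO_N2O
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "InventoryTable":
        df = pd.read_csv(path)
        if "substituted" in df.columns:
            df["substituted"] = df["substituted"].astype(bool)
        return cls(df)

    def validate_categories(self) -> None:
        for cat, sector in (
            self.df[["category", "sector"]].drop_duplicates().itertuples(index=False)
        ):
            expected = TAXONOMY.sector_of(cat)
            if expected != sector:
                raise ValueError(
                    f"category {cat!r} tagged sector {sector!r}, expected {expected!r}"
                )
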
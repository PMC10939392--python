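"""The AD x EF engine, gap-filling, and aggregation shared by all sectors.

A sector emission in year ``y`` is the sum over sources ``i`` and provinces
``j`` of ``AD_ij(y) x EF_i``, with the activity datum and the emission
factor composing through the unit registry to a mass of N2O-N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import ActivityRecord, EmissionEstimate, EmissionFactor, InventoryTable
from .taxonomy import TAXONOMY, RegionRegistry
from .units import compose_emission_gg_n2o_n

__all__ = ["emission", "gap_fill", "aggregate", "GapFilled", "StratumError"]


class StratumError(LookupError):
    """EF stratum keys do not match the activity record's attributes."""


def emission(activity: ActivityRecord, ef: EmissionFactor) -> EmissionEstimate:
    """Apply one emission factor to one activity record.

    The EF's stratum keys (climate region, land type, species, ...) must all
    be present on the activity record with equal values; its unit must
    compose with the activity unit to a mass of N2O or N2O-N.
    """
    if ef.category != activity.category:
        raise StratumError(
            f"EF is for category {ef.category!r}, activity is {activity.category!r}"
        )
    missing = []
    mismatched = []
    for key, val in ef.strata.items():
        if key not in activity.strata:
            missing.append(key)
        elif activity.strata[key] != val:
            mismatched.append((key, activity.strata[key], val))
    if missing or mismatched:
        raise StratumError(
            f"stratum mismatch for category {ef.category!r}: "
            f"missing keys {missing}, mismatched {mismatched}"
        )
    mass = compose_emission_gg_n2o_n(
        activity.value, activity.unit, ef.value, ef.unit
    )
    return EmissionEstimate(
        year=activity.year,
        province=activity.province,
        sector=TAXONOMY.sector_of(activity.category),
        category=activity.category,
        n2o_n_gg=mass,
    )


@dataclass(frozen=True)
class GapFilled:
    """A series value with provenance: substituted values carry the year
    they were borrowed from."""

    value: float
    substituted: bool
    source_year: int


def gap_fill(
    series: Mapping[int, float], years: Iterable[int]
) -> dict[int, GapFilled]:
    """Fill missing years with the nearest populated year's value.

    Ties between an earlier and a later populated year at equal distance
    break toward the later year.  Substituted values are flagged.
    """
    populated = sorted(series)
    if not populated:
        raise ValueError("cannot gap-fill an empty series")
    out: dict[int, GapFilled] = {}
    for y in years:
        if y in series:
            out[y] = GapFilled(series[y], substituted=False, source_year=y)
        else:
            # max() breaks the distance tie toward the later year
            src = max(populated, key=lambda p: (-abs(p - y), p))
            out[y] = GapFilled(series[src], substituted=True, source_year=src)
    return out


def aggregate(
    estimates: Iterable[EmissionEstimate] | InventoryTable,
    by: Sequence[str],
    registry: RegionRegistry | None = None,
):
    """Group-and-sum emission estimates; returns a frame with exact N2O-N
    sums and a Gg N2O reporting column."""
    if isinstance(estimates, InventoryTable):
        table = estimates
    else:
        table = InventoryTable.from_estimates(estimates, registry=registry)
    return table.aggregate(by)
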
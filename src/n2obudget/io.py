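"""CSV I/O for activity-data and emission-factor tables.

activity.csv: columns year, province, sector, category, variable, value,
unit (plus optional ``strata`` with semicolon-joined key=value pairs).
ef.csv: columns category, strata (semicolon-joined key=value pairs),
value, unit, low, high, distribution.
"""

from __future__ import annotations

import pandas as pd

from .records import ActivityRecord, EmissionFactor


def _parse_strata(cell) -> dict[str, str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return {}
    out = {}
    for pair in str(cell).split(";"):
        key, _, value = pair.partition("=")
        if not _:
            raise ValueError(f"malformed stratum pair {pair!r} (expected key=value)")
        out[key.strip()] = value.strip()
    return out


def _join_strata(strata) -> str:
    return ";".join(f"{k}={v}" for k, v in strata.items())


def read_activity_csv(path) -> list[ActivityRecord]:
    df = pd.read_csv(path)
    required = {"year", "province", "category", "variable", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns {sorted(missing)}")
    return [
        ActivityRecord(
            year=int(r.year), province=r.province, category=r.category,
            variable=r.variable, value=float(r.value), unit=r.unit,
            strata=_parse_strata(getattr(r, "strata", None)),
        )
        for r in df.itertuples(index=False)
    ]


def write_activity_csv(records, path) -> None:
    pd.DataFrame([
        {
            "year": r.year, "province": r.province, "category": r.category,
            "variable": r.variable, "value": r.value, "unit": r.unit,
            "strata": _join_strata(r.strata),
        }
        for r in records
    ]).to_csv(path, index=False)


def read_ef_csv(path) -> list[EmissionFactor]:
    df = pd.read_csv(path)
    required = {"category", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EF table missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        def _opt(name):
            v = getattr(r, name, None)
            return None if v is None or (isinstance(v, float) and pd.isna(v)) else v
        out.append(EmissionFactor(
            category=r.category, value=float(r.value), unit=r.unit,
            strata=_parse_strata(getattr(r, "strata", None)),
            low=_opt("low"), high=_opt("high"),
            distribution=_opt("distribution"),
        ))
    return out


def write_ef_csv(factors, path) -> None:
    pd.DataFrame([
        {
            "category": f.category, "strata": _join_strata(f.strata),
            "value": f.value, "unit": f.unit, "low": f.low, "high": f.high,
            "distribution": f.distribution,
        }
        for f in factors
    ]).to_csv(path, index=False)
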
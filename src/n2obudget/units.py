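"""Unit handling for the emission-factor engine.

The inventory works internally on an N2O-N mass basis (Gg N2O-N yr^-1);
reported tables are in Gg N2O.  Activity data arrive in a small closed set
of unit families (mass of N, mass of product/dry matter, energy in TJ,
head counts), and emission factors are expressed as <mass of N2O or N2O-N>
per <activity unit>.  This module parses those strings and composes them.
"""

from __future__ import annotations

import re

__all__ = [
    "UnitError",
    "N2O_N_TO_N2O",
    "n2o_n_to_n2o",
    "n2o_to_n2o_n",
    "parse_activity_unit",
    "parse_ef_unit",
    "compose_emission_gg_n2o_n",
]

# molar masses: N2O = 44 g/mol carries 28 g/mol of N
N2O_N_TO_N2O = 44.0 / 28.0

# mass multipliers to kg
_MASS = {"kg": 1.0, "t": 1e3, "kt": 1e6, "Gg": 1e6, "Tg": 1e9}

# unit "kinds" an EF denominator can bind to
_KINDS = {"N", "product", "dm", "TJ", "head"}


class UnitError(ValueError):
    """Raised when activity and emission-factor units do not compose."""


def n2o_n_to_n2o(mass_n2o_n: float) -> float:
    """Convert a mass on the N2O-N basis to the N2O basis (x 44/28)."""
    if mass_n2o_n < 0:
        raise ValueError(f"mass must be non-negative, got {mass_n2o_n}")
    return mass_n2o_n * N2O_N_TO_N2O


def n2o_to_n2o_n(mass_n2o: float) -> float:
    """Convert a mass of N2O to the nitrogen it contains (x 28/44)."""
    if mass_n2o < 0:
        raise ValueError(f"mass must be non-negative, got {mass_n2o}")
    return mass_n2o / N2O_N_TO_N2O


def parse_activity_unit(unit: str) -> tuple[float, str]:
    """Parse an activity unit into (multiplier to kg-or-native, kind).

    Accepted forms: ``"Gg N"``, ``"kt"`` (bare mass -> product), ``"kt dm"``,
    ``"TJ"``, ``"head"``.  For ``TJ`` and ``head`` the multiplier is 1 and
    the value is in native units.
    """
    s = unit.strip()
    if s == "TJ":
        return 1.0, "TJ"
    if s == "head":
        return 1.0, "head"
    parts = s.split()
    if parts and parts[0] in _MASS:
        mult = _MASS[parts[0]]
        kind = " ".join(parts[1:]) or "product"
        if kind not in _KINDS - {"TJ", "head"}:
            raise UnitError(f"unknown activity unit kind in {unit!r}")
        return mult, kind
    raise UnitError(f"cannot parse activity unit {unit!r}")


_EF_RE = re.compile(
    r"^\s*(?P<num_mass>kg|t|kt|Gg)\s+(?P<species>N2O-N|N2O)\s*"
    r"(?:/|per)\s*(?P<den>.+?)\s*$"
)


def parse_ef_unit(unit: str) -> tuple[float, str, float, str]:
    """Parse an EF unit like ``"kg N2O-N / kg N"`` or ``"kg N2O per TJ"``.

    Returns (numerator kg multiplier, species, denominator multiplier, kind).
    """
    m = _EF_RE.match(unit)
    if m is None:
        raise UnitError(f"cannot parse emission-factor unit {unit!r}")
    num_mult = _MASS[m.group("num_mass")]
    species = m.group("species")
    den = m.group("den")
    if den == "TJ":
        return num_mult, species, 1.0, "TJ"
    if den == "head":
        return num_mult, species, 1.0, "head"
    parts = den.split()
    if parts and parts[0] in _MASS:
        den_mult = _MASS[parts[0]]
        kind = " ".join(parts[1:]) or "product"
        if kind not in _KINDS - {"TJ", "head"}:
            raise UnitError(f"unknown EF denominator kind in {unit!r}")
        return num_mult, species, den_mult, kind
    raise UnitError(f"cannot parse EF denominator {den!r} in {unit!r}")


def compose_emission_gg_n2o_n(
    activity_value: float,
    activity_unit: str,
    ef_value: float,
    ef_unit: str,
) -> float:
    """AD x EF with unit composition, returning Gg N2O-N.

    Raises :class:`UnitError` naming both units when the EF denominator
    kind does not match the activity unit kind.
    """
    ad_mult, ad_kind = parse_activity_unit(activity_unit)
    num_mult, species, den_mult, ef_kind = parse_ef_unit(ef_unit)
    if ad_kind != ef_kind:
        raise UnitError(
            f"activity unit {activity_unit!r} (kind {ad_kind}) is incompatible "
            f"with EF unit {ef_unit!r} (per {ef_kind})"
        )
    emission_kg = activity_value * ad_mult * ef_value * (num_mult / den_mult)
    if species == "N2O":
        emission_kg = emission_kg / N2O_N_TO_N2O
    return emission_kg / _MASS["Gg"]
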
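"""Unit conversions at the I/O boundary.

Internally everything is millimolar glucose (mM), picomolar insulin (pM)
and minutes.  Clinical sources usually report mg/dL and uU/mL; the
conversion factors used are 180 mg/dL = 10 mM for glucose and
1 uU/mL = 6.945 pM for insulin, applied as exact linear maps.
"""

from __future__ import annotations

from .errors import ConfigError

#: mg/dL per mM of glucose (180 mg/dL = 10 mM).
MGDL_PER_MM = 18.0
#: pM per uU/mL of insulin.
PM_PER_UUML = 6.945
#: grams of glucose per mmol on the same scale as the glycemia factor.
GLUCOSE_G_PER_MMOL = 0.18

_GLYCEMIA_ALIASES = {
    "mg/dl": "mg/dL",
    "mg/dL": "mg/dL",
    "mgdl": "mg/dL",
    "mm": "mM",
    "mM": "mM",
    "mmol/l": "mM",
    "mmol/L": "mM",
}

_INSULIN_ALIASES = {
    "uu/ml": "uU/mL",
    "uU/mL": "uU/mL",
    "μu/ml": "uU/mL",  # μU/mL
    "µu/ml": "uU/mL",  # µU/mL (micro sign)
    "uiu/ml": "uU/mL",
    "mu/l": "uU/mL",  # mU/L is numerically identical to uU/mL
    "pm": "pM",
    "pM": "pM",
    "pmol/l": "pM",
    "pmol/L": "pM",
}


def _canonical(unit: str, aliases: dict, kind: str) -> str:
    try:
        return aliases[unit]
    except KeyError:
        pass
    try:
        return aliases[unit.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown {kind} unit {unit!r}; known units: {sorted(set(aliases.values()))}"
        ) from None


def convert_glycemia(value, from_unit: str, to_unit: str):
    """Convert a glucose concentration between mg/dL and mM.

    Accepts scalars or numpy arrays; the map is exactly linear, so a
    round trip reproduces the input.
    """
    src = _canonical(from_unit, _GLYCEMIA_ALIASES, "glycemia")
    dst = _canonical(to_unit, _GLYCEMIA_ALIASES, "glycemia")
    if src == dst:
        return value
    if src == "mg/dL":  # -> mM
        return value / MGDL_PER_MM
    return value * MGDL_PER_MM


def convert_insulinemia(value, from_unit: str, to_unit: str):
    """Convert an insulin concentration between uU/mL and pM."""
    src = _canonical(from_unit, _INSULIN_ALIASES, "insulinemia")
    dst = _canonical(to_unit, _INSULIN_ALIASES, "insulinemia")
    if src == dst:
        return value
    if src == "uU/mL":  # -> pM
        return value * PM_PER_UUML
    return value / PM_PER_UUML


def glucose_grams_to_mmol(grams: float) -> float:
    """Convert a glucose dose in grams to mmol (75 g -> 416.67 mmol)."""
    return grams / GLUCOSE_G_PER_MMOL
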
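"""Unit system and conversions.

All internal quantities use lengths in nm and energies in units of the
thermal energy k_BT at T = 298 K, for which k_BT = 4.114 pN nm.  Moduli
quoted in the experimental literature in mN/m (stretching modulus K_m) or
pN (pore rim line tension λ) are converted on input:

    1 mN/m = 1 pN/nm = (1/4.114) k_BT/nm^2 ≈ 0.2431 k_BT/nm^2
    1 pN   = (1/4.114) k_BT/nm  ≈ 0.2431 k_BT/nm
"""

from __future__ import annotations

import re

KBT_PN_NM = 4.114  # k_BT in pN*nm at T = 298 K

MN_PER_M_TO_KBT_PER_NM2 = 1.0 / KBT_PN_NM  # 1 mN/m = 1 pN/nm
PN_TO_KBT_PER_NM = 1.0 / KBT_PN_NM

#: conversion factors to internal units, keyed by unit string
_UNIT_FACTORS = {
    "kbt": 1.0,
    "kbt/nm": 1.0,
    "kbt/nm2": 1.0,
    "kbt/nm^2": 1.0,
    "nm": 1.0,
    "nm^-1": 1.0,
    "1/nm": 1.0,
    "mn/m": MN_PER_M_TO_KBT_PER_NM2,
    "pn": PN_TO_KBT_PER_NM,
    "pn/nm": MN_PER_M_TO_KBT_PER_NM2,
    "un/m": 1e-3 * MN_PER_M_TO_KBT_PER_NM2,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Z/^0-9_\-]*)\s*$")


def parse_quantity(value, default_unit: str = "") -> float:
    """Parse a dimensioned quantity into internal units.

    Accepts plain numbers (interpreted as already internal) or strings with
    a unit suffix, e.g. ``"80 mN/m"``, ``"15 pN"``, ``"10 kBT"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _QUANTITY_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num = float(m.group(1))
    unit = (m.group(2) or default_unit).lower()
    if unit == "":
        return num
    if unit not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit {m.group(2)!r} in {value!r}")
    return num * _UNIT_FACTORS[unit]


def kbt_per_nm2_to_mn_per_m(x: float) -> float:
    """Convert a tension/stress from k_BT/nm^2 back to mN/m."""
    return x * KBT_PN_NM
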
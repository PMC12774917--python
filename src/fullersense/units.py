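"""Energy-unit conversions and length constants.

All conversions pivot through hartree so that any cycle of conversions is
exactly consistent (round trips return the start value to machine precision).
Orbital energies are handled in eV, total electronic energies in hartree,
adsorption energies in kJ/mol and cohesive energies in kcal/mol throughout
the package; every cross-unit step goes through :func:`convert_energy`.
"""

from __future__ import annotations

import math

__all__ = [
    "HARTREE_TO",
    "BOHR_TO_ANGSTROM",
    "convert_energy",
    "normalize_unit",
]

# one hartree expressed in each supported unit
HARTREE_TO: dict[str, float] = {
    "hartree": 1.0,
    "eV": 27.211386,
    "kJ/mol": 2625.4996,
    "kcal/mol": 627.5095,
}

#: 1 bohr in Ångström (CODATA, truncated to the precision used in cube files)
BOHR_TO_ANGSTROM: float = 0.529177

_ALIASES = {
    "hartree": "hartree",
    "ha": "hartree",
    "au": "hartree",
    "a.u.": "hartree",
    "ev": "eV",
    "electronvolt": "eV",
    "kj/mol": "kJ/mol",
    "kjmol": "kJ/mol",
    "kj_mol": "kJ/mol",
    "kcal/mol": "kcal/mol",
    "kcalmol": "kcal/mol",
    "kcal_mol": "kcal/mol",
}


def normalize_unit(unit: str) -> str:
    """Map a unit spelling to its canonical name; raise on unknown tags."""
    try:
        return _ALIASES[unit.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown energy unit {unit!r}; supported: {sorted(set(_ALIASES.values()))}"
        ) from None


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between energy units.

    Parameters
    ----------
    value:
        Finite energy in ``from_unit``.
    from_unit, to_unit:
        Unit tags; case-insensitive, common aliases accepted
        (``hartree``/``ha``/``au``, ``eV``, ``kJ/mol``, ``kcal/mol``).
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot convert non-finite energy {value!r}")
    src = HARTREE_TO[normalize_unit(from_unit)]
    dst = HARTREE_TO[normalize_unit(to_unit)]
    return value * (dst / src)
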
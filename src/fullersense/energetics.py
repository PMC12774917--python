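"""Adsorption and cohesive energetics, and the dipole polarization shift.

The BSSE-corrected adsorption energy of an analyte on a sensor is
``E_ads = E_complex − (E_sensor + E_analyte) + E_BSSE`` with the raw
complexation energy in hartree converted to kJ/mol and the (repulsive)
counterpoise correction already in kJ/mol; negative E_ads means binding.
Cohesive energy per atom, ``−(E_tot − Σ_i n_i E_i)/n``, measures how much
energy disassembling a cage into free atoms releases; the "equation"
convention returns that expression literally (positive for bound systems),
the "reported" convention its negation (negative for bound systems, the
form usually plotted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .units import convert_energy

__all__ = [
    "AdsorptionResult",
    "CohesiveResult",
    "adsorption_energy",
    "cohesive_energy",
    "dipole_shift",
]


@dataclass(frozen=True)
class AdsorptionResult:
    """BSSE-corrected adsorption energetics for one complex (kJ/mol)."""

    e_ads: float
    e_raw: float
    e_bsse: float
    components: tuple[str, str, str] = ("complex", "sensor", "analyte")

    @property
    def binding(self) -> bool:
        return self.e_ads < 0


@dataclass(frozen=True)
class CohesiveResult:
    """Cohesive energy per atom (kcal/mol) under a stated sign convention."""

    e_coh: float
    n_atoms: int
    convention: Literal["equation", "reported"]


def adsorption_energy(
    e_complex: float,
    e_sensor: float,
    e_analyte: float,
    e_bsse: float = 0.0,
    labels: tuple[str, str, str] = ("complex", "sensor", "analyte"),
) -> AdsorptionResult:
    """Adsorption energy from total energies (hartree) and BSSE (kJ/mol)."""
    for name, v in (("complex", e_complex), ("sensor", e_sensor), ("analyte", e_analyte)):
        if not math.isfinite(v):
            raise ValueError(f"{name} energy must be finite")
    if e_bsse < 0:
        raise ValueError("counterpoise correction must be >= 0")
    e_raw = convert_energy(e_complex - e_sensor - e_analyte, "hartree", "kJ/mol")
    return AdsorptionResult(
        e_ads=e_raw + e_bsse, e_raw=e_raw, e_bsse=e_bsse, components=labels
    )


def cohesive_energy(
    e_total: float,
    atom_energies: Mapping[str, float],
    counts: Mapping[str, int],
    convention: Literal["equation", "reported"] = "reported",
) -> CohesiveResult:
    """Cohesive energy per atom in kcal/mol from hartree inputs.

    ``atom_energies`` maps element symbols to isolated-atom energies
    (hartree); ``counts`` gives the atom multiset of the structure.
    """
    if convention not in ("equation", "reported"):
        raise ValueError(f"unknown convention {convention!r}")
    n = sum(counts.values())
    if n < 1:
        raise ValueError("structure must contain at least one atom")
    missing = [el for el in counts if el not in atom_energies]
    if missing:
        raise KeyError(f"no atom energy for element(s): {', '.join(sorted(missing))}")
    atoms_sum = sum(atom_energies[el] * cnt for el, cnt in counts.items())
    e_coh_hartree = -(e_total - atoms_sum) / n
    if convention == "reported":
        e_coh_hartree = -e_coh_hartree
    return CohesiveResult(
        e_coh=convert_energy(e_coh_hartree, "hartree", "kcal/mol"),
        n_atoms=n,
        convention=convention,
    )


def dipole_shift(mu_bare: float, mu_complex: float) -> tuple[float, float | None]:
    """Polarization gained on adsorption: (Δµ in debye, µ_complex/µ_bare).

    The ratio is ``None`` (undefined) for an apolar baseline (µ_bare = 0)
    rather than infinity.
    """
    if mu_bare < 0 or mu_complex < 0:
        raise ValueError("dipole magnitudes must be >= 0")
    delta = mu_complex - mu_bare
    ratio = mu_complex / mu_bare if mu_bare > 0 else None
    return delta, ratio
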
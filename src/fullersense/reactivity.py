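"""Conceptual-DFT global reactivity descriptors and related quantities.

From the frontier-orbital energies of a structure the Koopmans-style global
descriptors follow: the HOMO–LUMO gap HLG = |E_HOMO − E_LUMO|, chemical
hardness η = HLG/2, chemical potential µ = (E_HOMO + E_LUMO)/2, softness
S = 1/(2η) and the maximum charge acceptance ΔNmax = −µ/η. The
electrophilicity-based charge transfer ECT compares ΔNmax of a sensor–analyte
complex with that of the bare sensor; a negative value indicates electron
flow from the analyte into the sensor. Also here: the NBO second-order
stabilization energy E(2) = q·F(i,j)²/ΔE and Gaussian-broadened density-of-
states curves from discrete orbital-level lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import QCRecord
from .units import convert_energy

__all__ = [
    "DegenerateGapError",
    "ReactivityDescriptors",
    "DOSCurve",
    "frontier_descriptors",
    "ect",
    "nbo_e2",
    "dos_curve",
    "descriptor_table",
]


class DegenerateGapError(ValueError):
    """Raised when HOMO and LUMO coincide, leaving S and ΔNmax undefined."""


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Global reactivity descriptors of a single structure (all energies eV)."""

    hlg: float  # HOMO–LUMO gap, eV
    hardness_eta: float  # η = HLG/2, eV
    potential_mu: float  # µ = (E_HOMO + E_LUMO)/2, eV
    softness_s: float  # S = 1/(2η), 1/eV
    dn_max: float  # ΔNmax = −µ/η, dimensionless


def frontier_descriptors(e_homo: float, e_lumo: float) -> ReactivityDescriptors:
    """Compute the global descriptors from frontier-orbital energies in eV.

    Raises
    ------
    DegenerateGapError
        If the gap vanishes (softness and ΔNmax would be infinite).
    """
    if not (math.isfinite(e_homo) and math.isfinite(e_lumo)):
        raise ValueError("frontier energies must be finite")
    if e_lumo < e_homo:
        raise ValueError(f"LUMO ({e_lumo}) below HOMO ({e_homo})")
    hlg = abs(e_homo - e_lumo)
    if hlg == 0.0:
        raise DegenerateGapError(
            "degenerate frontier orbitals: softness and ΔNmax are undefined"
        )
    eta = hlg / 2.0
    mu = (e_homo + e_lumo) / 2.0
    return ReactivityDescriptors(
        hlg=hlg,
        hardness_eta=eta,
        potential_mu=mu,
        softness_s=1.0 / (2.0 * eta),
        dn_max=-mu / eta,
    )


def ect(dn_max_complex: float, dn_max_sensor: float) -> float:
    """Electrophilicity-based charge transfer between complex and bare sensor.

    Returned as sensor − complex: negative when the complex accepts more
    charge than the bare sensor, i.e. electron flow from analyte to sensor.
    (The opposite subtraction order merely flips the sign; this convention is
    the one whose sign matches the reported charge-flow direction.)
    """
    return dn_max_sensor - dn_max_complex


def nbo_e2(f_ij: float, delta_e: float, occupancy: float = 1.0) -> float:
    """NBO second-order stabilization energy in kcal/mol.

    ``E(2) = occupancy · F(i,j)² / ΔE`` with the Fock matrix element ``f_ij``
    and orbital-energy difference ``delta_e`` both in hartree.
    """
    if delta_e <= 0:
        raise ValueError("donor–acceptor energy difference must be positive")
    if occupancy <= 0:
        raise ValueError("occupancy must be positive")
    if not math.isfinite(f_ij):
        raise ValueError("Fock element must be finite")
    return convert_energy(occupancy * f_ij**2 / delta_e, "hartree", "kcal/mol")


@dataclass(frozen=True)
class DOSCurve:
    """A Gaussian-broadened density-of-states curve (states per eV)."""

    energies: np.ndarray  # eV
    density: np.ndarray  # states / eV
    broadening: float  # Gaussian standard deviation, eV


def dos_curve(
    levels: Sequence[float],
    broadening: float,
    grid: Sequence[float] | None = None,
) -> DOSCurve:
    """Sum of unit-area Gaussians centered at the orbital levels.

    The default grid spans the levels ±5 broadenings with 2001 points, wide
    enough that the curve integrates to the number of levels within 0.1%.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("need at least one orbital level")
    if broadening <= 0:
        raise ValueError("broadening must be positive")
    if grid is None:
        lo = levels.min() - 5 * broadening
        hi = levels.max() + 5 * broadening
        grid = np.linspace(lo, hi, 2001)
    energies = np.asarray(grid, dtype=float)
    norm = 1.0 / (broadening * math.sqrt(2.0 * math.pi))
    z = (energies[:, None] - levels[None, :]) / broadening
    density = norm * np.exp(-0.5 * z**2).sum(axis=1)
    return DOSCurve(energies=energies, density=density, broadening=float(broadening))


def descriptor_table(records: Iterable[QCRecord]) -> pd.DataFrame:
    """Descriptor table with one row per record, columns ordered as reported.

    Complex records that name their bare sensor via ``components["sensor"]``
    get an ECT column entry; bare structures leave it empty.
    """
    records = list(records)
    dn_by_label = {}
    rows = []
    for rec in records:
        d = frontier_descriptors(rec.e_homo, rec.e_lumo)
        dn_by_label[rec.label] = d.dn_max
        rows.append(
            {
                "label": rec.label,
                "e_lumo_eV": rec.e_lumo,
                "e_homo_eV": rec.e_homo,
                "hlg_eV": d.hlg,
                "eta_eV": d.hardness_eta,
                "mu_eV": d.potential_mu,
                "softness_per_eV": d.softness_s,
                "dn_max": d.dn_max,
                "ect": np.nan,
            }
        )
    for rec, row in zip(records, rows):
        sensor = (rec.components or {}).get("sensor")
        if sensor is not None:
            if sensor not in dn_by_label:
                raise KeyError(f"{rec.label}: unknown sensor label {sensor!r}")
            row["ect"] = ect(row["dn_max"], dn_by_label[sensor])
    return pd.DataFrame(rows)
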
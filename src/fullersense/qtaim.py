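"""Bond-critical-point location and energy-density analysis of a density field.

A critical point of the electron density is a zero of ∇ρ; its (rank,
signature) label comes from the Hessian eigenvalue signs. A bond critical
point (BCP) is the (3, −1) case — one positive curvature along the bond path,
two negative across it. Points are found by damped Newton iteration from
caller-supplied seeds (midpoints of candidate atom pairs work well).

At each point the kinetic energy density is estimated with the Abramov
closed-shell expression G = (3/10)(3π²)^{2/3} ρ^{5/3} + (1/6)∇²ρ, the
potential energy density from the local virial theorem V = (1/4)∇²ρ − 2G,
and the total energy density Hb = G + V. Bond character follows the
sign-pattern classification of Hb and ∇²ρ (Rozas-style): the default
variant is strong (Hb < 0, ∇²ρ < 0), moderate (Hb > 0, ∇²ρ < 0), weak
(Hb > 0, ∇²ρ > 0); a ``"literature"`` variant uses the original ordering
with moderate at (Hb < 0, ∇²ρ > 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .fields import ScalarField
from .records import Geometry
from .units import BOHR_TO_ANGSTROM

__all__ = [
    "CriticalPoint",
    "ABRAMOV_COEFF",
    "energy_densities",
    "total_energy_density",
    "rozas_class",
    "find_bcp",
    "midpoint_seeds",
    "cp_table",
]

#: (3/10)(3π²)^{2/3}, the Thomas–Fermi coefficient in the Abramov estimate
ABRAMOV_COEFF = 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)

BondClass = Literal["strong", "moderate", "weak", "unclassified"]


@dataclass(frozen=True)
class CriticalPoint:
    """A located stationary point of ρ with curvature and energy densities."""

    position: np.ndarray  # (3,) bohr
    rho: float  # a.u.
    laplacian: float  # a.u.
    eigenvalues: np.ndarray  # ascending triple
    rank: int  # count of nonzero eigenvalues
    signature: int  # sum of eigenvalue signs
    g: float  # Abramov kinetic energy density, a.u.
    v: float  # virial potential energy density, a.u.
    hb: float  # total energy density G + V, a.u.
    bond_class: BondClass

    @property
    def is_bcp(self) -> bool:
        return self.rank == 3 and self.signature == -1


def energy_densities(rho: float, laplacian: float) -> tuple[float, float, float]:
    """Abramov G, virial V and Hb = G + V from ρ and ∇²ρ (all a.u.).

    Estimates are valid in the low-density closed-shell regions typical of
    non-covalent contacts; no clamping is applied.
    """
    if rho < 0:
        raise ValueError("electron density must be >= 0")
    g = ABRAMOV_COEFF * rho ** (5.0 / 3.0) + laplacian / 6.0
    v = 0.25 * laplacian - 2.0 * g
    return g, v, g + v


def total_energy_density(g: float, v: float) -> float:
    """Total energy density Hb = G + V."""
    if not (math.isfinite(g) and math.isfinite(v)):
        raise ValueError("energy densities must be finite")
    return g + v


def rozas_class(
    hb: float,
    laplacian: float,
    variant: Literal["as_stated", "literature"] = "as_stated",
) -> BondClass:
    """Bond-strength class from the signs of Hb and ∇²ρ.

    ``as_stated`` (default): strong (Hb<0, ∇²ρ<0), moderate (Hb>0, ∇²ρ<0),
    weak (Hb>0, ∇²ρ>0). ``literature``: strong (Hb<0, ∇²ρ<0), moderate
    (Hb<0, ∇²ρ>0), weak (Hb>0, ∇²ρ>0). Boundary and other sign patterns are
    ``unclassified``.
    """
    if variant == "as_stated":
        if hb < 0 and laplacian < 0:
            return "strong"
        if hb > 0 and laplacian < 0:
            return "moderate"
        if hb > 0 and laplacian > 0:
            return "weak"
    elif variant == "literature":
        if hb < 0 and laplacian < 0:
            return "strong"
        if hb < 0 and laplacian > 0:
            return "moderate"
        if hb > 0 and laplacian > 0:
            return "weak"
    else:
        raise ValueError(f"unknown classification variant {variant!r}")
    return "unclassified"


def _newton_refine(
    field: ScalarField,
    seed: np.ndarray,
    max_steps: int,
    grad_tol: float,
    step_cap: float,
) -> np.ndarray | None:
    x = np.asarray(seed, dtype=float).reshape(3).copy()
    for _ in range(max_steps):
        g = field.gradient(x)
        if float(np.linalg.norm(g)) < grad_tol:
            return x
        h = field.hessian(x)
        try:
            step = -np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(h) @ g
        norm = float(np.linalg.norm(step))
        if not math.isfinite(norm):
            return None
        if norm > step_cap:
            step *= step_cap / norm
        x = x + step
    return x if float(np.linalg.norm(field.gradient(x))) < grad_tol else None


def find_bcp(
    field: ScalarField,
    seeds: Iterable[Sequence[float]],
    max_steps: int = 100,
    grad_tol: float = 1e-8,
    step_cap: float = 0.5,
    dedup_tol: float = 1e-3,
    zero_eig: float = 1e-6,
    variant: Literal["as_stated", "literature"] = "as_stated",
) -> list[CriticalPoint]:
    """Locate rank-3 critical points of ρ by damped Newton iteration.

    Each seed is refined toward ∇ρ = 0 (step length capped at ``step_cap``
    bohr, convergence at |∇ρ| < ``grad_tol``); converged points closer than
    ``dedup_tol`` bohr are merged. Non-convergent seeds are dropped with a
    warning. All rank-3 points are returned, whatever their signature —
    filter with :attr:`CriticalPoint.is_bcp` for (3, −1) points only.
    Rank-deficient points (an eigenvalue below ``zero_eig`` in magnitude)
    are reported via warning and excluded.
    """
    found: list[np.ndarray] = []
    for seed in seeds:
        x = _newton_refine(field, np.asarray(seed, dtype=float), max_steps,
                           grad_tol, step_cap)
        if x is None:
            warnings.warn(
                f"seed {np.asarray(seed, dtype=float)} did not converge; dropped",
                stacklevel=2,
            )
            continue
        if any(float(np.linalg.norm(x - y)) < dedup_tol for y in found):
            continue
        found.append(x)

    points: list[CriticalPoint] = []
    for x in found:
        sample = field.sample(x)
        eig = sample.eigenvalues
        nonzero = np.abs(eig) > zero_eig
        rank = int(np.count_nonzero(nonzero))
        if rank < 3:
            warnings.warn(
                f"rank-deficient critical point at {x} (rank {rank}); excluded",
                stacklevel=2,
            )
            continue
        signature = int(np.sum(np.sign(eig[nonzero])))
        g, v, hb = energy_densities(max(sample.rho, 0.0), sample.laplacian)
        points.append(
            CriticalPoint(
                position=x,
                rho=sample.rho,
                laplacian=sample.laplacian,
                eigenvalues=eig,
                rank=rank,
                signature=signature,
                g=g,
                v=v,
                hb=hb,
                bond_class=rozas_class(hb, sample.laplacian, variant),
            )
        )
    return points


def midpoint_seeds(
    fragment_a: Geometry,
    fragment_b: Geometry,
    max_distance_bohr: float = 8.0,
) -> list[np.ndarray]:
    """Midpoints (bohr) of inter-fragment atom pairs closer than a cutoff.

    Geometries are in Å (package convention); the returned seed coordinates
    are in bohr to match the density fields. Bond paths of interest in a
    sensor–analyte complex are the inter-fragment contacts, so pairs within
    one fragment are never seeded.
    """
    a = fragment_a.coords / BOHR_TO_ANGSTROM
    b = fragment_b.coords / BOHR_TO_ANGSTROM
    seeds = []
    for pa in a:
        for pb in b:
            if float(np.linalg.norm(pa - pb)) < max_distance_bohr:
                seeds.append(0.5 * (pa + pb))
    return seeds


def cp_table(points: Sequence[CriticalPoint]) -> pd.DataFrame:
    """Critical-point report: one row per point, Abramov/virial G and V."""
    rows = []
    for p in points:
        rows.append(
            {
                "x_bohr": p.position[0],
                "y_bohr": p.position[1],
                "z_bohr": p.position[2],
                "rho_au": p.rho,
                "laplacian_au": p.laplacian,
                "lambda1_au": p.eigenvalues[0],
                "lambda2_au": p.eigenvalues[1],
                "lambda3_au": p.eigenvalues[2],
                "rank": p.rank,
                "signature": p.signature,
                "g_abramov_au": p.g,
                "v_virial_au": p.v,
                "hb_au": p.hb,
                "bond_class": p.bond_class,
            }
        )
    return pd.DataFrame(rows)
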
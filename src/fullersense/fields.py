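"""Evaluable electron-density fields and NCI/RDG analysis.

Two field backends share one interface: an analytic *promolecular* field —
a sum of atom-centered isotropic Gaussians whose gradient and Hessian have
closed forms (the differentiable synthetic stand-in for a quantum-mechanical
density) — and a *grid* field backed by a cube file, with trilinear value
interpolation and second-order central finite differences for derivatives
(one-sided at boundaries).

The non-covalent-interaction (NCI) analysis maps each probe point to
``(s, RDG)`` with ``s = sign(λ2)·ρ`` (λ2 the middle Hessian eigenvalue) and
the reduced density gradient ``RDG = |∇ρ| / (2 (3π²)^{1/3} ρ^{4/3})``.
Negative ``s`` marks attractive accumulation (hydrogen bonds, π–π stacking),
values near zero van der Waals contact, positive ``s`` steric repulsion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .cube import CubeGrid

__all__ = [
    "SyntheticAtom",
    "FieldSample",
    "ScalarField",
    "PromolecularField",
    "GridField",
    "promolecular_field",
    "grid_field",
    "nci_point",
    "nci_scan",
    "classify_nci",
    "NCIScatter",
    "RDG_PREFACTOR",
    "DEFAULT_RHO_FLOOR",
    "DEFAULT_RHO_CEILING",
    "DEFAULT_T_ATTR",
    "DEFAULT_T_REP",
]

#: 2 (3π²)^{1/3}, the RDG denominator prefactor
RDG_PREFACTOR = 2.0 * (3.0 * math.pi**2) ** (1.0 / 3.0)

DEFAULT_RHO_FLOOR = 1e-8  # a.u.; below this a point is numerical vacuum
DEFAULT_RHO_CEILING = 0.05  # a.u.; above this a point is intramolecular
DEFAULT_T_ATTR = -0.01  # a.u.; s below this counts as attractive
DEFAULT_T_REP = 0.01  # a.u.; s above this counts as repulsive


@dataclass(frozen=True)
class SyntheticAtom:
    """An isotropic Gaussian density ρ(r) = amplitude·exp(−exponent·|r−center|²)."""

    center: np.ndarray  # (3,) bohr
    amplitude: float = 1.0  # a.u.
    exponent: float = 1.0  # 1/bohr²

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )
        if self.amplitude <= 0 or self.exponent <= 0:
            raise ValueError("amplitude and exponent must be positive")


@dataclass(frozen=True)
class FieldSample:
    """Density, gradient and (symmetrized) Hessian at one point."""

    rho: float
    grad: np.ndarray  # (3,)
    hessian: np.ndarray  # (3, 3), symmetric
    eigenvalues: np.ndarray  # ascending (λ1 ≤ λ2 ≤ λ3)

    @property
    def lambda2(self) -> float:
        """Middle Hessian eigenvalue, the NCI bonding discriminator."""
        return float(self.eigenvalues[1])

    @property
    def laplacian(self) -> float:
        return float(np.trace(self.hessian))


def _make_sample(rho: float, grad: np.ndarray, hessian: np.ndarray) -> FieldSample:
    hessian = 0.5 * (hessian + hessian.T)
    return FieldSample(
        rho=float(rho),
        grad=np.asarray(grad, dtype=float),
        hessian=hessian,
        eigenvalues=np.linalg.eigvalsh(hessian),
    )


class ScalarField:
    """Interface: density value, gradient and Hessian at arbitrary points."""

    def rho(self, point: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, point: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def hessian(self, point: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sample(self, point: np.ndarray) -> FieldSample:
        point = np.asarray(point, dtype=float).reshape(3)
        return _make_sample(self.rho(point), self.gradient(point), self.hessian(point))


class PromolecularField(ScalarField):
    """Sum of atom-centered isotropic Gaussians, differentiable in closed form."""

    def __init__(self, atoms: Sequence[SyntheticAtom]):
        if not atoms:
            raise ValueError("a promolecular field needs at least one atom")
        self.atoms = tuple(atoms)
        self._centers = np.stack([a.center for a in self.atoms])  # (m, 3)
        self._amps = np.array([a.amplitude for a in self.atoms])
        self._exps = np.array([a.exponent for a in self.atoms])

    def _terms(self, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.asarray(point, dtype=float).reshape(3)[None, :] - self._centers
        vals = self._amps * np.exp(-self._exps * np.einsum("ij,ij->i", d, d))
        return d, vals

    def rho(self, point: np.ndarray) -> float:
        _, vals = self._terms(point)
        return float(vals.sum())

    def gradient(self, point: np.ndarray) -> np.ndarray:
        d, vals = self._terms(point)
        return (-2.0 * self._exps * vals) @ d

    def hessian(self, point: np.ndarray) -> np.ndarray:
        d, vals = self._terms(point)
        h = np.zeros((3, 3))
        for di, a, v in zip(d, self._exps, vals):
            h += v * (4.0 * a * a * np.outer(di, di) - 2.0 * a * np.eye(3))
        return h


class GridField(ScalarField):
    """Cube-backed field: trilinear values, finite-difference derivatives.

    Axes must be mutually orthogonal (not necessarily axis-aligned). Values,
    gradients and Hessians are precomputed on the grid — derivatives by
    second-order central differences, one-sided at boundaries — and each is
    interpolated trilinearly at probe points. Probes outside the box are
    clamped to the nearest face with a warning.
    """

    def __init__(self, grid: CubeGrid):
        axes = grid.axes
        gram = axes @ axes.T
        off = gram - np.diag(np.diag(gram))
        if np.max(np.abs(off)) > 1e-8 * np.max(np.abs(gram)):
            raise ValueError(
                "non-orthogonal cube axes are unsupported for derivative work"
            )
        if any(c < 5 for c in grid.counts):
            raise ValueError("need >= 5 points per axis for interior Hessians")
        self.grid = grid
        self._steps = grid.spacings  # (3,)
        self._units = axes / self._steps[:, None]  # orthonormal frame, rows
        self._origin = grid.origin
        coords = [np.arange(n) * s for n, s in zip(grid.counts, self._steps)]
        self._limits = np.array([c[-1] for c in coords])

        vals = grid.values
        # first derivatives along each (frame) axis
        grads = np.stack(
            [np.gradient(vals, self._steps[i], axis=i, edge_order=2) for i in range(3)]
        )
        # Hessian components in the frame; mixed partials averaged for symmetry
        hess = np.empty((3, 3) + vals.shape)
        for i in range(3):
            for j in range(i, 3):
                hij = np.gradient(grads[i], self._steps[j], axis=j, edge_order=2)
                if i != j:
                    hji = np.gradient(grads[j], self._steps[i], axis=i, edge_order=2)
                    hij = 0.5 * (hij + hji)
                hess[i, j] = hij
                hess[j, i] = hij

        def interp(a: np.ndarray) -> RegularGridInterpolator:
            return RegularGridInterpolator(coords, a, method="linear")

        self._rho = interp(vals)
        self._grad = [interp(grads[i]) for i in range(3)]
        self._hess = [[interp(hess[i, j]) for j in range(3)] for i in range(3)]

    def _frame_coords(self, point: np.ndarray) -> np.ndarray:
        u = self._units @ (np.asarray(point, dtype=float).reshape(3) - self._origin)
        clamped = np.clip(u, 0.0, self._limits)
        if not np.allclose(u, clamped, atol=1e-12):
            warnings.warn("probe outside the grid box; clamped to the boundary",
                          stacklevel=3)
        return clamped

    def rho(self, point: np.ndarray) -> float:
        return float(self._rho(self._frame_coords(point)).item())

    def gradient(self, point: np.ndarray) -> np.ndarray:
        u = self._frame_coords(point)
        g_frame = np.array([g(u).item() for g in self._grad])
        return self._units.T @ g_frame

    def hessian(self, point: np.ndarray) -> np.ndarray:
        u = self._frame_coords(point)
        h_frame = np.array(
            [[self._hess[i][j](u).item() for j in range(3)] for i in range(3)]
        )
        return self._units.T @ h_frame @ self._units


def promolecular_field(atoms: Sequence[SyntheticAtom]) -> PromolecularField:
    """Build an analytic promolecular field from Gaussian atoms."""
    return PromolecularField(atoms)


def grid_field(grid: CubeGrid) -> GridField:
    """Wrap a cube grid as an evaluable field."""
    return GridField(grid)


def nci_point(sample: FieldSample) -> tuple[float, float]:
    """Map a field sample to the NCI plane: (sign(λ2)·ρ, RDG).

    The caller must have filtered out vacuum points: ``rho <= 0`` is an error
    because the RDG denominator vanishes.
    """
    if sample.rho <= 0:
        raise ValueError("nci_point requires rho > 0; filter low-density points")
    lam2 = sample.lambda2
    sign = 0.0 if lam2 == 0.0 else math.copysign(1.0, lam2)
    s = sign * sample.rho
    rdg = float(np.linalg.norm(sample.grad)) / (RDG_PREFACTOR * sample.rho ** (4.0 / 3.0))
    return s, rdg


@dataclass(frozen=True)
class NCIScatter:
    """NCI plot data: (s, rdg) points plus interaction-bin counts."""

    points: np.ndarray  # (n, 2): columns s, rdg
    attractive: int
    vdw: int
    repulsive: int
    rho_floor: float
    rho_ceiling: float
    t_attr: float
    t_rep: float

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def classify_nci(
    s_values: np.ndarray | Sequence[float],
    t_attr: float = DEFAULT_T_ATTR,
    t_rep: float = DEFAULT_T_REP,
) -> tuple[int, int, int]:
    """Bin sign(λ2)·ρ values into (attractive, vdW, repulsive) counts.

    Bins are exhaustive and exclusive: attractive s < t_attr, repulsive
    s > t_rep, van der Waals otherwise.
    """
    if not t_attr < 0 < t_rep:
        raise ValueError("thresholds must straddle zero: t_attr < 0 < t_rep")
    s = np.asarray(s_values, dtype=float)
    attractive = int(np.sum(s < t_attr))
    repulsive = int(np.sum(s > t_rep))
    return attractive, int(s.size - attractive - repulsive), repulsive


def nci_scan(
    field_obj: ScalarField,
    lower: Sequence[float],
    upper: Sequence[float],
    spacing: float,
    rho_floor: float = DEFAULT_RHO_FLOOR,
    rho_ceiling: float = DEFAULT_RHO_CEILING,
    t_attr: float = DEFAULT_T_ATTR,
    t_rep: float = DEFAULT_T_REP,
) -> NCIScatter:
    """Sample a box on a regular lattice and collect the NCI scatter.

    Points with density at or below ``rho_floor`` (vacuum) or at or above
    ``rho_ceiling`` (intramolecular cores) are dropped before binning.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lower = np.asarray(lower, dtype=float).reshape(3)
    upper = np.asarray(upper, dtype=float).reshape(3)
    if np.any(upper < lower):
        raise ValueError("upper corner must not be below lower corner")
    axes = [np.arange(lo, hi + 0.5 * spacing, spacing) for lo, hi in zip(lower, upper)]
    pts: list[tuple[float, float]] = []
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                sample = field_obj.sample(np.array([x, y, z]))
                if sample.rho <= rho_floor or sample.rho >= rho_ceiling:
                    continue
                pts.append(nci_point(sample))
    points = np.asarray(pts, dtype=float).reshape(-1, 2)
    attractive, vdw, repulsive = classify_nci(points[:, 0], t_attr, t_rep)
    return NCIScatter(
        points=points,
        attractive=attractive,
        vdw=vdw,
        repulsive=repulsive,
        rho_floor=rho_floor,
        rho_ceiling=rho_ceiling,
        t_attr=t_attr,
        t_rep=t_rep,
    )
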
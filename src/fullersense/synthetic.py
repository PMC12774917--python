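"""Synthetic inputs that make every pipeline stage testable at desk scale.

Electronic-structure runs are expensive and non-portable; these generators
replace them with exactly invertible or closed-form stand-ins:

* :func:`make_mock_record` builds a calculation summary whose frontier
  energies reproduce a prescribed gap and chemical potential exactly;
* :func:`make_dimer` builds a symmetric two-Gaussian density scene — the
  minimal model of a sensor–analyte contact — both as analytic atoms and as
  a sampled cube grid, so grid-based derivatives can be checked against the
  closed form;
* :func:`reference_dataset` (re-exported from :mod:`fullersense.fixture`) is the
  bundled table of published values.

All generators are deterministic given their arguments; ``seed`` exists for
future noise injection only.
"""

from __future__ import annotations

import numpy as np

from .cube import CubeGrid
from .fields import PromolecularField, SyntheticAtom
from .fixture import ReferenceDataset, reference_dataset
from .records import QCRecord

__all__ = ["make_mock_record", "make_dimer", "reference_dataset", "ReferenceDataset"]


def make_mock_record(
    target_hlg: float,
    target_mu: float,
    label: str = "mock",
    seed: int = 0,
) -> QCRecord:
    """A record whose descriptors invert exactly to the requested targets.

    ``e_homo = µ − HLG/2`` and ``e_lumo = µ + HLG/2``, so recomputing the
    frontier descriptors recovers ``target_hlg`` and ``target_mu`` to
    machine precision.
    """
    if target_hlg <= 0:
        raise ValueError("target gap must be positive")
    half = target_hlg / 2.0
    return QCRecord(label=label, e_homo=target_mu - half, e_lumo=target_mu + half)


def make_dimer(
    separation: float,
    amplitude: float = 1.0,
    exponent: float = 1.0,
    grid_spacing: float = 0.25,
) -> tuple[tuple[SyntheticAtom, SyntheticAtom], CubeGrid]:
    """A symmetric Gaussian dimer on the z-axis plus its sampled cube.

    The two atoms sit at z = ±separation/2 (bohr). The cube box extends
    4/√exponent beyond each center along every axis — far enough that the
    density at the boundary is below 1e-6 of the peak — and node values are
    exact promolecular samples, so a grid-backed field reproduces the
    analytic one at the nodes. Deterministic by construction.
    """
    if separation <= 0 or amplitude <= 0 or exponent <= 0 or grid_spacing <= 0:
        raise ValueError("separation, amplitude, exponent and spacing must be positive")
    margin = 4.0 / np.sqrt(exponent)
    half_z = separation / 2.0 + margin
    half_xy = margin
    if grid_spacing > 2.0 * half_xy:
        raise ValueError("grid spacing exceeds the box size")
    atoms = (
        SyntheticAtom(center=np.array([0.0, 0.0, -separation / 2.0]),
                      amplitude=amplitude, exponent=exponent),
        SyntheticAtom(center=np.array([0.0, 0.0, separation / 2.0]),
                      amplitude=amplitude, exponent=exponent),
    )
    field = PromolecularField(atoms)

    def axis(half: float) -> np.ndarray:
        n = int(np.floor(2.0 * half / grid_spacing)) + 1
        # center the (symmetric) axis on the origin so the mirror plane is a node plane
        return (np.arange(n) - (n - 1) / 2.0) * grid_spacing

    xs, ys, zs = axis(half_xy), axis(half_xy), axis(half_z)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    diffs = pts[:, None, :] - np.stack([a.center for a in atoms])[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diffs, diffs)
    values = (amplitude * np.exp(-exponent * r2)).sum(axis=1)
    grid = CubeGrid(
        origin=np.array([xs[0], ys[0], zs[0]]),
        axes=np.diag([grid_spacing] * 3),
        counts=(len(xs), len(ys), len(zs)),
        atoms=[(1, 1.0, a.center.copy()) for a in atoms],
        values=values,
        comments=("synthetic Gaussian dimer (promolecular stand-in)",
                  f"separation={separation} amplitude={amplitude} "
                  f"exponent={exponent} spacing={grid_spacing}"),
    )
    # paranoia: the analytic field and the grid must agree at the first node
    assert abs(field.rho(pts[0]) - values[0]) < 1e-12
    return atoms, grid
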
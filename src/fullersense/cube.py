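"""Gaussian cube file reading and writing.

Cube files carry a volumetric scalar field (here: electron density in atomic
units) on a regular grid: two comment lines, an origin/atom-count line, three
axis lines (count + step vector, bohr), one line per atom, then values in
Fortran order with the last (z) index fastest, at most six per line. A
negative atom count marks a molecular-orbital cube whose atom block is
followed by one extra line of orbital indices; only the first data block is
retained (total-density semantics downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CubeGrid", "read_cube", "write_cube"]


@dataclass
class CubeGrid:
    """A regular volumetric grid in bohr with per-atom metadata."""

    origin: np.ndarray  # (3,) bohr
    axes: np.ndarray  # (3, 3) rows are step vectors, bohr
    counts: tuple[int, int, int]
    atoms: list[tuple[int, float, np.ndarray]]  # (atomic number, charge, position bohr)
    values: np.ndarray  # shape == counts
    comments: tuple[str, str] = ("fullersense cube", "")

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.counts = tuple(int(c) for c in self.counts)  # type: ignore[assignment]
        if any(c < 2 for c in self.counts):
            raise ValueError(f"need >= 2 points per axis, got {self.counts}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != int(np.prod(self.counts)):
            raise ValueError(
                f"value count {self.values.size} != n1*n2*n3 = {int(np.prod(self.counts))}"
            )
        self.values = self.values.reshape(self.counts)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")

    @property
    def spacings(self) -> np.ndarray:
        """Step length along each axis (bohr)."""
        return np.linalg.norm(self.axes, axis=1)


def _floats(tokens: list[str]) -> list[float]:
    return [float(t) for t in tokens]


def read_cube(path: str | Path) -> CubeGrid:
    """Parse a Gaussian cube file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path}: too short to be a cube file")
    comments = (lines[0], lines[1])
    head = lines[2].split()
    natoms = int(head[0])
    origin = np.array(_floats(head[1:4]))
    counts = []
    axes = []
    for ax_line in lines[3:6]:
        parts = ax_line.split()
        counts.append(int(parts[0]))
        axes.append(_floats(parts[1:4]))
    mo_cube = natoms < 0
    natoms = abs(natoms)
    atoms = []
    for line in lines[6 : 6 + natoms]:
        parts = line.split()
        atoms.append((int(parts[0]), float(parts[1]), np.array(_floats(parts[2:5]))))
    data_start = 6 + natoms
    n_orbitals = 1
    if mo_cube:
        # orbital-index line: count followed by that many indices (may wrap,
        # but a single line covers every case this package emits or accepts)
        idx = lines[data_start].split()
        n_orbitals = int(idx[0])
        data_start += 1
    raw: list[float] = []
    for line in lines[data_start:]:
        raw.extend(_floats(line.split()))
    expected = int(np.prod(counts)) * n_orbitals
    if len(raw) != expected:
        raise ValueError(
            f"{path}: expected {expected} values, found {len(raw)}"
        )
    values = np.asarray(raw)
    if mo_cube and n_orbitals > 1:
        # MO cubes interleave orbitals fastest; keep the first block
        values = values.reshape(*counts, n_orbitals)[..., 0]
    return CubeGrid(
        origin=origin,
        axes=np.asarray(axes),
        counts=tuple(counts),  # type: ignore[arg-type]
        atoms=atoms,
        values=values.reshape(counts),
        comments=comments,
    )


def write_cube(grid: CubeGrid, path: str | Path) -> None:
    """Write a cube file (z-fastest ordering, six values per line)."""
    if grid.values.shape != tuple(grid.counts):
        raise ValueError("grid values inconsistent with counts")
    out = [grid.comments[0], grid.comments[1]]
    ox, oy, oz = grid.origin
    out.append(f"{len(grid.atoms):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    for count, axis in zip(grid.counts, grid.axes):
        out.append(f"{count:5d} {axis[0]:12.6f} {axis[1]:12.6f} {axis[2]:12.6f}")
    for z, charge, pos in grid.atoms:
        out.append(
            f"{z:5d} {charge:12.6f} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}"
        )
    flat = grid.values.reshape(-1)
    for start in range(0, flat.size, 6):
        out.append(" ".join(f"{v: .6E}" for v in flat[start : start + 6]))
    Path(path).write_text("\n".join(out) + "\n")
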
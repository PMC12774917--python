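"""Calculation-summary records, molecular geometries and geometry measures.

A :class:`QCRecord` is the structured summary of one electronic-structure
calculation: frontier-orbital energies (eV), optional total energy (hartree),
dipole magnitude (debye), counterpoise correction (kJ/mol) and Cartesian
geometry (Å). Summaries live in JSON documents so the pipeline has a stable
contract independent of any particular quantum-chemistry code's log format.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .units import convert_energy

__all__ = [
    "Geometry",
    "QCRecord",
    "bond_length",
    "bond_angle",
    "read_qc_summary",
    "write_qc_summary",
    "read_xyz",
    "write_xyz",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Geometry:
    """An ordered list of atoms: element symbols plus Cartesian coordinates in Å."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # shape (n, 3), Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got {coords.shape}")
        if len(self.symbols) != coords.shape[0]:
            raise ValueError("symbol count does not match coordinate count")
        if coords.shape[0] < 1:
            raise ValueError("a geometry needs at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class QCRecord:
    """Summary of one structure's calculation.

    ``e_homo``/``e_lumo`` are in eV, ``e_total`` in hartree, ``dipole`` in
    debye and ``e_bsse`` (counterpoise correction, repulsive hence >= 0) in
    kJ/mol. ``components`` optionally names the bare sensor and analyte
    records a complex was assembled from, keyed ``"sensor"``/``"analyte"``.
    """

    label: str
    e_homo: float
    e_lumo: float
    e_total: float | None = None
    dipole: float | None = None
    geometry: Geometry | None = None
    e_bsse: float = 0.0
    components: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("record label must be non-empty")
        for name in ("e_homo", "e_lumo"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.label}: {name} must be finite")
        if self.e_lumo < self.e_homo:
            raise ValueError(
                f"{self.label}: LUMO ({self.e_lumo}) below HOMO ({self.e_homo})"
            )
        if self.dipole is not None and self.dipole < 0:
            raise ValueError(f"{self.label}: dipole magnitude must be >= 0")
        if self.e_bsse < 0:
            raise ValueError(f"{self.label}: counterpoise correction must be >= 0")


def bond_length(g: Geometry, i: int, j: int) -> float:
    """Euclidean distance between atoms ``i`` and ``j`` in Å."""
    if i == j:
        raise ValueError("bond length requires two distinct atoms")
    return float(np.linalg.norm(g.coords[i] - g.coords[j]))


def bond_angle(g: Geometry, i: int, j: int, k: int) -> float:
    """Angle i–j–k in degrees, vertex at ``j``; in [0, 180]."""
    if len({i, j, k}) != 3:
        raise ValueError("bond angle requires three distinct atoms")
    a = g.coords[i] - g.coords[j]
    b = g.coords[k] - g.coords[j]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("bond angle undefined for coincident atoms")
    cosine = float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosine)))


def _geometry_from_obj(obj: Any, label: str) -> Geometry:
    try:
        symbols = tuple(str(a[0]) for a in obj)
        coords = np.array([[float(v) for v in a[1:4]] for a in obj], dtype=float)
    except (TypeError, ValueError, IndexError) as exc:
        raise ValueError(f"record {label!r}: malformed geometry block") from exc
    return Geometry(symbols, coords)


def _record_from_doc(doc: Mapping[str, Any], default_unit: str | None) -> QCRecord:
    label = doc.get("label")
    if not label:
        raise ValueError("record without a label in summary file")
    unit = doc.get("unit", default_unit)
    if unit is None:
        raise ValueError(f"record {label!r}: no energy unit declared")
    missing = [k for k in ("e_homo", "e_lumo") if k not in doc]
    if missing:
        raise ValueError(f"record {label!r}: missing {', '.join(missing)}")
    e_homo = convert_energy(float(doc["e_homo"]), unit, "eV")
    e_lumo = convert_energy(float(doc["e_lumo"]), unit, "eV")
    geometry = None
    if "geometry" in doc and doc["geometry"] is not None:
        geometry = _geometry_from_obj(doc["geometry"], label)
    return QCRecord(
        label=str(label),
        e_homo=e_homo,
        e_lumo=e_lumo,
        e_total=float(doc["e_total"]) if doc.get("e_total") is not None else None,
        dipole=float(doc["dipole"]) if doc.get("dipole") is not None else None,
        geometry=geometry,
        e_bsse=float(doc.get("e_bsse", 0.0)),
        components=dict(doc["components"]) if doc.get("components") else None,
    )


def read_qc_summary(path: str | Path) -> list[QCRecord]:
    """Read a JSON calculation-summary file into :class:`QCRecord` objects.

    The document is either a list of record objects or
    ``{"energy_unit": ..., "records": [...]}``; orbital energies are
    normalized to eV using each record's ``unit`` (or the file-level
    ``energy_unit``). An empty file yields an empty list with a warning.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        warnings.warn(f"{path}: empty summary file, no records read", stacklevel=2)
        return []
    data = json.loads(text)
    if isinstance(data, Mapping):
        default_unit = data.get("energy_unit")
        docs = data.get("records", [])
    else:
        default_unit = None
        docs = data
    records = [_record_from_doc(doc, default_unit) for doc in docs]
    log.debug("read %d records from %s", len(records), path)
    return records


def write_qc_summary(records: Iterable[QCRecord], path: str | Path) -> None:
    """Write records to a JSON summary file (orbital energies in eV)."""
    docs = []
    for rec in records:
        doc: dict[str, Any] = {
            "label": rec.label,
            "unit": "eV",
            "e_homo": rec.e_homo,
            "e_lumo": rec.e_lumo,
        }
        if rec.e_total is not None:
            doc["e_total"] = rec.e_total
        if rec.dipole is not None:
            doc["dipole"] = rec.dipole
        if rec.e_bsse:
            doc["e_bsse"] = rec.e_bsse
        if rec.components:
            doc["components"] = dict(rec.components)
        if rec.geometry is not None:
            doc["geometry"] = [
                [s, *map(float, xyz)]
                for s, xyz in zip(rec.geometry.symbols, rec.geometry.coords)
            ]
        docs.append(doc)
    Path(path).write_text(json.dumps({"energy_unit": "eV", "records": docs}, indent=1))


def read_xyz(path: str | Path) -> Geometry:
    """Read an XYZ file (count line, comment line, ``symbol x y z`` lines)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: not an XYZ file")
    n = int(lines[0].split()[0])
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(body)}")
    symbols, coords = [], []
    for line in body:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return Geometry(tuple(symbols), np.asarray(coords))


def write_xyz(g: Geometry, path: str | Path, comment: str = "") -> None:
    lines = [str(len(g)), comment.replace("\n", " ")]
    for s, (x, y, z) in zip(g.symbols, g.coords):
        lines.append(f"{s:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")
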
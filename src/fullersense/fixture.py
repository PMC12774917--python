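"""The bundled reference dataset of printed study values.

Six fullerene structures — pristine C60, boron-doped BC59, nitrogen-doped
NC59 and their p-xylene complexes — with the published frontier-orbital
energies, derived descriptors, BSSE-corrected adsorption energies, sensor
metrics, dipole moments, bond-critical-point data, geometry measures and
cohesive energies. Printed values are stored as strings exactly as
published, so reproduction reports can derive a one-unit-in-the-last-digit
tolerance from each cell; known truncation/sign anomalies are enumerated as
data rather than scattered through test code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "Table3Row",
    "Table4Row",
    "Table7Row",
    "Anomaly",
    "ReferenceDataset",
    "reference_dataset",
    "printed_tolerance",
]


def printed_tolerance(printed: str) -> float:
    """One unit in the last printed digit of a decimal or sci-notation string."""
    s = printed.strip().lower().lstrip("+-")
    mantissa, _, exponent = s.partition("e")
    scale = 10.0 ** int(exponent) if exponent else 1.0
    _, _, frac = mantissa.partition(".")
    return 10.0 ** (-len(frac)) * scale


@dataclass(frozen=True)
class Table3Row:
    """Frontier energies (inputs) plus the printed descriptor cells."""

    label: str
    e_lumo: float  # eV
    e_homo: float  # eV
    printed: Mapping[str, str]  # keys: hlg, eta, mu, s, dn_max, optional ect


@dataclass(frozen=True)
class Table4Row:
    """Adsorption/sensor data; bare structures carry only a conductivity."""

    label: str
    sigma: str  # printed σ, nominal S/m
    e_ads: float | None = None  # kJ/mol
    e_bsse: float | None = None  # kJ/mol
    tau: str | None = None  # printed τ, s


@dataclass(frozen=True)
class Table7Row:
    """Bond-critical-point data; G and V are wavefunction-derived inputs."""

    label: str
    rho: float  # a.u.
    g: float  # a.u.
    v: float  # a.u.
    laplacian: float  # a.u.
    hb_text: str  # Hb quoted in the discussion text


@dataclass(frozen=True)
class Anomaly:
    """A known mismatch between a printed cell and its recomputed value."""

    table: str
    cell: str
    printed: str
    recomputed: str
    note: str


@dataclass(frozen=True)
class ReferenceDataset:
    table3: tuple[Table3Row, ...]
    table4: tuple[Table4Row, ...]
    table7: tuple[Table7Row, ...]
    dipoles: Mapping[str, tuple[float, float | None]]  # bare, complex (debye)
    table2: Mapping[str, Mapping[str, float]]
    fig2_cohesive: Mapping[str, float]  # kcal/mol per atom
    anomalies: tuple[Anomaly, ...]

    def table3_row(self, label: str) -> Table3Row:
        return _by_label(self.table3, label)

    def table4_row(self, label: str) -> Table4Row:
        return _by_label(self.table4, label)

    def table7_row(self, label: str) -> Table7Row:
        return _by_label(self.table7, label)


def _by_label(rows, label):
    for row in rows:
        if row.label == label:
            return row
    raise KeyError(f"no fixture row labelled {label!r}")


def _m(**kw: str) -> Mapping[str, str]:
    return MappingProxyType(dict(kw))


_TABLE3 = (
    Table3Row("C60", -3.70, -5.38,
              _m(hlg="1.68", eta="0.84", mu="-4.54", s="0.59", dn_max="5.40")),
    Table3Row("BC59", -3.58, -4.93,
              _m(hlg="1.35", eta="0.67", mu="-4.25", s="0.74", dn_max="6.30")),
    Table3Row("NC59", -3.79, -5.20,
              _m(hlg="1.41", eta="0.70", mu="-4.49", s="0.70", dn_max="6.37")),
    Table3Row("C60@p-xylene", -3.54, -5.08,
              _m(hlg="1.54", eta="0.77", mu="-4.31", s="0.64", dn_max="5.59",
                 ect="-0.19")),
    Table3Row("BC59@p-xylene", -3.47, -4.68,
              _m(hlg="1.21", eta="0.60", mu="-4.07", s="0.82", dn_max="6.73",
                 ect="-0.43")),
    Table3Row("NC59@p-xylene", -3.35, -4.08,
              _m(hlg="0.73", eta="0.36", mu="-3.71", s="1.36", dn_max="10.17",
                 ect="-3.80")),
)

#: complex label -> bare sensor label
COMPLEX_SENSOR = MappingProxyType(
    {
        "C60@p-xylene": "C60",
        "BC59@p-xylene": "BC59",
        "NC59@p-xylene": "NC59",
    }
)

_TABLE4 = (
    Table4Row("C60", sigma="1.92e-5"),
    Table4Row("BC59", sigma="1.18e-2"),
    Table4Row("NC59", sigma="3.68e-3"),
    Table4Row("C60@p-xylene", sigma="2.93e-4", e_ads=-34.30, e_bsse=12.71,
              tau="9.8e-7"),
    Table4Row("BC59@p-xylene", sigma="1.81e-1", e_ads=-41.68, e_bsse=13.68,
              tau="1.9e-5"),
    Table4Row("NC59@p-xylene", sigma="2.07e3", e_ads=-31.71, e_bsse=12.92,
              tau="3.5e-7"),
)

_TABLE7 = (
    Table7Row("C60@p-xylene", rho=0.008, g=0.005, v=-0.001, laplacian=-0.006,
              hb_text="0.004"),
    Table7Row("BC59@p-xylene", rho=0.019, g=0.008, v=0.0007, laplacian=-0.007,
              hb_text="0.009"),
    Table7Row("NC59@p-xylene", rho=0.010, g=0.005, v=-0.001, laplacian=-0.007,
              hb_text="0.004"),
)

_DIPOLES = MappingProxyType(
    {
        # bare, complex (debye); C60 is apolar and its complex moment is
        # described only as "small", so it is carried as unknown
        "C60": (0.0, None),
        "BC59": (1.50, 3.91),
        "NC59": (1.39, 3.05),
    }
)

_TABLE2 = MappingProxyType(
    {
        "C60": MappingProxyType(
            {"C1-C4": 1.45, "C2-C4": 1.40, "C3-C4": 1.45,
             "C1-C4-C2": 119.98, "C1-C4-C3": 107.99, "C2-C4-C3": 119.99}
        ),
        "BC59": MappingProxyType(
            {"C1-B": 1.53, "C2-B": 1.55, "C3-B": 1.55,
             "C1-B-C2": 118.46, "C1-B-C3": 118.46, "C2-B-C3": 106.26}
        ),
        "NC59": MappingProxyType(
            {"C1-N": 1.40, "C2-N": 1.42, "C3-N": 1.42,
             # printed with one more digit than its neighbours; kept verbatim
             "C1-N-C2": 119.22, "C1-N-C3": 119.22, "C2-N-C3": 107.411}
        ),
    }
)

_FIG2 = MappingProxyType({"C60": -197.3, "BC59": -195.9, "NC59": -196.1})

_ANOMALIES = (
    Anomaly(
        table="3",
        cell="NC59@p-xylene:s",
        printed="1.36",
        recomputed="1.370",
        note="softness cell truncated rather than rounded; reported as a "
             "known anomaly even though |Δ| = 0.0099 is marginally inside "
             "the one-unit-last-digit tolerance",
    ),
    Anomaly(
        table="4",
        cell="NC59@p-xylene:sigma",
        printed="2.07e3",
        recomputed="2.07e3",
        note="abstract prints 2.07e-3 while the table and conclusion print "
             "2.07e3; the conduction formula with HLG = 0.73 eV gives the "
             "latter, which is adopted",
    ),
    Anomaly(
        table="3",
        cell="ect:sign-convention",
        printed="-0.19/-0.43/-3.80",
        recomputed="+0.19/+0.43/+3.80",
        note="the charge-transfer definition written as complex minus sensor "
             "yields the opposite sign of every printed value; the package "
             "returns sensor minus complex to match the printed table",
    ),
    Anomaly(
        table="2",
        cell="NC59:C2-N-C3",
        printed="107.411",
        recomputed="107.411",
        note="one more printed digit than neighbouring angle cells; stored "
             "verbatim",
    ),
)

_FIXTURE = ReferenceDataset(
    table3=_TABLE3,
    table4=_TABLE4,
    table7=_TABLE7,
    dipoles=_DIPOLES,
    table2=_TABLE2,
    fig2_cohesive=_FIG2,
    anomalies=_ANOMALIES,
)


def reference_dataset() -> ReferenceDataset:
    """Return the immutable bundled reference dataset."""
    return _FIXTURE
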
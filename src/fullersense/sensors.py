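"""Chemiresistive sensor figures of merit.

Two transition-state-theory/semiconductor expressions turn desk-scale inputs
into device-relevant numbers:

* recovery time  τ = v0⁻¹ · exp(|E_ads| / kB·T) — the expected desorption
  timescale; the adsorption energy enters by magnitude so stronger binding
  always gives longer recovery, and a positive (non-binding) E_ads only
  triggers a warning;
* conductivity   σ = A · T^{3/2} · exp(−HLG / 2·kB·T) — thermally activated
  conduction with the HOMO–LUMO gap as activation energy. The Richardson
  prefactor makes the units nominal S/m (the source formula is dimensionally
  loose); values are meaningful as ratios, which is how the modulation
  figure of merit σ_complex/σ_bare uses them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import pandas as pd

from .units import convert_energy

__all__ = [
    "SensorConstants",
    "SensorMetrics",
    "SensorThresholds",
    "Recommendation",
    "SensorAssessment",
    "recovery_time",
    "conductivity",
    "modulation_ratio",
    "temperature_sweep",
    "assess",
]

#: Boltzmann constant in eV/K
K_B_EV = 8.617e-5


@dataclass(frozen=True)
class SensorConstants:
    """Physical constants entering the sensor metrics."""

    k_b: float = K_B_EV  # eV/K
    v0: float = 1e12  # attempt frequency, 1/s
    richardson_a: float = 6e5  # A·m⁻²·K⁻²
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        for name in ("k_b", "v0", "richardson_a", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_CONSTANTS = SensorConstants()


def recovery_time(
    e_ads_kj_mol: float, constants: SensorConstants = DEFAULT_CONSTANTS
) -> float:
    """Recovery (desorption) time in seconds from E_ads in kJ/mol."""
    if constants.temperature <= 0:
        raise ValueError("temperature must be positive")
    if e_ads_kj_mol > 0:
        warnings.warn(
            "positive adsorption energy: complex is unbound, recovery time "
            "is formal only",
            stacklevel=2,
        )
    e_ev = abs(convert_energy(e_ads_kj_mol, "kJ/mol", "eV"))
    return (1.0 / constants.v0) * math.exp(e_ev / (constants.k_b * constants.temperature))


def conductivity(
    hlg_ev: float, constants: SensorConstants = DEFAULT_CONSTANTS
) -> float:
    """Thermally activated conductivity (nominal S/m) from the gap in eV."""
    if hlg_ev < 0:
        raise ValueError("HOMO–LUMO gap must be >= 0")
    if constants.temperature <= 0:
        raise ValueError("temperature must be positive")
    t = constants.temperature
    return constants.richardson_a * t**1.5 * math.exp(
        -hlg_ev / (2.0 * constants.k_b * t)
    )


def modulation_ratio(sigma_complex: float, sigma_bare: float) -> float:
    """Conductivity modulation σ_complex / σ_bare on adsorption."""
    if sigma_complex <= 0 or sigma_bare <= 0:
        raise ValueError("conductivities must be strictly positive")
    return sigma_complex / sigma_bare


@dataclass(frozen=True)
class SensorMetrics:
    """Recovery time, bare/complex conductivities and their ratio."""

    tau: float  # s
    sigma_bare: float  # nominal S/m
    sigma_complex: float  # nominal S/m
    modulation: float
    constants: SensorConstants


def temperature_sweep(
    e_ads_kj_mol: float,
    hlg_ev: float,
    t_grid: Sequence[float],
    constants: SensorConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """τ and σ across temperatures: columns temperature_K, tau_s, sigma_S_per_m."""
    t_grid = list(t_grid)
    if not t_grid:
        raise ValueError("temperature grid must be non-empty")
    if any(t <= 0 for t in t_grid):
        raise ValueError("temperatures must be strictly positive")
    rows = []
    for t in t_grid:
        c = replace(constants, temperature=float(t))
        rows.append(
            {
                "temperature_K": float(t),
                "tau_s": recovery_time(e_ads_kj_mol, c),
                "sigma_S_per_m": conductivity(hlg_ev, c),
            }
        )
    return pd.DataFrame(rows)


class Recommendation(str, Enum):
    ADSORBENT = "adsorbent"
    SENSOR = "sensor"
    DUAL = "dual"
    WEAK = "weak"


@dataclass(frozen=True)
class SensorThresholds:
    """Cutoffs for the adsorbent-vs-sensor recommendation.

    A material is an effective *adsorbent* when it binds at least
    ``adsorbent_e_ads`` strongly, and a usable *sensor* when adsorption both
    modulates conduction by ``sensor_modulation`` or more and releases the
    analyte within ``sensor_tau`` seconds.
    """

    adsorbent_e_ads: float = -40.0  # kJ/mol
    sensor_modulation: float = 100.0
    sensor_tau: float = 1e-6  # s


@dataclass(frozen=True)
class SensorAssessment:
    label: str
    e_ads: float  # kJ/mol
    metrics: SensorMetrics
    recommendation: Recommendation


def assess(
    label: str,
    e_ads_kj_mol: float,
    hlg_bare_ev: float,
    hlg_complex_ev: float,
    constants: SensorConstants = DEFAULT_CONSTANTS,
    thresholds: SensorThresholds = SensorThresholds(),
) -> SensorAssessment:
    """Classify a sensor–analyte pair as adsorbent, sensor, dual or weak."""
    sigma_bare = conductivity(hlg_bare_ev, constants)
    sigma_complex = conductivity(hlg_complex_ev, constants)
    metrics = SensorMetrics(
        tau=recovery_time(e_ads_kj_mol, constants),
        sigma_bare=sigma_bare,
        sigma_complex=sigma_complex,
        modulation=modulation_ratio(sigma_complex, sigma_bare),
        constants=constants,
    )
    is_adsorbent = e_ads_kj_mol <= thresholds.adsorbent_e_ads
    is_sensor = (
        metrics.modulation >= thresholds.sensor_modulation
        and metrics.tau <= thresholds.sensor_tau
    )
    if is_adsorbent and is_sensor:
        rec = Recommendation.DUAL
    elif is_adsorbent:
        rec = Recommendation.ADSORBENT
    elif is_sensor:
        rec = Recommendation.SENSOR
    else:
        rec = Recommendation.WEAK
    return SensorAssessment(
        label=label, e_ads=e_ads_kj_mol, metrics=metrics, recommendation=rec
    )
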
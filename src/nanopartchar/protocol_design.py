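"""Stokes-law sedimentation calculator for centrifugation protocol design.

Centrifugation steps in particle sample preparation are dimensioned so that
particles of a target size traverse the liquid column within the spin time.
Under the constant-field (fixed effective radius) approximation the settling
velocity of a sphere of diameter ``d`` is

    v = (rho_p - rho_f) · g_eff · d² / (18 · eta),    g_eff = RCF · 9.81 m/s²

so the descended distance is linear in time and quadratic in diameter.

The default fluid/particle parameter set (density contrast 2.90 g/cm³,
viscosity 0.93 mPa·s, RCF 2000) is a fit: it is the unique
rounding-consistent mobility that reproduces a published six-entry table of
anatase TiO₂ sedimentation distances (20/40/60 nm at 30 min and 2 h) to
0.1 cm.  All parameters are overridable per spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

G_STANDARD = 9.81  # m/s^2

__all__ = [
    "SedimentationSpec",
    "ProtocolPreset",
    "stokes_velocity",
    "sedimentation_distance",
    "clearance_time",
    "protocol_preset",
    "PROTOCOL_PRESETS",
]


@dataclass(frozen=True)
class SedimentationSpec:
    """Parameters of a centrifugal sedimentation problem.

    particle_diameter in nm, densities in g/cm³, viscosity in mPa·s,
    rcf in multiples of standard gravity, path_length in cm.
    """

    particle_diameter: float
    particle_density: float = 3.90   # anatase TiO2
    fluid_density: float = 1.00      # water
    viscosity: float = 0.93
    rcf: float = 2000.0
    path_length: float = 1.75

    def __post_init__(self) -> None:
        if self.particle_diameter <= 0:
            raise ValueError("particle_diameter must be positive")
        if self.viscosity <= 0 or self.particle_density <= 0 or self.fluid_density <= 0:
            raise ValueError("densities and viscosity must be positive")
        if self.rcf < 0 or self.path_length <= 0:
            raise ValueError("rcf must be >= 0 and path_length positive")

    def with_diameter(self, d_nm: float) -> "SedimentationSpec":
        return replace(self, particle_diameter=d_nm)


def stokes_velocity(spec: SedimentationSpec) -> float:
    """Terminal settling velocity in cm/h."""
    delta_rho = spec.particle_density - spec.fluid_density
    if delta_rho <= 0:
        raise ValueError("particle must be denser than the fluid to sediment")
    # SI: kg/m^3, m/s^2, m, Pa.s
    delta_rho_si = delta_rho * 1000.0
    g_eff = spec.rcf * G_STANDARD
    d_m = spec.particle_diameter * 1e-9
    eta_si = spec.viscosity * 1e-3
    v_m_s = delta_rho_si * g_eff * d_m**2 / (18.0 * eta_si)
    return v_m_s * 100.0 * 3600.0  # cm/h


def sedimentation_distance(spec: SedimentationSpec, time_min: float, rounded: bool = True) -> float:
    """Distance (cm) descended in ``time_min`` minutes; 0.1 cm display rounding."""
    if time_min < 0:
        raise ValueError("time must be >= 0")
    dist = stokes_velocity(spec) * time_min / 60.0
    return round(dist, 1) if rounded else dist


def clearance_time(spec: SedimentationSpec) -> float:
    """Minutes for a particle of the given size to traverse ``path_length``."""
    v = stokes_velocity(spec)
    if v == 0:
        raise ValueError("settling velocity is zero; clearance time undefined")
    return spec.path_length / v * 60.0


@dataclass(frozen=True)
class ProtocolPreset:
    """A published sample-preparation protocol for TEM analysis of TiO2 additives."""

    name: str
    mass_mg: float
    concentration_mg_ml: float
    ph_range: tuple[float, float]
    sonication_kJ: Optional[float]
    centrifugation_min: Optional[float]


PROTOCOL_PRESETS: dict[str, ProtocolPreset] = {
    "P1": ProtocolPreset("P1", 25.0, 2.5, (10.0, 10.0), 35.0, None),
    "P2": ProtocolPreset("P2", 88.0, 2.5, (6.0, 7.0), None, 30.0),
    "P3": ProtocolPreset("P3", 88.0, 2.5, (6.0, 7.0), None, 120.0),
    "P4": ProtocolPreset("P4", 88.0, 2.5, (6.0, 7.0), 10.0, None),
    "P5": ProtocolPreset("P5", 88.0, 2.5, (6.0, 7.0), 10.0, 30.0),
    "P6": ProtocolPreset("P6", 88.0, 2.5, (6.0, 7.0), 10.0, 120.0),
}


def protocol_preset(name: str) -> ProtocolPreset:
    """Look up one of the six standard preparation protocols P1–P6."""
    try:
        return PROTOCOL_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown protocol {name!r}; expected one of P1..P6") from None
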
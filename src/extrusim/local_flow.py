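"""Elementary per-element physics.

Each screw element contributes a pressure step (C-chamber drag/pressure
balance), viscous dissipation evaluated at representative channel and
flight-gap shear rates, and an energy-balance temperature step with
conductive exchange to the barrel through a Nusselt-number closure.

Sign and direction conventions: axial position is measured from the die
toward the hopper; a *positive* pressure step means pressure rises in the
conveying direction (toward the die), which happens wherever drag
over-supplies the net throughput (die-fed or restrictive-backed sections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, GeometryError
from .materials import Material, ViscosityParams, apparent_viscosity, melt_property
from .machine import ShapeFactors

__all__ = [
    "ElementState", "pressure_step", "representative_shear_rate",
    "dissipated_power", "energy_step",
]


@dataclass
class ElementState:
    """Melt state at one axial station (position in m from the die)."""

    position: float
    temperature_c: float
    pressure: float  # Pa, >= 0
    sme_cum: float  # kJ/kg accumulated since the melting point
    eta_local: float  # Pa s at the channel shear rate
    fill_ratio: float  # (0, 1]
    residence_time: float  # s spent between the melting point and here
    element_label: str = ""

    def __post_init__(self):
        if self.pressure < -1e-9:
            raise DomainError(f"negative pressure {self.pressure}")
        if not 0.0 < self.fill_ratio <= 1.0 + 1e-12:
            raise DomainError(f"fill ratio {self.fill_ratio} outside (0, 1]")


def pressure_step(sf: ShapeFactors, qv: float, omega: float, eta: float,
                  fraction: float = 1.0) -> tuple[float, bool]:
    """Pressure change over (a fraction of) an element, positive toward the
    die, from Qv = A*Omega + (B/eta)*(dP/dtheta):

        dP = (A*Omega - Qv) * eta * dtheta / B

    Returns (dP, fully_filled) where ``fully_filled`` says whether the
    element must run full for the balance to hold (drag deficit, i.e.
    reverse elements or over-fed conveying).
    """
    if eta <= 0:
        raise DomainError(f"viscosity must be > 0, got {eta}")
    if sf.b <= 0:
        raise GeometryError("pressure coefficient B is zero")
    dp = (sf.a * omega - qv) * eta * sf.dtheta * fraction / sf.b
    return dp, sf.a * omega <= qv


def representative_shear_rate(sf: ShapeFactors, screw_diameter: float,
                              n_rpm: float) -> tuple[float, float]:
    """Channel and flight-gap shear rates (1/s): pi*D*N / h and pi*D*N / gap.

    The channel value linearizes the power-law melt around the dominant
    drag shear (the standard 1D-global treatment); the gap value feeds the
    clearance part of the dissipation split.
    """
    if n_rpm < 0:
        raise DomainError(f"screw speed must be >= 0, got {n_rpm}")
    v_tip = math.pi * screw_diameter * n_rpm / 60.0
    return v_tip / sf.channel_depth, v_tip / sf.gap


def dissipated_power(sf: ShapeFactors, params: ViscosityParams,
                     screw_diameter: float, temperature_c: float, mc: float,
                     sme: float, n_rpm: float, fill_ratio: float = 1.0,
                     pressurized: bool = True) -> float:
    """Viscous power (W) dissipated in one element: W = integral(eta*gdot^2).

    Split into channel and flight-gap contributions, each evaluated at its
    own shear rate; partially filled chambers dissipate proportionally to
    filled volume.  The clearance term only acts where the channel is
    pressurized (in starved sections the melt pool does not feed the
    flight gaps).
    """
    if n_rpm == 0:
        return 0.0
    g_ch, g_gap = representative_shear_rate(sf, screw_diameter, n_rpm)
    eta_ch = apparent_viscosity(params, g_ch, temperature_c, mc, sme)
    w = eta_ch * g_ch ** 2 * sf.v_channel
    if pressurized:
        eta_gap = apparent_viscosity(params, g_gap, temperature_c, mc, sme)
        w += eta_gap * g_gap ** 2 * sf.v_gap
    return fill_ratio * sf.dissipation_factor * w


def energy_step(material: Material, mc: float, w_dot: float, qv: float,
                temperature_c: float, barrel_temp_c: float, nusselt: float,
                exchange_area: float, char_length: float) -> float:
    """Temperature change (degC) over an element from the specific energy
    balance Cp*dT + Ecd = Ev:

        Ev  = W_dot / (rho_m * Qv)              (viscous dissipation, J/kg)
        Ecd = h_t * S * (T - Tb) / (rho_m * Qv) (conduction to barrel, J/kg)
        h_t = Nu * k_melt / L_char

    ``char_length`` is the characteristic length of the Nusselt closure
    (the solver uses the screw diameter).
    """
    rho = melt_property(material, mc, "rho")
    cp = melt_property(material, mc, "cp")
    k_melt = melt_property(material, mc, "k")
    h_t = nusselt * k_melt / char_length
    m_dot = rho * qv
    ev = w_dot / m_dot
    ecd = h_t * exchange_area * (temperature_c - barrel_temp_c) / m_dot
    return (ev - ecd) / cp
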
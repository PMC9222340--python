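"""Extruder description and geometry-derived flow coefficients.

The 1D global model treats every screw element as a C-chamber whose
volumetric throughput obeys

    Qv = A * Omega + (B / eta) * (dP / dtheta)

with ``A`` the drag coefficient (m^3/rad), ``Omega`` the screw speed (rad/s)
and ``B`` the pressure-flow coefficient; ``dP/dtheta`` is the pressure
gradient over the element's angular extent.  ``A`` and ``B`` come from
shallow-rectangular-channel lubrication formulas; ``B`` additionally carries a
leakage conductance through the flight-tip clearances, which dominates the
pressure flow of reverse (left-handed) elements.

Kneading-disc blocks are represented as equivalent conveying elements: the
stagger angle implies an apparent pitch (one full turn per 360/stagger
discs) and a drag efficiency cos(stagger), so 45-degree forward blocks
convey weakly and 90-degree blocks are neutral, while an inter-disc
leakage path is added to B.  This is an acknowledged stand-in for dedicated
kneading-block flow models; it lives entirely behind :func:`shape_factors`
so a literal model can replace it.

Exact channel geometry of the published machines is not public; the shipped
machine fixtures reconstruct them from conventional co-rotating twin-screw
ratios (channel depth ~ 0.16-0.2 D, conveying pitch ~ 1 D).  Axial positions
are measured from the die (position 0) toward the hopper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


from scipy.optimize import brentq

from .errors import ConfigError, DomainError, GeometryError
from .materials import ViscosityParams, consistency, flow_index

__all__ = [
    "ScrewElement", "DieElement", "Extruder", "ShapeFactors",
    "shape_factors", "die_pressure_drop", "DiePressureResult",
]

#: Fraction of the bore circumference (times pi*D) taken as barrel-facing
#: exchange surface of the twin bore.
BARREL_ARC_FACTOR = 1.6
#: Fraction of the swept annulus that is free channel volume (flights and
#: intermeshing overlap removed).
CHANNEL_FILL_FACTOR = 0.85
#: Intermeshing C-chamber transfer efficiency folded into the drag term.
INTERMESH_EFFICIENCY = 0.68
#: Default flight-tip land width as a fraction of the (effective) pitch.
TIP_WIDTH_FRACTION = 0.05
#: Default flight-tip clearance as a fraction of the screw diameter.
GAP_FRACTION = {"conveying_rh": 0.022, "reverse_lh": 0.03,
                "kneading_block": 0.022}
#: Inter-disc leakage of kneading blocks relative to the base clearance.
KNEADING_GAP_MULTIPLIER = 1.0
#: Drag efficiency of reverse elements (leakage undercuts backward drag).
REVERSE_DRAG_EFFICIENCY = 0.4
#: Dissipation intensification of reverse elements over the plain C-chamber
#: shear estimate (recirculation through the clearances).
REVERSE_DISSIPATION_FACTOR = 1.4


@dataclass(frozen=True)
class ScrewElement:
    """One screw element.  Lengths in metres; pitch signed (negative for
    left-handed/reverse elements); stagger/disc fields only for kneading
    blocks."""

    kind: str  # conveying_rh | reverse_lh | kneading_block
    length: float
    pitch: float = 0.0
    channel_depth: float = 0.0
    flight_count: int = 2
    stagger_angle: float | None = None  # degrees
    disc_thickness: float | None = None  # m
    flight_gap: float | None = None  # m; default GAP_FRACTION[kind]*D
    flight_width: float | None = None  # m; default TIP_WIDTH_FRACTION*|pitch|
    label: str = ""

    def __post_init__(self):
        problems = []
        if self.kind not in ("conveying_rh", "reverse_lh", "kneading_block"):
            problems.append(f"unknown screw element kind {self.kind!r}")
        if self.length <= 0:
            problems.append("length must be > 0")
        if self.channel_depth <= 0:
            problems.append("channel_depth must be > 0")
        if self.kind == "conveying_rh" and self.pitch <= 0:
            problems.append("conveying_rh requires pitch > 0")
        if self.kind == "reverse_lh" and self.pitch >= 0:
            problems.append("reverse_lh requires pitch < 0 (left-handed)")
        if self.kind == "kneading_block":
            if self.stagger_angle is None or self.disc_thickness is None:
                problems.append(
                    "kneading_block requires stagger_angle and disc_thickness")
        if problems:
            raise ConfigError([f"screw element: {p}" for p in problems])

    @property
    def is_restrictive(self) -> bool:
        return self.kind in ("reverse_lh", "kneading_block")


@dataclass(frozen=True)
class DieElement:
    """One die channel: circular (radius) or slit (width x height), length in
    metres.  Elements are in series unless they share a ``group`` id, in
    which case the group members run in parallel."""

    kind: str  # circular | slit
    length: float
    radius: float | None = None
    width: float | None = None
    height: float | None = None
    group: str | None = None

    def __post_init__(self):
        problems = []
        if self.kind not in ("circular", "slit"):
            problems.append(f"unknown die element kind {self.kind!r}")
        if self.length <= 0:
            problems.append("length must be > 0")
        if self.kind == "circular" and (self.radius is None or self.radius <= 0):
            problems.append("circular die requires radius > 0")
        if self.kind == "slit" and (
                self.width is None or self.width <= 0
                or self.height is None or self.height <= 0):
            problems.append("slit die requires width > 0 and height > 0")
        if problems:
            raise ConfigError([f"die element: {p}" for p in problems])


@dataclass(frozen=True)
class Extruder:
    """Machine description: ordered screw elements (hopper -> die), die
    elements and barrel zones.

    ``barrel_zone_lengths`` lists the axial span of each temperature zone
    from hopper to die; the zone *set temperatures* belong to the operating
    point, not the machine.
    """

    name: str
    screw_diameter: float  # m
    total_screw_length: float  # m
    elements: tuple  # ScrewElement, hopper -> die
    die: tuple  # DieElement
    barrel_zone_lengths: tuple  # m, hopper -> die
    centerline_distance: float | None = None
    feed_position: float | None = None  # m from die; default = screw length
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        problems = []
        total = sum(e.length for e in self.elements)
        if total > self.total_screw_length * (1 + 1e-9):
            problems.append(
                f"element lengths sum to {total * 1e3:.1f} mm "
                f"> screw length {self.total_screw_length * 1e3:.1f} mm")
        zones = sum(self.barrel_zone_lengths)
        if abs(zones - self.total_screw_length) > 1e-6:
            problems.append(
                f"barrel zones tile {zones * 1e3:.1f} mm, expected "
                f"{self.total_screw_length * 1e3:.1f} mm (no gaps/overlap)")
        if not any(e.is_restrictive for e in self.elements):
            problems.append(
                "no restrictive element (reverse_lh or kneading_block); the "
                "melting rule requires at least one downstream of the feed")
        if not self.die:
            problems.append("no die elements")
        if problems:
            raise ConfigError([f"extruder {self.name!r}: {p}" for p in problems])
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "die", tuple(self.die))
        object.__setattr__(self, "barrel_zone_lengths",
                           tuple(self.barrel_zone_lengths))
        if self.feed_position is None:
            object.__setattr__(self, "feed_position", self.total_screw_length)

    @property
    def n_zones(self) -> int:
        return len(self.barrel_zone_lengths)

    def element_positions(self) -> list:
        """(position of downstream end, element) pairs, measured from the die."""
        out = []
        pos = 0.0
        for element in reversed(self.elements):
            out.append((pos, element))
            pos += element.length
        return out

    def zone_at(self, position_from_die: float) -> int:
        """Barrel-zone index (hopper -> die order) at an axial position."""
        from_hopper = self.total_screw_length - position_from_die
        acc = 0.0
        for i, span in enumerate(self.barrel_zone_lengths):
            acc += span
            if from_hopper <= acc + 1e-12:
                return i
        return len(self.barrel_zone_lengths) - 1


@dataclass(frozen=True)
class ShapeFactors:
    """Geometry-derived coefficients and volumes of one screw element.

    ``a``: drag coefficient (m^3/rad, signed); ``b``: total pressure-flow
    coefficient (channel + flight-gap leakage); volumes/areas feed the
    dissipation and heat-exchange terms.
    """

    a: float
    b: float
    b_channel: float
    b_leak: float
    dtheta: float  # total angular extent, rad
    helix_angle: float  # rad
    channel_width: float  # m
    channel_depth: float  # m
    gap: float  # flight-tip clearance, m
    tip_width: float  # m
    v_channel: float  # m^3 free channel volume
    v_gap: float  # m^3 clearance volume
    area_barrel: float  # m^2 barrel-facing surface
    l_channel: float  # m helical channel length
    drag_efficiency: float
    #: dissipation intensity of the element kind relative to the plain
    #: C-chamber shear estimate (reverse elements recirculate the charge
    #: through their clearances, dissipating more than the drag term alone)
    dissipation_factor: float = 1.0


def _effective_pitch(element: ScrewElement) -> float:
    if element.kind == "kneading_block":
        return element.disc_thickness * 360.0 / element.stagger_angle
    return abs(element.pitch)


def shape_factors(element: ScrewElement, screw_diameter: float) -> ShapeFactors:
    """Drag/pressure coefficients (A, B) and element volumes.

    Raises :class:`GeometryError` for degenerate geometry (channel deeper
    than the screw radius, pitch-free conveying element).
    """
    d = screw_diameter
    h = element.channel_depth
    if h >= d / 2:
        raise GeometryError(
            f"channel depth {h * 1e3:.1f} mm >= D/2 ({d * 500:.1f} mm)")
    pitch = _effective_pitch(element)
    if pitch <= 0:
        raise GeometryError("element has no effective pitch")
    n_fl = element.flight_count
    dissipation_factor = 1.0
    if element.flight_gap is not None:
        gap = element.flight_gap
    else:
        gap = GAP_FRACTION[element.kind] * d

    helix = math.atan2(pitch, math.pi * d)
    cos_h, sin_h = math.cos(helix), math.sin(helix)
    if element.kind == "kneading_block":
        tip_width = 0.25 * element.disc_thickness
        gap = KNEADING_GAP_MULTIPLIER * gap  # staggered discs leak broadly
        drag_eff = math.cos(math.radians(element.stagger_angle))
    else:
        tip_width = (element.flight_width if element.flight_width is not None
                     else TIP_WIDTH_FRACTION * pitch)
        drag_eff = 1.0
    if element.kind == "reverse_lh":
        # leakage around the backward flights undercuts their drag, while
        # the charge recirculating through the clearances dissipates beyond
        # the plain C-chamber estimate (stand-in for the dedicated
        # reverse-element flow models)
        drag_eff = REVERSE_DRAG_EFFICIENCY
        dissipation_factor = REVERSE_DISSIPATION_FACTOR
    width = (pitch / n_fl) * cos_h - tip_width
    if width <= 0:
        raise GeometryError(
            f"flight width {tip_width * 1e3:.1f} mm leaves no channel "
            f"(pitch {pitch * 1e3:.1f} mm, {n_fl} flights)")

    n_ch = 2 * n_fl * INTERMESH_EFFICIENCY  # both screws, C-chamber transfer
    sign = -1.0 if element.kind == "reverse_lh" else 1.0
    a = sign * drag_eff * n_ch * 0.5 * (d / 2.0) * cos_h * width * h

    dtheta = 2.0 * math.pi * element.length / pitch
    l_channel = element.length / sin_h
    b_channel = n_ch * width * h ** 3 * dtheta / (12.0 * l_channel)

    # flight-tip leakage: slit of length ~ pi*D/cos(helix) per flight and
    # screw, crossings in series once per flight per turn
    tip_len = 2.0 * math.pi * d / cos_h
    g_cross = tip_len * gap ** 3 / (12.0 * tip_width)
    b_leak = g_cross * 2.0 * math.pi / n_fl

    v_channel = 2 * n_fl * width * h * l_channel * CHANNEL_FILL_FACTOR
    n_cross = n_fl * element.length / pitch
    v_gap = tip_len * tip_width * gap * n_cross
    area_barrel = BARREL_ARC_FACTOR * math.pi * d * element.length

    return ShapeFactors(
        a=a, b=b_channel + b_leak, b_channel=b_channel, b_leak=b_leak,
        dtheta=dtheta, helix_angle=helix, channel_width=width,
        channel_depth=h, gap=gap, tip_width=tip_width,
        v_channel=v_channel, v_gap=v_gap, area_barrel=area_barrel,
        l_channel=l_channel, drag_efficiency=drag_eff,
        dissipation_factor=dissipation_factor)


# ---------------------------------------------------------------------------
# Die flow
# ---------------------------------------------------------------------------

def _die_wall_shear(el: DieElement, qv: float, n: float) -> float:
    if el.kind == "circular":
        return (3.0 * n + 1.0) / n * qv / (math.pi * el.radius ** 3)
    return 2.0 * (2.0 * n + 1.0) / n * qv / (el.width * el.height ** 2)


def _die_dp(el: DieElement, qv: float, k: float, n: float) -> float:
    """Power-law Poiseuille pressure drop of one die element."""
    gw = _die_wall_shear(el, qv, n)
    if el.kind == "circular":
        return 2.0 * el.length * k * gw ** n / el.radius
    return 2.0 * el.length * k * gw ** n / el.height


def _die_q(el: DieElement, dp: float, k: float, n: float) -> float:
    """Inverse of :func:`_die_dp` (flow at a given pressure drop)."""
    if el.kind == "circular":
        return (math.pi * el.radius ** 3 * n / (3.0 * n + 1.0)) * \
            (dp * el.radius / (2.0 * el.length * k)) ** (1.0 / n)
    return (el.width * el.height ** 2 * n / (2.0 * (2.0 * n + 1.0))) * \
        (dp * el.height / (2.0 * el.length * k)) ** (1.0 / n)


@dataclass(frozen=True)
class DiePressureResult:
    dp: float  # Pa
    wall_shear_rates: tuple  # 1/s, one per die element (listed order)
    element_dp: tuple  # Pa per series stage (parallel group -> one value)
    k: float
    n: float


def die_pressure_drop(die: Sequence[DieElement], qv: float,
                      params: ViscosityParams, temperature_c: float,
                      mc: float, sme: float) -> DiePressureResult:
    """Total die pressure drop for a power-law melt.

    Series elements add their drops; parallel groups (shared ``group`` id)
    split the flow so every branch sees the same drop (1D root find).  Wall
    shear rates are reported per element for viscosity evaluation.
    """
    die = list(die)
    if not die:
        raise ConfigError(["die has no elements"])
    if qv <= 0:
        raise DomainError(f"Qv must be > 0, got {qv}")
    k = consistency(params, temperature_c + 273.15, mc, sme)
    n = flow_index(params, temperature_c, mc, sme)

    # series stages: either a lone element or a parallel group
    stages: list[list[DieElement]] = []
    seen_groups: dict[str, list] = {}
    for el in die:
        if el.group is None:
            stages.append([el])
        elif el.group in seen_groups:
            seen_groups[el.group].append(el)
        else:
            seen_groups[el.group] = [el]
            stages.append(seen_groups[el.group])

    total = 0.0
    shear = {}
    stage_dp = []
    for stage in stages:
        if len(stage) == 1:
            dp = _die_dp(stage[0], qv, k, n)
            shear[id(stage[0])] = _die_wall_shear(stage[0], qv, n)
        else:
            def excess(dp_try):
                return sum(_die_q(el, dp_try, k, n) for el in stage) - qv
            dp_hi = max(_die_dp(el, qv, k, n) for el in stage)
            dp = brentq(excess, 1e-12, dp_hi * 1.0000001, xtol=1e-6,
                        rtol=1e-12, maxiter=200)
            for el in stage:
                shear[id(el)] = _die_wall_shear(el, _die_q(el, dp, k, n), n)
        stage_dp.append(dp)
        total += dp
    return DiePressureResult(
        dp=total,
        wall_shear_rates=tuple(shear[id(el)] for el in die),
        element_dp=tuple(stage_dp), k=k, n=n)
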
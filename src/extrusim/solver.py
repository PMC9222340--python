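"""Backward-shooting global solver.

The die-exit temperature is unknown, so the computation starts from the die
and proceeds upstream element by element; the exit temperature is iterated
(bracketing bisection) until the temperature computed at the melting point
matches the melting temperature T_m(MC).  The melting point follows the
instantaneous-melting rule: melt exists from the first restrictive element
(counted from the feed) to the die, and the boundary sits where the
backed-up pressure vanishes upstream of that element.

Cumulative specific mechanical energy is itself an input of the viscosity
model, but it is only known after a march; an inner damped fixed-point
iteration resolves that circularity (the SME profile used to evaluate
viscosity is updated from the march it produced until stationary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


from .errors import ConfigError, ConvergenceError
from .local_flow import ElementState, dissipated_power, energy_step, \
    representative_shear_rate
from .machine import Extruder, die_pressure_drop, shape_factors
from .materials import Material, apparent_viscosity, melt_property, \
    melting_temperature

__all__ = ["OperatingPoint", "SimulationResult", "locate_melting_section",
           "solve_profile", "summarize"]


@dataclass(frozen=True)
class OperatingPoint:
    """Operating conditions: screw speed N (rpm), feed rate Q (kg/h),
    wet-basis moisture fraction, barrel-zone set temperatures (degC, hopper
    to die, one per machine zone), die set temperature and Nusselt number."""

    n_rpm: float
    q_kgh: float
    mc: float
    barrel_temps_c: tuple
    die_temp_c: float | None = None
    nusselt: float = 20.0

    def __post_init__(self):
        problems = []
        if self.n_rpm <= 0:
            problems.append(f"screw speed must be > 0 rpm, got {self.n_rpm}")
        if self.q_kgh <= 0:
            problems.append(f"feed rate must be > 0 kg/h, got {self.q_kgh}")
        if not 0.0 < self.mc < 0.9:
            problems.append(f"moisture fraction must be in (0, 0.9), got {self.mc}")
        if self.nusselt <= 0:
            problems.append(f"Nusselt number must be > 0, got {self.nusselt}")
        if problems:
            raise ConfigError([f"operating point: {p}" for p in problems])
        object.__setattr__(self, "barrel_temps_c", tuple(self.barrel_temps_c))
        if self.die_temp_c is None:
            object.__setattr__(self, "die_temp_c", self.barrel_temps_c[-1])

    def with_(self, **kwargs) -> "OperatingPoint":
        """Copy with some fields replaced (convenience for sweeps)."""
        base = dict(n_rpm=self.n_rpm, q_kgh=self.q_kgh, mc=self.mc,
                    barrel_temps_c=self.barrel_temps_c,
                    die_temp_c=self.die_temp_c, nusselt=self.nusselt)
        if "last_barrel_temp_c" in kwargs:
            # "last barrel temperature" regulates the melt-region zones: the
            # contiguous tail of zones sharing the current last set value
            # (e.g. the four 90-degC zones of a 20/40/60/90x4 profile), plus
            # the die
            tb = kwargs.pop("last_barrel_temp_c")
            temps = list(base["barrel_temps_c"])
            tail = temps[-1]
            i = len(temps)
            while i > 1 and temps[i - 1] == tail:
                i -= 1
            temps[i:] = [tb] * (len(temps) - i)
            base["barrel_temps_c"] = tuple(temps)
            base["die_temp_c"] = tb
        base.update(kwargs)
        return OperatingPoint(**base)


@dataclass
class SimulationResult:
    """Axial melt states (die -> melting point) and die-exit summary."""

    states: list  # ElementState, ordered from the die upstream
    t_com: float  # die-exit melt temperature, degC
    sme_com: float  # cumulative SME at die exit, kJ/kg (screw elements)
    p_com: float  # die-entrance pressure, Pa
    eta_com: float  # apparent viscosity at the die-exit wall shear, Pa s
    mean_residence_time: float  # s, melting point -> die exit
    melting_position: float  # m from die
    converged: bool
    iterations: int
    melting_temp_c: float
    sme_melting_enthalpy: float  # kJ/kg, reported separately
    over_fed: bool = False
    die_wall_shear: float = 0.0
    meta: dict = field(default_factory=dict)

    def profile_frame(self) -> pd.DataFrame:
        """Axial profile as a tidy frame (one row per station, die first)."""
        return pd.DataFrame({
            "position_m": [s.position for s in self.states],
            "element_id": [s.element_label for s in self.states],
            "T_C": [s.temperature_c for s in self.states],
            "P_Pa": [s.pressure for s in self.states],
            "SME_kJkg": [s.sme_cum for s in self.states],
            "eta_Pas": [s.eta_local for s in self.states],
            "fill_ratio": [s.fill_ratio for s in self.states],
            "residence_s": [s.residence_time for s in self.states],
        })


def locate_melting_section(extruder_or_elements) -> int:
    """Index (hopper -> die order) of the first restrictive element counted
    from the feed; the melting boundary condition is applied at/upstream of
    this element."""
    if isinstance(extruder_or_elements, Extruder):
        elements = extruder_or_elements.elements
    else:
        elements = tuple(extruder_or_elements)
    for i, el in enumerate(elements):
        if el.is_restrictive:
            return i
    raise ConfigError(
        ["screw profile has no restrictive element (reverse_lh or "
         "kneading_block); add one so a melting section exists"])


@dataclass
class _March:
    """One backward march at a fixed die-exit temperature."""

    t_melt: float  # temperature reached at the melting point
    melt_position: float
    stations: list  # (position, element, t, p, fill, w_dot, dt_res, sub_len)
    die_dp: float
    die_shear: float
    over_fed: bool
    sme_com: float
    sme_positions: np.ndarray  # increasing position from die
    sme_values: np.ndarray  # SME at those positions (kJ/kg)


def _march(extruder: Extruder, material: Material, op: OperatingPoint,
           t_die: float, sme_of_pos, n_substeps: int) -> _March:
    d = extruder.screw_diameter
    mc = op.mc
    rho = melt_property(material, mc, "rho")
    m_dot = op.q_kgh / 3600.0
    qv = m_dot / rho
    omega = 2.0 * math.pi * op.n_rpm / 60.0
    params = material.viscosity

    melt_idx = locate_melting_section(extruder)
    # upstream end (position from die) of the first restrictive element
    pos_end = 0.0
    first_restrictive_upstream = None
    for pos, el in extruder.element_positions():
        if el is extruder.elements[melt_idx]:
            first_restrictive_upstream = pos + el.length
        pos_end = pos + el.length
    assert first_restrictive_upstream is not None

    # die: pressure drop and temperature step (pressure work vs die-wall
    # exchange), evaluated at the exit state
    sme_exit = float(sme_of_pos(0.0))
    die = die_pressure_drop(extruder.die, qv, params, t_die, mc, sme_exit)
    cp = melt_property(material, mc, "cp")
    k_melt = melt_property(material, mc, "k")
    # die: conduction through each wall at its hydraulic diameter
    ecd_rate = 0.0
    for el in extruder.die:
        if el.kind == "circular":
            area, d_h = 2.0 * math.pi * el.radius * el.length, 2.0 * el.radius
        else:
            area, d_h = 2.0 * (el.width + el.height) * el.length, 2.0 * el.height
        ecd_rate += op.nusselt * k_melt / d_h * area * (t_die - op.die_temp_c)
    ev_die = die.dp / rho
    ecd_die = ecd_rate / m_dot
    dt_die = (ev_die - ecd_die) / cp
    t = t_die - dt_die
    p = die.dp
    t = min(max(t, 1.0), 450.0)  # truncate hopeless shooting guesses

    stations = []
    over_fed = False
    stop_pos = None
    t_stop = None
    # explicit backward march diverges outside any physical melt state; a
    # guard truncates hopeless shooting guesses (the residual keeps its sign)
    t_floor, t_ceil = 1.0, 450.0
    for pos_dn, el in extruder.element_positions():
        sf = shape_factors(el, d)
        n_sub = max(n_substeps, int(math.ceil(el.length / 0.012)))
        sub_len = el.length / n_sub
        frac = 1.0 / n_sub
        a_omega = sf.a * omega
        for j in range(n_sub):
            p_dn = p
            pos_mid = pos_dn + (j + 0.5) * sub_len
            tb = op.barrel_temps_c[extruder.zone_at(pos_mid)]
            sme_loc = float(sme_of_pos(pos_mid))
            g_ch, _ = representative_shear_rate(sf, d, op.n_rpm)

            pressurized = p_dn > 0.0 or a_omega <= qv
            starved_fill = min(1.0, qv / a_omega) if a_omega > 0 else 1.0
            if a_omega < qv and el.kind == "conveying_rh" and p_dn <= 0.0:
                over_fed = True

            def rates(t_at):
                """Dissipation, temperature step and pressure step at a trial
                temperature; where the pressure vanishes inside the sub-step
                the filled and starved parts are blended by the pressurized
                length fraction (removes filled-length quantization)."""
                if pressurized:
                    eta_ch = apparent_viscosity(params, g_ch, t_at, mc,
                                                sme_loc)
                    dp = (a_omega - qv) * eta_ch * sf.dtheta * frac / sf.b
                    wf = 1.0 if (dp <= 0.0 or dp <= p_dn) else p_dn / dp
                else:
                    dp, wf = 0.0, 0.0
                w_full = dissipated_power(
                    sf, params, d, t_at, mc, sme_loc, op.n_rpm,
                    fill_ratio=1.0, pressurized=True) * frac
                w_starv = dissipated_power(
                    sf, params, d, t_at, mc, sme_loc, op.n_rpm,
                    fill_ratio=starved_fill, pressurized=False) * frac
                w = wf * w_full + (1.0 - wf) * w_starv
                fill_eff = wf + (1.0 - wf) * starved_fill
                dt = energy_step(material, mc, w, qv, t_at, tb, op.nusselt,
                                 sf.area_barrel * frac * fill_eff,
                                 2.0 * sf.channel_depth)
                return w, dt, dp, fill_eff

            # midpoint rule: evaluate the step rates at the half-step state
            _, dt_e, _, _ = rates(t)
            t_half = min(max(t - 0.5 * dt_e, 1.0), 450.0)
            w_dot, dt, dp, fill_eff = rates(t_half)
            p_up = max(p_dn - dp, 0.0) if pressurized else 0.0

            t_res = fill_eff * sf.v_channel * frac / qv
            stations.append((pos_mid, el, t, p_dn, fill_eff, w_dot, t_res,
                             sub_len))
            t = t - dt
            p = p_up
            pos_top = pos_dn + (j + 1) * sub_len
            if not t_floor < t < t_ceil:
                t = min(max(t, t_floor), t_ceil)
                stop_pos = pos_top
                t_stop = t
                break
            if pos_top >= first_restrictive_upstream - 1e-12 and p <= 0.0:
                stop_pos = pos_top
                t_stop = t
                break
        if stop_pos is not None:
            break
    if stop_pos is None:
        # pressure backed up to the hopper: over-fed machine
        stop_pos = pos_end
        t_stop = t
        over_fed = True

    # cumulative SME marching forward (melting point -> die)
    pos_arr = np.array([s[0] for s in stations])
    w_arr = np.array([s[5] for s in stations])
    order = np.argsort(pos_arr)[::-1]  # upstream first
    cum = np.cumsum(w_arr[order]) / m_dot / 1000.0  # kJ/kg
    sme_pos = pos_arr[order][::-1].copy()
    sme_val = cum[::-1].copy()
    return _March(
        t_melt=t_stop, melt_position=stop_pos, stations=stations,
        die_dp=die.dp, die_shear=max(die.wall_shear_rates), over_fed=over_fed,
        sme_com=float(cum[-1]) if len(cum) else 0.0,
        sme_positions=sme_pos, sme_values=sme_val)


def _sme_interp(march: _March):
    """SME-vs-position lookup from a march (0 beyond the melting point)."""
    pos = march.sme_positions  # decreasing? stored increasing from die
    val = march.sme_values

    def f(x):
        return np.interp(x, pos, val, left=val[0] if len(val) else 0.0,
                         right=0.0)
    return f


def solve_profile(extruder: Extruder, material: Material, op: OperatingPoint,
                  n_substeps: int = 4, tol_t: float = 0.1,
                  max_shoot: int = 60, sme_tol: float = 1e-3,
                  sme_damping: float = 0.5,
                  include_melting_enthalpy: bool = False) -> SimulationResult:
    """Solve the axial thermo-mechanical profile for one operating point.

    Outer loop: bracketing root find (brentq) on the die-exit temperature so
    the marched temperature at the melting point equals T_m(MC) within
    ``tol_t``.  Inner loop: damped Picard iteration of the SME profile that
    feeds the viscosity model.  Raises :class:`ConvergenceError` with the
    last bracket when shooting fails.
    """
    if len(op.barrel_temps_c) != extruder.n_zones:
        raise ConfigError(
            [f"operating point has {len(op.barrel_temps_c)} barrel "
             f"temperatures, machine {extruder.name!r} has "
             f"{extruder.n_zones} zones"])
    t_m = melting_temperature(material, op.mc)
    m_dot = op.q_kgh / 3600.0

    evals = {"marches": 0, "shots": 0}

    def converge_sme(t_die: float) -> _March:
        evals["shots"] += 1
        # start every evaluation from the same flat profile so the shooting
        # residual is a deterministic function of t_die
        def f(x):
            return np.zeros_like(np.asarray(x, dtype=float)) \
                + material.viscosity.sme0_ref
        last = None
        for _ in range(60):
            m = _march(extruder, material, op, t_die, f, n_substeps)
            evals["marches"] += 1
            new = _sme_interp(m)
            if last is not None:
                ref = max(m.sme_com, 1.0)
                if abs(m.sme_com - last) / ref < sme_tol:
                    return m
            damped_prev, damped_new = f, new

            def f(x, a=damped_prev, b=damped_new, w=sme_damping):
                return (1.0 - w) * np.asarray(a(x)) + w * np.asarray(b(x))
            last = m.sme_com
        raise ConvergenceError(
            "SME fixed-point iteration did not converge",
            detail={"t_die": t_die, "last_sme": last})

    def residual(t_die: float) -> float:
        return converge_sme(t_die).t_melt - t_m

    # bracket the die-exit temperature (usually t_die > t at the melting
    # point, so start at T_m and expand upward; expand downward only for
    # conduction-dominated cold runs)
    lo, hi = t_m - 5.0, t_m + 60.0
    r_lo = residual(lo)
    r_hi = residual(hi)
    tries = 0
    while r_lo * r_hi > 0 and tries < 8:
        if r_lo > 0:  # even a cold die overshoots T_m: go colder
            lo -= 30.0
            r_lo = residual(lo)
        else:
            hi += 50.0
            r_hi = residual(hi)
        tries += 1
    if r_lo * r_hi > 0:
        raise ConvergenceError(
            "could not bracket the die-exit temperature",
            detail={"bracket": (lo, hi), "residuals": (r_lo, r_hi)})
    # plain bisection: the backward march amplifies die-temperature
    # perturbations strongly (the forward problem is self-regulating, so the
    # backward one is anti-damped), making the residual steep; bisection on
    # the sign is robust where secant/Brent steps overshoot
    t_die = 0.5 * (lo + hi)
    march = converge_sme(t_die)
    for _ in range(max_shoot):
        err = march.t_melt - t_m
        if abs(err) < tol_t or (hi - lo) < 1e-9:
            break
        if err > 0:
            hi = t_die
        else:
            lo = t_die
        t_die = 0.5 * (lo + hi)
        march = converge_sme(t_die)
    converged = abs(march.t_melt - t_m) < tol_t

    # assemble states die -> melting point with SME/viscosity/residence
    sme_f = _sme_interp(march)
    d = extruder.screw_diameter
    states = []
    res_cum_from_melt = {}
    order = sorted(range(len(march.stations)),
                   key=lambda i: -march.stations[i][0])
    acc = 0.0
    for i in order:
        acc += march.stations[i][6]
        res_cum_from_melt[i] = acc
    for i, st in enumerate(march.stations):
        pos, el, t, p, fill, w_dot, t_res, sub_len = st
        sf = shape_factors(el, d)
        g_ch, _ = representative_shear_rate(sf, d, op.n_rpm)
        sme_loc = float(sme_f(pos))
        eta = apparent_viscosity(material.viscosity, g_ch, t, op.mc, sme_loc)
        states.append(ElementState(
            position=pos, temperature_c=t, pressure=p, sme_cum=sme_loc,
            eta_local=eta, fill_ratio=fill,
            residence_time=res_cum_from_melt[i],
            element_label=el.label or el.kind))

    eta_com = apparent_viscosity(material.viscosity, march.die_shear, t_die,
                                 op.mc, march.sme_com)
    die_volume = 0.0
    for el in extruder.die:
        if el.kind == "circular":
            die_volume += math.pi * el.radius ** 2 * el.length
        else:
            die_volume += el.width * el.height * el.length
    rho = melt_property(material, op.mc, "rho")
    qv = m_dot / rho
    mean_res = (max(res_cum_from_melt.values()) if res_cum_from_melt else 0.0) \
        + die_volume / qv
    dh_melt = material.melting_enthalpy / 1000.0  # kJ/kg
    sme_com = march.sme_com + (dh_melt if include_melting_enthalpy else 0.0)
    return SimulationResult(
        states=states, t_com=t_die, sme_com=sme_com, p_com=march.die_dp,
        eta_com=eta_com, mean_residence_time=mean_res,
        melting_position=march.melt_position, converged=converged,
        iterations=evals["shots"], melting_temp_c=t_m,
        sme_melting_enthalpy=dh_melt, over_fed=march.over_fed,
        die_wall_shear=march.die_shear,
        meta={"marches": evals["marches"],
              "machine": extruder.name, "material": material.name,
              "n_rpm": op.n_rpm, "q_kgh": op.q_kgh, "mc": op.mc,
              "barrel_temps_c": list(op.barrel_temps_c),
              "die_temp_c": op.die_temp_c, "nusselt": op.nusselt})


def summarize(result: SimulationResult) -> dict:
    """Flat die-exit record; refuses unconverged results."""
    if not result.converged:
        raise ConvergenceError(
            "refusing to summarize an unconverged simulation",
            detail={"iterations": result.iterations})
    rec = {
        "T_com_C": result.t_com,
        "SME_com_kJkg": result.sme_com,
        "P_com_Pa": result.p_com,
        "eta_com_Pas": result.eta_com,
        "mean_residence_s": result.mean_residence_time,
        "melting_position_m": result.melting_position,
        "melting_temp_C": result.melting_temp_c,
        "sme_melting_enthalpy_kJkg": result.sme_melting_enthalpy,
    }
    rec.update({f"op_{k}": v for k, v in result.meta.items()})
    return rec
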
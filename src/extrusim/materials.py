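"""Material definitions and melt rheology.

The viscous behaviour of molten starchy feeds is described by the
Ostwald-de Waele power law

    eta = K * gamma_dot**(n - 1)

whose consistency ``K`` carries an Arrhenius temperature term, a moisture
plasticization term and a thermomechanical-history (SME) term:

    K = K0 * exp( E/R * (1/Ta - 1/T0) - alpha*(MC - MC0) - beta*(SME - SME0) )

with Ta the absolute melt temperature (K), MC the wet-basis moisture mass
fraction and SME the cumulative specific mechanical energy (kJ/kg).  The flow
index is an empirical polynomial in T (degC), MC and SME:

    n = n0 + a1*T + a2*MC + a3*SME + a4*T*MC + a5*T*SME + a6*MC*SME

Two parameter dialects circulate in the literature.  The *referenced* dialect
is the form above; the *absolute* dialect omits the reference state, i.e.
``K = K0 * exp(E/R / Ta - alpha*MC - beta*SME)`` with a correspondingly
rescaled K0.  Both are supported; :func:`convert_to_referenced` maps one onto
the other in closed form.

A database of published parameter sets for maize starches of several amylose
contents, potato starch, two breakfast-cereal recipes, pea flour and wheat
flour / wheat-bran blends ships with the package (``load_material``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, DomainError, RangeError, SingularFitError

__all__ = [
    "ViscosityParams",
    "Material",
    "RheometryPoint",
    "consistency",
    "flow_index",
    "apparent_viscosity",
    "melting_temperature",
    "melt_property",
    "convert_to_referenced",
    "fit_viscosity_params",
    "ViscosityFit",
    "load_material",
    "available_materials",
    "material_from_dict",
]

logger = logging.getLogger(__name__)

#: Reference state of the consistency model (absolute T, moisture fraction,
#: specific mechanical energy in kJ/kg).
T0_REF_K = 353.0
MC0_REF = 0.10
SME0_REF_KJKG = 350.0

CELSIUS_OFFSET = 273.15


@dataclass(frozen=True)
class ViscosityParams:
    """Power-law consistency/flow-index parameter set.

    ``dialect`` is ``"referenced"`` (reference-state form) or ``"absolute"``
    (no reference state; K0 is then typically many orders of magnitude
    smaller).  Coefficients printed as "-" in published tables are exact
    zeros, meaning the corresponding dependence was not retained by the
    original fit.
    """

    k0: float  # Pa s^n
    e_over_r: float  # K
    alpha: float = 0.0  # per moisture fraction
    beta: float = 0.0  # kg/kJ
    n0: float = 0.0
    a1: float = 0.0  # 1/degC
    a2: float = 0.0
    a3: float = 0.0  # kg/kJ
    a4: float = 0.0  # 1/degC (on T*MC)
    a5: float = 0.0  # kg/(degC kJ)
    a6: float = 0.0  # kg/kJ (on MC*SME)
    t0_ref: float = T0_REF_K  # K
    mc0_ref: float = MC0_REF
    sme0_ref: float = SME0_REF_KJKG  # kJ/kg
    dialect: str = "referenced"

    def __post_init__(self):
        if self.k0 <= 0:
            raise DomainError(f"K0 must be > 0, got {self.k0}")
        if self.e_over_r < 0:
            raise DomainError(f"E/R must be >= 0, got {self.e_over_r}")
        if self.dialect not in ("referenced", "absolute"):
            raise ConfigError(f"unknown viscosity dialect {self.dialect!r}")


@dataclass(frozen=True)
class RheometryPoint:
    """One rheometer observation (shear rate in 1/s, T in degC, eta in Pa s)."""

    shear_rate: float
    temperature_c: float
    mc: float
    sme: float
    eta: float

    def __post_init__(self):
        if self.shear_rate <= 0:
            raise DomainError("shear_rate must be > 0")
        if self.eta <= 0:
            raise DomainError("eta must be > 0")


@dataclass(frozen=True)
class Material:
    """A feed recipe: composition, thermal properties, melting curve, rheology.

    Thermal properties are stored as (dry melt, water) pairs and blended
    linearly in the moisture mass fraction by :func:`melt_property`.  The
    melting curve is a table of (MC fraction, T_m degC) pairs with T_m
    strictly decreasing in MC.
    """

    name: str
    composition: dict = field(default_factory=dict)
    rho_dry: float = 1400.0  # kg/m3
    rho_water: float = 1000.0
    cp_dry: float = 1550.0  # J/(kg K)
    cp_water: float = 4186.0
    k_dry: float = 0.25  # W/(m K)
    k_water: float = 0.60
    melting_curve: tuple = ()  # ((mc, tm_c), ...)
    melting_enthalpy: float = 14000.0  # J/kg
    viscosity: ViscosityParams = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        problems = []
        for key, frac in self.composition.items():
            if not 0.0 <= frac <= 1.0:
                problems.append(f"composition[{key}] = {frac} outside [0, 1]")
        for prop in ("rho_dry", "rho_water", "cp_dry", "cp_water", "k_dry", "k_water",
                     "melting_enthalpy"):
            if getattr(self, prop) <= 0:
                problems.append(f"{prop} must be > 0")
        curve = tuple((float(mc), float(tm)) for mc, tm in self.melting_curve)
        object.__setattr__(self, "melting_curve", curve)
        mcs = [mc for mc, _ in curve]
        tms = [tm for _, tm in curve]
        if sorted(mcs) != mcs:
            problems.append("melting_curve moisture values must be increasing")
        if len(curve) >= 2 and any(t2 >= t1 for t1, t2 in zip(tms, tms[1:])) \
                and len(set(mcs)) == len(mcs):
            problems.append("melting_curve T_m must strictly decrease with MC")
        if problems:
            raise ConfigError([f"material {self.name!r}: {p}" for p in problems])


def _check_state(temperature_k: float, mc: float, sme: float) -> None:
    if temperature_k <= 0:
        raise DomainError(f"absolute temperature must be > 0 K, got {temperature_k}")
    if not 0.0 < mc < 1.0:
        raise DomainError(f"moisture fraction must be in (0, 1), got {mc}")
    if sme < 0:
        raise DomainError(f"SME must be >= 0, got {sme}")


def consistency(params: ViscosityParams, temperature_k: float, mc: float,
                sme: float) -> float:
    """Consistency K (Pa s^n) at absolute temperature (K), moisture fraction
    and SME (kJ/kg), honouring the parameter dialect."""
    _check_state(temperature_k, mc, sme)
    if params.dialect == "referenced":
        expo = (params.e_over_r * (1.0 / temperature_k - 1.0 / params.t0_ref)
                - params.alpha * (mc - params.mc0_ref)
                - params.beta * (sme - params.sme0_ref))
    else:  # absolute
        expo = (params.e_over_r / temperature_k
                - params.alpha * mc
                - params.beta * sme)
    return params.k0 * math.exp(expo)


_flow_index_clamped_once: list = []


def flow_index(params: ViscosityParams, temperature_c: float, mc: float,
               sme: float, n_min: float = 0.05) -> float:
    """Flow index n at temperature (degC), moisture fraction and SME (kJ/kg).

    The raw polynomial is clamped into [n_min, 1]: it is an empirical surface
    valid only inside its calibration window, while the power law requires
    0 <= n <= 1.  Clamping is logged at warning level.
    """
    _check_state(temperature_c + CELSIUS_OFFSET, mc, sme)
    t, s = temperature_c, sme
    n = (params.n0 + params.a1 * t + params.a2 * mc + params.a3 * s
         + params.a4 * t * mc + params.a5 * t * s + params.a6 * mc * s)
    if n < n_min or n > 1.0:
        clamped = min(max(n, n_min), 1.0)
        # warn once per process, then demote to debug (solver marches can
        # probe far outside the calibration window while bracketing)
        level = logging.WARNING if not _flow_index_clamped_once else logging.DEBUG
        _flow_index_clamped_once.append(True)
        logger.log(
            level,
            "flow index %.4g at (T=%.4g degC, MC=%.4g, SME=%.4g) outside "
            "[%.3g, 1]; clamped to %.4g", n, t, mc, s, n_min, clamped)
        n = clamped
    return n


def apparent_viscosity(params: ViscosityParams, shear_rate: float,
                       temperature_c: float, mc: float, sme: float,
                       n_min: float = 0.05) -> float:
    """Apparent shear viscosity eta = K * gamma_dot**(n-1) in Pa s."""
    if shear_rate <= 0:
        raise DomainError(f"shear rate must be > 0, got {shear_rate}")
    k = consistency(params, temperature_c + CELSIUS_OFFSET, mc, sme)
    n = flow_index(params, temperature_c, mc, sme, n_min=n_min)
    return k * shear_rate ** (n - 1.0)


def convert_to_referenced(params: ViscosityParams) -> ViscosityParams:
    """Closed-form conversion of an absolute-dialect set to the referenced
    dialect: K0' = K0 * exp(E/R / T0 - alpha*MC0 - beta*SME0)."""
    if params.dialect == "referenced":
        return params
    k0_ref = params.k0 * math.exp(params.e_over_r / params.t0_ref
                                  - params.alpha * params.mc0_ref
                                  - params.beta * params.sme0_ref)
    return replace(params, k0=k0_ref, dialect="referenced")


def melting_temperature(material: Material, mc: float) -> float:
    """Melting temperature T_m (degC) at moisture fraction ``mc``, by monotone
    piecewise-linear interpolation of the material's melting curve.
    Extrapolation outside the tabulated moisture range is refused."""
    curve = material.melting_curve
    if len(curve) < 1:
        raise ConfigError(f"material {material.name!r} has no melting curve")
    mcs = np.array([p[0] for p in curve])
    tms = np.array([p[1] for p in curve])
    if mc < mcs[0] or mc > mcs[-1]:
        raise RangeError(
            f"MC = {mc} outside melting-curve range [{mcs[0]}, {mcs[-1]}] "
            f"of material {material.name!r}")
    return float(np.interp(mc, mcs, tms))


def melt_property(material: Material, mc: float, which: str) -> float:
    """Moisture-blended melt property: ``which`` in {"rho", "cp", "k"}.

    prop(MC) = MC * prop_water + (1 - MC) * prop_dry  (mass-fraction rule).
    """
    pairs = {
        "rho": (material.rho_dry, material.rho_water),
        "cp": (material.cp_dry, material.cp_water),
        "k": (material.k_dry, material.k_water),
    }
    if which not in pairs:
        raise ConfigError(f"unknown melt property {which!r}; expected rho|cp|k")
    if not 0.0 <= mc <= 1.0:
        raise DomainError(f"moisture fraction must be in [0, 1], got {mc}")
    dry, water = pairs[which]
    return mc * water + (1.0 - mc) * dry


# ---------------------------------------------------------------------------
# Parameter fitting from rheometry data
# ---------------------------------------------------------------------------

_TERMS = ("log_k0", "e_over_r", "alpha", "beta", "n0", "a1", "a2", "a3",
          "a4", "a5", "a6")


@dataclass
class ViscosityFit:
    """Result of :func:`fit_viscosity_params`."""

    params: ViscosityParams
    terms: tuple
    residual_se: float  # on log(eta)
    coef_se: dict  # per-term standard errors
    n_obs: int
    r_squared: float


def _regressor(term: str, lg: np.ndarray, t_c: np.ndarray, inv_ta: np.ndarray,
               mc: np.ndarray, sme: np.ndarray, dialect: str) -> np.ndarray:
    """Column of the log-linear design for one coefficient.

    log eta = log K0 + E/R*(1/Ta - 1/T0) - alpha*(MC - MC0) - beta*(SME - SME0)
              + (n - 1) * log gamma_dot
    is linear in every coefficient once n is expanded; n's coefficients enter
    multiplied by log gamma_dot.
    """
    if dialect == "referenced":
        x_t = inv_ta - 1.0 / T0_REF_K
        x_mc = -(mc - MC0_REF)
        x_sme = -(sme - SME0_REF_KJKG)
    else:
        x_t = inv_ta
        x_mc = -mc
        x_sme = -sme
    cols = {
        "log_k0": np.ones_like(lg),
        "e_over_r": x_t,
        "alpha": x_mc,
        "beta": x_sme,
        "n0": lg,
        "a1": t_c * lg,
        "a2": mc * lg,
        "a3": sme * lg,
        "a4": t_c * mc * lg,
        "a5": t_c * sme * lg,
        "a6": mc * sme * lg,
    }
    return cols[term]


def fit_viscosity_params(data: Sequence[RheometryPoint],
                         dialect: str = "referenced",
                         terms: Iterable[str] | None = None) -> ViscosityFit:
    """Least-squares calibration of the viscosity model on log eta.

    The model is linear in log K0, E/R, alpha, beta and, through the
    log-shear-rate interaction, in the flow-index coefficients, so ordinary
    least squares applies.  When ``terms`` is None, coefficients are selected
    automatically: a factor's coefficient is fit only if that factor varies in
    the data (fixed factors pin their coefficients to zero).  Interaction
    coefficients require both factors to vary.

    Raises :class:`SingularFitError` naming the unidentifiable coefficients
    when the selected design is rank deficient.
    """
    pts = list(data)
    if len(pts) < 2:
        raise DomainError("need at least 2 rheometry points")
    lg = np.log(np.array([p.shear_rate for p in pts]))
    t_c = np.array([p.temperature_c for p in pts])
    inv_ta = 1.0 / (t_c + CELSIUS_OFFSET)
    mc = np.array([p.mc for p in pts])
    sme = np.array([p.sme for p in pts])
    log_eta = np.log(np.array([p.eta for p in pts]))

    def varies(x):
        return np.ptp(x) > 1e-12

    if terms is None:
        sel = ["log_k0"]
        if varies(t_c):
            sel.append("e_over_r")
        if varies(mc):
            sel.append("alpha")
        if varies(sme):
            sel.append("beta")
        if varies(lg):
            sel.append("n0")
            if varies(t_c):
                sel.append("a1")
            if varies(mc):
                sel.append("a2")
            if varies(sme):
                sel.append("a3")
            if varies(t_c) and varies(mc):
                sel.append("a4")
            if varies(t_c) and varies(sme):
                sel.append("a5")
            if varies(mc) and varies(sme):
                sel.append("a6")
    else:
        bad = set(terms) - set(_TERMS)
        if bad:
            raise ConfigError(f"unknown fit term(s): {sorted(bad)}")
        sel = [t for t in _TERMS if t in set(terms)]
        if "log_k0" not in sel:
            sel.insert(0, "log_k0")

    x = np.column_stack([_regressor(t, lg, t_c, inv_ta, mc, sme, dialect)
                         for t in sel])
    # offset the fixed "-1" in (n - 1) * log gamma_dot
    y = log_eta + lg

    if len(pts) < len(sel):
        raise SingularFitError(sel[len(pts):])
    # rank analysis on column-normalized design so ill-scaled regressors do
    # not mask collinearity
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    _, s_n, vt_n = np.linalg.svd(x / norms, full_matrices=False)
    rank = int(np.sum(s_n > s_n[0] * 1e-8))
    if rank < len(sel):
        # name the terms involved in the null-space directions, preferring
        # the specific coefficients over the always-present intercept
        culprits = set()
        for row in vt_n[rank:]:
            involved = [sel[i] for i in np.flatnonzero(
                np.abs(row) > 0.3 * np.abs(row).max())]
            named = [t for t in involved if t != "log_k0"] or involved
            culprits.update(named)
        raise SingularFitError(sorted(culprits))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    dof = max(len(pts) - len(sel), 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = vt.T @ np.diag(1.0 / s**2) @ vt
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0

    values = dict.fromkeys(_TERMS, 0.0)
    for t, c in zip(sel, coef):
        values[t] = float(c)
    params = ViscosityParams(
        k0=math.exp(values["log_k0"]),
        e_over_r=max(values["e_over_r"], 0.0),
        alpha=values["alpha"], beta=values["beta"], n0=values["n0"],
        a1=values["a1"], a2=values["a2"], a3=values["a3"], a4=values["a4"],
        a5=values["a5"], a6=values["a6"], dialect=dialect)
    return ViscosityFit(params=params, terms=tuple(sel),
                        residual_se=math.sqrt(sigma2),
                        coef_se={t: float(e) for t, e in zip(sel, se)},
                        n_obs=len(pts), r_squared=r2)


# ---------------------------------------------------------------------------
# Shipped material database
# ---------------------------------------------------------------------------

_ALIASES = {"lb": "wf_lb", "hb_bran": "wf_hb", "maizea": "maize_a",
            "maizeb": "maize_b", "maizec": "maize_c", "maized": "maize_d",
            "potato1": "potato_1"}


def material_from_dict(doc: dict, name: str | None = None) -> Material:
    """Build a :class:`Material` from a parsed YAML document."""
    problems = []
    visc_doc = doc.get("viscosity")
    if visc_doc is None:
        problems.append("missing 'viscosity' section")
        raise ConfigError(problems)
    try:
        visc = ViscosityParams(
            k0=float(visc_doc["K0_Pasn"]),
            e_over_r=float(visc_doc["E_over_R_K"]),
            alpha=float(visc_doc.get("alpha", 0.0)),
            beta=float(visc_doc.get("beta_kgkJ", 0.0)),
            n0=float(visc_doc.get("n0", 0.0)),
            a1=float(visc_doc.get("a1", 0.0)),
            a2=float(visc_doc.get("a2", 0.0)),
            a3=float(visc_doc.get("a3", 0.0)),
            a4=float(visc_doc.get("a4", 0.0)),
            a5=float(visc_doc.get("a5", 0.0)),
            a6=float(visc_doc.get("a6", 0.0)),
            dialect=visc_doc.get("dialect", "referenced"),
        )
    except KeyError as exc:
        raise ConfigError([f"viscosity section missing key {exc}"]) from exc
    thermal = doc.get("thermal", {})
    comp = {k: _fraction(v) for k, v in doc.get("composition", {}).items()}
    return Material(
        name=doc.get("name", name or "unnamed"),
        composition=comp,
        rho_dry=float(thermal.get("rho_dry_kgm3", 1400.0)),
        rho_water=float(thermal.get("rho_water_kgm3", 1000.0)),
        cp_dry=float(thermal.get("cp_dry_JkgK", 1550.0)),
        cp_water=float(thermal.get("cp_water_JkgK", 4186.0)),
        k_dry=float(thermal.get("k_dry_WmK", 0.25)),
        k_water=float(thermal.get("k_water_WmK", 0.60)),
        melting_curve=tuple((float(mc), float(tm))
                            for mc, tm in doc.get("melting_curve", ())),
        melting_enthalpy=float(thermal.get("melting_enthalpy_Jkg", 14000.0)),
        viscosity=visc,
        meta=doc.get("meta", {}),
    )


def _fraction(value) -> float:
    """Accept 0.15, "15%" or 15 (percent heuristic only for strings)."""
    if isinstance(value, str):
        value = value.strip()
        if value.endswith("%"):
            return float(value[:-1]) / 100.0
        return float(value)
    return float(value)


def available_materials() -> list[str]:
    """Names of the shipped material database entries."""
    root = resources.files("extrusim") / "data" / "materials"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_material(name_or_path: str) -> Material:
    """Load a material by database name (e.g. "cb", "pf", "maize_b") or from a
    YAML file path."""
    key = name_or_path.lower().replace("-", "_")
    key = _ALIASES.get(key, key)
    root = resources.files("extrusim") / "data" / "materials"
    candidate = root / f"{key}.yaml"
    if candidate.is_file():
        doc = yaml.safe_load(candidate.read_text())
        return material_from_dict(doc, name=key)
    try:
        with open(name_or_path) as fh:
            doc = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(
            [f"no shipped material {name_or_path!r} "
             f"(have: {', '.join(available_materials())}) and not a readable file"]
        ) from exc
    return material_from_dict(doc)
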
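"""Config reading/validation, scenario fixtures and synthetic-data generators.

Everything the test-suite and the examples consume is either shipped as a
small YAML fixture or generated deterministically here; nothing is
downloaded.  Configs use the process units practitioners write (mm, rpm,
kg/h, degC, kJ/kg, percent wet-basis moisture) with explicit key suffixes;
SI is used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .machine import DieElement, Extruder, ScrewElement
from .materials import Material, RheometryPoint, ViscosityParams, \
    load_material, material_from_dict, _fraction
from .solver import OperatingPoint

__all__ = [
    "ScenarioFixture", "SCENARIOS", "get_scenario",
    "load_machine", "machine_from_dict", "load_config", "save_config",
    "generate_rheometry", "generate_feature_data",
]


# ---------------------------------------------------------------------------
# Machine configs
# ---------------------------------------------------------------------------

_MM = 1e-3


def _screw_element_from_dict(doc: dict, problems: list, idx: int) -> ScrewElement | None:
    known = {"kind", "length_mm", "pitch_mm", "channel_depth_mm",
             "flight_count", "stagger_angle_deg", "disc_thickness_mm",
             "flight_gap_mm", "flight_width_mm", "label"}
    unknown = set(doc) - known
    if unknown:
        problems.append(f"elements[{idx}]: unknown key(s) {sorted(unknown)}")
    try:
        return ScrewElement(
            kind=doc.get("kind", ""),
            length=float(doc.get("length_mm", 0.0)) * _MM,
            pitch=float(doc.get("pitch_mm", 0.0)) * _MM,
            channel_depth=float(doc.get("channel_depth_mm", 0.0)) * _MM,
            flight_count=int(doc.get("flight_count", 2)),
            stagger_angle=(float(doc["stagger_angle_deg"])
                           if "stagger_angle_deg" in doc else None),
            disc_thickness=(float(doc["disc_thickness_mm"]) * _MM
                            if "disc_thickness_mm" in doc else None),
            flight_gap=(float(doc["flight_gap_mm"]) * _MM
                        if "flight_gap_mm" in doc else None),
            flight_width=(float(doc["flight_width_mm"]) * _MM
                          if "flight_width_mm" in doc else None),
            label=doc.get("label", ""),
        )
    except ConfigError as exc:
        problems.extend(f"elements[{idx}]: {p}" for p in exc.problems)
        return None


def _die_element_from_dict(doc: dict, problems: list, idx: int) -> DieElement | None:
    known = {"kind", "length_mm", "radius_mm", "width_mm", "height_mm", "group"}
    unknown = set(doc) - known
    if unknown:
        problems.append(f"die[{idx}]: unknown key(s) {sorted(unknown)}")
    try:
        return DieElement(
            kind=doc.get("kind", ""),
            length=float(doc.get("length_mm", 0.0)) * _MM,
            radius=(float(doc["radius_mm"]) * _MM if "radius_mm" in doc else None),
            width=(float(doc["width_mm"]) * _MM if "width_mm" in doc else None),
            height=(float(doc["height_mm"]) * _MM if "height_mm" in doc else None),
            group=doc.get("group"),
        )
    except ConfigError as exc:
        problems.extend(f"die[{idx}]: {p}" for p in exc.problems)
        return None


def machine_from_dict(doc: dict) -> Extruder:
    """Build an :class:`Extruder` from a parsed YAML document, reporting all
    validation failures together."""
    problems: list[str] = []
    elements = [_screw_element_from_dict(e, problems, i)
                for i, e in enumerate(doc.get("elements", []))]
    die = [_die_element_from_dict(e, problems, i)
           for i, e in enumerate(doc.get("die", []))]
    zones_doc = doc.get("barrel_zone_lengths_mm")
    if zones_doc is None:
        problems.append("missing barrel_zone_lengths_mm")
        zones = ()
    else:
        zones = tuple(float(z) * _MM for z in zones_doc)
        spans = np.cumsum([0.0] + list(zones_doc))
        for i in range(len(zones_doc)):
            if zones_doc[i] <= 0:
                problems.append(
                    f"barrel zone {i} span [{spans[i]:.1f}, {spans[i + 1]:.1f}] mm"
                    " has non-positive length (zones must tile without overlap)")
    if problems or any(e is None for e in elements) or any(d is None for d in die):
        raise ConfigError(problems or ["invalid machine config"])
    try:
        return Extruder(
            name=doc.get("name", "unnamed"),
            screw_diameter=float(doc["screw_diameter_mm"]) * _MM,
            total_screw_length=float(doc["total_screw_length_mm"]) * _MM,
            elements=tuple(elements), die=tuple(die),
            barrel_zone_lengths=zones,
            centerline_distance=(float(doc["centerline_distance_mm"]) * _MM
                                 if "centerline_distance_mm" in doc else None),
            feed_position=(float(doc["feed_position_mm"]) * _MM
                           if "feed_position_mm" in doc else None),
            meta=doc.get("meta", {}),
        )
    except KeyError as exc:
        raise ConfigError([f"machine config missing key {exc}"]) from exc


def available_machines() -> list[str]:
    root = resources.files("extrusim") / "data" / "machines"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_machine(name_or_path: str) -> Extruder:
    """Load a machine fixture by name (zsk26_like, bc45_like, process11_like,
    evolum25_like) or from a YAML file path."""
    key = name_or_path.lower().replace("-", "_")
    root = resources.files("extrusim") / "data" / "machines"
    candidate = root / f"{key}.yaml"
    if candidate.is_file():
        return machine_from_dict(yaml.safe_load(candidate.read_text()))
    try:
        with open(name_or_path) as fh:
            return machine_from_dict(yaml.safe_load(fh))
    except OSError as exc:
        raise ConfigError(
            [f"no shipped machine {name_or_path!r} "
             f"(have: {', '.join(available_machines())}) and not a readable file"]
        ) from exc


def _operating_point_from_dict(doc: dict) -> OperatingPoint:
    known = {"n_rpm", "q_kgh", "mc", "barrel_temps_c", "die_temp_c", "nusselt"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError([f"operating_point: unknown key(s) {sorted(unknown)}"])
    return OperatingPoint(
        n_rpm=float(doc["n_rpm"]),
        q_kgh=float(doc["q_kgh"]),
        mc=_fraction(doc["mc"]),
        barrel_temps_c=tuple(float(t) for t in doc["barrel_temps_c"]),
        die_temp_c=(float(doc["die_temp_c"]) if doc.get("die_temp_c")
                    is not None else None),
        nusselt=float(doc.get("nusselt", 20.0)),
    )


def load_config(path: str) -> tuple[Extruder, Material, OperatingPoint]:
    """Load a full scenario config: machine + material + operating point.

    ``machine`` and ``material`` may be shipped-fixture names or inline
    documents.  All validation failures are aggregated into one
    :class:`ConfigError`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    problems = []
    extruder = material = op = None
    m_doc = doc.get("machine")
    try:
        if isinstance(m_doc, str):
            extruder = load_machine(m_doc)
        elif isinstance(m_doc, dict):
            extruder = machine_from_dict(m_doc)
        else:
            problems.append("missing 'machine' (name or inline mapping)")
    except ConfigError as exc:
        problems.extend(exc.problems)
    mat_doc = doc.get("material")
    try:
        if isinstance(mat_doc, str):
            material = load_material(mat_doc)
        elif isinstance(mat_doc, dict):
            material = material_from_dict(mat_doc)
        else:
            problems.append("missing 'material' (name or inline mapping)")
    except ConfigError as exc:
        problems.extend(exc.problems)
    try:
        op_doc = doc.get("operating_point")
        if not isinstance(op_doc, dict):
            problems.append("missing 'operating_point' mapping")
        else:
            op = _operating_point_from_dict(op_doc)
    except ConfigError as exc:
        problems.extend(exc.problems)
    if problems:
        raise ConfigError([f"{path}: {p}" for p in problems])
    return extruder, material, op


def save_config(path: str, extruder: Extruder, material_name: str,
                op: OperatingPoint) -> None:
    """Write a scenario config referencing a shipped material by name."""
    doc = {
        "machine": _machine_to_dict(extruder),
        "material": material_name,
        "operating_point": {
            "n_rpm": op.n_rpm, "q_kgh": op.q_kgh, "mc": op.mc,
            "barrel_temps_c": list(op.barrel_temps_c),
            "die_temp_c": op.die_temp_c, "nusselt": op.nusselt,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _machine_to_dict(ex: Extruder) -> dict:
    elements = []
    for e in ex.elements:
        d = {"kind": e.kind, "length_mm": e.length / _MM,
             "channel_depth_mm": e.channel_depth / _MM}
        if e.kind != "kneading_block":
            d["pitch_mm"] = e.pitch / _MM
        else:
            d["stagger_angle_deg"] = e.stagger_angle
            d["disc_thickness_mm"] = e.disc_thickness / _MM
        if e.flight_count != 2:
            d["flight_count"] = e.flight_count
        if e.flight_gap is not None:
            d["flight_gap_mm"] = e.flight_gap / _MM
        if e.flight_width is not None:
            d["flight_width_mm"] = e.flight_width / _MM
        if e.label:
            d["label"] = e.label
        elements.append(d)
    die = []
    for el in ex.die:
        d = {"kind": el.kind, "length_mm": el.length / _MM}
        if el.radius is not None:
            d["radius_mm"] = el.radius / _MM
        if el.width is not None:
            d["width_mm"] = el.width / _MM
        if el.height is not None:
            d["height_mm"] = el.height / _MM
        if el.group is not None:
            d["group"] = el.group
        die.append(d)
    return {"name": ex.name, "screw_diameter_mm": ex.screw_diameter / _MM,
            "total_screw_length_mm": ex.total_screw_length / _MM,
            "barrel_zone_lengths_mm": [z / _MM for z in ex.barrel_zone_lengths],
            "elements": elements, "die": die}


# ---------------------------------------------------------------------------
# Scenario fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioFixture:
    """A named machine/material/operating-point combination with the
    qualitative behaviour it is expected to show and optional quantitative
    anchors (each anchor records its provenance tag in ``anchors``)."""

    name: str
    machine: str
    material: str
    op: OperatingPoint
    expect: dict = field(default_factory=dict)
    anchors: dict = field(default_factory=dict)

    def load(self):
        return load_machine(self.machine), load_material(self.material), self.op


_BARREL_ZSK = (20.0, 40.0, 60.0, 90.0, 90.0, 90.0, 90.0)

SCENARIOS = {
    "cb_breakfast": ScenarioFixture(
        name="cb_breakfast", machine="zsk26_like", material="cb",
        op=OperatingPoint(n_rpm=500, q_kgh=20, mc=0.15,
                          barrel_temps_c=_BARREL_ZSK, die_temp_c=90.0),
        expect={"pressure_support": "restrictive and die-fed only",
                "sme_monotone": True, "melt_hotter_than_barrel": True},
        anchors={"max_temp_c": {"value": 230.0, "tol": 15.0,
                                "provenance": "printed simulation value"},
                 "kneading_step_c": {"range": (5.0, 10.0), "rel_tol": 0.5,
                                     "provenance": "printed profile description"},
                 "reverse_step_c": {"range": (35.0, 60.0), "rel_tol": 0.5,
                                    "provenance": "printed profile description"}},
    ),
    "hb_breakfast": ScenarioFixture(
        name="hb_breakfast", machine="zsk26_like", material="hb",
        op=OperatingPoint(n_rpm=500, q_kgh=20, mc=0.15,
                          barrel_temps_c=_BARREL_ZSK, die_temp_c=90.0),
        expect={"below": "cb_breakfast"},
        anchors={"max_temp_c": {"value": 185.0, "tol": 15.0,
                                "provenance": "printed simulation value"}},
    ),
    "hb_sensitivity": ScenarioFixture(
        name="hb_sensitivity", machine="zsk26_like", material="hb",
        op=OperatingPoint(n_rpm=500, q_kgh=20, mc=0.19,
                          barrel_temps_c=_BARREL_ZSK, die_temp_c=90.0),
        expect={"sme_up_with_n": True, "sme_down_with_q": True,
                "p_up_with_q": True, "eta_down_with_tb": True},
    ),
    "cb_moisture": ScenarioFixture(
        name="cb_moisture", machine="zsk26_like", material="cb",
        op=OperatingPoint(n_rpm=500, q_kgh=20, mc=0.19,
                          barrel_temps_c=_BARREL_ZSK, die_temp_c=90.0),
        expect={"sme_down_with_mc": True},
        anchors={"sme_ratio_mc19_mc23": {"value": 3.0, "rel_tol": 0.2,
                                         "provenance": "printed factor"}},
    ),
    "pea_snack": ScenarioFixture(
        name="pea_snack", machine="zsk26_like", material="pf",
        op=OperatingPoint(n_rpm=500, q_kgh=20, mc=0.21,
                          barrel_temps_c=_BARREL_ZSK, die_temp_c=90.0),
        expect={"melt_hotter_than_barrel": True},
    ),
}


def get_scenario(name: str) -> ScenarioFixture:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ConfigError(
            [f"unknown scenario {name!r}; have {', '.join(sorted(SCENARIOS))}"]
        ) from None


# ---------------------------------------------------------------------------
# Deterministic synthetic-data generators
# ---------------------------------------------------------------------------

def generate_rheometry(params: ViscosityParams, design: dict,
                       noise_cv: float = 0.0, seed: int = 0) -> list:
    """Full-factorial synthetic rheometer dataset.

    ``design`` maps factor names (shear_rate, temperature_c, mc, sme) to
    level lists; viscosities are drawn lognormally around the model truth
    with coefficient of variation ``noise_cv`` (exactly on the model when
    zero).  Pure function of (inputs, seed).
    """
    if noise_cv < 0:
        raise ConfigError(["noise_cv must be >= 0"])
    from .materials import apparent_viscosity
    levels = [np.atleast_1d(np.asarray(design[k], dtype=float))
              for k in ("shear_rate", "temperature_c", "mc", "sme")]
    grids = np.meshgrid(*levels, indexing="ij")
    flat = [g.ravel() for g in grids]
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv ** 2))
    out = []
    for g, t, mc, sme in zip(*flat):
        eta = apparent_viscosity(params, g, t, mc, sme)
        if noise_cv > 0:
            eta *= math.exp(rng.normal(-0.5 * sigma ** 2, sigma))
        out.append(RheometryPoint(shear_rate=float(g), temperature_c=float(t),
                                  mc=float(mc), sme=float(sme), eta=float(eta)))
    return out


def generate_feature_data(model, x_grid, noise_cv: float = 0.0,
                          seed: int = 0) -> pd.DataFrame:
    """Synthetic product-feature dataset around a correlation model.

    Lognormal multiplicative noise (exact at zero noise); deterministic for
    a fixed seed.  Returns a (x, y) frame named after the model.
    """
    if noise_cv < 0:
        raise ConfigError(["noise_cv must be >= 0"])
    x = np.atleast_1d(np.asarray(x_grid, dtype=float))
    y = np.array([model.predict(v, warn=False) for v in x])
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = math.sqrt(math.log1p(noise_cv ** 2))
        y = y * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=y.shape))
    return pd.DataFrame({model.predictor: x, model.feature: y})
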
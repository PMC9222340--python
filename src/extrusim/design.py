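"""Operating charts, feasible regions and product-feature correlations.

The design workflow has three steps: (1) correlate a product feature (starch
depolymerization, protein insolubilization, density, cell density, water
solubility...) with a computed extrusion variable (SME_com, T_com or
eta_com); (2) sweep the operating parameters (N, Q, Tb, MC) into a chart
grid of the computed variables; (3) invert the feature targets into
intervals on the computed variables and intersect them with process
constraints on the grid to obtain the feasible operating window.

Published numeric fit parameters for the feature correlations are not
available; the models in :func:`reconstructed_correlations` are anchored to
the printed chart landmarks and labelled "reconstructed" — they exercise the
full workflow and are meant to be replaced by user fits
(:func:`fit_correlation`) on real measurement tables.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, ConvergenceError, DomainError
from .machine import Extruder
from .materials import Material
from .solver import OperatingPoint, solve_profile

__all__ = [
    "ChartGrid", "CorrelationModel", "DesignTarget", "run_grid",
    "feasible_region", "fit_correlation", "predict_feature",
    "invert_feature", "design", "reconstructed_correlations",
    "power_through_points", "exponential_through_points",
]

logger = logging.getLogger(__name__)

RESPONSES = ("T_com", "SME_com", "P_com", "eta_com")
_AXES = ("n_rpm", "q_kgh", "mc", "last_barrel_temp_c")


# ---------------------------------------------------------------------------
# Correlation models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationModel:
    """A feature = f(computed variable) relationship.

    ``form``: linear  y = a + b*x
              power   y = a * x**b
              exponential  y = a * exp(b*x)
    ``validity`` is the predictor interval covered by the calibration data;
    predictions outside it are flagged.
    """

    feature: str
    predictor: str  # T_com | SME_com | eta_com
    form: str
    a: float
    b: float
    r_squared: float = 1.0
    residual_se: float = 0.0
    n_obs: int = 0
    validity: tuple = (0.0, math.inf)
    provenance: str = "fitted"

    def __post_init__(self):
        if self.form not in ("linear", "power", "exponential"):
            raise ConfigError([f"unknown correlation form {self.form!r}"])
        if self.validity[0] > self.validity[1]:
            raise ConfigError(["validity interval is empty"])

    def predict(self, x: float, warn: bool = True) -> float:
        """Evaluate the fitted functional form at predictor value ``x``."""
        if warn and not (self.validity[0] <= x <= self.validity[1]):
            logger.warning(
                "%s(%s): prediction at %s = %.4g outside validity "
                "[%.4g, %.4g]", self.feature, self.form, self.predictor, x,
                *self.validity)
        if self.form == "linear":
            return self.a + self.b * x
        if self.form == "power":
            if x <= 0:
                raise DomainError("power form requires x > 0")
            return self.a * x ** self.b
        return self.a * math.exp(self.b * x)

    @property
    def monotone_increasing(self) -> bool | None:
        """True/False if strictly monotone on (0, inf), None if flat."""
        if self.b == 0:
            return None
        sign = self.b > 0
        if self.form == "power" and self.a < 0:
            sign = not sign
        if self.form == "exponential" and self.a < 0:
            sign = not sign
        return sign

    def invert(self, y: float) -> float:
        """Closed-form inverse of the (monotone) form."""
        if self.b == 0:
            raise DomainError(f"{self.feature}: constant model is not invertible")
        if self.form == "linear":
            return (y - self.a) / self.b
        if self.form == "power":
            if y / self.a <= 0:
                raise DomainError(f"{self.feature}: {y} not in the power-law range")
            return (y / self.a) ** (1.0 / self.b)
        if y / self.a <= 0:
            raise DomainError(f"{self.feature}: {y} not in the exponential range")
        return math.log(y / self.a) / self.b


def fit_correlation(x, y, form: str, feature: str = "feature",
                    predictor: str = "SME_com") -> CorrelationModel:
    """Least-squares fit of one correlation form.

    Power and exponential forms are log-linearized for a starting point and
    refined by nonlinear least squares on the original scale.  Requires
    n >= 3 and strictly positive x for the power form (y must be positive
    for the log-linearized start of power/exponential fits).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DomainError("need at least 3 points to fit a correlation")
    if form == "power" and np.any(x <= 0):
        raise DomainError("power form requires strictly positive x")
    if form in ("power", "exponential") and np.any(y <= 0):
        raise DomainError(f"{form} form requires strictly positive y")

    if form == "linear":
        b, a = np.polyfit(x, y, 1)
        yhat = a + b * x
    elif form == "power":
        b0, la0 = np.polyfit(np.log(x), np.log(y), 1)
        popt, _ = curve_fit(lambda t, a, b: a * t ** b, x, y,
                            p0=(math.exp(la0), b0), maxfev=10000)
        a, b = popt
        yhat = a * x ** b
    else:
        b0, la0 = np.polyfit(x, np.log(y), 1)
        popt, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                            p0=(math.exp(la0), b0), maxfev=10000)
        a, b = popt
        yhat = a * np.exp(b * x)
    resid = y - yhat
    dof = max(len(x) - 2, 1)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
    return CorrelationModel(
        feature=feature, predictor=predictor, form=form, a=float(a),
        b=float(b), r_squared=r2,
        residual_se=float(np.sqrt(resid @ resid / dof)), n_obs=len(x),
        validity=(float(x.min()), float(x.max())))


def predict_feature(model: CorrelationModel, x: float) -> float:
    """Functional-form evaluation (warns outside the validity interval)."""
    return model.predict(x)


def invert_feature(model: CorrelationModel,
                   interval: tuple) -> tuple:
    """Map a target feature interval to a predictor interval.

    Requires the model to be monotone; the result is clipped to the model's
    validity interval.  Raises :class:`DomainError` when the intersection is
    empty (infeasible target).
    """
    lo, hi = interval
    if lo > hi:
        raise ConfigError([f"{model.feature}: empty target interval {interval}"])
    if model.monotone_increasing is None:
        raise DomainError(
            f"{model.feature}: constant model cannot be inverted")
    v0, v1 = model.validity
    if not (math.isfinite(v0) and math.isfinite(v1)):
        raise DomainError(
            f"{model.feature}: cannot invert over an unbounded validity "
            "interval")
    # image of the validity interval under the monotone form; the target is
    # intersected with it so one-sided targets (e.g. density below a limit)
    # invert cleanly to a validity endpoint
    y0, y1 = model.predict(v0, warn=False), model.predict(v1, warn=False)
    img_lo, img_hi = (y0, y1) if y0 <= y1 else (y1, y0)
    lo_c, hi_c = max(lo, img_lo), min(hi, img_hi)
    if lo_c > hi_c:
        raise DomainError(
            f"{model.feature}: target {interval} lies outside the range "
            f"[{img_lo:.4g}, {img_hi:.4g}] the {model.predictor} correlation "
            f"covers on its validity interval {model.validity}")
    x1, x2 = model.invert(lo_c), model.invert(hi_c)
    if x1 > x2:
        x1, x2 = x2, x1
    return (max(x1, v0), min(x2, v1))


def power_through_points(p1, p2, feature, predictor,
                         provenance="reconstructed") -> CorrelationModel:
    """Power law fixed exactly by two anchor points (x1,y1), (x2,y2)."""
    (x1, y1), (x2, y2) = p1, p2
    b = math.log(y2 / y1) / math.log(x2 / x1)
    a = y1 / x1 ** b
    return CorrelationModel(feature=feature, predictor=predictor,
                            form="power", a=a, b=b, n_obs=2,
                            validity=(min(x1, x2), max(x1, x2)),
                            provenance=provenance)


def exponential_through_points(p1, p2, feature, predictor,
                               provenance="reconstructed") -> CorrelationModel:
    """Exponential fixed exactly by two anchor points."""
    (x1, y1), (x2, y2) = p1, p2
    b = math.log(y2 / y1) / (x2 - x1)
    a = y1 * math.exp(-b * x1)
    return CorrelationModel(feature=feature, predictor=predictor,
                            form="exponential", a=a, b=b, n_obs=2,
                            validity=(min(x1, x2), max(x1, x2)),
                            provenance=provenance)


def reconstructed_correlations() -> dict:
    """Shipped feature-correlation fixtures, anchored to printed chart
    landmarks (all labelled "reconstructed"; replace with your own
    :func:`fit_correlation` results where measurements exist).

    Anchors used:
      * intrinsic-viscosity drop of 47%-amylose maize: power law through
        (SME 625, 45%) and (SME 875, 55%);
      * remnant-granule count / residual molar mass of dense potato starch:
        windows 150-300 granules/mm2 and 40-60% both mapping to
        SME 500-550 kJ/kg;
      * pea-snack density: exponential with the printed 200 kg/m3 onset at
        T_com 155 degC (scaled from 800 kg/m3 at 125 degC);
      * pea-snack insoluble protein: exponential through (155 degC, 5%) and
        (165 degC, 10%);
      * wheat-snack starch solubility: linear with WSI 50% at
        SME 375 kJ/kg;
      * bran-snack cell density: exponential, tenfold over T_com 125->195;
      * bran-snack sectional expansion: mild exponential decrease with T.
    """
    models = {
        "dVis_pct": power_through_points(
            (625.0, 45.0), (875.0, 55.0), "dVis_pct", "SME_com"),
        "Ng_per_mm2": exponential_through_points(
            (500.0, 300.0), (550.0, 150.0), "Ng_per_mm2", "SME_com"),
        "RM_pct": power_through_points(
            (500.0, 60.0), (550.0, 40.0), "RM_pct", "SME_com"),
        "density_kgm3": exponential_through_points(
            (125.0, 800.0), (155.0, 200.0), "density_kgm3", "T_com"),
        "insoluble_protein_pct": exponential_through_points(
            (155.0, 5.0), (165.0, 10.0), "insoluble_protein_pct", "T_com"),
        "WSI_starch_pct": CorrelationModel(
            feature="WSI_starch_pct", predictor="SME_com", form="linear",
            a=50.0 - 0.05 * 375.0, b=0.05, n_obs=2,
            validity=(150.0, 800.0), provenance="reconstructed"),
        "NC_per_cm3": exponential_through_points(
            (125.0, 300.0), (195.0, 3000.0), "NC_per_cm3", "T_com"),
        "SEI": exponential_through_points(
            (125.0, 7.5), (195.0, 3.7), "SEI", "T_com"),
    }
    # widen validity so design windows may extend to the profile edges
    models["density_kgm3"] = replace(models["density_kgm3"],
                                     validity=(110.0, 200.0))
    models["insoluble_protein_pct"] = replace(
        models["insoluble_protein_pct"], validity=(110.0, 200.0))
    return models


# ---------------------------------------------------------------------------
# Chart grids
# ---------------------------------------------------------------------------

@dataclass
class ChartGrid:
    """Cartesian sweep of operating parameters with response surfaces.

    ``axes`` maps axis names (n_rpm, q_kgh, mc, last_barrel_temp_c) to 1D
    value arrays; each response array has the axes' Cartesian shape.
    Unconverged nodes are masked (NaN + ``ok`` False).
    """

    axes: dict
    responses: dict  # name -> ndarray
    ok: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return tuple(len(v) for v in self.axes.values())

    def frame(self) -> pd.DataFrame:
        """Tidy one-row-per-node export."""
        names = list(self.axes)
        grids = np.meshgrid(*[self.axes[n] for n in names], indexing="ij")
        data = {n: g.ravel() for n, g in zip(names, grids)}
        for r, arr in self.responses.items():
            data[r] = arr.ravel()
        data["converged"] = self.ok.ravel()
        return pd.DataFrame(data)


def run_grid(extruder: Extruder, material: Material, op_base: OperatingPoint,
             sweep: dict, n_substeps: int = 4) -> ChartGrid:
    """Solve the profile at every node of a parameter sweep.

    ``sweep`` maps axis names to value lists, e.g.
    ``{"n_rpm": [150, ..., 700], "q_kgh": [10, ..., 50]}``.  Unconverged or
    infeasible nodes are masked and logged, not fatal.
    """
    bad = set(sweep) - set(_AXES)
    if bad:
        raise ConfigError([f"unknown sweep axis(es) {sorted(bad)}; "
                           f"have {_AXES}"])
    names = [a for a in _AXES if a in sweep]
    axes = {n: np.atleast_1d(np.asarray(sweep[n], dtype=float)) for n in names}
    shape = tuple(len(axes[n]) for n in names)
    responses = {r: np.full(shape, np.nan) for r in RESPONSES}
    ok = np.zeros(shape, dtype=bool)
    for idx in itertools.product(*[range(s) for s in shape]):
        kwargs = {n: float(axes[n][i]) for n, i in zip(names, idx)}
        op = op_base.with_(**kwargs)
        try:
            res = solve_profile(extruder, material, op, n_substeps=n_substeps)
        except (ConvergenceError, DomainError) as exc:
            logger.warning("grid node %s masked: %s", kwargs, exc)
            continue
        if not res.converged:
            logger.warning("grid node %s unconverged; masked", kwargs)
            continue
        responses["T_com"][idx] = res.t_com
        responses["SME_com"][idx] = res.sme_com
        responses["P_com"][idx] = res.p_com
        responses["eta_com"][idx] = res.eta_com
        ok[idx] = True
    return ChartGrid(axes=axes, responses=responses, ok=ok,
                     provenance={"machine": extruder.name,
                                 "material": material.name,
                                 "base": op_base.__dict__.copy()})


@dataclass
class FeasibleRegion:
    """Boolean mask over a chart grid plus a per-axis window summary."""

    grid: ChartGrid
    mask: np.ndarray
    constraints: dict
    empty: bool

    def windows(self) -> dict:
        """For each axis: the (min, max) of feasible node coordinates, or
        None when no node is feasible."""
        out = {}
        if self.empty:
            return {n: None for n in self.grid.axes}
        names = list(self.grid.axes)
        grids = np.meshgrid(*[self.grid.axes[n] for n in names], indexing="ij")
        for n, g in zip(names, grids):
            vals = g[self.mask]
            out[n] = (float(vals.min()), float(vals.max()))
        return out

    def report(self) -> str:
        lines = [f"constraints: {self.constraints}"]
        if self.empty:
            lines.append("no feasible window: no grid node satisfies all "
                         "constraints")
        else:
            lines.append(f"feasible nodes: {int(self.mask.sum())} / "
                         f"{self.mask.size}")
            for axis, win in self.windows().items():
                lines.append(f"  {axis}: {win[0]:g} .. {win[1]:g}")
        return "\n".join(lines)


def feasible_region(grid: ChartGrid, targets: dict) -> FeasibleRegion:
    """Nodes satisfying closed-interval constraints on grid responses.

    ``targets`` maps response names to (lo, hi) intervals (use -inf/inf for
    one-sided limits).  An empty region is a legal, explicitly reported
    outcome.
    """
    mask = grid.ok.copy()
    for resp, (lo, hi) in targets.items():
        if resp not in grid.responses:
            raise ConfigError(
                [f"response {resp!r} not on the grid; have "
                 f"{sorted(grid.responses)}"])
        arr = grid.responses[resp]
        with np.errstate(invalid="ignore"):
            mask &= (arr >= lo) & (arr <= hi)
    return FeasibleRegion(grid=grid, mask=mask, constraints=dict(targets),
                          empty=not bool(mask.any()))


# ---------------------------------------------------------------------------
# Full design workflow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignTarget:
    """Feature targets (closed intervals keyed by feature name) plus direct
    process constraints (closed intervals keyed by response name)."""

    features: dict = field(default_factory=dict)
    process: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in {**self.features, **self.process}.items():
            if lo > hi:
                raise ConfigError([f"target {name!r}: empty interval "
                                   f"[{lo}, {hi}]"])


@dataclass
class DesignReport:
    """Outcome of the three-step design workflow."""

    grid: ChartGrid
    region: FeasibleRegion
    predictor_intervals: dict  # response -> (lo, hi) after inversion
    target: DesignTarget

    def summary(self) -> str:
        lines = ["design windows on computed variables:"]
        for resp, (lo, hi) in self.predictor_intervals.items():
            lines.append(f"  {resp}: [{lo:.4g}, {hi:.4g}]")
        lines.append(self.region.report())
        return "\n".join(lines)


def design(extruder: Extruder, material: Material, op_base: OperatingPoint,
           sweep: dict, models: dict, target: DesignTarget,
           n_substeps: int = 4) -> DesignReport:
    """Invert feature targets through their correlation models, intersect
    the resulting predictor intervals (and direct process constraints) and
    extract the feasible operating region from a fresh chart grid."""
    intervals: dict = {}
    for feature, interval in target.features.items():
        if feature not in models:
            raise ConfigError(
                [f"no correlation model for feature {feature!r}; have "
                 f"{sorted(models)}"])
        model = models[feature]
        lo, hi = invert_feature(model, interval)
        prev = intervals.get(model.predictor)
        if prev is None:
            intervals[model.predictor] = (lo, hi)
        else:  # same predictor: intersect
            intervals[model.predictor] = (max(prev[0], lo), min(prev[1], hi))
    for resp, interval in target.process.items():
        prev = intervals.get(resp)
        if prev is None:
            intervals[resp] = interval
        else:
            intervals[resp] = (max(prev[0], interval[0]),
                               min(prev[1], interval[1]))
    infeasible = {r: iv for r, iv in intervals.items() if iv[0] > iv[1]}
    grid = run_grid(extruder, material, op_base, sweep, n_substeps=n_substeps)
    if infeasible:
        region = FeasibleRegion(grid=grid,
                                mask=np.zeros(grid.shape, dtype=bool),
                                constraints=intervals, empty=True)
        return DesignReport(grid=grid, region=region,
                            predictor_intervals=intervals, target=target)
    region = feasible_region(grid, intervals)
    return DesignReport(grid=grid, region=region,
                        predictor_intervals=intervals, target=target)
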
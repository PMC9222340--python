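"""Viscosity model, melting curves, property blending and parameter fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import extrusim as ex
from extrusim.errors import ConfigError, DomainError, RangeError, \
    SingularFitError
from extrusim.fixtures import generate_rheometry
from extrusim.materials import ViscosityParams, convert_to_referenced, \
    fit_viscosity_params


@pytest.fixture(scope="module")
def db():
    return {name: ex.load_material(name) for name in ex.available_materials()}


class TestConsistency:
    def test_reference_state_identity_for_whole_database(self, db):
        """At (T0, MC0, SME0) every exponent term vanishes and K = K0."""
        for name, mat in db.items():
            p = convert_to_referenced(mat.viscosity)
            k = ex.consistency(p, p.t0_ref, p.mc0_ref, p.sme0_ref)
            assert k == pytest.approx(p.k0, rel=1e-12), name

    @pytest.mark.parametrize("material,t_k,mc,sme,expected,rel", [
        ("maize_a", 353.0, 0.10, 350.0, 1.21e7, 1e-12),  # reference state
        ("pf", 433.0, 0.10, 350.0, 8.94e4, 5e-3),  # Arrhenius drop exp(-2.203)
        ("wf", 433.0, 0.22, 400.0, 5.48e3, 5e-3),  # absolute-dialect form
    ])
    def test_hand_evaluated_values(self, db, material, t_k, mc, sme,
                                   expected, rel):
        k = ex.consistency(db[material].viscosity, t_k, mc, sme)
        assert k == pytest.approx(expected, rel=rel)

    def test_rejects_nonphysical_state(self, db):
        p = db["pf"].viscosity
        with pytest.raises(DomainError):
            ex.consistency(p, -10.0, 0.2, 350.0)
        with pytest.raises(DomainError):
            ex.consistency(p, 433.0, 1.2, 350.0)
        with pytest.raises(DomainError):
            ex.consistency(p, 433.0, 0.2, -5.0)

    def test_monotone_decreasing_in_t_mc_sme_across_database(self, db):
        """Hotter, wetter or more sheared melts are always thinner."""
        rng = np.random.default_rng(7)
        for name, mat in db.items():
            p = mat.viscosity
            for _ in range(20):
                t = rng.uniform(380.0, 470.0)
                mc = rng.uniform(0.12, 0.35)
                sme = rng.uniform(50.0, 1500.0)
                k0 = ex.consistency(p, t, mc, sme)
                assert ex.consistency(p, t + 5.0, mc, sme) < k0, name
                assert ex.consistency(p, t, mc + 0.01, sme) < k0, name
                assert ex.consistency(p, t, mc, sme + 50.0) <= k0, name


class TestDialects:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k0=st.floats(1e-3, 1e3), e_r=st.floats(0.0, 12000.0),
           alpha=st.floats(0.0, 35.0), beta=st.floats(0.0, 8e-3),
           t=st.floats(360.0, 470.0), mc=st.floats(0.05, 0.4),
           sme=st.floats(0.0, 2000.0))
    def test_absolute_dialect_converts_exactly(self, k0, e_r, alpha, beta,
                                               t, mc, sme):
        """K0' = K0*exp(E/R/T0 - alpha*MC0 - beta*SME0) reproduces the
        referenced evaluation at every state."""
        p_abs = ViscosityParams(k0=k0, e_over_r=e_r, alpha=alpha, beta=beta,
                                dialect="absolute")
        p_ref = convert_to_referenced(p_abs)
        assert p_ref.dialect == "referenced"
        assert ex.consistency(p_ref, t, mc, sme) == pytest.approx(
            ex.consistency(p_abs, t, mc, sme), rel=1e-9)


class TestFlowIndex:
    def test_pea_flour_index_is_constant(self, db):
        """Only n0 = 0.29 is nonzero for pea flour."""
        p = db["pf"].viscosity
        for t, mc, sme in [(120, 0.18, 200), (165, 0.26, 900), (140, 0.2, 0)]:
            assert ex.flow_index(p, t, mc, sme) == pytest.approx(0.29)

    def test_polynomial_evaluation(self, db):
        # 3.70e-3*150 - 2.55*0.19 + 9.5e-3*150*0.19
        n = ex.flow_index(db["hb"].viscosity, 150.0, 0.19, 350.0)
        assert n == pytest.approx(0.34125, abs=1e-6)

    def test_newtonian_limit(self):
        p = ViscosityParams(k0=100.0, e_over_r=0.0, n0=1.0)
        assert ex.flow_index(p, 120.0, 0.2, 100.0) == 1.0
        assert ex.apparent_viscosity(p, 37.0, 120.0, 0.2, 100.0) == \
            pytest.approx(100.0)

    def test_clamped_outside_physical_band(self, caplog):
        p = ViscosityParams(k0=1.0, e_over_r=0.0, n0=2.5)
        assert ex.flow_index(p, 100.0, 0.2, 100.0) == 1.0
        p = ViscosityParams(k0=1.0, e_over_r=0.0, n0=-0.4)
        assert ex.flow_index(p, 100.0, 0.2, 100.0) == 0.05


class TestApparentViscosity:
    def test_reference_shear_thinning(self, db):
        p = db["pf"].viscosity
        assert ex.apparent_viscosity(p, 1.0, 353.0 - 273.15, 0.10, 350.0) == \
            pytest.approx(8.1e5, rel=1e-9)
        # 8.1e5 * 100**(0.29 - 1)
        assert ex.apparent_viscosity(p, 100.0, 353.0 - 273.15, 0.10, 350.0) \
            == pytest.approx(3.08e4, rel=5e-3)

    def test_decreasing_in_shear_rate_when_shear_thinning(self, db):
        p = db["cb"].viscosity
        etas = [ex.apparent_viscosity(p, g, 170.0, 0.15, 300.0)
                for g in (10.0, 50.0, 250.0)]
        assert etas[0] > etas[1] > etas[2]

    def test_rejects_nonpositive_shear(self, db):
        with pytest.raises(DomainError):
            ex.apparent_viscosity(db["cb"].viscosity, 0.0, 170.0, 0.15, 300.0)


class TestMeltingCurve:
    @pytest.mark.parametrize("name,mc,tm", [("hb", 0.15, 133.0),
                                            ("cb", 0.15, 165.0)])
    def test_anchored_values(self, db, name, mc, tm):
        assert ex.melting_temperature(db[name], mc) == pytest.approx(tm)

    def test_interpolation_identity_on_duplicated_point(self, cb):
        from dataclasses import replace
        dup = replace(cb, melting_curve=((0.2, 120.0), (0.2, 120.0)))
        assert ex.melting_temperature(dup, 0.2) == pytest.approx(120.0)

    def test_extrapolation_refused(self, db):
        with pytest.raises(RangeError):
            ex.melting_temperature(db["cb"], 0.95)

    def test_monotone_decreasing_in_moisture(self, db):
        for mat in db.values():
            mcs = np.linspace(mat.melting_curve[0][0],
                              mat.melting_curve[-1][0], 17)
            tms = [ex.melting_temperature(mat, m) for m in mcs]
            assert all(a >= b for a, b in zip(tms, tms[1:]))


class TestMeltProperties:
    def test_endpoints_and_blend(self, cb):
        from dataclasses import replace
        mat = replace(cb, cp_dry=1500.0, cp_water=4186.0)
        assert ex.melt_property(mat, 0.0, "cp") == 1500.0
        assert ex.melt_property(mat, 1.0, "cp") == 4186.0
        assert ex.melt_property(mat, 0.20, "cp") == pytest.approx(2037.2)

    def test_unknown_property_rejected(self, cb):
        with pytest.raises(ConfigError):
            ex.melt_property(cb, 0.2, "viscoelasticity")


class TestFitting:
    def test_noise_free_recovery_is_exact(self, db):
        """A log-linear model interpolates its own noise-free data."""
        truth = db["pf"].viscosity
        data = generate_rheometry(truth, {
            "shear_rate": [5.0, 20.0, 80.0, 320.0],
            "temperature_c": [110.0, 140.0, 170.0],
            "mc": [0.14, 0.20, 0.26],
            "sme": [100.0, 400.0, 800.0]}, noise_cv=0.0, seed=0)
        fit = fit_viscosity_params(data)
        assert fit.params.k0 == pytest.approx(truth.k0, rel=1e-6)
        assert fit.params.e_over_r == pytest.approx(truth.e_over_r, rel=1e-6)
        assert fit.params.alpha == pytest.approx(truth.alpha, rel=1e-6)
        assert fit.params.n0 == pytest.approx(truth.n0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_recovery_within_ten_percent(self, db):
        """Maize-D coefficients from 200 points at 5% lognormal noise."""
        truth = db["maize_d"].viscosity
        data = generate_rheometry(truth, {
            "shear_rate": [5.0, 15.0, 45.0, 135.0, 400.0],
            "temperature_c": [110.0, 130.0, 150.0, 170.0],
            "mc": [0.14, 0.18, 0.22, 0.26, 0.30],
            "sme": [150.0, 650.0]}, noise_cv=0.05, seed=42)
        assert len(data) == 200
        fit = fit_viscosity_params(data)
        assert fit.params.k0 == pytest.approx(truth.k0, rel=0.10)
        assert fit.params.e_over_r == pytest.approx(truth.e_over_r, rel=0.10)
        assert fit.params.alpha == pytest.approx(truth.alpha, rel=0.10)
        assert fit.params.beta == pytest.approx(truth.beta, rel=0.10)

    def test_two_points_give_exact_power_law(self):
        """At a single (T, MC, SME) state two shear rates pin (K, n)."""
        pts = [ex.RheometryPoint(shear_rate=g, temperature_c=79.85, mc=0.10,
                                 sme=350.0, eta=5000.0 * g ** (0.4 - 1.0))
               for g in (10.0, 1000.0)]
        fit = fit_viscosity_params(pts)
        assert set(fit.terms) == {"log_k0", "n0"}
        assert fit.params.k0 == pytest.approx(5000.0, rel=1e-9)
        assert fit.params.n0 == pytest.approx(0.4, abs=1e-9)

    def test_rank_deficient_design_names_culprits(self):
        # shear rate fixed -> no flow-index information; forcing n-terms in
        # must fail loudly
        pts = [ex.RheometryPoint(shear_rate=50.0, temperature_c=t, mc=0.2,
                                 sme=300.0, eta=1000.0 - t)
               for t in (100.0, 120.0, 140.0)]
        with pytest.raises(SingularFitError) as err:
            fit_viscosity_params(pts, terms=("log_k0", "e_over_r", "n0"))
        assert "n0" in err.value.terms

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(k0=st.floats(1e2, 1e7), e_r=st.floats(1000.0, 12000.0),
           alpha=st.floats(5.0, 30.0), n0=st.floats(0.1, 0.9))
    def test_recovery_property_across_parameter_space(self, k0, e_r, alpha,
                                                      n0):
        truth = ViscosityParams(k0=k0, e_over_r=e_r, alpha=alpha, n0=n0)
        data = generate_rheometry(truth, {
            "shear_rate": [10.0, 100.0], "temperature_c": [120.0, 160.0],
            "mc": [0.15, 0.25], "sme": [350.0]}, noise_cv=0.0, seed=1)
        fit = fit_viscosity_params(data)
        assert fit.params.k0 == pytest.approx(k0, rel=1e-5)
        assert fit.params.e_over_r == pytest.approx(e_r, rel=1e-5)
        assert fit.params.alpha == pytest.approx(alpha, rel=1e-5)


class TestDatabase:
    def test_expected_entries_shipped(self):
        names = set(ex.available_materials())
        assert {"maize_a", "maize_b", "maize_c", "maize_d", "potato_1",
                "cb", "hb", "pf", "wf", "wf_lb", "wf_hb"} <= names

    def test_wheat_entries_use_absolute_dialect(self, db):
        for name in ("wf", "wf_lb", "wf_hb"):
            assert db[name].viscosity.dialect == "absolute"

    def test_alias_lookup(self):
        assert ex.load_material("LB").name == "wf_lb"
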
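"""Operating charts, correlation models and the design workflow."""

import math

import numpy as np
import pytest

import extrusim as ex
from extrusim.design import (CorrelationModel, DesignTarget, FeasibleRegion,
                             exponential_through_points, power_through_points,
                             reconstructed_correlations)
from extrusim.errors import ConfigError, DomainError
from extrusim.fixtures import generate_feature_data


class TestFitCorrelation:
    def test_power_form_exact_on_noise_free_data(self):
        x = np.linspace(1.0, 50.0, 12)
        model = ex.fit_correlation(x, 2.0 * x ** 0.5, "power")
        assert model.a == pytest.approx(2.0, rel=1e-7)
        assert model.b == pytest.approx(0.5, rel=1e-7)
        assert model.r_squared == pytest.approx(1.0)

    def test_exponential_form_exact_on_noise_free_data(self):
        x = np.linspace(100.0, 900.0, 9)
        model = ex.fit_correlation(x, 100.0 * np.exp(-0.004 * x),
                                   "exponential")
        assert model.a == pytest.approx(100.0, rel=1e-7)
        assert model.b == pytest.approx(-0.004, rel=1e-7)

    def test_linear_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        model = ex.fit_correlation(x, 5.0 + 3.0 * x, "linear")
        assert model.a == pytest.approx(5.0)
        assert model.b == pytest.approx(3.0)

    def test_noisy_power_exponent_within_twenty_percent(self):
        """Exponent recovery from 12 points at 10% lognormal noise."""
        truth = power_through_points((625.0, 45.0), (875.0, 55.0),
                                     "dVis_pct", "SME_com")
        x = np.linspace(300.0, 1000.0, 12)
        data = generate_feature_data(truth, x, noise_cv=0.10, seed=11)
        model = ex.fit_correlation(data["SME_com"], data["dVis_pct"],
                                   "power", feature="dVis_pct",
                                   predictor="SME_com")
        assert model.b == pytest.approx(truth.b, rel=0.20)

    def test_requires_three_points_and_positive_x(self):
        with pytest.raises(DomainError):
            ex.fit_correlation([1.0, 2.0], [1.0, 2.0], "linear")
        with pytest.raises(DomainError):
            ex.fit_correlation([-1.0, 1.0, 2.0], [1.0, 2.0, 3.0], "power")


class TestPredictInvert:
    @pytest.mark.parametrize("model", [
        CorrelationModel(feature="f", predictor="SME_com", form="linear",
                         a=3.0, b=2.0, validity=(0.0, 100.0)),
        CorrelationModel(feature="f", predictor="SME_com", form="power",
                         a=0.8, b=0.6, validity=(1.0, 500.0)),
        CorrelationModel(feature="f", predictor="T_com", form="exponential",
                         a=120.0, b=-0.02, validity=(100.0, 200.0)),
    ])
    def test_invert_predict_roundtrip(self, model):
        for x in np.linspace(*model.validity, 7):
            y = model.predict(x)
            assert model.invert(y) == pytest.approx(x, rel=1e-9)

    def test_identity_linear_model(self):
        ident = CorrelationModel(feature="f", predictor="SME_com",
                                 form="linear", a=0.0, b=1.0,
                                 validity=(0.0, 10.0))
        assert ex.predict_feature(ident, 4.2) == 4.2
        assert ex.invert_feature(ident, (2.0, 3.0)) == (2.0, 3.0)

    def test_power_model_at_unit_predictor(self):
        m = CorrelationModel(feature="f", predictor="SME_com", form="power",
                             a=7.7, b=1.3, validity=(0.5, 2.0))
        assert m.predict(1.0) == pytest.approx(7.7)

    def test_decreasing_model_swaps_interval_endpoints(self):
        m = exponential_through_points((100.0, 800.0), (200.0, 100.0),
                                       "density", "T_com")
        lo, hi = ex.invert_feature(m, (200.0, 400.0))
        assert lo < hi
        assert m.predict(lo) == pytest.approx(400.0, rel=1e-9)
        assert m.predict(hi) == pytest.approx(200.0, rel=1e-9)

    def test_out_of_validity_prediction_warns(self, caplog):
        m = CorrelationModel(feature="f", predictor="SME_com", form="linear",
                             a=0.0, b=1.0, validity=(0.0, 10.0))
        import logging
        with caplog.at_level(logging.WARNING, logger="extrusim.design"):
            m.predict(50.0)
        assert "outside validity" in caplog.text

    def test_constant_model_not_invertible(self):
        m = CorrelationModel(feature="f", predictor="SME_com", form="linear",
                             a=5.0, b=0.0, validity=(0.0, 10.0))
        with pytest.raises(DomainError):
            ex.invert_feature(m, (1.0, 2.0))

    def test_target_outside_model_range_is_infeasible(self):
        m = power_through_points((625.0, 45.0), (875.0, 55.0), "dVis_pct",
                                 "SME_com")
        with pytest.raises(DomainError):
            ex.invert_feature(m, (90.0, 95.0))


class TestReconstructedFixtures:
    def test_dvis_inversion_recovers_anchor_interval(self):
        """The 47%-amylose depolymerization target 50 +- 5% maps exactly to
        the anchored SME window [625, 875] kJ/kg."""
        m = reconstructed_correlations()["dVis_pct"]
        lo, hi = ex.invert_feature(m, (45.0, 55.0))
        assert lo == pytest.approx(625.0, rel=1e-9)
        assert hi == pytest.approx(875.0, rel=1e-9)

    def test_dvis_midpoint_prediction(self):
        m = reconstructed_correlations()["dVis_pct"]
        assert m.predict(750.0) == pytest.approx(50.1, abs=0.2)

    def test_pea_snack_window_from_two_constraints(self):
        """Density < 200 kg/m3 pushes T_com above 155 degC; insoluble
        protein < 10% caps it at 165 degC."""
        models = reconstructed_correlations()
        lo_d, hi_d = ex.invert_feature(models["density_kgm3"], (0.0, 200.0))
        lo_p, hi_p = ex.invert_feature(models["insoluble_protein_pct"],
                                       (0.0, 10.0))
        window = (max(lo_d, lo_p), min(hi_d, hi_p))
        assert window[0] == pytest.approx(155.0, abs=1e-6)
        assert window[1] == pytest.approx(165.0, abs=1e-6)

    def test_all_fixtures_are_labelled_reconstructed(self):
        for m in reconstructed_correlations().values():
            assert m.provenance == "reconstructed"

    def test_granule_and_molar_mass_windows_intersect(self):
        models = reconstructed_correlations()
        ng = ex.invert_feature(models["Ng_per_mm2"], (150.0, 300.0))
        rm = ex.invert_feature(models["RM_pct"], (40.0, 60.0))
        lo = max(ng[0], rm[0])
        hi = min(ng[1], rm[1])
        assert (lo, hi) == pytest.approx((500.0, 550.0), abs=1e-6)


def _toy_grid():
    axes = {"n_rpm": np.array([100.0, 200.0, 300.0]),
            "q_kgh": np.array([10.0, 20.0])}
    t = np.array([[150.0, 140.0], [160.0, 150.0], [170.0, 160.0]])
    sme = np.array([[300.0, 200.0], [400.0, 300.0], [500.0, 400.0]])
    return ex.ChartGrid(axes=axes,
                        responses={"T_com": t, "SME_com": sme,
                                   "P_com": np.full((3, 2), 5e6),
                                   "eta_com": np.full((3, 2), 200.0)},
                        ok=np.ones((3, 2), dtype=bool))


class TestFeasibleRegion:
    def test_full_range_constraint_keeps_everything(self):
        grid = _toy_grid()
        region = ex.feasible_region(grid, {"T_com": (-np.inf, np.inf)})
        assert region.mask.all()
        assert not region.empty

    def test_disjoint_constraint_reports_no_window(self):
        grid = _toy_grid()
        region = ex.feasible_region(grid, {"T_com": (500.0, 600.0)})
        assert region.empty
        assert "no feasible window" in region.report()
        assert region.windows() == {"n_rpm": None, "q_kgh": None}

    def test_interval_intersection(self):
        grid = _toy_grid()
        region = ex.feasible_region(grid, {"T_com": (150.0, 165.0),
                                           "SME_com": (350.0, 600.0)})
        windows = region.windows()
        assert windows["n_rpm"] == (200.0, 300.0)

    def test_unknown_response_rejected(self):
        with pytest.raises(ConfigError):
            ex.feasible_region(_toy_grid(), {"bogus": (0.0, 1.0)})


class TestRunGrid:
    def test_single_node_equals_direct_solve(self, zsk26, hb):
        op = ex.get_scenario("hb_sensitivity").op
        grid = ex.run_grid(zsk26, hb, op, {"n_rpm": [500.0]})
        direct = ex.solve_profile(zsk26, hb, op)
        assert grid.responses["SME_com"][0] == pytest.approx(direct.sme_com)
        assert grid.responses["T_com"][0] == pytest.approx(direct.t_com)
        assert grid.ok.all()

    def test_sme_surface_monotone_in_n_and_q(self, zsk26, hb):
        """The operating chart rises with screw speed and falls with feed
        rate at every grid node."""
        op = ex.get_scenario("hb_sensitivity").op
        grid = ex.run_grid(zsk26, hb, op, {"n_rpm": [200.0, 450.0, 700.0],
                                           "q_kgh": [12.0, 30.0, 48.0]})
        sme = grid.responses["SME_com"]
        assert grid.ok.all()
        assert (np.diff(sme, axis=0) > 0).all()  # N rises
        assert (np.diff(sme, axis=1) < 0).all()  # Q rises

    def test_sme_follows_power_law_in_q_over_n(self, zsk26, cb):
        """At fixed moisture the die-exit SME collapses onto a decreasing
        power law of the filling ratio Q/N (R^2 > 0.95)."""
        op = ex.get_scenario("cb_moisture").op
        grid = ex.run_grid(zsk26, cb, op, {"n_rpm": [250.0, 450.0, 650.0],
                                           "q_kgh": [10.0, 22.0, 34.0]})
        frame = grid.frame()
        ratio = frame.q_kgh / frame.n_rpm
        model = ex.fit_correlation(ratio, frame.SME_com, "power")
        assert model.b < 0
        assert model.r_squared > 0.95


class TestDesignWorkflow:
    def test_contradictory_targets_give_empty_region(self, zsk26, pf):
        models = reconstructed_correlations()
        op = ex.get_scenario("pea_snack").op
        target = DesignTarget(features={"density_kgm3": (0.0, 200.0)},
                              process={"T_com": (0.0, 100.0)})
        report = ex.design(zsk26, pf, op, {"n_rpm": [300.0, 500.0]}, models,
                           target)
        assert report.region.empty

    def test_pea_snack_design_window(self, zsk26, pf):
        """Composed density/protein targets produce the 155-165 degC window
        and a nonempty screw-speed band on the chart."""
        models = reconstructed_correlations()
        op = ex.get_scenario("pea_snack").op
        target = DesignTarget(
            features={"density_kgm3": (0.0, 200.0),
                      "insoluble_protein_pct": (0.0, 10.0)})
        report = ex.design(zsk26, pf, op,
                           {"n_rpm": np.linspace(200.0, 700.0, 6)},
                           models, target)
        lo, hi = report.predictor_intervals["T_com"]
        assert lo == pytest.approx(155.0, abs=1e-6)
        assert hi == pytest.approx(165.0, abs=1e-6)
        assert "T_com" in report.summary()
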
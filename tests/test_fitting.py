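"""Rate estimation, equilibrium diagnostics and scenario classification."""

import numpy as np
import pytest

from pevkit import (ConversionRateEstimator, ConversionRates, Scenario,
                    TimeCourse, bootstrap_ci, classify_scenario,
                    diagnose_equilibrium, fit_rates, sse_objective,
                    synth_dual_selection)
from pevkit.fitting import courses_to_xy

from conftest import noiseless_dual_courses


class TestObjective:
    def test_zero_on_self_consistent_data(self, wt_rates):
        courses = noiseless_dual_courses(wt_rates, [0, 5, 10, 20, 40])
        assert sse_objective(wt_rates, courses) < 1e-20

    def test_single_point_hand_value(self):
        # URA origin (y0=1), generation 1, observed 0: predicted 1-Y_A(1)=c_as
        course = TimeCourse("URA", 0, np.array([1.0]), np.array([0.0]))
        val = sse_objective(ConversionRates(0.15, 0.06), [course])
        assert val == pytest.approx(0.06**2, abs=1e-15)

    def test_order_invariance(self, wt_rates):
        courses = noiseless_dual_courses(ConversionRates(0.1, 0.02),
                                         [0, 5, 10, 20])
        assert sse_objective(wt_rates, courses) == pytest.approx(
            sse_objective(wt_rates, courses[::-1]), abs=1e-15)

    def test_empty_input_errors(self, wt_rates):
        with pytest.raises(ValueError):
            sse_objective(wt_rates, [])


class TestFit:
    def test_noiseless_recovery_wt(self, wt_rates):
        courses = noiseless_dual_courses(wt_rates, [0, 5, 10, 15, 20, 30, 40])
        res = fit_rates(courses)
        assert res.rates_hat.c_sa == pytest.approx(0.080, abs=1e-3)
        assert res.rates_hat.c_as == pytest.approx(0.063, abs=1e-3)
        assert res.converged and res.identifiable

    def test_noiseless_recovery_slow_rates(self):
        truth = ConversionRates(0.0044, 0.0006)
        courses = noiseless_dual_courses(truth, [0, 10, 20, 30, 40, 50])
        res = fit_rates(courses)
        assert res.rates_hat.c_sa == pytest.approx(truth.c_sa, rel=0.10)
        assert res.rates_hat.c_as == pytest.approx(truth.c_as, rel=0.10)

    def test_single_generation_errors(self):
        course = TimeCourse("FOA", 0, np.array([10.0, 10.0]),
                            np.array([0.5, 0.52]))
        with pytest.raises(ValueError, match="insufficient time resolution"):
            fit_rates([course])

    def test_single_origin_warns_in_result(self, wt_rates):
        courses = [noiseless_dual_courses(wt_rates, [0, 5, 10, 20, 40])[0]]
        res = fit_rates(courses)
        assert any("selection origin" in w for w in res.warnings)

    def test_sklearn_interface(self, wt_rates):
        X, y = courses_to_xy(
            noiseless_dual_courses(wt_rates, [0, 5, 10, 20, 40]))
        est = ConversionRateEstimator().fit(X, y)
        assert est.c_sa_ == pytest.approx(0.080, abs=1e-3)
        pred = est.predict(X)
        assert np.allclose(pred, y, atol=1e-6)
        params = est.get_params()
        assert params["bounds"] == (1e-5, 0.5)
        est.set_params(grid_size=21)
        assert est.grid_size == 21

    def test_never_beaten_by_exhaustive_grid(self):
        """The fitter's optimum is at least as good as a 50x50 grid scan."""
        truth = ConversionRates(0.0566, 0.0017)
        pair = synth_dual_selection(truth, list(range(0, 21, 2)), 200, seed=8)
        res = fit_rates(pair)
        axis = np.geomspace(1e-5, 0.5, 50)
        grid_min = min(
            sse_objective(ConversionRates(a, b), pair)
            for a in axis for b in axis
        )
        assert res.sse <= grid_min + 1e-12

    def test_plateau_only_data_not_identifiable(self):
        """Equilibrium-only points pin down only the rate ratio."""
        truth = ConversionRates(0.15, 0.06)
        courses = noiseless_dual_courses(truth, [200, 210, 220])
        res = fit_rates(courses)
        assert not res.identifiable
        ratio = res.rates_hat.c_sa / (res.rates_hat.c_sa + res.rates_hat.c_as)
        assert ratio == pytest.approx(0.714286, abs=0.02)

    @pytest.mark.parametrize("truth", [
        ConversionRates(0.08, 0.063),
        ConversionRates(0.0044, 0.0006),
        ConversionRates(0.0566, 0.0017),
    ])
    def test_noisy_recovery_within_20_percent(self, truth):
        """Mean fit over 25 Poisson-noise datasets tracks the generator."""
        gens = list(range(0, 51, 5))
        fits = []
        for s in range(25):
            pair = synth_dual_selection(truth, gens, 200, seed=300 + s)
            fits.append(fit_rates(pair).rates_hat)
        mean_sa = np.mean([r.c_sa for r in fits])
        mean_as = np.mean([r.c_as for r in fits])
        assert mean_sa == pytest.approx(truth.c_sa, rel=0.20)
        assert mean_as == pytest.approx(truth.c_as, rel=0.20)


class TestBootstrap:
    def test_noiseless_intervals_are_degenerate(self, wt_rates):
        courses = noiseless_dual_courses(wt_rates, [0, 5, 10, 15, 20, 30, 40])
        res = bootstrap_ci(courses, B=50, seed=11)
        assert res.ci_c_sa[1] - res.ci_c_sa[0] < 1e-3
        assert res.ci_c_as[1] - res.ci_c_as[0] < 1e-3
        assert res.ci_c_sa[0] <= res.rates_hat.c_sa <= res.ci_c_sa[1]

    def test_determinism(self, wt_rates):
        pair = synth_dual_selection(wt_rates, list(range(0, 41, 5)), 200,
                                    seed=5)
        a = bootstrap_ci(pair, B=40, seed=7)
        b = bootstrap_ci(pair, B=40, seed=7)
        assert a.ci_c_sa == b.ci_c_sa and a.ci_c_as == b.ci_c_as

    def test_small_b_flagged_unstable(self, wt_rates):
        pair = synth_dual_selection(wt_rates, list(range(0, 41, 10)), 200,
                                    seed=5)
        with pytest.warns(UserWarning, match="unstable"):
            res = bootstrap_ci(pair, B=10, seed=3)
        assert not res.ci_stable


class TestDiagnostics:
    @pytest.mark.parametrize("a, b, expected_label, expected_delta", [
        (0.38, 0.41, "at_equilibrium", 0.03),       # wild-type VIIL plating
        (0.93, 0.01, "selection_dependent", 0.92),  # cac1-deletion hysteresis
        (0.5, 0.5, "at_equilibrium", 0.0),
    ])
    def test_dual_selection_diagnostic(self, a, b, expected_label,
                                       expected_delta):
        label, delta = diagnose_equilibrium(a, b)
        assert label == expected_label
        assert delta == pytest.approx(expected_delta, abs=1e-12)
        # symmetric in its inputs
        label_rev, delta_rev = diagnose_equilibrium(b, a)
        assert (label_rev, delta_rev) == (label, delta)

    def test_out_of_range_input(self):
        with pytest.raises(ValueError):
            diagnose_equilibrium(1.3, 0.5)


class TestScenario:
    @pytest.mark.parametrize("ref, test, expected", [
        ((0.080, 0.063), (0.0044, 0.0006), Scenario.GAIN_OF_STABILITY),
        ((0.03, 0.03), (0.15, 0.0001), Scenario.LOSS_OF_SILENCING),
        ((0.03, 0.03), (0.03, 0.15), Scenario.GAIN_OF_SILENCING),
        ((0.03, 0.03), (0.15, 0.15), Scenario.LOSS_OF_STABILITY),
        ((0.08, 0.06), (0.08, 0.06), Scenario.UNCHANGED),
        ((0.08, 0.06), (0.1, 0.05), Scenario.UNCHANGED),
    ])
    def test_rule_table(self, ref, test, expected):
        label = classify_scenario(ConversionRates(*ref),
                                  ConversionRates(*test))
        assert label.label is expected

    def test_zero_reference_rate_gives_infinite_fold(self):
        label = classify_scenario(ConversionRates(0.0, 0.05),
                                  ConversionRates(0.1, 0.05))
        assert label.fold_c_sa == np.inf
        assert label.label is Scenario.LOSS_OF_SILENCING
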
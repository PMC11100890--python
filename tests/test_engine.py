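"""g-computation engine: regimes, baseline resampling, simulation semantics,
Monte Carlo behaviour and the natural-course diagnostic."""

import numpy as np
import pandas as pd
import pytest

import pegf
from pegf.engine import RegimeError

from conftest import tiny_two_var_panel


class TestRegimeConstruction:
    def test_never_sets_all_components_to_zero(self, school_specs):
        reg = pegf.never(school_specs)
        for comp in ("component_audit", "component_feedback",
                     "component_teacher", "component_mti"):
            assert reg.assignment(comp) == (0.0,) * 4

    def test_always_all_sets_all_components_to_one(self, school_specs):
        reg = pegf.always_all(school_specs)
        for comp in reg.components:
            assert reg.assignment(comp) == (1.0,) * 4

    def test_only_teacher_isolates_one_component(self, school_specs):
        reg = pegf.only("component_teacher", school_specs)
        assert reg.assignment("component_teacher") == (1.0,) * 4
        for comp in ("component_audit", "component_feedback", "component_mti"):
            assert reg.assignment(comp) == (0.0,) * 4

    def test_decreasing_absorbing_path_rejected(self, school_specs):
        asg = {s.name: 0 for s in school_specs if s.role == "treatment"}
        asg["component_audit"] = (1, 0, 0, 0)
        with pytest.raises(RegimeError, match="decreasing"):
            pegf.build_regime("bad", asg, school_specs)

    def test_yearly_component_may_toggle(self, school_specs):
        asg = {s.name: 0 for s in school_specs if s.role == "treatment"}
        asg["component_mti"] = (1, 0, 1, 0)
        reg = pegf.build_regime("toggle", asg, school_specs)
        assert reg.assignment("component_mti") == (1.0, 0.0, 1.0, 0.0)

    def test_missing_component_rejected(self, school_specs):
        with pytest.raises(RegimeError, match="missing assignments"):
            pegf.build_regime("partial", {"component_audit": 1}, school_specs)


class TestBaselineSampling:
    def test_single_unit_resampling_copies_baseline(self):
        panel = tiny_two_var_panel(n=1, T=1)
        base = pegf.draw_baseline_sample(panel, 7, np.random.default_rng(0))
        assert all(len(v) == 7 for v in base.values())
        assert np.ptp(base["y"]) == 0.0

    def test_multinomial_frequencies(self, small_panel):
        """Each school's resampling frequency is within 3 binomial SEs of
        n_mc / n_units."""
        n_mc = 20_000
        rng = np.random.default_rng(3)
        base = pegf.draw_baseline_sample(small_panel, n_mc, rng)
        # recover which source unit each draw came from via a unique column
        w = small_panel.wide()["enrollment"][:, 0]
        counts = pd.Series(base["enrollment"]).value_counts()
        p = 1.0 / small_panel.n_units
        se = np.sqrt(n_mc * p * (1 - p))
        assert abs(counts.mean() - n_mc * p) < 3 * se

    def test_same_seed_identical_sample(self, small_panel):
        b1 = pegf.draw_baseline_sample(small_panel, 100, np.random.default_rng(9))
        b2 = pegf.draw_baseline_sample(small_panel, 100, np.random.default_rng(9))
        for k in b1:
            np.testing.assert_array_equal(b1[k], b2[k])

    def test_nonpositive_n_mc_rejected(self, small_panel):
        with pytest.raises(ValueError):
            pegf.draw_baseline_sample(small_panel, 0, np.random.default_rng(0))


class TestSimulation:
    def test_never_regime_zeroes_components_and_mediators(self, small_panel):
        fitted = pegf.fit_models(small_panel)
        base = pegf.draw_baseline_sample(small_panel, 500,
                                         np.random.default_rng(0))
        sim = pegf.simulate_histories(fitted, base,
                                      pegf.never(small_panel.specs),
                                      small_panel.specs,
                                      np.random.default_rng(1))
        w = sim.wide()
        for comp in ("component_audit", "component_feedback",
                     "component_teacher", "component_mti"):
            assert np.all(w[comp][:, 1:] == 0.0)
        assert np.all(w["audit_conditions_met"][:, 1:] == 0.0)
        assert np.all(w["coaching_interactions"][:, 1:] == 0.0)

    def test_simulated_panel_passes_validation(self, small_panel):
        fitted = pegf.fit_models(small_panel)
        base = pegf.draw_baseline_sample(small_panel, 400,
                                         np.random.default_rng(2))
        for regime in (pegf.natural_regime(small_panel.specs),
                       pegf.always_all(small_panel.specs)):
            sim = pegf.simulate_histories(fitted, base, regime,
                                          small_panel.specs,
                                          np.random.default_rng(3))
            assert pegf.validate_panel(sim).clean

    def test_constant_outcome_model_gives_equal_regimes(self):
        """Residual-SD-0, intercept-only outcome: the simulated outcome is
        constant and identical across regimes."""
        panel = tiny_two_var_panel(n=20, T=2, y_values=0.5)
        fitted = pegf.fit_models(panel)
        base = pegf.draw_baseline_sample(panel, 50, np.random.default_rng(0))
        reg_a = pegf.build_regime("a", {}, panel.specs, T=2)  # no treatments
        sim = pegf.simulate_histories(fitted, base, reg_a, panel.specs,
                                      np.random.default_rng(1))
        assert np.all(sim.wide()["y"] == 0.5)


class TestRunGFormula:
    def test_rerun_is_identical(self, small_panel):
        reg = pegf.never(small_panel.specs)
        r1 = pegf.run_gformula(small_panel, None, reg, n_mc=800, seed=4)
        r2 = pegf.run_gformula(small_panel, None, reg, n_mc=800, seed=4)
        np.testing.assert_array_equal(r1.means, r2.means)
        np.testing.assert_array_equal(r1.mc_se, r2.mc_se)

    def test_means_are_proportions(self, small_panel):
        res = pegf.run_gformula(small_panel, None,
                                pegf.always_all(small_panel.specs),
                                n_mc=800, seed=0)
        assert np.all((res.means >= 0) & (res.means <= 1))
        assert np.all(res.mc_se >= 0)

    def test_mc_se_halves_when_n_mc_quadruples(self, small_panel):
        reg = pegf.natural_regime(small_panel.specs)
        fitted = pegf.fit_models(small_panel)
        r1 = pegf.run_gformula(small_panel, None, reg, n_mc=4_000, seed=1,
                               fitted=fitted)
        r2 = pegf.run_gformula(small_panel, None, reg, n_mc=16_000, seed=2,
                               fitted=fitted)
        ratio = r1.mc_se[-1] / r2.mc_se[-1]
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_natural_equals_all_natural_assignment(self, small_panel):
        """The convenience natural regime is definitionally the regime that
        assigns 'natural' to every component."""
        specs = small_panel.specs
        explicit = pegf.build_regime(
            "natural", {s.name: "natural" for s in specs
                        if s.role == "treatment"}, specs)
        r1 = pegf.run_gformula(small_panel, None,
                               pegf.natural_regime(specs), n_mc=600, seed=7)
        r2 = pegf.run_gformula(small_panel, None, explicit, n_mc=600, seed=7)
        np.testing.assert_array_equal(r1.means, r2.means)


class TestNaturalCourse:
    def test_self_consistency_on_well_specified_data(self, small_panel):
        """On data generated from the model family the engine fits, the
        simulated natural course tracks the observed means within combined
        Monte Carlo + sampling error at every wave."""
        nc = pegf.natural_course_check(small_panel, seed=3)
        gap = nc["difference"].abs()
        tol = 3 * (nc["mc_se"] + nc["sampling_se"])
        assert (gap < tol).all()

    def test_unit_relabeling_leaves_fit_invariant(self, small_panel):
        relabeled = small_panel.df.copy()
        relabeled["unit_id"] = relabeled["unit_id"].map(
            lambda u: f"z{(u * 37) % small_panel.n_units:04d}")
        panel2 = pegf.SchoolPanel(relabeled, small_panel.specs)
        f1 = pegf.fit_models(small_panel)
        f2 = pegf.fit_models(panel2)
        for name in f1.models:
            if f1[name].coef is not None:
                np.testing.assert_allclose(f1[name].coef, f2[name].coef,
                                           atol=1e-8)

    def test_relabeling_shifts_natural_course_only_by_mc_noise(self, small_panel):
        relabeled = small_panel.df.copy()
        relabeled["unit_id"] = relabeled["unit_id"].map(
            lambda u: f"z{(u * 37) % small_panel.n_units:04d}")
        panel2 = pegf.SchoolPanel(relabeled, small_panel.specs)
        nc1 = pegf.natural_course_check(small_panel, n_mc=6_000, seed=3)
        nc2 = pegf.natural_course_check(panel2, n_mc=6_000, seed=3)
        gap = (nc1["simulated_mean"] - nc2["simulated_mean"]).abs()
        tol = 3 * (nc1["mc_se"] + nc2["mc_se"])
        assert (gap < tol).all()
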
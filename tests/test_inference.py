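"""Contrasts, cluster bootstrap, effect modification and the full driver."""

import logging

import numpy as np
import pandas as pd
import pytest

import pegf
from pegf.inference import ProvenanceError

from conftest import tiny_two_var_panel


@pytest.fixture(scope="module")
def frag_pair(small_panel):
    """Paired stratified bootstrap fragments (female/male) on one panel."""
    frags = {}
    for label in ("female", "male"):
        specs = pegf.school_specs(outcome=f"outcome_prop_{label}")
        regs = [pegf.never(specs), pegf.always_all(specs)]
        frags[label] = pegf.bootstrap_analysis(
            small_panel, specs, regs, [("never", "always_all")],
            n_boot=60, seed=5, stratum=label)
    return frags


@pytest.fixture(scope="module")
def results(small_panel):
    specs = small_panel.specs
    fitted = pegf.fit_models(small_panel)
    return {name: pegf.run_gformula(small_panel, specs, reg, n_mc=1000,
                                    seed=1, fitted=fitted)
            for name, reg in [("never", pegf.never(specs)),
                              ("natural", pegf.natural_regime(specs)),
                              ("always", pegf.always_all(specs))]}


class TestContrasts:
    def test_self_contrast_is_zero(self, results):
        assert pegf.contrast_regimes(results["never"], results["never"]) == 0.0

    def test_antisymmetry(self, results):
        ab = pegf.contrast_regimes(results["never"], results["always"])
        ba = pegf.contrast_regimes(results["always"], results["never"])
        assert ab == pytest.approx(-ba)

    def test_telescoping(self, results):
        ab = pegf.contrast_regimes(results["never"], results["natural"])
        bc = pegf.contrast_regimes(results["natural"], results["always"])
        ac = pegf.contrast_regimes(results["never"], results["always"])
        assert ac == pytest.approx(ab + bc)

    def test_reported_in_percentage_points(self, results):
        diff_prop = results["always"].means[-1] - results["never"].means[-1]
        assert pegf.contrast_regimes(results["never"], results["always"]) == \
            pytest.approx(diff_prop * 100)

    def test_provenance_mismatch_rejected(self, small_panel, results):
        other_fit = pegf.fit_models(
            pegf.generate_panel(pegf.SyntheticConfig(n_units=50, n_pilot=5),
                                seed=99))
        alien = pegf.run_gformula(small_panel, None,
                                  pegf.never(small_panel.specs),
                                  n_mc=200, seed=0, fitted=other_fit)
        with pytest.raises(ProvenanceError):
            pegf.contrast_regimes(results["never"], alien)


class TestBootstrap:
    def test_replicate_count_and_ci_are_order_statistics(self, small_panel):
        frag = pegf.bootstrap_analysis(
            small_panel, None, None, None, n_boot=25, seed=2)
        vals = frag.replicate_contrasts[("never", "always_all")]
        assert len(vals) == 25
        lo, hi = frag.contrast_cis[("never", "always_all")]
        np.testing.assert_allclose([lo, hi], np.percentile(vals, [2.5, 97.5]))

    def test_zero_variance_data_gives_zero_width_ci(self):
        """Identical units with deterministic models: every replicate is the
        same analysis, so the percentile CI has width 0."""
        base = tiny_two_var_panel(n=1, T=2, y_values=0.5)
        df = pd.concat([base.df.assign(unit_id=i) for i in range(20)],
                       ignore_index=True)
        panel = pegf.SchoolPanel(df, base.specs)
        reg = pegf.build_regime("noop", {}, panel.specs, T=2)
        frag = pegf.bootstrap_analysis(panel, None, [reg], [], n_boot=10, seed=0)
        lo, hi = frag.mean_cis["noop"]
        assert lo == hi == 0.5

    def test_small_n_boot_flagged_unstable(self, small_panel, caplog):
        with caplog.at_level(logging.WARNING, logger="pegf.inference"):
            frag = pegf.bootstrap_analysis(small_panel, None, None, None,
                                           n_boot=2, seed=0)
        assert frag.unstable
        assert any("unstable" in r.message for r in caplog.records)

    def test_n_boot_below_two_rejected(self, small_panel):
        with pytest.raises(ValueError):
            pegf.bootstrap_analysis(small_panel, None, None, None, n_boot=1)

    def test_point_estimate_comes_from_original_panel(self, small_panel):
        """The reported point estimate must match an independent run on the
        unresampled panel with the same seed."""
        frag = pegf.bootstrap_analysis(small_panel, None, None, None,
                                       n_boot=5, seed=9)
        direct = pegf.run_gformula(small_panel, None,
                                   pegf.never(small_panel.specs), seed=9)
        np.testing.assert_allclose(frag.point["never"].means, direct.means)


class TestEffectModification:
    def test_identical_strata_give_p_one(self, small_panel):
        """Duplicating one outcome column into two strata: every replicate
        difference is 0, so the degenerate-SD convention returns p = 1."""
        frags = {}
        for label in ("s1", "s2"):
            specs = pegf.school_specs(outcome="outcome_prop")
            regs = [pegf.never(specs), pegf.always_all(specs)]
            frags[label] = pegf.bootstrap_analysis(
                small_panel, specs, regs, [("never", "always_all")],
                n_boot=10, seed=3, stratum=label)
        p = pegf.effect_modification_test(frags["s1"], frags["s2"],
                                          ("never", "always_all"))
        assert p == 1.0

    def test_symmetry(self, frag_pair):
        c = ("never", "always_all")
        p_ab = pegf.effect_modification_test(frag_pair["female"],
                                             frag_pair["male"], c)
        p_ba = pegf.effect_modification_test(frag_pair["male"],
                                             frag_pair["female"], c)
        assert p_ab == pytest.approx(p_ba)
        assert 0.0 <= p_ab <= 1.0

    def test_unpaired_fragments_rejected(self, small_panel, frag_pair):
        specs = pegf.school_specs(outcome="outcome_prop_male")
        regs = [pegf.never(specs), pegf.always_all(specs)]
        other = pegf.bootstrap_analysis(
            small_panel, specs, regs, [("never", "always_all")],
            n_boot=60, seed=6, stratum="male")  # different seed -> unpaired
        with pytest.raises(ValueError, match="not paired"):
            pegf.effect_modification_test(frag_pair["female"], other,
                                          ("never", "always_all"))

    def test_detects_large_stratum_effect_difference(self):
        """One stratum carries the full component effect, the other none:
        the paired test should reject at the 5% level in nearly all runs."""
        cfg = pegf.SyntheticConfig(
            n_units=300, n_pilot=30,
            strata=(("hi", 0.0, 1.0), ("lo", 0.0, 0.0)))
        hits = 0
        n_rep = 6
        for rep in range(n_rep):
            panel = pegf.generate_panel(cfg, seed=400 + rep)
            frags = {}
            for label in ("hi", "lo"):
                specs = pegf.school_specs(outcome=f"outcome_prop_{label}")
                regs = [pegf.never(specs), pegf.always_all(specs)]
                frags[label] = pegf.bootstrap_analysis(
                    panel, specs, regs, [("never", "always_all")],
                    n_boot=60, seed=rep, stratum=label)
            p = pegf.effect_modification_test(frags["hi"], frags["lo"],
                                              ("never", "always_all"))
            hits += p < 0.05
        assert hits >= n_rep - 1


@pytest.fixture(scope="module")
def report(small_panel):
    config = dict(
        panel=small_panel,
        strata={"all": "outcome_prop", "female": "outcome_prop_female",
                "male": "outcome_prop_male"},
        options={"n_boot": 20, "seed": 8})
    return config, pegf.run_full_analysis(config)


class TestFullAnalysis:
    def test_schema_covers_all_regimes_and_strata(self, report):
        _, rep = report
        assert len(rep.means) == 8 * 3  # 8 regimes x (all + 2 strata)
        assert set(rep.means.stratum) == {"all", "female", "male"}
        assert {"ci_lower_pct", "ci_upper_pct"} <= set(rep.means.columns)
        assert (rep.contrasts.ci_lower_pp <= rep.contrasts.ci_upper_pp).all()
        # effect modification only between non-overall strata
        assert set(zip(rep.effect_modification.stratum_a,
                       rep.effect_modification.stratum_b)) == {("female", "male")}

    def test_rerun_with_same_seed_is_byte_identical(self, report):
        config, rep = report
        rep2 = pegf.run_full_analysis(config)
        assert rep.to_text() == rep2.to_text()

    def test_provenance_recorded(self, report):
        _, rep = report
        assert rep.provenance["n_boot"] == 20
        assert rep.provenance["seed"] == 8
        assert "config_hash" in rep.provenance

    def test_custom_variable_and_regime_blocks(self, small_panel):
        """The driver accepts declarative variable blocks and ad-hoc regime
        assignments (here: a phased path turning everything on at wave 3)."""
        variables = [
            dict(name=s.name, role=s.role, family=s.family,
                 predictors=[list(p) for p in s.predictors],
                 sim_order=s.sim_order, zero_when=list(s.zero_when),
                 bounds=list(s.bounds) if s.bounds else None,
                 levels=list(s.levels) if s.levels else None)
            for s in pegf.school_specs()
        ]
        phased = {"name": "phase_in",
                  "assignments": {"component_audit": [0, 0, 1, 1],
                                  "component_feedback": [0, 0, 1, 1],
                                  "component_teacher": [0, 0, 1, 1],
                                  "component_mti": [0, 0, 1, 1]}}
        config = dict(panel=small_panel, variables=variables,
                      regimes=["never", phased, "always_all"],
                      contrasts=[("never", "phase_in"),
                                 ("never", "always_all")],
                      options={"n_boot": 5, "seed": 2})
        rep = pegf.run_full_analysis(config)
        assert set(rep.means.regime) == {"never", "phase_in", "always_all"}
        row = rep.contrasts.set_index("comparison")
        # phasing in late yields less than sustained full implementation
        assert row.loc["phase_in", "difference_pp"] < \
            row.loc["always_all", "difference_pp"]

    def test_estimator_consistency_bias_shrinks_with_n(self):
        """Always-vs-never point estimates concentrate on the truth as the
        school count grows (no bootstrap; point estimates only)."""
        specs = pegf.school_specs()
        nev, alw = pegf.never(specs), pegf.always_all(specs)
        errs = {}
        for n in (150, 600):
            cfg = pegf.SyntheticConfig(n_units=n, n_pilot=max(5, n // 12))
            truth = (pegf.true_regime_mean(cfg, alw, 40_000, seed=900)
                     - pegf.true_regime_mean(cfg, nev, 40_000, seed=900)) * 100
            e = []
            for rep in range(40):
                panel = pegf.generate_panel(cfg, seed=1000 + rep)
                fitted = pegf.fit_models(panel)
                rn = pegf.run_gformula(panel, specs, nev, seed=rep, fitted=fitted)
                ra = pegf.run_gformula(panel, specs, alw, seed=rep, fitted=fitted)
                e.append(pegf.contrast_regimes(rn, ra) - truth)
            errs[n] = np.abs(e).mean()
        assert errs[600] < errs[150]
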
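"""Regime contrasts, percentile-bootstrap inference and stratified analyses.

Point estimates come from the original panel; confidence intervals are
empirical 2.5th/97.5th percentiles over cluster-bootstrap replicates that
resample whole school histories, refit every sequential model, and re-run the
Monte Carlo standardization for every regime.  Stratified analyses swap the
outcome column and share the per-replicate resampled unit sets, which makes
the paired effect-modification test well defined.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import engine
from .engine import (InterventionRegime, RegimeResult, always_all,
                     build_regime, combined, natural_regime, never, only,
                     run_gformula, substream)
from .models import DesignCache, FitError
from .panel import SchoolPanel, school_specs

log = logging.getLogger(__name__)

FINAL = -1  # wave index of the headline estimand


class ProvenanceError(ValueError):
    """Contrasted results do not share fitted-model provenance."""


@dataclass(frozen=True)
class ContrastEstimate:
    reference: str
    comparison: str
    wave: int
    difference_pp: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_boot: int = 0
    seed: int = 0


def contrast_regimes(a: RegimeResult, b: RegimeResult, wave: int = FINAL) -> float:
    """Percentage-point difference ``mean_b - mean_a`` at a wave.

    Both results must come from the same fitted-model set (same Step-1 fit on
    the same data); antisymmetric and telescoping by construction.
    """
    if a.provenance != b.provenance:
        raise ProvenanceError(
            f"results {a.regime!r} and {b.regime!r} have different fitted-model "
            "provenance")
    if len(a.means) != len(b.means):
        raise ProvenanceError("results have different wave grids")
    return float((b.means[wave] - a.means[wave]) * 100.0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapFragment:
    """Point estimates plus the full replicate table for one stratum."""
    stratum: str
    point: dict                      # regime name -> RegimeResult
    point_contrasts: dict            # (ref, comp) -> pp difference
    replicate_ids: np.ndarray        # indices of retained replicates
    replicate_means: dict            # regime -> array of wave-T means (proportion)
    replicate_contrasts: dict        # (ref, comp) -> array of pp differences
    mean_cis: dict                   # regime -> (lo, hi) proportion scale
    contrast_cis: dict               # (ref, comp) -> (lo, hi) pp scale
    n_boot: int
    n_dropped: int
    seed: int
    unstable: bool = False


def _percentile_ci(values: np.ndarray) -> tuple:
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def bootstrap_analysis(panel: SchoolPanel, specs=None, regimes=None,
                       contrasts=None, *, n_boot: int = 500,
                       n_mc: int | None = None, n_mc_boot: int | None = None,
                       seed: int = 0, stratum: str = "all") -> BootstrapFragment:
    """Nonparametric cluster bootstrap of all regimes and contrasts.

    Each replicate resamples schools (entire histories) with replacement,
    refits the full model set and re-simulates every regime; the per-replicate
    resampled unit sets depend only on ``seed`` and the replicate index, so
    stratified runs with the same seed are paired.  ``n_mc_boot`` (default 4x
    the school count) controls the within-replicate Monte Carlo sample; the
    point estimate uses ``n_mc`` (default 10x).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if n_boot < 50:
        log.warning("bootstrap_analysis: n_boot=%d is small; CIs flagged unstable",
                    n_boot)
    specs = panel.specs if specs is None else specs
    T = panel.T
    regimes = regimes if regimes is not None else [
        natural_regime(specs, T), never(specs, T), always_all(specs, T)]
    contrasts = contrasts if contrasts is not None else [
        ("never", "always_all")]
    n = panel.n_units
    n_mc = n_mc or 10 * n
    n_mc_boot = n_mc_boot or 4 * n
    outcome = next(s.name for s in specs if s.role == "outcome")

    cache = DesignCache(panel, specs)
    fitted = cache.fit()
    point = {reg.name: run_gformula(panel, specs, reg, n_mc=n_mc, seed=seed,
                                    fitted=fitted)
             for reg in regimes}
    point_contrasts = {(a, b): contrast_regimes(point[a], point[b])
                       for a, b in contrasts}

    base = panel.baseline(specs)
    kept, dropped = [], 0
    rep_means = {reg.name: [] for reg in regimes}
    for r in range(n_boot):
        idx = substream(seed, "units", r).integers(0, n, size=n)
        try:
            fit_r = cache.fit(idx)
        except FitError:
            dropped += 1
            continue
        for reg in regimes:
            rng = substream(seed, "mc", r, reg.name)
            sub = idx[rng.integers(0, n, size=n_mc_boot)]
            baseline = {k: v[sub] for k, v in base.items()}
            wide = engine._simulate_wide(fit_r, baseline, reg, specs, rng)
            rep_means[reg.name].append(float(wide[outcome][:, -1].mean()))
        kept.append(r)
    if dropped > 0.1 * n_boot:
        raise FitError(f"{dropped}/{n_boot} bootstrap replicates failed to fit")
    if dropped:
        log.info("bootstrap_analysis: dropped %d replicate(s)", dropped)

    rep_means = {k: np.asarray(v) for k, v in rep_means.items()}
    rep_contrasts = {(a, b): (rep_means[b] - rep_means[a]) * 100.0
                     for a, b in contrasts}
    return BootstrapFragment(
        stratum=stratum, point=point, point_contrasts=point_contrasts,
        replicate_ids=np.asarray(kept),
        replicate_means=rep_means, replicate_contrasts=rep_contrasts,
        mean_cis={k: _percentile_ci(v) for k, v in rep_means.items()},
        contrast_cis={k: _percentile_ci(v) for k, v in rep_contrasts.items()},
        n_boot=n_boot, n_dropped=dropped, seed=seed, unstable=n_boot < 50)


def effect_modification_test(frag_a: BootstrapFragment,
                             frag_b: BootstrapFragment,
                             contrast: tuple) -> float:
    """Two-sided p-value for equal contrasts in two strata.

    Uses the paired bootstrap: the point difference of the stratum contrasts
    divided by the bootstrap SD of the per-replicate paired difference,
    referred to a standard normal.  Requires both fragments to share the
    replicate pairing (same seed and replicate count).
    """
    if frag_a.seed != frag_b.seed or frag_a.n_boot != frag_b.n_boot:
        raise ValueError("fragments are not paired (different seed or n_boot)")
    common, ia, ib = np.intersect1d(frag_a.replicate_ids, frag_b.replicate_ids,
                                    return_indices=True)
    if len(common) < 2:
        raise ValueError("fewer than 2 shared replicates")
    d_point = frag_a.point_contrasts[contrast] - frag_b.point_contrasts[contrast]
    d_rep = (frag_a.replicate_contrasts[contrast][ia]
             - frag_b.replicate_contrasts[contrast][ib])
    sd = float(np.std(d_rep, ddof=1))
    if sd == 0.0:
        return 1.0 if d_point == 0.0 else 0.0
    return float(2.0 * stats.norm.sf(abs(d_point) / sd))


# ---------------------------------------------------------------------------
# full analysis driver
# ---------------------------------------------------------------------------

DEFAULT_REGIME_NAMES = ("natural", "never", "always_all", "only_teacher",
                        "only_mti", "only_audit", "only_feedback",
                        "audit+feedback")


def default_regimes(specs, T: int = 4) -> list[InterventionRegime]:
    """The regime battery covering every standard comparison.

    Natural course, never, always-all and one single-component regime per
    treatment; for the school component set, additionally the audit+feedback
    combination.
    """
    regs = [natural_regime(specs, T), never(specs, T), always_all(specs, T)]
    treatments = [s.name for s in specs if s.role == "treatment"]
    regs += [only(c, specs, T) for c in treatments]
    if {"component_audit", "component_feedback"} <= set(treatments):
        regs.append(combined(["component_audit", "component_feedback"],
                             specs, T))
    return regs


@dataclass
class AnalysisReport:
    """Stratified regime means, contrasts, effect-modification p-values."""
    means: pd.DataFrame
    contrasts: pd.DataFrame
    effect_modification: pd.DataFrame
    fragments: dict
    provenance: dict = field(default_factory=dict)

    def to_text(self) -> str:
        """Deterministic report body (timestamps excluded by construction)."""
        parts = [
            "# regime means (percent)", self.means.to_csv(index=False),
            "# contrasts (percentage points)", self.contrasts.to_csv(index=False),
            "# effect modification", self.effect_modification.to_csv(index=False),
            "# provenance", json.dumps(self.provenance, sort_keys=True),
        ]
        return "\n".join(parts)

    def replicate_table(self) -> pd.DataFrame:
        rows = []
        for stratum, frag in self.fragments.items():
            for reg, vals in frag.replicate_means.items():
                for rid, v in zip(frag.replicate_ids, vals):
                    rows.append((stratum, reg, int(rid), v))
        return pd.DataFrame(rows, columns=["stratum", "regime", "replicate", "mean"])

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.means.to_csv(out / "means.csv", index=False)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        self.effect_modification.to_csv(out / "effect_modification.csv", index=False)
        self.replicate_table().to_csv(out / "replicates.csv", index=False,
                                      float_format="%.6f")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, sort_keys=True, indent=2))


def _config_hash(config: dict) -> str:
    def default(o):
        return repr(o)
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=default).encode()
    ).hexdigest()[:16]


def run_full_analysis(config: dict) -> AnalysisReport:
    """Run the full stratified bootstrap analysis described by ``config``.

    Config keys: ``panel`` (a SchoolPanel or CSV path), ``variables``
    (optional list of variable blocks, see
    :func:`pegf.panel.specs_from_config`; default: the school variable set),
    ``strata`` (mapping label -> outcome column), ``regimes`` (names from
    the default battery, or blocks ``{"name": ..., "assignments":
    {component: 0 | 1 | path | "natural"}}``), ``contrasts`` (pairs of
    regime names) and ``options`` (n_boot, n_mc, n_mc_boot, seed).
    """
    from .panel import specs_from_config, with_outcome_column

    options = dict(config.get("options", {}))
    seed = int(options.get("seed", 0))
    n_boot = int(options.get("n_boot", 500))

    if "variables" in config:
        base_specs = specs_from_config(config["variables"])
    else:
        base_specs = school_specs()
    base_outcome = next(s.name for s in base_specs if s.role == "outcome")
    strata = dict(config.get("strata", {"all": base_outcome}))

    panel = config["panel"]
    if not isinstance(panel, SchoolPanel):
        from .panel import read_panel
        panel = read_panel(panel, base_specs)
    T = panel.T

    wanted_raw = config.get("regimes", DEFAULT_REGIME_NAMES)
    wanted = tuple(item if isinstance(item, str) else item["name"]
                   for item in wanted_raw)
    contrast_pairs = [tuple(c) for c in config.get(
        "contrasts", [("never", name) for name in wanted if name != "never"])]

    fragments = {}
    for label, outcome_col in strata.items():
        specs = with_outcome_column(base_specs, outcome_col)
        battery = {r.name: r for r in default_regimes(specs, T)}
        regs = [battery[item] if isinstance(item, str)
                else build_regime(item["name"], item["assignments"], specs, T)
                for item in wanted_raw]
        fragments[label] = bootstrap_analysis(
            panel, specs, regs, contrast_pairs, n_boot=n_boot,
            n_mc=options.get("n_mc"), n_mc_boot=options.get("n_mc_boot"),
            seed=seed, stratum=label)

    mean_rows, contrast_rows, em_rows = [], [], []
    for label, frag in fragments.items():
        for reg_name, res in frag.point.items():
            lo, hi = frag.mean_cis[reg_name]
            mean_rows.append((label, reg_name, res.means[FINAL] * 100,
                              lo * 100, hi * 100))
        for (a, b), est in frag.point_contrasts.items():
            lo, hi = frag.contrast_cis[(a, b)]
            contrast_rows.append((label, a, b, est, lo, hi))
    pairs = [(a, b) for i, a in enumerate(strata) for b in list(strata)[i + 1:]
             if a != "all" and b != "all"]
    for a, b in pairs:
        for c in contrast_pairs:
            p = effect_modification_test(fragments[a], fragments[b], c)
            em_rows.append((a, b, c[0], c[1], p))

    conf_for_hash = {k: v for k, v in config.items() if k != "panel"}
    provenance = {
        "config_hash": _config_hash(conf_for_hash),
        "panel_hash": DesignCache(panel, with_outcome_column(
            base_specs, next(iter(strata.values()))))._base_hash,
        "seed": seed, "n_boot": n_boot,
        "n_dropped": {k: f.n_dropped for k, f in fragments.items()},
        "unstable": any(f.unstable for f in fragments.values()),
        "regimes": list(wanted), "strata": list(strata),
    }
    return AnalysisReport(
        means=pd.DataFrame(mean_rows, columns=[
            "stratum", "regime", "mean_pct", "ci_lower_pct", "ci_upper_pct"]),
        contrasts=pd.DataFrame(contrast_rows, columns=[
            "stratum", "reference", "comparison", "difference_pp",
            "ci_lower_pp", "ci_upper_pp"]),
        effect_modification=pd.DataFrame(em_rows, columns=[
            "stratum_a", "stratum_b", "reference", "comparison", "p_value"]),
        fragments=fragments, provenance=provenance)
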
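"""Monte Carlo g-computation engine.

Step 2 of the g-formula: draw a Monte Carlo sample from the baseline wave,
then simulate forward one wave at a time, updating every variable in its
declared ``sim_order`` from the Step-1 fitted models -- with the intervention
components either forced to a static regime value or drawn from their own
fitted models ("natural course").  The wave-T mean of the simulated outcome is
the standardized (counterfactual) mean under the regime.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import DesignCache, FittedModelSet, sample_next_value
from .panel import CovariateSpec, SchoolPanel

NATURAL = "natural"


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent, reproducible random stream for a labelled sub-task.

    A master seed spawns one stream per (regime, bootstrap replicate, ...) so
    that adding a regime or replicate never perturbs another's draws.
    """
    ints = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0x7FFFFFFF)
        else:
            h = hashlib.sha256(str(k).encode()).digest()
            ints.append(int.from_bytes(h[:4], "little"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(ints)))


class RegimeError(ValueError):
    pass


@dataclass(frozen=True)
class InterventionRegime:
    """Static per-component assignment: a fixed 0/1 path over waves 1..T,
    or ``"natural"`` (drawn from the component's own fitted model)."""
    name: str
    assignments: tuple  # tuple of (component, "natural" | tuple of values)

    def assignment(self, component: str):
        for comp, val in self.assignments:
            if comp == component:
                return val
        raise KeyError(component)

    @property
    def components(self):
        return tuple(c for c, _ in self.assignments)


def _treatment_specs(specs):
    return [s for s in specs if s.role == "treatment"]


def build_regime(name: str, assignments: dict, specs: list[CovariateSpec],
                 T: int | None = None) -> InterventionRegime:
    """Validate and canonicalise a component -> value-or-natural mapping.

    Scalar values are broadcast over all intervention waves.  Fixed paths for
    absorbing components must be nondecreasing.
    """
    treats = _treatment_specs(specs)
    missing = [s.name for s in treats if s.name not in assignments]
    if missing:
        raise RegimeError(f"regime {name!r} missing assignments for {missing}")
    T = T or 4
    canon = []
    for s in treats:
        val = assignments[s.name]
        if val == NATURAL:
            canon.append((s.name, NATURAL))
            continue
        path = tuple(float(v) for v in (val if np.ndim(val) else [val] * T))
        if any(v not in (0.0, 1.0) for v in path):
            raise RegimeError(f"regime {name!r}: non-binary value for {s.name}")
        if s.family == "binary_absorbing" and any(
                b < a for a, b in zip(path, path[1:])):
            raise RegimeError(
                f"regime {name!r}: decreasing path for absorbing component {s.name}")
        canon.append((s.name, path))
    return InterventionRegime(name=name, assignments=tuple(canon))


def never(specs, T: int = 4) -> InterventionRegime:
    """All components withheld at every intervention wave."""
    return build_regime("never", {s.name: 0 for s in _treatment_specs(specs)},
                        specs, T)


def always_all(specs, T: int = 4) -> InterventionRegime:
    """Immediate, sustained implementation of every component."""
    return build_regime("always_all",
                        {s.name: 1 for s in _treatment_specs(specs)}, specs, T)


def only(component: str, specs, T: int = 4) -> InterventionRegime:
    """One component implemented immediately, all others withheld."""
    asg = {s.name: (1 if s.name == component else 0)
           for s in _treatment_specs(specs)}
    if component not in asg:
        raise RegimeError(f"unknown component {component!r}")
    return build_regime(f"only_{component.removeprefix('component_')}",
                        asg, specs, T)


def natural_regime(specs, T: int = 4) -> InterventionRegime:
    """No intervention: every component drawn from its fitted model."""
    return build_regime("natural",
                        {s.name: NATURAL for s in _treatment_specs(specs)},
                        specs, T)


def combined(components: list[str], specs, T: int = 4,
             name: str | None = None) -> InterventionRegime:
    asg = {s.name: (1 if s.name in components else 0)
           for s in _treatment_specs(specs)}
    name = name or "+".join(c.removeprefix("component_") for c in components)
    return build_regime(name, asg, specs, T)


@dataclass
class RegimeResult:
    """Per-wave mean outcome trajectory under one regime."""
    regime: str
    means: np.ndarray      # length T+1, proportion scale
    mc_se: np.ndarray      # Monte Carlo standard error per wave
    n_mc: int
    seed: int
    provenance: str        # fitted-model provenance tag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "regime": self.regime, "wave": np.arange(len(self.means)),
            "mean": self.means, "mc_se": self.mc_se,
            "n_mc": self.n_mc, "seed": self.seed})


# ---------------------------------------------------------------------------

def draw_baseline_sample(panel: SchoolPanel, n_mc: int,
                         rng: np.random.Generator,
                         specs: list[CovariateSpec] | None = None) -> dict:
    """Sample ``n_mc`` baseline records with replacement from wave 0."""
    if n_mc <= 0:
        raise ValueError("n_mc must be positive")
    base = panel.baseline(specs)
    idx = rng.integers(0, panel.n_units, size=n_mc)
    return {k: v[idx] for k, v in base.items()}


def _simulate_wide(fitted: FittedModelSet, baseline: dict,
                   regime: InterventionRegime, specs: list[CovariateSpec],
                   rng: np.random.Generator) -> dict:
    """Forward-simulate wave 1..T; returns ``{variable: (n_mc, T+1) array}``."""
    T = fitted.T
    n = len(next(iter(baseline.values())))
    order = sorted(specs, key=lambda s: s.sim_order)
    wide = {}
    for s in specs:
        wide[s.name] = np.empty((n, T + 1))
        wide[s.name][:, 0] = baseline[s.name]
        if not s.is_fitted:  # baseline constants carried forward
            wide[s.name][:, 1:] = baseline[s.name][:, None]
    for t in range(1, T + 1):
        for s in order:
            if not s.is_fitted:
                continue
            if s.role == "treatment":
                asg = regime.assignment(s.name)
                if asg != NATURAL:
                    wide[s.name][:, t] = asg[t - 1]
                    continue
            state = {"wave": t}
            for var, lag in s.predictors:
                state[(var, lag)] = wide[var][:, max(t - lag, 0)]
            if s.family == "binary_absorbing":
                state[(s.name, 1)] = wide[s.name][:, t - 1]
            for comp in s.zero_when:
                state[(comp, 0)] = wide[comp][:, t]
            wide[s.name][:, t] = sample_next_value(fitted, s, state, rng, size=n)
    return wide


def simulate_histories(fitted: FittedModelSet, baseline: dict,
                       regime: InterventionRegime,
                       specs: list[CovariateSpec],
                       rng: np.random.Generator) -> SchoolPanel:
    """Simulate counterfactual covariate histories as a :class:`SchoolPanel`."""
    wide = _simulate_wide(fitted, baseline, regime, specs, rng)
    n = len(next(iter(wide.values())))
    T = fitted.T
    data = {"unit_id": np.repeat(np.arange(n), T + 1),
            "time": np.tile(np.arange(T + 1), n)}
    for s in specs:
        data[s.name] = wide[s.name].ravel()
    return SchoolPanel(pd.DataFrame(data), specs)


def run_gformula(panel: SchoolPanel, specs: list[CovariateSpec] | None,
                 regime: InterventionRegime, *, n_mc: int | None = None,
                 seed: int = 0, fitted: FittedModelSet | None = None,
                 cache: DesignCache | None = None,
                 rng: np.random.Generator | None = None) -> RegimeResult:
    """Fit (unless given), draw baseline, simulate, summarise one regime.

    Default Monte Carlo sample size is 10x the number of baseline units.  A
    pre-fitted :class:`FittedModelSet` lets one Step-1 fit feed many regimes.
    """
    specs = panel.specs if specs is None else specs
    if fitted is None:
        fitted = (cache or DesignCache(panel, specs)).fit()
    n_mc = n_mc or 10 * panel.n_units
    if rng is None:
        rng = substream(seed, "regime", regime.name)
    baseline = draw_baseline_sample(panel, n_mc, rng, specs)
    wide = _simulate_wide(fitted, baseline, regime, specs, rng)
    outcome = next(s.name for s in specs if s.role == "outcome")
    y = wide[outcome]
    return RegimeResult(regime=regime.name,
                        means=y.mean(axis=0),
                        mc_se=y.std(axis=0, ddof=1) / np.sqrt(n_mc),
                        n_mc=n_mc, seed=seed, provenance=fitted.provenance)


def natural_course_check(panel: SchoolPanel,
                         specs: list[CovariateSpec] | None = None, *,
                         n_mc: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Model-adequacy diagnostic: observed vs natural-course simulated means.

    Returns one row per wave with the observed mean outcome, the simulated
    natural-course mean, their difference, the Monte Carlo SE and the
    observed-mean sampling SE.
    """
    specs = panel.specs if specs is None else specs
    res = run_gformula(panel, specs, natural_regime(specs, panel.T),
                       n_mc=n_mc, seed=seed)
    outcome = next(s.name for s in specs if s.role == "outcome")
    y = panel.wide(specs)[outcome]
    obs = np.nanmean(y, axis=0)
    n_obs = np.sum(~np.isnan(y), axis=0)
    obs_se = np.nanstd(y, axis=0, ddof=1) / np.sqrt(np.maximum(n_obs, 1))
    return pd.DataFrame({
        "wave": np.arange(panel.T + 1),
        "observed_mean": obs,
        "simulated_mean": res.means,
        "difference": res.means - obs,
        "mc_se": res.mc_se,
        "sampling_se": obs_se,
    })
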
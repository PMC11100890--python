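"""Exact nonparametric g-formula on tiny discrete systems.

A :class:`DiscreteSystem` is a fully specified sequential law over binary
variables: independent Bernoulli baselines, then per-wave conditional
probability tables for each variable given its declared parents.  The exact
g-formula standardises the final-wave outcome over every covariate path, with
treatment factors replaced by regime indicators -- the correctness oracle for
the Monte Carlo parametric engine, which should agree (with saturated models,
large samples) up to Monte Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import NATURAL, InterventionRegime
from .panel import CovariateSpec, SchoolPanel

MAX_PATHS = 10**6


class PathBoundError(ValueError):
    pass


@dataclass(frozen=True)
class DiscreteVar:
    """One binary variable: parents as (name, lag) pairs and a CPT.

    ``table`` maps ``(wave, parent_values)`` -- or just ``parent_values`` when
    the law is wave-constant -- to P(var = 1 | parents).  ``absorbing`` makes
    the variable stick at 1 regardless of the table.
    """
    name: str
    role: str                      # treatment | covariate | outcome
    parents: tuple = ()
    table: dict = field(default_factory=dict)
    absorbing: bool = False
    baseline_p: float = 0.0

    def prob(self, wave: int, parent_vals: tuple) -> float:
        if (wave, parent_vals) in self.table:
            p = self.table[(wave, parent_vals)]
        elif parent_vals in self.table:
            p = self.table[parent_vals]
        else:
            raise KeyError(f"{self.name}: no CPT entry for wave {wave}, "
                           f"parents {parent_vals}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{self.name}: probability {p} outside [0,1]")
        return float(p)


@dataclass(frozen=True)
class DiscreteSystem:
    T: int
    variables: tuple  # DiscreteVar in within-wave update order; outcome last

    def __post_init__(self):
        if self.variables[-1].role != "outcome":
            raise ValueError("last variable must be the outcome")
        n_branch = len(self.variables) * (self.T + 1)
        if 2 ** n_branch > MAX_PATHS:
            raise PathBoundError(
                "state space too large to enumerate; use the parametric engine")

    def var(self, name: str) -> DiscreteVar:
        return next(v for v in self.variables if v.name == name)

    # -- conversion for the parametric engine -------------------------------

    def to_specs(self) -> list[CovariateSpec]:
        """Saturated CovariateSpecs so the engine can mirror this system."""
        specs = []
        for i, v in enumerate(self.variables):
            fam = "binary_absorbing" if v.absorbing else "binary"
            role = {"treatment": "treatment", "covariate": "confounder",
                    "outcome": "outcome"}[v.role]
            specs.append(CovariateSpec(v.name, role, fam, predictors=v.parents,
                                       sim_order=i, saturated=True))
        return specs

    def sample(self, n: int, rng: np.random.Generator) -> SchoolPanel:
        """Draw an observational panel of ``n`` units from the system."""
        vals = {v.name: np.zeros((n, self.T + 1)) for v in self.variables}
        for v in self.variables:
            vals[v.name][:, 0] = (rng.random(n) < v.baseline_p).astype(float)
        for t in range(1, self.T + 1):
            for v in self.variables:
                p = np.empty(n)
                parent_cols = [vals[nm][:, max(t - lag, 0)] for nm, lag in v.parents]
                if parent_cols:
                    stacked = np.column_stack(parent_cols).astype(int)
                    # vectorise CPT lookup over the (few) distinct parent rows
                    uniq, inv = np.unique(stacked, axis=0, return_inverse=True)
                    probs = np.array([v.prob(t, tuple(r)) for r in uniq])
                    p = probs[inv]
                else:
                    p[:] = v.prob(t, ())
                draw = (rng.random(n) < p).astype(float)
                if v.absorbing:
                    draw = np.maximum(draw, vals[v.name][:, t - 1])
                vals[v.name][:, t] = draw
        data = {"unit_id": np.repeat(np.arange(n), self.T + 1),
                "time": np.tile(np.arange(self.T + 1), n)}
        for nm, arr in vals.items():
            data[nm] = arr.ravel()
        return SchoolPanel(pd.DataFrame(data), self.to_specs())


def exact_gformula(system: DiscreteSystem, regime: InterventionRegime) -> float:
    """Exact standardized wave-T outcome mean under a static regime.

    Sums E[Y_T | path] * P(path under regime) over all covariate paths, with
    treatment factors replaced by the regime's indicators (or left at their
    observational law under a "natural" assignment).  Exact to floating
    precision; enumeration order does not matter.
    """
    T = system.T
    regime_map = dict(regime.assignments) if regime is not None else {}

    def parent_vals(hist, v, t):
        return tuple(int(hist[(nm, max(t - lag, 0))]) for nm, lag in v.parents)

    total = 0.0

    def recurse(t, vi, hist, prob):
        nonlocal total
        if prob == 0.0:
            return
        if vi == len(system.variables):
            if t == T:
                total += prob * hist[(system.variables[-1].name, T)]
                return
            recurse(t + 1, 0, hist, prob)
            return
        v = system.variables[vi]
        if t == 0:
            p1 = v.baseline_p
        elif v.role == "treatment" and regime_map.get(v.name, NATURAL) != NATURAL:
            p1 = float(regime_map[v.name][t - 1])
        else:
            p1 = v.prob(t, parent_vals(hist, v, t))
            if v.absorbing and hist[(v.name, t - 1)] == 1:
                p1 = 1.0
        for val, pr in ((1, p1), (0, 1.0 - p1)):
            if pr == 0.0:
                continue
            hist[(v.name, t)] = val
            recurse(t, vi + 1, hist, prob * pr)
        del hist[(v.name, t)]

    recurse(0, 0, {}, 1.0)
    return total


# ---------------------------------------------------------------------------
# config dialect
# ---------------------------------------------------------------------------

def _parse_table_key(key) -> tuple:
    """Parse a CPT key: ``"0 1"`` -> parents (0, 1); ``"2|0 1"`` -> wave 2
    with parents (0, 1); ``""`` -> no parents."""
    key = str(key).strip()
    if "|" in key:
        wave, rest = key.split("|", 1)
        parents = tuple(int(v) for v in rest.split())
        return (int(wave), parents)
    return tuple(int(v) for v in key.split())


def system_from_config(cfg: dict) -> DiscreteSystem:
    """Build a DiscreteSystem from a plain config mapping.

    Expected shape::

        T: 2
        variables:
          - name: A
            role: treatment
            absorbing: true
            baseline_p: 0.0
            parents: [[L, 1]]
            table: {"0": 0.25, "1": 0.65}

    Table keys are space-separated parent values, optionally prefixed with
    ``wave|`` for wave-specific entries.
    """
    variables = []
    for block in cfg["variables"]:
        table = {_parse_table_key(k): float(v)
                 for k, v in dict(block.get("table", {})).items()}
        variables.append(DiscreteVar(
            name=block["name"], role=block["role"],
            parents=tuple((str(v), int(l)) for v, l in block.get("parents", [])),
            table=table, absorbing=bool(block.get("absorbing", False)),
            baseline_p=float(block.get("baseline_p", 0.0))))
    return DiscreteSystem(T=int(cfg["T"]), variables=tuple(variables))


# ---------------------------------------------------------------------------
# the standard test battery system
# ---------------------------------------------------------------------------

def feedback_toy() -> DiscreteSystem:
    """Two-wave binary system with treatment-confounder feedback.

    The covariate L responds to earlier treatment and drives later treatment
    uptake (A is absorbing), and the outcome depends on the full history --
    the structure in which naive regression fails but the g-formula is exact.
    """
    A = DiscreteVar(
        "A", "treatment", parents=(("L", 1),),
        table={(0,): 0.25, (1,): 0.65}, absorbing=True, baseline_p=0.0)
    L = DiscreteVar(
        "L", "covariate", parents=(("L", 1), ("A", 0)),
        table={(0, 0): 0.25, (0, 1): 0.55, (1, 0): 0.60, (1, 1): 0.85},
        baseline_p=0.4)
    Y = DiscreteVar(
        "Y", "outcome", parents=(("A", 0), ("A", 1), ("L", 0)),
        table={(0, 0, 0): 0.20, (0, 0, 1): 0.35, (1, 0, 0): 0.40,
               (1, 0, 1): 0.55, (1, 1, 0): 0.50, (1, 1, 1): 0.70,
               (0, 1, 0): 0.30, (0, 1, 1): 0.45},
        baseline_p=0.3)
    return DiscreteSystem(T=2, variables=(A, L, Y))
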
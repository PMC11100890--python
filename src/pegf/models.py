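"""Sequential ("Step 1") pooled models for every time-varying panel variable.

Each declared variable is fitted by a pooled-over-waves regression on its
declared predictors plus an intercept and wave dummies: logistic for binary
families (absorbing indicators restricted to the at-risk rows whose lag-1
value is 0), linear-Gaussian for bounded/count families with the residual SD
and the observed training range stored for truncated draws.  Fits are exposed
through :class:`FittedModelSet`; :func:`sample_next_value` draws one wave of
one variable given the current simulated state.

A :class:`DesignCache` pre-builds the pooled design matrices once per panel so
that the cluster bootstrap can refit thousands of times by row indexing alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _glm
from .panel import CovariateSpec, SchoolPanel, validate_specs

log = logging.getLogger(__name__)

BINARY_FAMILIES = ("binary", "binary_absorbing")


class FitError(RuntimeError):
    """A covariate model could not be fitted; the message names the variable."""


@dataclass
class FittedModel:
    name: str
    family: str
    kind: str                      # logit | linear | constant | zero | saturated
    terms: list = field(default_factory=list)
    coef: np.ndarray | None = None
    resid_sd: float = 0.0
    y_min: float = 0.0
    y_max: float = 1.0
    const_value: float = 0.0       # for kind == constant / zero
    n_obs: int = 0
    converged: bool = True
    # saturated-fit payload: dense lookup arrays indexed by an integer cell code
    sat_mean: np.ndarray | None = None
    sat_sd: np.ndarray | None = None
    sat_radix: np.ndarray | None = None
    sat_fallback: float = 0.0


@dataclass
class FittedModelSet:
    """One fitted entry per non-fixed spec, plus fit provenance."""
    models: dict
    specs: list
    T: int
    provenance: str

    def __getitem__(self, name: str) -> FittedModel:
        return self.models[name]

    def to_frame(self) -> pd.DataFrame:
        """Plain-text coefficient table for audit / cross-implementation use."""
        rows = []
        for m in self.models.values():
            if m.coef is not None:
                for term, est in zip(m.terms, m.coef):
                    rows.append((m.name, m.kind, term, est, m.resid_sd,
                                 m.y_min, m.y_max, m.n_obs))
            else:
                rows.append((m.name, m.kind, "(value)", m.const_value,
                             m.resid_sd, m.y_min, m.y_max, m.n_obs))
        return pd.DataFrame(rows, columns=["variable", "kind", "term", "estimate",
                                           "resid_sd", "min", "max", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# design-matrix construction
# ---------------------------------------------------------------------------

def _expand_term(values: np.ndarray, spec: CovariateSpec, lag: int):
    """Columns and names for one (variable, lag) predictor."""
    if spec.family == "categorical_fixed":
        levels = spec.levels or tuple(np.unique(values[~np.isnan(values)]))
        cols = [(values == lv).astype(float) for lv in levels[1:]]
        names = [f"{spec.name}[{lv}].l{lag}" for lv in levels[1:]]
        return cols, names
    return [values], [f"{spec.name}.l{lag}"]


def design_columns(spec: CovariateSpec, by_name: dict, T: int) -> list[str]:
    names = ["const"] + [f"wave_{t}" for t in range(2, T + 1)]
    for var, lag in spec.predictors:
        _, nm = _expand_term(np.zeros(1), by_name[var], lag)
        names.extend(nm)
    return names


class DesignCache:
    """Pooled design matrices, responses and fit masks for one panel.

    Rows are unit-major over waves 1..T, so a bootstrap resample of units maps
    to contiguous row blocks.  Lags index wave ``max(t - lag, 0)`` (clamped at
    baseline, which implements the convention that an outcome lag-2 term
    equals lag-1 at wave 1).
    """

    def __init__(self, panel: SchoolPanel, specs: list[CovariateSpec] | None = None):
        specs = panel.specs if specs is None else specs
        validate_specs(specs)
        self.specs = specs
        self.by_name = {s.name: s for s in specs}
        self.T = T = panel.T
        self.n_units = n = panel.n_units
        wide = panel.wide(specs)
        self.entries: dict[str, dict] = {}

        for s in specs:
            if not s.is_fitted:
                continue
            y = wide[s.name][:, 1:].reshape(-1)
            k = len(design_columns(s, self.by_name, T))
            X = np.empty((n, T, k))
            X[:, :, 0] = 1.0
            for t in range(1, T + 1):
                col = 1
                for tw in range(2, T + 1):
                    X[:, t - 1, col] = 1.0 if t == tw else 0.0
                    col += 1
                for var, lag in s.predictors:
                    vals = wide[var][:, max(t - lag, 0)]
                    cols, _ = _expand_term(vals, self.by_name[var], lag)
                    for c in cols:
                        X[:, t - 1, col] = c
                        col += 1
            X = X.reshape(n * T, k)

            mask = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
            if s.family == "binary_absorbing":
                mask &= wide[s.name][:, 0:T].reshape(-1) == 0  # at-risk rows
            for comp in s.zero_when:
                mask &= wide[comp][:, 1:].reshape(-1) == 1     # treated rows

            entry = {"X": X, "y": y, "mask": mask,
                     "terms": design_columns(s, self.by_name, T)}
            if s.saturated:
                V = np.empty((n, T, 1 + len(s.predictors)), dtype=np.int64)
                for t in range(1, T + 1):
                    V[:, t - 1, 0] = t
                    for j, (var, lag) in enumerate(s.predictors):
                        V[:, t - 1, j + 1] = wide[var][:, max(t - lag, 0)]
                entry["V"] = V.reshape(n * T, -1)
            self.entries[s.name] = entry

        self._base_hash = hashlib.sha1(
            b"".join(np.ascontiguousarray(wide[s.name]).tobytes() for s in specs)
            + repr([(s.name, s.family, s.predictors) for s in specs]).encode()
        ).hexdigest()[:16]

    # -- fitting ------------------------------------------------------------

    def rows_for_units(self, unit_idx: np.ndarray | None) -> np.ndarray | None:
        if unit_idx is None:
            return None
        return (np.asarray(unit_idx)[:, None] * self.T
                + np.arange(self.T)).reshape(-1)

    def fit(self, unit_idx: np.ndarray | None = None) -> FittedModelSet:
        rows = self.rows_for_units(unit_idx)
        models = {}
        for s in self.specs:
            if not s.is_fitted:
                continue
            e = self.entries[s.name]
            if rows is None:
                X, y, mask = e["X"], e["y"], e["mask"]
            else:
                X, y, mask = e["X"][rows], e["y"][rows], e["mask"][rows]
            Xf, yf = X[mask], y[mask]
            m = FittedModel(name=s.name, family=s.family, kind="linear",
                            terms=e["terms"], n_obs=len(yf))
            if len(yf) == 0:
                m.kind = "zero"
                m.const_value = 0.0
                if s.family == "binary_absorbing":
                    log.warning("fit_models: empty at-risk set for %s; "
                                "using probability-0 initiation rule", s.name)
                models[s.name] = m
                continue
            if s.saturated:
                V = e["V"] if rows is None else e["V"][rows]
                _fit_saturated(m, V[mask], yf)
            elif np.all(yf == yf[0]):
                m.kind = "constant"
                m.const_value = float(yf[0])
                m.y_min = m.y_max = float(yf[0])
            elif s.family in BINARY_FAMILIES:
                m.kind = "logit"
                try:
                    m.coef = _glm.fit_logistic(Xf, yf)
                except _glm.NonConvergenceError as exc:
                    raise FitError(f"model for {s.name!r} did not converge") from exc
            else:
                m.kind = "linear"
                m.coef, m.resid_sd = _glm.fit_linear(Xf, yf)
                m.y_min = float(np.min(yf))
                m.y_max = float(np.max(yf))
            models[s.name] = m
        tag = self._base_hash
        if unit_idx is not None:
            tag += ":" + hashlib.sha1(
                np.asarray(unit_idx).tobytes()).hexdigest()[:8]
        return FittedModelSet(models=models, specs=self.specs, T=self.T,
                              provenance=tag)


def _fit_saturated(m: FittedModel, V: np.ndarray, y: np.ndarray) -> None:
    """Empirical cell means/SDs on the discrete cross of wave x predictors."""
    radix = V.max(axis=0).astype(int) + 1
    codes = np.zeros(len(V), dtype=np.int64)
    for j in range(V.shape[1]):
        codes = codes * radix[j] + V[:, j]
    size = int(np.prod(radix))
    if size > 10**6:
        raise FitError(f"saturated design for {m.name!r} too large ({size} cells)")
    cnt = np.bincount(codes, minlength=size).astype(float)
    s1 = np.bincount(codes, weights=y, minlength=size)
    s2 = np.bincount(codes, weights=y * y, minlength=size)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean**2, 0.0)
    m.kind = "saturated"
    m.sat_mean = mean
    m.sat_sd = np.sqrt(var)
    m.sat_radix = radix
    m.sat_fallback = float(y.mean())
    m.y_min = float(np.min(y))
    m.y_max = float(np.max(y))
    m.n_obs = len(y)


def fit_models(panel: SchoolPanel,
               specs: list[CovariateSpec] | None = None) -> FittedModelSet:
    """Fit all Step-1 pooled sequential models on the panel."""
    return DesignCache(panel, specs).fit()


# ---------------------------------------------------------------------------
# conditional draws
# ---------------------------------------------------------------------------

def _model_mean(m: FittedModel, spec: CovariateSpec, by_name: dict,
                state: dict, T: int, n: int, idx=slice(None)):
    """Conditional mean (probability for binary families) for active rows."""
    if m.kind == "zero":
        return np.zeros(n), 0.0
    if m.kind == "constant":
        return np.full(n, m.const_value), 0.0
    if m.kind == "saturated":
        t = state["wave"]
        cols = [np.full(n, t, dtype=int)] + \
               [np.asarray(state[(var, lag)])[idx].astype(int)
                for var, lag in spec.predictors]
        codes = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for j, c in enumerate(cols):
            ok &= (c >= 0) & (c < m.sat_radix[j])
            codes = codes * m.sat_radix[j] + np.clip(c, 0, m.sat_radix[j] - 1)
        mean = np.where(ok, m.sat_mean[codes], np.nan)
        sd = np.where(ok, m.sat_sd[codes], 0.0)
        unseen = ~np.isfinite(mean)
        if unseen.any():
            mean[unseen] = m.sat_fallback
            sd[unseen] = 0.0
        return mean, sd
    t = state["wave"]
    X = np.empty((n, len(m.coef)))
    X[:, 0] = 1.0
    col = 1
    for tw in range(2, T + 1):
        X[:, col] = 1.0 if t == tw else 0.0
        col += 1
    for var, lag in spec.predictors:
        vals = np.asarray(state[(var, lag)], dtype=float)[idx]
        cols, _ = _expand_term(vals, by_name[var], lag)
        for c in cols:
            X[:, col] = c
            col += 1
    if m.kind == "logit":
        return _glm.predict_logistic(X, m.coef), 0.0
    return X @ m.coef, m.resid_sd


def sample_next_value(fitted: FittedModelSet, spec: CovariateSpec,
                      state: dict, rng: np.random.Generator,
                      size: int | None = None) -> np.ndarray:
    """Draw the next-wave value of one variable for every simulated unit.

    ``state`` maps ``(variable, lag)`` keys to value arrays resolved at the
    current wave, plus ``state["wave"] = t``.  Absorbing indicators with lag-1
    value 1 return 1 without consuming randomness; variables whose
    ``zero_when`` trigger is off return 0 deterministically; binary families
    are Bernoulli draws at the model probability; continuous families are
    Gaussian draws truncated to the observed training range; count families
    are additionally rounded half-to-even and floored at 0.
    """
    m = fitted[spec.name]
    by_name = {s.name: s for s in fitted.specs}
    if size is None:
        some = next(v for k, v in state.items() if isinstance(k, tuple))
        size = len(np.asarray(some))
    out = np.zeros(size)
    active = np.ones(size, dtype=bool)
    if spec.family == "binary_absorbing":
        prev = np.asarray(state[(spec.name, 1)])
        out[prev == 1] = 1.0
        active &= prev == 0
    for comp in spec.zero_when:
        active &= np.asarray(state[(comp, 0)]) == 1
    nact = int(active.sum())
    if nact == 0:
        return out
    mean, sd = _model_mean(m, spec, by_name, state, fitted.T, nact, idx=active)
    if spec.family in BINARY_FAMILIES:
        p = np.clip(mean, 0.0, 1.0)
        if np.all(p == 1.0):
            out[active] = 1.0
        elif np.all(p == 0.0):
            pass
        else:
            out[active] = (rng.random(nact) < p).astype(float)
    else:
        draws = mean + np.asarray(sd) * rng.standard_normal(nact)
        draws = np.clip(draws, m.y_min, m.y_max)
        if spec.family == "count_continuous":
            draws = np.maximum(np.rint(draws), 0.0)
        out[active] = draws
    return out
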
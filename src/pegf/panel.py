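"""Longitudinal school-panel container, variable metadata, IO and validation.

The unit of analysis is the school-year: one row per school per discrete wave
(wave 0 = baseline, waves 1..T = intervention years).  Variables are declared
through :class:`CovariateSpec` objects which drive model fitting, simulation
order and validation; the panel itself is a thin wrapper around a long-format
:class:`pandas.DataFrame` with a cached wide (unit x wave) array view used by
the numerical code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: recognised model families
FAMILIES = (
    "binary",
    "binary_absorbing",
    "bounded_continuous",
    "count_continuous",
    "categorical_fixed",
)

ROLES = ("treatment", "confounder", "mediator", "outcome")


class PanelFormatError(ValueError):
    """Raised when an input table cannot be interpreted as a school panel."""


class SpecError(ValueError):
    """Raised when a set of CovariateSpec declarations is inconsistent."""


@dataclass(frozen=True)
class CovariateSpec:
    """Declaration of one panel variable.

    Parameters
    ----------
    name:
        Column name in the panel.
    role:
        One of ``treatment``, ``confounder``, ``mediator``, ``outcome``.
    family:
        Distribution family used for fitting/simulation.  ``binary_absorbing``
        marks an indicator that stays 1 once it becomes 1 (audit, feedback,
        PE-teacher components); ``categorical_fixed`` marks a baseline
        constant that is never modelled (cohort).
    predictors:
        Ordered ``(variable, lag)`` pairs.  Lag 0 refers to the same wave and
        is only allowed for variables earlier in ``sim_order``.  Negative lags
        are clamped to wave 0 (so an outcome lag-2 term equals the lag-1 term
        at wave 1).
    sim_order:
        Position in the within-wave update sequence; the outcome must be last.
    zero_when:
        Component names whose value 0 at the current wave forces this
        variable to 0 (audit-derived mediators are undefined pre-audit).
    bounds:
        Structural validation bounds, e.g. ``(0, 1)`` for proportions or
        ``(0, 9)`` for audit condition counts.  ``None`` disables the check
        apart from family defaults.
    levels:
        Category levels for ``categorical_fixed`` variables.
    saturated:
        Fit by empirical cell means on the discrete predictor cross
        (wave x predictor values) instead of a regression -- used by the
        enumeration-oracle equivalence checks.
    """

    name: str
    role: str
    family: str
    predictors: tuple = ()
    sim_order: int = 0
    zero_when: tuple = ()
    bounds: tuple | None = None
    levels: tuple | None = None
    saturated: bool = False

    def __post_init__(self):
        if self.role not in ROLES:
            raise SpecError(f"{self.name}: unknown role {self.role!r}")
        if self.family not in FAMILIES:
            raise SpecError(f"{self.name}: unknown family {self.family!r}")
        object.__setattr__(self, "predictors",
                           tuple((str(v), int(l)) for v, l in self.predictors))
        object.__setattr__(self, "zero_when", tuple(self.zero_when))

    @property
    def is_fitted(self) -> bool:
        return self.family != "categorical_fixed"


def specs_from_config(blocks: list[dict]) -> list[CovariateSpec]:
    """Build CovariateSpecs from plain config blocks.

    Each block is a mapping with ``name``, ``role``, ``family`` and the
    optional keys ``predictors`` (list of ``[variable, lag]`` pairs),
    ``sim_order``, ``zero_when``, ``bounds``, ``levels``, ``saturated``.
    """
    specs = []
    for b in blocks:
        b = dict(b)
        for key in ("predictors", "zero_when", "bounds", "levels"):
            if key in b and b[key] is not None:
                b[key] = tuple(tuple(p) if isinstance(p, (list, tuple)) else p
                               for p in b[key])
        specs.append(CovariateSpec(**b))
    validate_specs(specs)
    return specs


def with_outcome_column(specs: list[CovariateSpec],
                        column: str) -> list[CovariateSpec]:
    """Swap the outcome variable for an alternate panel column.

    Used by stratified analyses: the stratum outcome column replaces the
    outcome everywhere, including self-referencing lag predictors, and the
    rest of the pipeline runs unchanged.
    """
    outcome = next(s for s in specs if s.role == "outcome")
    if column == outcome.name:
        return list(specs)

    def sub(nm):
        return column if nm == outcome.name else nm

    return [replace(s, name=sub(s.name),
                    predictors=tuple((sub(v), l) for v, l in s.predictors))
            for s in specs]


def validate_specs(specs: list[CovariateSpec]) -> None:
    """Check cross-spec consistency; raise :class:`SpecError` on violation."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SpecError("duplicate variable names in specs")
    by_name = {s.name: s for s in specs}
    outcomes = [s for s in specs if s.role == "outcome"]
    if len(outcomes) != 1:
        raise SpecError(f"exactly one outcome spec required, got {len(outcomes)}")
    max_order = max(s.sim_order for s in specs)
    if outcomes[0].sim_order != max_order:
        raise SpecError("outcome spec must be last in sim_order")
    for s in specs:
        for var, lag in s.predictors:
            if var not in by_name:
                raise SpecError(f"{s.name}: predictor {var!r} not declared")
            if lag < 0:
                raise SpecError(f"{s.name}: negative lag for {var!r}")
            ref = by_name[var]
            if lag == 0 and ref.is_fitted and ref.sim_order >= s.sim_order:
                raise SpecError(
                    f"{s.name}: lag-0 predictor {var!r} is not earlier in sim_order")
        for comp in s.zero_when:
            if comp not in by_name:
                raise SpecError(f"{s.name}: zero_when component {comp!r} not declared")


# ---------------------------------------------------------------------------
# default variable metadata for the school panel
# ---------------------------------------------------------------------------

COMPONENTS = ("component_audit", "component_feedback", "component_teacher",
              "component_mti")


def school_specs(outcome: str = "outcome_prop",
                 outcome_lags: int = 2,
                 extra_outcome_predictors: tuple = ()) -> list[CovariateSpec]:
    """Default variable declarations for the school PE panel.

    ``outcome`` may name an alternate outcome column (e.g.
    ``outcome_prop_female``) so that stratified analyses run through the
    identical pipeline with the outcome column swapped.

    The outcome model regresses on its own lags (``outcome_lags`` of them),
    cohort, the four intervention components, the audit-derived mediators,
    staffing and demographic covariates; every fitted model additionally gets
    an intercept and wave dummies (secular trend).
    """
    def P(*pairs):
        return tuple(pairs)

    conf = [(outcome, 1), ("frpm_prop", 1), ("cohort", 0)]
    specs = [
        CovariateSpec("cohort", "confounder", "categorical_fixed",
                      levels=(1, 2, 3), sim_order=0),
        CovariateSpec("component_audit", "treatment", "binary_absorbing",
                      predictors=P(*conf), sim_order=1),
        CovariateSpec("component_feedback", "treatment", "binary_absorbing",
                      predictors=P(*conf, ("component_audit", 0)), sim_order=2),
        CovariateSpec("component_teacher", "treatment", "binary_absorbing",
                      predictors=P(*conf), sim_order=3),
        CovariateSpec("component_mti", "treatment", "binary",
                      predictors=P(("component_mti", 1), *conf), sim_order=4),
        CovariateSpec("audit_conditions_met", "mediator", "count_continuous",
                      predictors=P(("audit_conditions_met", 1), ("cohort", 0)),
                      sim_order=5, zero_when=("component_audit",), bounds=(0, 9)),
        CovariateSpec("audit_conditions_changed", "mediator", "count_continuous",
                      predictors=P(("audit_conditions_changed", 1), ("cohort", 0)),
                      sim_order=6, zero_when=("component_audit",), bounds=(0, 9)),
        CovariateSpec("coaching_interactions", "mediator", "count_continuous",
                      predictors=P(("coaching_interactions", 1), ("cohort", 0)),
                      sim_order=7,
                      zero_when=("component_audit", "component_feedback")),
        CovariateSpec("n_pe_teachers", "mediator", "count_continuous",
                      predictors=P(("n_pe_teachers", 1), ("component_teacher", 0)),
                      sim_order=8),
        CovariateSpec("pe_days_per_week", "confounder", "bounded_continuous",
                      predictors=P(("pe_days_per_week", 1),
                                   ("component_teacher", 0), ("cohort", 0)),
                      sim_order=9, bounds=(0, 5)),
        CovariateSpec("enrollment", "confounder", "count_continuous",
                      predictors=P(("enrollment", 1)), sim_order=10),
        CovariateSpec("frpm_prop", "confounder", "bounded_continuous",
                      predictors=P(("frpm_prop", 1)), sim_order=11, bounds=(0, 1)),
        CovariateSpec("white_prop", "confounder", "bounded_continuous",
                      predictors=P(("white_prop", 1)), sim_order=12, bounds=(0, 1)),
        CovariateSpec("n_tested", "confounder", "count_continuous",
                      predictors=P(("n_tested", 1), ("enrollment", 0)),
                      sim_order=13),
        CovariateSpec(outcome, "outcome", "bounded_continuous",
                      predictors=tuple(
                          [(outcome, lag) for lag in range(1, outcome_lags + 1)]
                          + [("cohort", 0),
                             ("component_audit", 0), ("component_feedback", 0),
                             ("component_teacher", 0), ("component_mti", 0),
                             ("component_mti", 1),
                             ("n_pe_teachers", 0), ("audit_conditions_met", 0),
                             ("audit_conditions_changed", 0),
                             ("coaching_interactions", 0),
                             ("enrollment", 0), ("frpm_prop", 0),
                             ("white_prop", 0), ("n_tested", 0),
                             ("pe_days_per_week", 0)]
                          + list(extra_outcome_predictors)),
                      sim_order=14, bounds=(0, 1)),
    ]
    validate_specs(specs)
    return specs


# ---------------------------------------------------------------------------
# the panel container
# ---------------------------------------------------------------------------

class SchoolPanel:
    """Long-format unit x wave panel with declared variable metadata."""

    def __init__(self, df: pd.DataFrame, specs: list[CovariateSpec],
                 unit_col: str = "unit_id", time_col: str = "time"):
        validate_specs(specs)
        for col in (unit_col, time_col):
            if col not in df.columns:
                raise PanelFormatError(f"missing column: {col!r}")
        self.unit_col = unit_col
        self.time_col = time_col
        self.specs = list(specs)
        self.df = (df.sort_values([unit_col, time_col], kind="mergesort")
                     .reset_index(drop=True))
        self.units = np.asarray(
            pd.unique(self.df[unit_col]))
        self.n_units = len(self.units)
        self.T = int(self.df[time_col].max())
        self._columns: dict[str, np.ndarray] = {}
        self._grid_ok = False

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variables(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> CovariateSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def _check_grid(self) -> None:
        if self._grid_ok:
            return
        n, T = self.n_units, self.T
        if len(self.df) != n * (T + 1):
            raise PanelFormatError(
                "panel grid incomplete: expected one row per unit per wave "
                f"({n * (T + 1)}), got {len(self.df)}")
        t = self.df[self.time_col].to_numpy()
        if not np.array_equal(t, np.tile(np.arange(T + 1), n)):
            raise PanelFormatError("panel grid incomplete or duplicated keys")
        self._grid_ok = True

    def column_wide(self, name: str) -> np.ndarray:
        """(n_units, T+1) value array for one column; requires a full grid."""
        if name not in self._columns:
            self._check_grid()
            if name not in self.df.columns:
                raise PanelFormatError(f"missing column: {name!r}")
            self._columns[name] = (self.df[name].to_numpy(dtype=float)
                                   .reshape(self.n_units, self.T + 1))
        return self._columns[name]

    def wide(self, specs: list[CovariateSpec] | None = None) -> dict[str, np.ndarray]:
        """``{variable: (n_units, T+1) array}`` for the given (default: own) specs.

        Alternate spec sets may reference any panel column -- this is how
        stratified analyses swap in an alternate outcome column.
        """
        return {s.name: self.column_wide(s.name)
                for s in (self.specs if specs is None else specs)}

    def baseline(self, specs: list[CovariateSpec] | None = None) -> dict[str, np.ndarray]:
        """Wave-0 value arrays per variable (length ``n_units``)."""
        return {k: v[:, 0].copy() for k, v in self.wide(specs).items()}

    def subset_units(self, idx: np.ndarray) -> "SchoolPanel":
        """Panel restricted to (possibly repeated) unit positions ``idx``.

        Repeated units receive fresh unit ids; used by the cluster bootstrap.
        """
        wide = self.wide()
        out = {self.unit_col: np.repeat(np.arange(len(idx)), self.T + 1),
               self.time_col: np.tile(np.arange(self.T + 1), len(idx))}
        for name, arr in wide.items():
            out[name] = arr[idx].ravel()
        return SchoolPanel(pd.DataFrame(out), self.specs,
                           unit_col=self.unit_col, time_col=self.time_col)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_panel(path, specs: list[CovariateSpec],
               unit_col: str = "unit_id", time_col: str = "time",
               impute_baseline: bool = True,
               max_missing_outcome_waves: int = 1) -> SchoolPanel:
    """Read a long-format CSV into a validated :class:`SchoolPanel`.

    Values are taken as-is (a ``0.497`` in the file stays ``0.497``; no
    percent rescaling).  Empty cells become NaN.  Missing baseline covariates
    are imputed by the wave-0 sample mean (continuous/count) or mode
    (binary/categorical); units missing more than ``max_missing_outcome_waves``
    outcome waves are dropped.  Both operations are logged with counts.
    """
    validate_specs(specs)
    df = pd.read_csv(path, float_precision="round_trip")
    required = [unit_col, time_col] + [s.name for s in specs]
    for col in required:
        if col not in df.columns:
            raise PanelFormatError(f"missing column: {col!r}")
    for s in specs:
        coerced = pd.to_numeric(df[s.name], errors="coerce")
        bad = coerced.isna() & df[s.name].notna() & (df[s.name].astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelFormatError(
                f"unparseable value in column {s.name!r}, row {i}: "
                f"{df[s.name].iloc[i]!r}")
        df[s.name] = coerced
    df[time_col] = pd.to_numeric(df[time_col], errors="raise").astype(int)

    # complete the unit x wave grid (missing rows -> NaN records)
    T = int(df[time_col].max())
    grid = pd.MultiIndex.from_product(
        [pd.unique(df[unit_col]), range(T + 1)], names=[unit_col, time_col])
    df = (df.set_index([unit_col, time_col]).reindex(grid).reset_index())

    outcome = next(s.name for s in specs if s.role == "outcome")
    miss = df.groupby(unit_col)[outcome].apply(lambda s: s.isna().sum())
    drop = miss[miss > max_missing_outcome_waves].index
    if len(drop):
        log.info("read_panel: dropping %d unit(s) with >%d missing outcome waves",
                 len(drop), max_missing_outcome_waves)
        df = df[~df[unit_col].isin(drop)]

    if impute_baseline:
        base = df[time_col] == 0
        n_imputed = 0
        for s in specs:
            col = df.loc[base, s.name]
            if not col.isna().any():
                continue
            if s.family in ("binary", "binary_absorbing", "categorical_fixed"):
                fill = col.mode(dropna=True)
                fill = float(fill.iloc[0]) if len(fill) else 0.0
            else:
                fill = float(col.mean())
            n_imputed += int(col.isna().sum())
            df.loc[base & df[s.name].isna(), s.name] = fill
        if n_imputed:
            log.info("read_panel: imputed %d missing baseline value(s)", n_imputed)

    return SchoolPanel(df, specs, unit_col=unit_col, time_col=time_col)


def write_panel(panel: SchoolPanel, path) -> None:
    """Write the panel back to CSV (missing values as empty cells).

    Floats use 17 significant digits so a write/read cycle is lossless.
    """
    panel.df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    unit: object
    time: int | None
    variable: str | None
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.violations

    def __repr__(self):
        head = f"<ValidationReport: {'clean' if self.clean else f'{len(self.violations)} violation(s)'}>"
        return head


_FAMILY_BOUNDS = {"binary": (0, 1), "binary_absorbing": (0, 1)}


def validate_panel(panel: SchoolPanel,
                   specs: list[CovariateSpec] | None = None) -> ValidationReport:
    """Check every panel invariant; violations are reported, never raised.

    Checks: duplicate (unit, time) keys, missing baseline wave, absorbing
    indicators that decrease within a unit, out-of-range values per family
    bounds, cohort varying within unit.
    """
    specs = panel.specs if specs is None else specs
    rep = ValidationReport()
    df = panel.df
    u, t = panel.unit_col, panel.time_col

    dup = df.duplicated([u, t])
    for _, row in df[dup].iterrows():
        rep.violations.append(Violation(row[u], int(row[t]), None,
                                        "duplicate (unit, time) record"))
    has_base = df.groupby(u)[t].min()
    for unit in has_base[has_base != 0].index:
        rep.violations.append(Violation(unit, None, None, "missing baseline wave"))

    for s in specs:
        if s.name not in df.columns:
            rep.violations.append(Violation(None, None, s.name, "missing column"))
            continue
        vals = df[s.name]
        bounds = s.bounds or _FAMILY_BOUNDS.get(s.family)
        if bounds is not None:
            lo, hi = bounds
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            for i in np.flatnonzero(bad.to_numpy()):
                rep.violations.append(Violation(
                    df[u].iloc[i], int(df[t].iloc[i]), s.name,
                    f"out of range {lo}-{hi}: {vals.iloc[i]}"))
        if s.family == "count_continuous":
            bad = vals.notna() & (vals < 0)
            for i in np.flatnonzero(bad.to_numpy()):
                rep.violations.append(Violation(
                    df[u].iloc[i], int(df[t].iloc[i]), s.name,
                    f"negative count: {vals.iloc[i]}"))
        if s.family == "binary_absorbing":
            g = df.sort_values([u, t]).groupby(u)[s.name]
            dec = g.diff() < 0
            for i in np.flatnonzero(dec.to_numpy()):
                rep.violations.append(Violation(
                    df[u].iloc[i], int(df[t].iloc[i]), s.name,
                    f"absorbing indicator decreased at time {int(df[t].iloc[i])}"))
        if s.family == "categorical_fixed":
            nun = df.groupby(u)[s.name].nunique(dropna=True)
            for unit in nun[nun > 1].index:
                rep.violations.append(Violation(
                    unit, None, s.name, "baseline-constant variable varies in time"))
    return rep
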
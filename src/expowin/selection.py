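"""Window screening, backward ΔAIC-6 top-set selection with the nesting rule,
and double-penalty (shrinkage) selection.

The candidate pool for the top set is every model fitted along the backward
drop-one-term path.  The top set is all pool models within ``delta`` (default
6) AIC of the pool minimum; the nesting rule then removes any model that a
strictly nested simpler candidate matches to within ``nest_tol`` (default 2)
AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from expowin.exposure import (
    DEFAULT_WINDOWS,
    CompositeVariable,
    build_exposure_matrix,
    exposure_label,
    reduce_collinearity,
)
from expowin.ingest import DailyEnvPanel
from expowin.pgam import (
    ConvergenceError,
    FitControl,
    ModelSpec,
    PgamFit,
    SmoothTermSpec,
    c_index,
    fit_pgam,
)

logger = logging.getLogger(__name__)


@dataclass
class CandidateModel:
    spec: ModelSpec
    fit: PgamFit
    provenance: str = "backward-step"
    delta_aic: float = np.nan

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def terms(self) -> frozenset:
        return frozenset(self.spec.term_names)

    @property
    def formula(self) -> str:
        return self.spec.formula()


@dataclass
class NestingElimination:
    eliminated: str          # formula of the removed model
    by: str                  # formula of the nested simpler model
    aic_eliminated: float
    aic_by: float


@dataclass
class SelectionReport:
    candidates: list          # retained, ranked
    eliminations: list = field(default_factory=list)
    pool_size: int = 0
    failures: list = field(default_factory=list)
    table: pd.DataFrame | None = None

    @property
    def best(self) -> CandidateModel:
        return self.candidates[0]

    def retained_formulas(self) -> list:
        return [c.formula for c in self.candidates]

    def to_json_dict(self) -> dict:
        rows = self.table.to_dict(orient="records") if self.table is not None else []
        return {
            "models": rows,
            "pool_size": self.pool_size,
            "eliminations": [
                {
                    "eliminated": e.eliminated,
                    "by": e.by,
                    "aic_eliminated": e.aic_eliminated,
                    "aic_by": e.aic_by,
                }
                for e in self.eliminations
            ],
            "failures": list(self.failures),
        }

    def to_markdown(self) -> str:
        if self.table is None:
            return "(empty report)"
        lines = ["| # | Model | R2_adj | AIC | dAIC | C-index (95% CI) |",
                 "|---|-------|--------|-----|------|------------------|"]
        for i, row in self.table.iterrows():
            ci = (
                f"{row['c_index']:.2f} ({row['c_lo']:.2f}-{row['c_hi']:.2f})"
                if np.isfinite(row.get("c_index", np.nan))
                else "-"
            )
            lines.append(
                f"| {i + 1} | {row['formula']} | {row['r2_adj']:.3f} | "
                f"{row['aic']:.2f} | {row['delta_aic']:.2f} | {ci} |"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# window screening
# ---------------------------------------------------------------------------

@dataclass
class WindowScreenResult:
    variable: str
    aic_table: pd.DataFrame      # columns: window, label, aic
    selected_window: int
    selected_label: str
    failures: dict = field(default_factory=dict)


def screen_windows(
    variable: str,
    data: pd.DataFrame,
    confounders: ModelSpec,
    windows=DEFAULT_WINDOWS,
    env_k: int = 10,
    control: FitControl | None = None,
) -> WindowScreenResult:
    """Fit the confounder base model plus one smooth per candidate window of
    ``variable``; return the per-window AIC table and the AIC-minimal window
    (ties broken toward the shorter window)."""
    rows = []
    failures = {}
    for win in sorted(windows):
        label = exposure_label(variable, win)
        if label not in data.columns:
            raise KeyError(f"exposure column {label!r} not in data")
        spec = ModelSpec(
            outcome=confounders.outcome,
            smooth_terms=(SmoothTermSpec((label,), k=env_k),) + confounders.smooth_terms,
            factor_terms=confounders.factor_terms,
            family=confounders.family,
        )
        try:
            fit = fit_pgam(spec, data, control=control)
        except (ConvergenceError, ValueError) as exc:
            failures[win] = str(exc)
            warnings.warn(f"{label}: fit failed and was excluded ({exc})", stacklevel=2)
            continue
        rows.append({"window": win, "label": label, "aic": fit.aic})
    if not rows:
        raise ConvergenceError(f"all window fits failed for {variable}")
    table = pd.DataFrame(rows).sort_values("window", kind="stable").reset_index(drop=True)
    best = table.loc[table["aic"].idxmin()]  # idxmin takes the first (shorter) on ties
    return WindowScreenResult(
        variable=variable,
        aic_table=table,
        selected_window=int(best["window"]),
        selected_label=str(best["label"]),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# nesting rule and backward selection
# ---------------------------------------------------------------------------

def nesting_rule(candidates, tol: float = 2.0):
    """Remove any candidate whose term set strictly contains a candidate that
    is at most ``tol`` AIC worse; returns (retained, eliminations).

    The AIC-minimum candidate is always retained: the rule targets complex
    models that fail to beat a simpler nested one, never the best model.
    """
    retained = []
    eliminations = []
    best_aic = min(c.aic for c in candidates) if candidates else np.nan
    for cand in candidates:
        eliminator = None
        if cand.aic == best_aic:
            retained.append(cand)
            continue
        for other in candidates:
            if other is cand:
                continue
            if other.terms < cand.terms and other.aic <= cand.aic + tol:
                eliminator = other
                break
        if eliminator is None:
            retained.append(cand)
        else:
            eliminations.append(
                NestingElimination(
                    eliminated=cand.formula,
                    by=eliminator.formula,
                    aic_eliminated=cand.aic,
                    aic_by=eliminator.aic,
                )
            )
    return retained, eliminations


def backward_select(
    base: ModelSpec,
    data: pd.DataFrame,
    delta: float = 6.0,
    nest_tol: float = 2.0,
    stop_margin: float | None = None,
    control: FitControl | None = None,
    rank_kwargs: dict | None = None,
) -> SelectionReport:
    """Backward drop-one-term search; pool = every fitted model on the path.

    The search steps to the best single-term deletion while it does not
    worsen the AIC by more than ``stop_margin`` (default: ``delta``, so the
    path explores the whole top-set range).  Returns the ranked top set after
    the ΔAIC threshold and the nesting rule.
    """
    stop_margin = delta if stop_margin is None else stop_margin
    pool: dict[frozenset, CandidateModel] = {}
    failures: list[str] = []

    base_fit = fit_pgam(base, data, control=control)  # base failure propagates
    current = CandidateModel(base, base_fit, provenance="base")
    pool[current.terms] = current

    while current.spec.term_names:
        best_step = None
        for name in current.spec.term_names:
            sub = current.spec.drop_term(name)
            key = frozenset(sub.term_names)
            if key in pool:
                cand = pool[key]
            else:
                try:
                    cand = CandidateModel(sub, fit_pgam(sub, data, control=control))
                except (ConvergenceError, ValueError) as exc:
                    failures.append(f"{sub.formula()}: {exc}")
                    continue
                pool[key] = cand
            if best_step is None or cand.aic < best_step.aic:
                best_step = cand
        if best_step is None or best_step.aic > current.aic + stop_margin:
            break
        current = best_step

    candidates = list(pool.values())
    pool_min = min(c.aic for c in candidates)
    top = [c for c in candidates if c.aic - pool_min <= delta]
    retained, eliminations = nesting_rule(top, tol=nest_tol)
    report = rank_and_report(retained, data, **(rank_kwargs or {}))
    report.eliminations = eliminations
    report.pool_size = len(candidates)
    report.failures = failures
    return report


def rank_and_report(
    candidates,
    data: pd.DataFrame | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> SelectionReport:
    """Deterministic ranking by AIC (ties: fewer terms, then lexical formula)
    with per-model adjusted R2 and C-index."""
    ranked = sorted(candidates, key=lambda c: (c.aic, len(c.terms), c.formula))
    if not ranked:
        raise ValueError("no candidates to rank")
    best_aic = ranked[0].aic
    rows = []
    for cand in ranked:
        cand.delta_aic = cand.aic - best_aic
        row = {
            "formula": cand.formula,
            "n_terms": len(cand.terms),
            "aic": cand.aic,
            "delta_aic": cand.delta_aic,
            "r2_adj": cand.fit.adjusted_r2,
            "edf": cand.fit.edf_total,
            "c_index": np.nan,
            "c_lo": np.nan,
            "c_hi": np.nan,
        }
        if cand.spec.family == "binomial":
            if n_boot > 0:
                c, (lo, hi) = c_index(cand.fit.fitted, cand.fit.y, n_boot=n_boot, seed=seed)
                row.update(c_index=c, c_lo=lo, c_hi=hi)
            else:
                row["c_index"] = c_index(cand.fit.fitted, cand.fit.y)
        rows.append(row)
    return SelectionReport(candidates=ranked, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# double-penalty selection
# ---------------------------------------------------------------------------

@dataclass
class DoublePenaltyResult:
    fit: PgamFit
    surviving: list
    removed: list
    threshold: float

    def to_json_dict(self) -> dict:
        return {
            "formula": self.fit.spec.formula(),
            "surviving": list(self.surviving),
            "removed": list(self.removed),
            "threshold": self.threshold,
            "edf_by_term": self.fit.edf_by_term,
            "aic": self.fit.aic,
        }


def double_penalty_select(
    base: ModelSpec,
    data: pd.DataFrame,
    threshold: float = 0.05,
    control: FitControl | None = None,
    selectable=None,
) -> DoublePenaltyResult:
    """Single fit with an extra penalty on every smooth's penalty null space;
    a smooth whose total EDF falls below ``threshold`` counts as selected out.

    ``selectable`` restricts the report to a subset of smooth-term names
    (e.g. only the environmental terms); default is all smooths.
    """
    spec = base.with_double_penalty(True)
    fit = fit_pgam(spec, data, control=control)
    smooth_names = [t.name for t in spec.smooth_terms]
    watch = list(selectable) if selectable is not None else smooth_names
    surviving = [n for n in watch if fit.edf_by_term[n] >= threshold]
    removed = [n for n in watch if fit.edf_by_term[n] < threshold]
    return DoublePenaltyResult(fit=fit, surviving=surviving, removed=removed,
                               threshold=threshold)


# ---------------------------------------------------------------------------
# end-to-end pipeline (screen -> composites -> base model -> selection)
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    screening: dict                       # variable -> WindowScreenResult
    composites: list                      # CompositeVariable
    env_terms: list                       # smooth-term names entering the base model
    base_spec: ModelSpec
    backward: SelectionReport
    double_penalty: DoublePenaltyResult
    data: pd.DataFrame


def full_selection(
    panel: DailyEnvPanel,
    cohort: pd.DataFrame,
    variables,
    confounders: ModelSpec,
    windows=DEFAULT_WINDOWS,
    corr_threshold: float = 0.8,
    delta: float = 6.0,
    nest_tol: float = 2.0,
    dp_threshold: float = 0.05,
    env_k: int = 10,
    control: FitControl | None = None,
    rank_kwargs: dict | None = None,
) -> PipelineResult:
    """The full analysis: per-variable window screening, composite reduction
    of the screened columns at ``corr_threshold``, then backward ΔAIC
    selection and double-penalty selection from the shared base model.

    ``confounders`` is a ModelSpec holding outcome, family and the
    non-environmental terms; environmental smooths are added to it.
    """
    exposures = build_exposure_matrix(panel, cohort, variables, windows)
    screen_data = pd.concat([cohort.reset_index(drop=True),
                             exposures.reset_index(drop=True)], axis=1)

    screening = {}
    for var in variables:
        screening[var] = screen_windows(
            var, screen_data, confounders, windows=windows, env_k=env_k, control=control
        )
        logger.info("screened %s -> window %d", var, screening[var].selected_window)

    selected_cols = [screening[v].selected_label for v in variables]
    reduced, composites = reduce_collinearity(
        exposures[selected_cols].reset_index(drop=True), threshold=corr_threshold
    )
    env_terms = list(reduced.columns)

    data = pd.concat([cohort.reset_index(drop=True), reduced], axis=1)
    base_spec = ModelSpec(
        outcome=confounders.outcome,
        smooth_terms=tuple(SmoothTermSpec((c,), k=env_k) for c in env_terms)
        + confounders.smooth_terms,
        factor_terms=confounders.factor_terms,
        family=confounders.family,
    )
    backward = backward_select(
        base_spec, data, delta=delta, nest_tol=nest_tol, control=control,
        rank_kwargs=rank_kwargs,
    )
    dp = double_penalty_select(
        base_spec, data, threshold=dp_threshold, control=control, selectable=env_terms
    )
    return PipelineResult(
        screening=screening,
        composites=composites,
        env_terms=env_terms,
        base_spec=base_spec,
        backward=backward,
        double_penalty=dp,
        data=data,
    )
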
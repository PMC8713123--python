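"""Surrogate-prediction experiment, external-cohort replication, sensitivity reruns."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from expowin.ingest import DailyEnvPanel
from expowin.pgam import FitControl, ModelSpec, PgamFit, SmoothTermSpec, fit_pgam, predict
from expowin.selection import (
    DoublePenaltyResult,
    PipelineResult,
    double_penalty_select,
    full_selection,
)

#: default surrogate design: drivers (variable, window) -> target (variable, window)
DEFAULT_SURROGATE_PREDICTORS = (("NO", 365), ("wind", 365), ("humidity", 180), ("PM2.5", 120))
DEFAULT_SURROGATE_TARGET = ("O3", 270)


def rolling_trailing_mean(panel: DailyEnvPanel, variable: str, window: int) -> pd.Series:
    """Daily trailing mean over the ``window`` days ending the day before each
    date (same convention as recruitment-matched exposures); NaN during run-in."""
    s = panel.values[variable]
    if window == 0:
        return s.copy()
    return s.shift(1).rolling(window, min_periods=window).mean()


@dataclass
class SurrogateExperiment:
    predictors: tuple
    target: tuple
    train_start: pd.Timestamp
    train_end: pd.Timestamp
    test_start: pd.Timestamp
    test_end: pd.Timestamp
    fit: PgamFit
    train_adjusted_r2: float
    test_rmse: float
    predictions: pd.DataFrame  # date, observed, predicted, lo, hi
    train_dates: pd.DatetimeIndex
    test_dates: pd.DatetimeIndex


def surrogate_experiment(
    panel: DailyEnvPanel,
    split_date,
    predictors=DEFAULT_SURROGATE_PREDICTORS,
    target=DEFAULT_SURROGATE_TARGET,
    k: int = 10,
    control: FitControl | None = None,
) -> SurrogateExperiment:
    """Train a Gaussian additive model of the target trailing average on the
    driver trailing averages up to ``split_date``; predict the disjoint test
    interval after it with 95% intervals."""
    split = pd.Timestamp(split_date)
    if not (panel.dates[0] < split < panel.dates[-1]):
        raise ValueError(f"split date {split.date()} outside panel coverage")
    if not panel.is_complete:
        raise ValueError("panel must be complete (impute first)")

    cols = {}
    for var, win in predictors:
        cols[f"{var} {win}"] = rolling_trailing_mean(panel, var, win)
    tgt_label = f"{target[0]} {target[1]}"
    if tgt_label in cols:
        raise ValueError("target must not be among the predictors")
    cols[tgt_label] = rolling_trailing_mean(panel, *target)
    frame = pd.DataFrame(cols).dropna()

    train = frame.loc[frame.index <= split]
    test = frame.loc[frame.index > split]
    if train.empty or test.empty:
        raise ValueError("split leaves an empty train or test interval")
    assert train.index.max() < test.index.min()  # no leakage across the split

    spec = ModelSpec(
        outcome=tgt_label,
        smooth_terms=tuple(SmoothTermSpec((c,), k=k) for c in cols if c != tgt_label),
        family="gaussian",
    )
    fit = fit_pgam(spec, train.reset_index(drop=True), control=control)

    with warnings.catch_warnings():
        warnings.simplefilter("always")
        pred = predict(fit, test.reset_index(drop=True))
    observed = test[tgt_label].to_numpy()
    rmse = float(np.sqrt(np.mean((pred.fit - observed) ** 2)))
    predictions = pd.DataFrame(
        {
            "date": test.index,
            "observed": observed,
            "predicted": pred.fit,
            "lo": pred.ci_lo,
            "hi": pred.ci_hi,
        }
    )
    return SurrogateExperiment(
        predictors=tuple(predictors),
        target=tuple(target),
        train_start=train.index.min(),
        train_end=train.index.max(),
        test_start=test.index.min(),
        test_end=test.index.max(),
        fit=fit,
        train_adjusted_r2=fit.adjusted_r2,
        test_rmse=rmse,
        predictions=predictions,
        train_dates=train.index,
        test_dates=test.index,
    )


def replicate_external(
    cohort: pd.DataFrame,
    panel: DailyEnvPanel,
    variables=("PM10", "NO2", "O3"),
    outcome: str = "SCORAD30",
    confounders: ModelSpec | None = None,
    **kwargs,
) -> PipelineResult:
    """Run the identical pipeline on an external cohort (screening, composite
    reduction, backward selection, double penalty) with a different
    outcome/covariate configuration."""
    if confounders is None:
        confounders = ModelSpec(
            outcome=outcome,
            smooth_terms=(SmoothTermSpec(("age",), k=10),),
            factor_terms=("sex", "season"),
            family="binomial",
        )
    return full_selection(panel, cohort, variables, confounders, **kwargs)


@dataclass
class SensitivityRun:
    name: str
    n_rows: int
    result: DoublePenaltyResult


@dataclass
class SensitivityReport:
    runs: list
    stable_terms: list   # environmental terms surviving in every rerun

    def to_json_dict(self) -> dict:
        return {
            "runs": [
                {"name": r.name, "n_rows": r.n_rows, **r.result.to_json_dict()}
                for r in self.runs
            ],
            "stable_terms": list(self.stable_terms),
        }


def sensitivity_rerun(
    base_spec: ModelSpec,
    data: pd.DataFrame,
    filters: dict,
    threshold: float = 0.05,
    control: FitControl | None = None,
    selectable=None,
) -> SensitivityReport:
    """Re-run double-penalty selection on declaratively truncated cohorts.

    ``filters`` maps a run name to a predicate ``f(data) -> boolean mask``;
    the canonical content of the filter is the mask it produces, so two
    filters keeping the same rows give identical reports.
    """
    runs = []
    for name, pred in filters.items():
        mask = np.asarray(pred(data), dtype=bool)
        sub = data.loc[mask].reset_index(drop=True)
        y = sub[base_spec.outcome]
        if base_spec.family == "binomial" and y.nunique() < 2:
            raise ValueError(f"filter {name!r} leaves a single outcome class")
        result = double_penalty_select(
            base_spec, sub, threshold=threshold, control=control, selectable=selectable
        )
        runs.append(SensitivityRun(name=name, n_rows=int(mask.sum()), result=result))
    if runs:
        stable = set(runs[0].result.surviving)
        for r in runs[1:]:
            stable &= set(r.result.surviving)
    else:
        stable = set()
    return SensitivityReport(runs=runs, stable_terms=sorted(stable))
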
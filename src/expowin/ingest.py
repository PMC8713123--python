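"""Hourly station exports -> QC filter -> daily panel -> EM-spline imputation.

Input dialect (both weather and air-quality exports): CSV with columns
``timestamp`` (ISO-8601, hour resolution), ``variable``, ``value`` and ``qc``
(``pass`` / ``fail`` / empty meaning absent).  Records whose flag is not
``pass`` are dropped and counted.  Hourly values are averaged to 24-hour
means; a day is missing only when it has zero valid hours.  Missing days are
filled by a multivariate expectation-maximization model: a per-variable
smooth time trend (cubic B-spline) plus jointly Gaussian same-day residuals
across variables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from expowin._bspline import bspline_design, bspline_knots

logger = logging.getLogger(__name__)

WEATHER_VARIABLES = ("wind", "humidity", "temperature")
POLLUTANT_VARIABLES = ("NO", "NO2", "O3", "PM10", "PM2.5")
ALL_VARIABLES = WEATHER_VARIABLES + POLLUTANT_VARIABLES

#: canonical units, for documentation and the AQ unit check
UNITS = {
    "wind": "mph",
    "humidity": "%",
    "temperature": "degC",
    "NO": "ug/m3",
    "NO2": "ug/m3",
    "O3": "ug/m3",
    "PM10": "ug/m3",
    "PM2.5": "ug/m3",
}

_ACCEPTED_UG_M3 = {"ug/m3", "ugm-3", "ug m-3", "µg/m³", "ug/m^3"}


class IngestError(ValueError):
    """Malformed station export (bad timestamp, unknown variable, duplicates)."""


class InsufficientHistoryError(ValueError):
    """A requested date range is not covered by the panel."""


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------

@dataclass
class DailyEnvPanel:
    """Date-indexed daily means of ambient variables with a missingness record.

    ``values`` holds one float column per variable over a contiguous daily
    ``DatetimeIndex`` (NaN where missing).  ``provenance`` mirrors its shape
    with one of ``observed`` / ``imputed`` / ``missing`` per cell.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("panel index must be a DatetimeIndex")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise IngestError(f"duplicate panel date {dup.date()}")
        if not idx.is_monotonic_increasing:
            raise IngestError("panel dates must be strictly increasing")
        if list(self.provenance.columns) != list(self.values.columns):
            raise ValueError("provenance columns must match value columns")

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "DailyEnvPanel":
        prov = pd.DataFrame(
            np.where(values.isna(), "missing", "observed"),
            index=values.index,
            columns=values.columns,
        )
        return cls(values=values.astype(float), provenance=prov)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the value is currently missing."""
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    def copy(self) -> "DailyEnvPanel":
        return DailyEnvPanel(self.values.copy(), self.provenance.copy())

    # -- plain-text round trip ------------------------------------------------
    def to_csv(self, path, provenance_path=None) -> None:
        out = self.values.copy()
        out.index.name = "date"
        out.to_csv(path)
        if provenance_path is not None:
            prov = self.provenance.copy()
            prov.index.name = "date"
            prov.to_csv(provenance_path)

    @classmethod
    def read_csv(cls, path, provenance_path=None) -> "DailyEnvPanel":
        values = pd.read_csv(path, index_col="date", parse_dates=["date"])
        if provenance_path is None:
            return cls.from_values(values)
        prov = pd.read_csv(provenance_path, index_col="date", parse_dates=["date"])
        return cls(values=values.astype(float), provenance=prov)


# ---------------------------------------------------------------------------
# hourly readers
# ---------------------------------------------------------------------------

@dataclass
class HourlyReadResult:
    """QC-filtered hourly records plus the drop tally."""

    records: pd.DataFrame  # columns: timestamp, variable, value
    n_dropped: int
    dropped_by_flag: dict = field(default_factory=dict)

    def per_variable_counts(self) -> dict:
        return self.records.groupby("variable").size().to_dict()


def _read_hourly(source, known_variables, unit_check: bool) -> HourlyReadResult:
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"timestamp", "variable", "value", "qc"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise IngestError(f"missing columns: {sorted(missing_cols)}")
    if raw.empty:
        warnings.warn("empty hourly export", stacklevel=3)
        return HourlyReadResult(
            records=pd.DataFrame(columns=["timestamp", "variable", "value"]),
            n_dropped=0,
        )

    unknown = set(raw["variable"]) - set(known_variables)
    if unknown:
        raise IngestError(f"unknown variable name(s): {sorted(unknown)}")

    try:
        ts = pd.to_datetime(raw["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise IngestError(f"unparseable timestamp: {exc}") from exc

    if unit_check and "unit" in raw.columns:
        bad = set(raw["unit"].str.strip().str.lower()) - _ACCEPTED_UG_M3 - {""}
        if bad:
            raise IngestError(f"unexpected pollutant unit(s): {sorted(bad)}")

    qc = raw["qc"].str.strip().str.lower().replace("", "absent")
    keep = qc == "pass"
    dropped_by_flag = qc[~keep].value_counts().to_dict()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d records failing QC: %s", n_dropped, dropped_by_flag)

    records = pd.DataFrame(
        {
            "timestamp": ts[keep],
            "variable": raw.loc[keep, "variable"],
            "value": pd.to_numeric(raw.loc[keep, "value"], errors="raise"),
        }
    ).reset_index(drop=True)

    dup = records.duplicated(subset=["timestamp", "variable"])
    if dup.any():
        first = records.loc[dup.idxmax()]
        raise IngestError(
            f"duplicate timestamp {first['timestamp']} for variable {first['variable']}"
        )
    return HourlyReadResult(records, n_dropped, dropped_by_flag)


def read_weather_hourly(source) -> HourlyReadResult:
    """Read an hourly weather export (wind mph, humidity %, temperature degC)."""
    return _read_hourly(source, WEATHER_VARIABLES, unit_check=False)


def read_aq_hourly(source) -> HourlyReadResult:
    """Read an hourly air-quality export (pollutants in ug/m3, ratified QC)."""
    return _read_hourly(source, POLLUTANT_VARIABLES, unit_check=True)


# ---------------------------------------------------------------------------
# daily averaging
# ---------------------------------------------------------------------------

def daily_average(records, variables=None) -> DailyEnvPanel:
    """24-hour means over available valid hours; a day with zero hours is missing.

    ``records`` may be a :class:`HourlyReadResult` or its ``records`` frame,
    or a list of them (weather + air quality) to merge.
    """
    frames = []
    items = records if isinstance(records, (list, tuple)) else [records]
    for item in items:
        frames.append(item.records if isinstance(item, HourlyReadResult) else item)
    rec = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    if rec.empty:
        cols = list(variables) if variables else []
        empty = pd.DataFrame(columns=cols, index=pd.DatetimeIndex([], name="date"))
        return DailyEnvPanel.from_values(empty)

    rec = rec.assign(date=pd.to_datetime(rec["timestamp"]).dt.normalize())
    daily = rec.pivot_table(
        index="date", columns="variable", values="value", aggfunc="mean"
    )
    full = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(full)
    daily.index.name = "date"
    if variables is not None:
        daily = daily.reindex(columns=list(variables))
    daily.columns.name = None
    return DailyEnvPanel.from_values(daily)


def missingness_report(panel: DailyEnvPanel, start=None, end=None) -> dict:
    """Per-variable missing percentage and longest gap (days) over a date range."""
    values = panel.values
    if start is not None or end is not None:
        values = values.loc[slice(pd.Timestamp(start) if start else None,
                                  pd.Timestamp(end) if end else None)]
    report = {}
    for var in values.columns:
        isna = values[var].isna().to_numpy()
        longest = run = 0
        for flag in isna:
            run = run + 1 if flag else 0
            longest = max(longest, run)
        report[var] = {
            "percent_missing": float(100.0 * isna.mean()) if len(isna) else float("nan"),
            "longest_gap_days": int(longest),
            "n_days": int(len(isna)),
        }
    return report


# ---------------------------------------------------------------------------
# EM-spline multivariate imputation
# ---------------------------------------------------------------------------

@dataclass
class EMImputeConfig:
    df_per_year: float = 12.0
    max_iterations: int = 100
    tolerance: float = 1e-4  # relative change of imputed values
    clamp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.df_per_year < 4:
            raise ValueError("df_per_year must be >= 4")


@dataclass
class EMImputeInfo:
    n_iterations: int
    converged: bool
    last_delta: float
    loglik_trace: list[float]
    n_imputed: dict


class EMConvergenceError(RuntimeError):
    pass


def _trend_basis(n_days: int, df_per_year: float) -> np.ndarray:
    years = n_days / 365.25
    q = max(4, int(round(df_per_year * years)))
    q = min(q, max(4, n_days // 4))  # keep the trend identifiable on short panels
    t = np.arange(n_days, dtype=float)
    knots = bspline_knots(0.0, float(n_days - 1), q)
    return bspline_design(t, knots)


def em_spline_impute(
    panel: DailyEnvPanel, cfg: EMImputeConfig | None = None
) -> tuple[DailyEnvPanel, EMImputeInfo]:
    """Fill missing daily values by EM under trend + joint Gaussian residuals.

    E-step: conditional expectation of each missing cell given the observed
    same-day values under the current trend and residual covariance.  M-step:
    refit per-variable spline trends on the completed data and update the
    residual covariance (including the conditional covariance of the filled
    cells, so the observed-data log-likelihood is non-decreasing).
    """
    cfg = cfg or EMImputeConfig()
    values = panel.values
    miss = values.isna().to_numpy()
    n, m = values.shape

    frac = miss.mean(axis=0)
    for j, var in enumerate(values.columns):
        if frac[j] > 0.4:
            warnings.warn(
                f"{var}: {100 * frac[j]:.1f}% missing exceeds the 40% validity bound",
                stacklevel=2,
            )

    if not miss.any():
        info = EMImputeInfo(1, True, 0.0, [], {v: 0 for v in values.columns})
        return panel.copy(), info

    F = _trend_basis(n, cfg.df_per_year)
    X = values.to_numpy(dtype=float).copy()
    obs_sd = np.nanstd(X, axis=0)
    obs_sd[~(obs_sd > 0)] = 1.0

    # initialize: per-variable trend fit on observed rows, residual fill 0
    for j in range(m):
        o = ~miss[:, j]
        if o.sum() < F.shape[1] + 2:
            coef, *_ = np.linalg.lstsq(
                np.ones((int(o.sum()), 1)), X[o, j], rcond=None
            )
            X[miss[:, j], j] = coef[0]
        else:
            coef, *_ = np.linalg.lstsq(F[o], X[o, j], rcond=None)
            X[miss[:, j], j] = F[miss[:, j]] @ coef

    A, *_ = np.linalg.lstsq(F, X, rcond=None)
    R = X - F @ A
    sigma = R.T @ R / n
    sigma += np.eye(m) * 1e-10 * max(np.trace(sigma) / m, 1e-12)

    patterns: dict[tuple, np.ndarray] = {}
    rows_any = np.where(miss.any(axis=1))[0]
    for t in rows_any:
        patterns.setdefault(tuple(miss[t]), []).append(t)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    loglik_trace: list[float] = []
    last_delta = np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        mu = F @ A
        # E-step + observed-data loglik, grouped by missingness pattern
        ll = 0.0
        obs_rows = ~miss.any(axis=1)
        if obs_rows.any():
            ll += _mvn_loglik(X[obs_rows] - mu[obs_rows], sigma)
        cond_cov_sum = np.zeros((m, m))
        X_new = X.copy()
        for patt, rows in patterns.items():
            mi = np.asarray(patt)
            oi = ~mi
            if oi.any():
                s_oo = sigma[np.ix_(oi, oi)]
                s_mo = sigma[np.ix_(mi, oi)]
                sol = np.linalg.solve(s_oo, (X[np.ix_(rows, oi)] - mu[np.ix_(rows, oi)]).T)
                fill = mu[np.ix_(rows, mi)] + (s_mo @ sol).T
                cond = sigma[np.ix_(mi, mi)] - s_mo @ np.linalg.solve(s_oo, s_mo.T)
                ll += _mvn_loglik(X[np.ix_(rows, oi)] - mu[np.ix_(rows, oi)], s_oo)
            else:
                fill = mu[np.ix_(rows, mi)]
                cond = sigma
            for r, row in enumerate(rows):
                X_new[row, mi] = fill[r]
            full_cond = np.zeros((m, m))
            full_cond[np.ix_(mi, mi)] = cond
            cond_cov_sum += len(rows) * full_cond
        loglik_trace.append(ll)

        delta = float(
            np.max(np.abs((X_new - X)[miss]) / np.repeat(obs_sd[None, :], n, axis=0)[miss])
        )
        X = X_new

        # M-step
        A, *_ = np.linalg.lstsq(F, X, rcond=None)
        R = X - F @ A
        sigma = (R.T @ R + cond_cov_sum) / n
        sigma += np.eye(m) * 1e-10 * max(np.trace(sigma) / m, 1e-12)

        last_delta = delta
        if delta < cfg.tolerance:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"EM did not converge in {cfg.max_iterations} iterations "
            f"(last delta {last_delta:.3g})",
            stacklevel=2,
        )

    out = values.copy()
    out.loc[:, :] = X
    # physical bounds, applied after convergence so EM monotonicity holds
    if cfg.clamp_nonnegative:
        for var in out.columns:
            if var in POLLUTANT_VARIABLES:
                out[var] = out[var].clip(lower=0.0)
    if "humidity" in out.columns:
        out["humidity"] = out["humidity"].clip(0.0, 100.0)

    prov = panel.provenance.copy()
    prov_arr = prov.to_numpy()
    prov_arr[miss] = "imputed"
    prov.loc[:, :] = prov_arr
    info = EMImputeInfo(
        n_iterations=it,
        converged=converged,
        last_delta=last_delta,
        loglik_trace=loglik_trace,
        n_imputed={v: int(c) for v, c in zip(values.columns, miss.sum(axis=0))},
    )
    return DailyEnvPanel(values=out, provenance=prov), info


def _mvn_loglik(resid: np.ndarray, cov: np.ndarray) -> float:
    """Sum of zero-mean multivariate normal log-densities for rows of resid."""
    d = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return -np.inf
    sol = np.linalg.solve(cov, resid.T)
    quad = np.einsum("ij,ji->i", resid, sol)
    return float(-0.5 * (len(resid) * (d * np.log(2 * np.pi) + logdet) + quad.sum()))


def linear_interpolate(panel: DailyEnvPanel) -> DailyEnvPanel:
    """Per-variable linear interpolation baseline (used for head-to-head scoring)."""
    out = panel.values.interpolate(method="linear", limit_direction="both")
    prov = panel.provenance.copy()
    prov_arr = prov.to_numpy()
    prov_arr[panel.mask.to_numpy()] = "imputed"
    prov.loc[:, :] = prov_arr
    return DailyEnvPanel(values=out, provenance=prov)
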
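"""Recruitment-matched trailing averages, derived covariates, composites.

Window convention: a window of N > 0 days is the arithmetic mean over the N
calendar days ending the day *before* recruitment; window 0 ("day-of") is the
value on the recruitment day itself.  Exposure columns are labelled
``"<variable> <window>"``, e.g. ``"O3 270"`` (``"O3 0"`` for day-of).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from expowin.ingest import DailyEnvPanel, InsufficientHistoryError

#: candidate trailing windows in days; 0 denotes the recruitment-day value
DEFAULT_WINDOWS = (0, 7, 15, 30, 60, 90, 120, 180, 270, 365)

#: lon/lat box used to flag participants living completely out of the area
DEFAULT_AREA_BOUNDS = {"lon": (-0.2, 0.15), "lat": (51.45, 51.60)}

_SEASON_CUTOFFS = ((3, 20, "Spring"), (6, 21, "Summer"), (9, 22, "Autumn"), (12, 21, "Winter"))


def trailing_mav(panel: DailyEnvPanel, variable: str, window: int, date) -> float:
    """Trailing mean of ``variable`` over ``window`` days preceding ``date``."""
    if variable not in panel.values.columns:
        raise KeyError(f"unknown variable {variable!r}")
    date = pd.Timestamp(date)
    series = panel.values[variable]
    if window == 0:
        if date not in series.index or pd.isna(series.loc[date]):
            raise InsufficientHistoryError(
                f"{variable}: no value on recruitment day {date.date()}"
            )
        return float(series.loc[date])
    if window < 0:
        raise ValueError("window must be >= 0")
    lo = date - pd.Timedelta(days=window)
    hi = date - pd.Timedelta(days=1)
    chunk = series.loc[lo:hi]
    if len(chunk) != window or chunk.isna().any():
        raise InsufficientHistoryError(
            f"{variable}: incomplete history for window {window} ending {hi.date()}"
        )
    return float(chunk.mean())


def exposure_label(variable: str, window: int) -> str:
    return f"{variable} {window}"


def build_exposure_matrix(
    panel: DailyEnvPanel,
    cohort: pd.DataFrame,
    variables=None,
    windows=DEFAULT_WINDOWS,
    date_column: str = "recruitment_date",
) -> pd.DataFrame:
    """Participants x (variable, window) trailing averages, no missing entries."""
    variables = list(variables) if variables is not None else list(panel.variables)
    dates = pd.to_datetime(cohort[date_column])
    unique_dates = dates.drop_duplicates()

    cols = {}
    for var in variables:
        for win in windows:
            vals = {}
            for d in unique_dates:
                try:
                    vals[d] = trailing_mav(panel, var, win, d)
                except InsufficientHistoryError as exc:
                    pid = cohort.loc[dates == d].iloc[0].get("participant_id", "?")
                    raise InsufficientHistoryError(
                        f"participant {pid}: {exc}"
                    ) from exc
            cols[exposure_label(var, win)] = dates.map(vals).to_numpy()
    out = pd.DataFrame(cols, index=cohort.index)
    return out


def assign_season(date) -> str:
    """Season from fixed solstice/equinox calendar dates; boundary day starts
    the new season (Mar 20 Spring, Jun 21 Summer, Sep 22 Autumn, Dec 21 Winter)."""
    date = pd.Timestamp(date)
    md = (date.month, date.day)
    season = "Winter"
    for month, day, name in _SEASON_CUTOFFS:
        if md >= (month, day):
            season = name
    return season


def collapse_esec(esec_class: int) -> str:
    """Collapse ESeC 1-9 into higher (1-3) / middle (4-6) / working (7-9)."""
    c = int(esec_class)
    if not 1 <= c <= 9:
        raise ValueError(f"ESeC class must be in 1..9, got {esec_class}")
    if c <= 3:
        return "higher"
    if c <= 6:
        return "middle"
    return "working"


# ---------------------------------------------------------------------------
# cohort filtering
# ---------------------------------------------------------------------------

def filter_cohort(
    raw: pd.DataFrame, area_bounds: dict = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the exclusion filters; each dropped row is tallied under the first
    matching reason (out-of-area, missing sex, missing TEWL/SH, missing ESeC,
    missing height/weight or BMI)."""
    bounds = area_bounds or DEFAULT_AREA_BOUNDS
    tally = {"out_of_area": 0, "sex": 0, "tewl_sh": 0, "esec": 0, "height_weight": 0}
    keep = np.ones(len(raw), dtype=bool)

    lon_lo, lon_hi = bounds["lon"]
    lat_lo, lat_hi = bounds["lat"]

    def _missing(col):
        if col not in raw.columns:
            return pd.Series(True, index=raw.index)
        s = raw[col]
        miss = s.isna()
        if s.dtype == object:
            miss |= s.astype(str).str.strip().eq("")
        return miss

    has_bmi = "BMI" in raw.columns
    miss_body = (
        _missing("BMI") if has_bmi else (_missing("height") | _missing("weight"))
    )

    for i, (_, row) in enumerate(raw.iterrows()):
        lon, lat = row.get("lon", np.nan), row.get("lat", np.nan)
        if (
            pd.isna(lon)
            or pd.isna(lat)
            or not (lon_lo <= lon <= lon_hi and lat_lo <= lat <= lat_hi)
        ):
            tally["out_of_area"] += 1
            keep[i] = False
        elif _missing("sex").iloc[i]:
            tally["sex"] += 1
            keep[i] = False
        elif _missing("TEWL").iloc[i] or _missing("SH").iloc[i]:
            tally["tewl_sh"] += 1
            keep[i] = False
        elif _missing("esec_class").iloc[i]:
            tally["esec"] += 1
            keep[i] = False
        elif miss_body.iloc[i]:
            tally["height_weight"] += 1
            keep[i] = False

    filtered = raw.loc[keep].copy()
    if "EASI" in filtered.columns:
        filtered["EASI10"] = (filtered["EASI"] > 10).astype(int)
    return filtered, tally


# ---------------------------------------------------------------------------
# collinearity reduction
# ---------------------------------------------------------------------------

@dataclass
class CompositeVariable:
    """Principal-component dimension 1 of a standardized, highly correlated pair.

    Loadings have unit norm with the sign fixed so the first-named member
    loads positively; the score is ``z @ loadings`` where ``z`` are the
    members standardized by the stored means/sds.
    """

    members: tuple
    loadings: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    label: str
    explained_variance: float = 0.0

    def apply(self, df: pd.DataFrame) -> pd.Series:
        z = (df[list(self.members)].to_numpy() - self.means) / self.sds
        return pd.Series(z @ self.loadings, index=df.index, name=self.label)

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "loadings": [float(v) for v in self.loadings],
            "means": [float(v) for v in self.means],
            "sds": [float(v) for v in self.sds],
            "label": self.label,
            "explained_variance": float(self.explained_variance),
        }


def reduce_collinearity(
    columns: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, list[CompositeVariable]]:
    """Iteratively merge the most correlated pair (|r| > threshold) into its
    first principal component until all pairwise |r| <= threshold."""
    df = columns.copy()
    sds = df.std(ddof=0)
    if (sds <= 0).any():
        bad = sds.index[sds <= 0][0]
        raise ValueError(f"constant column {bad!r}: correlation undefined")

    composites: list[CompositeVariable] = []
    while df.shape[1] >= 2:
        corr = df.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        if abs(corr[i, j]) <= threshold:
            break
        a, b = df.columns[min(i, j)], df.columns[max(i, j)]
        comp = _pair_pca(df, a, b)
        composites.append(comp)
        score = comp.apply(df)
        df = df.drop(columns=[a, b])
        df[comp.label] = score
    return df, composites


def apply_composites(
    columns: pd.DataFrame, composites: list[CompositeVariable]
) -> pd.DataFrame:
    """Re-apply stored composite definitions (in order) to new data."""
    df = columns.copy()
    for comp in composites:
        score = comp.apply(df)
        df = df.drop(columns=list(comp.members))
        df[comp.label] = score
    return df


def _pair_pca(df: pd.DataFrame, a: str, b: str) -> CompositeVariable:
    x = df[[a, b]].to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    z = (x - means) / sds
    corr = np.corrcoef(z.T)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    v = eigvecs[:, order[0]]
    if v[0] < 0:
        v = -v
    return CompositeVariable(
        members=(a, b),
        loadings=v,
        means=means,
        sds=sds,
        label=f"{a}/{b} Dim 1",
        explained_variance=float(eigvals[order[0]] / eigvals.sum()),
    )
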
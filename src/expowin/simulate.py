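"""Synthetic environment panels and cohorts with recorded ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes: multi-year daily series with annual seasonality and AR(1) serial
correlation, an ozone series structurally coupled to NO, humidity, wind and
fine particulates (so long-window averages of those variables predict
long-window ozone), realistic missingness (isolated days plus multi-day
gaps), and a cohort whose binary severity outcome is driven by a smooth
function of one variable's trailing average over one known window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from expowin.ingest import ALL_VARIABLES, DailyEnvPanel
from expowin.exposure import DEFAULT_WINDOWS, assign_season, collapse_esec, trailing_mav

SEASON_LEVELS = ("Spring", "Summer", "Autumn", "Winter")

_DEFAULT_MEANS = {
    "wind": 10.0, "humidity": 75.0, "temperature": 11.0,
    "NO": 30.0, "NO2": 40.0, "O3": 30.0, "PM10": 22.0, "PM2.5": 13.0,
}
_DEFAULT_AMPLITUDES = {
    "wind": 1.5, "humidity": 6.0, "temperature": 7.0,
    "NO": 12.0, "NO2": 10.0, "O3": 8.0, "PM10": 4.0, "PM2.5": 3.0,
}
# phase in radians: 0 peaks at start-of-year + 91 days; winter-peaking
# pollutants are offset by pi relative to summer-peaking temperature/ozone
_DEFAULT_PHASES = {
    "wind": np.pi, "humidity": np.pi, "temperature": 0.0,
    "NO": np.pi, "NO2": np.pi, "O3": 0.0, "PM10": np.pi, "PM2.5": np.pi,
}
_DEFAULT_NOISE_SD = {
    "wind": 2.0, "humidity": 5.0, "temperature": 2.0,
    "NO": 8.0, "NO2": 7.0, "O3": 4.0, "PM10": 5.0, "PM2.5": 3.5,
}
# structural equation for O3 deviations from its own seasonal cycle
_DEFAULT_COUPLING = {"NO": -0.25, "humidity": -0.30, "wind": 0.40, "PM2.5": -0.45}


class SimulationError(ValueError):
    pass


@dataclass
class EnvSimParams:
    n_days: int = 1200
    start_date: str = "2015-01-01"
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    amplitudes: dict = field(default_factory=lambda: dict(_DEFAULT_AMPLITUDES))
    phases: dict = field(default_factory=lambda: dict(_DEFAULT_PHASES))
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    ar_coefficient: float = 0.7
    coupling: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    missing_rate: float = 0.05
    max_gap_days: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 400:
            raise SimulationError("n_days must be >= 400 to support 365-day windows")
        if not (0.0 <= self.missing_rate < 0.4):
            raise SimulationError("missing_rate must be in [0, 0.4)")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise SimulationError("ar_coefficient must be in [0, 1)")
        if self.max_gap_days < 0:
            raise SimulationError("max_gap_days must be >= 0")
        for var in ALL_VARIABLES:
            # zero is allowed for degenerate (noise-free) test fixtures
            if self.noise_sd.get(var, 1.0) < 0:
                raise SimulationError(f"noise_sd[{var}] must be >= 0")


@dataclass
class EnvSimResult:
    panel: DailyEnvPanel        # with missingness injected (NaN)
    truth: DailyEnvPanel        # complete, pre-missingness values
    seasonal: pd.DataFrame      # deterministic seasonal component per variable
    params: EnvSimParams

    @property
    def mask(self) -> pd.DataFrame:
        return self.panel.mask


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(max(1.0 - phi**2, 1e-12)) if phi > 0 else eps[0]
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def simulate_env(params: EnvSimParams) -> EnvSimResult:
    """Simulate the daily ambient panel; deterministic under a fixed seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n_days
    dates = pd.date_range(params.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    season_angle = 2 * np.pi * doy / 365.25

    seasonal = {}
    series = {}
    for var in ALL_VARIABLES:
        seas = params.amplitudes.get(var, 0.0) * np.sin(
            season_angle + params.phases.get(var, 0.0)
        )
        seasonal[var] = seas
        if var == "O3":
            continue
        noise = _ar1(rng, n, params.ar_coefficient, params.noise_sd.get(var, 1.0))
        series[var] = params.means.get(var, 0.0) + seas + noise

    # ozone: own seasonal cycle + structural coupling to the drivers' deviations
    o3 = params.means.get("O3", 0.0) + seasonal["O3"]
    for var, coef in params.coupling.items():
        o3 = o3 + coef * (series[var] - params.means.get(var, 0.0) - seasonal[var])
    o3 = o3 + _ar1(rng, n, params.ar_coefficient, params.noise_sd.get("O3", 1.0))
    series["O3"] = o3

    truth = pd.DataFrame(series, index=dates)[list(ALL_VARIABLES)]
    truth.index.name = "date"
    if not np.isfinite(truth.to_numpy()).all():
        raise SimulationError("coupling produced non-finite values")

    # missingness: isolated days + Poisson-placed gaps of length U{2..max_gap}
    mask = np.zeros(truth.shape, dtype=bool)
    if params.missing_rate > 0:
        iso_rate = params.missing_rate / 2.0
        gap_rate = params.missing_rate - iso_rate
        for j in range(truth.shape[1]):
            mask[:, j] = rng.random(n) < iso_rate
            if params.max_gap_days >= 2:
                mean_len = (2 + params.max_gap_days) / 2.0
                n_gaps = rng.poisson(gap_rate * n / mean_len)
                for _ in range(n_gaps):
                    length = int(rng.integers(2, params.max_gap_days + 1))
                    start = int(rng.integers(0, max(n - length, 1)))
                    mask[start : start + length, j] = True

    values = truth.where(~mask)
    seasonal_df = pd.DataFrame(seasonal, index=dates)[list(ALL_VARIABLES)]
    return EnvSimResult(
        panel=DailyEnvPanel.from_values(values),
        truth=DailyEnvPanel.from_values(truth),
        seasonal=seasonal_df,
        params=params,
    )


def expand_hourly(panel: DailyEnvPanel, jitter_sd: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Hourly record table (daily value + i.i.d. jitter) to exercise ingestion."""
    rng = np.random.default_rng(seed)
    rows = []
    for date, row in panel.values.iterrows():
        for var, val in row.items():
            if np.isnan(val):
                continue
            jit = rng.normal(0.0, jitter_sd, size=24)
            jit -= jit.mean()  # keep the daily mean exact
            for h in range(24):
                rows.append((date + pd.Timedelta(hours=h), var, val + jit[h], "pass"))
    return pd.DataFrame(rows, columns=["timestamp", "variable", "value", "qc"])


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

EFFECT_SHAPES = ("linear", "saturating", "bump")


@dataclass
class CohortSimParams:
    n_participants: int = 600
    recruit_start: str | None = None   # default: panel start + 365 days
    recruit_end: str | None = None     # default: panel end
    true_variable: str = "O3"
    true_window: int = 270             # 0 means day-of
    effect_shape: str = "linear"
    effect_amplitude: float = 1.5      # logit scale, applied to the z-scored MAv
    intercept: float = -1.0
    beta_age: float = 0.3              # per SD of age
    beta_sex: float = 0.3
    beta_season: dict = field(
        default_factory=lambda: {"Spring": 0.0, "Summer": 0.2, "Autumn": 0.1, "Winter": 0.3}
    )
    beta_esec: dict = field(
        default_factory=lambda: {"higher": 0.0, "middle": 0.4, "working": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_window not in DEFAULT_WINDOWS:
            raise SimulationError(
                f"true_window must be one of {DEFAULT_WINDOWS}, got {self.true_window}"
            )
        if self.effect_shape not in EFFECT_SHAPES:
            raise SimulationError(f"unknown effect shape {self.effect_shape!r}")
        if self.true_variable not in ALL_VARIABLES:
            raise SimulationError(f"unknown variable {self.true_variable!r}")


@dataclass
class SimulationTruth:
    env_params: EnvSimParams | None
    cohort_params: CohortSimParams
    prevalence: float
    linear_predictor: np.ndarray

    def to_dict(self) -> dict:
        return {
            "env_params": asdict(self.env_params) if self.env_params else None,
            "cohort_params": asdict(self.cohort_params),
            "prevalence": self.prevalence,
            "linear_predictor": [float(v) for v in self.linear_predictor],
        }


def effect_function(shape: str, amplitude: float):
    """Named smooth effect shapes on the z-scored exposure."""
    if shape == "linear":
        return lambda z: amplitude * z
    if shape == "saturating":
        return lambda z: amplitude * np.tanh(1.5 * z)
    if shape == "bump":
        return lambda z: amplitude * np.exp(-0.5 * (z / 0.6) ** 2)
    raise SimulationError(f"unknown effect shape {shape!r}")


def simulate_cohort(
    panel: DailyEnvPanel, params: CohortSimParams
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw a cohort whose outcome depends on one trailing average of the panel.

    The panel must be complete (impute first).  Every recruitment date is
    placed so that 365 days of panel history exist.
    """
    if not panel.is_complete:
        raise SimulationError("panel must be complete before cohort simulation")
    rng = np.random.default_rng(params.seed)
    n = params.n_participants

    start = (
        pd.Timestamp(params.recruit_start)
        if params.recruit_start
        else panel.dates[0] + pd.Timedelta(days=365)
    )
    end = pd.Timestamp(params.recruit_end) if params.recruit_end else panel.dates[-1]
    if start < panel.dates[0] + pd.Timedelta(days=365):
        raise SimulationError("recruitment start lacks 365 days of panel history")
    if end > panel.dates[-1] or end < start:
        raise SimulationError("recruitment span outside panel coverage")

    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=n)
    dates = start + pd.to_timedelta(offsets, unit="D")

    age = rng.uniform(1.0, 30.0, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    bmi = np.exp(rng.normal(np.log(18.0), 0.2, size=n))
    esec_group = rng.choice([0, 1, 2], size=n, p=[0.3, 0.25, 0.45])
    esec_class = np.array(
        [int(rng.integers(1, 4)) + 3 * g for g in esec_group]
    )  # 1-3 / 4-6 / 7-9
    lon = rng.normal(-0.03, 0.015, size=n)
    lat = rng.normal(51.52, 0.01, size=n)
    tewl = np.exp(rng.normal(np.log(11.0), 0.3, size=n))
    sh = rng.normal(25.0, 6.0, size=n).clip(min=1.0)
    investigator = rng.choice(["inv1", "inv2", "inv3", "inv4"], size=n,
                              p=[0.5, 0.3, 0.1, 0.1])
    season = np.array([assign_season(d) for d in dates])

    mav = np.array(
        [
            trailing_mav(panel, params.true_variable, params.true_window, d)
            for d in dates
        ]
    )
    z = (mav - mav.mean()) / (mav.std() or 1.0)
    effect = effect_function(params.effect_shape, params.effect_amplitude)

    eta = (
        params.intercept
        + effect(z)
        + params.beta_age * (age - age.mean()) / (age.std() or 1.0)
        + params.beta_sex * (sex == "male")
        + np.array([params.beta_season.get(s, 0.0) for s in season])
        + np.array([params.beta_esec.get(collapse_esec(c), 0.0) for c in esec_class])
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    outcome = (rng.random(n) < prob).astype(int)

    # EASI synthesized consistently with the binary label (<=10 vs >10)
    easi = np.where(
        outcome == 1,
        10.0 + rng.exponential(8.0, size=n),
        rng.uniform(0.0, 10.0, size=n),
    )

    cohort = pd.DataFrame(
        {
            "participant_id": [f"P{i:04d}" for i in range(n)],
            "recruitment_date": dates,
            "EASI": easi,
            "EASI10": outcome,
            "age": age,
            "sex": sex,
            "BMI": bmi,
            "lon": lon,
            "lat": lat,
            "TEWL": tewl,
            "SH": sh,
            "esec_class": esec_class,
            "investigator": investigator,
            "season": season,
        }
    )
    prevalence = float(outcome.mean())
    truth = SimulationTruth(
        env_params=None,
        cohort_params=params,
        prevalence=prevalence,
        linear_predictor=eta,
    )
    return cohort, truth


def score_imputation(
    truth: DailyEnvPanel, imputed: DailyEnvPanel, mask: pd.DataFrame
) -> dict:
    """RMSE per variable, computed only over the masked (originally missing) cells."""
    if not mask.to_numpy().any():
        raise ValueError("empty mask: nothing to score")
    if list(mask.columns) != list(truth.variables) or len(mask) != len(truth.values):
        raise ValueError("mask does not align with the truth panel")
    out = {}
    for var in truth.variables:
        sel = mask[var].to_numpy()
        if not sel.any():
            out[var] = float("nan")
            continue
        diff = imputed.values[var].to_numpy()[sel] - truth.values[var].to_numpy()[sel]
        out[var] = float(np.sqrt(np.mean(diff**2)))
    return out
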
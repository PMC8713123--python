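import numpy as np
import pandas as pd
import pytest

from expowin.ingest import DailyEnvPanel
from expowin.simulate import (
    CohortSimParams,
    EnvSimParams,
    simulate_cohort,
    simulate_env,
)


@pytest.fixture(scope="session")
def env_sim():
    """A default 900-day simulated environment (with missingness)."""
    return simulate_env(EnvSimParams(n_days=900, missing_rate=0.05, seed=42))


@pytest.fixture(scope="session")
def complete_panel(env_sim):
    return env_sim.truth


@pytest.fixture(scope="session")
def cohort_with_effect(complete_panel):
    """Cohort driven by PM2.5 over a 120-day window (known ground truth)."""
    params = CohortSimParams(
        n_participants=400,
        true_variable="PM2.5",
        true_window=120,
        effect_shape="linear",
        effect_amplitude=1.5,
        seed=7,
    )
    cohort, truth = simulate_cohort(complete_panel, params)
    return cohort, truth


def make_correlated_panel(n_days=900, n_vars=4, seed=0, missing_rate=0.10, max_gap=7):
    """Strongly cross-correlated panel with a seasonal trend, plus a missing
    mask of isolated days and multi-day gaps.  Returns (truth, masked, mask)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    latent = np.zeros(n_days)
    eps = rng.normal(0, 1, n_days)
    for i in range(1, n_days):
        latent[i] = 0.8 * latent[i - 1] + eps[i]
    season = 3.0 * np.sin(2 * np.pi * t / 365.25)
    vals = {}
    for j in range(n_vars):
        vals[f"v{j + 1}"] = (
            10.0 + season + (1.0 + 0.1 * j) * latent + rng.normal(0, 0.4, n_days)
        )
    truth = pd.DataFrame(vals, index=pd.date_range("2015-01-01", periods=n_days))
    truth.index.name = "date"

    mask = np.zeros((n_days, n_vars), dtype=bool)
    for j in range(n_vars):
        mask[rng.random(n_days) < missing_rate / 2, j] = True
        mean_len = (2 + max_gap) / 2
        for _ in range(rng.poisson(missing_rate / 2 * n_days / mean_len)):
            length = int(rng.integers(2, max_gap + 1))
            start = int(rng.integers(0, n_days - length))
            mask[start : start + length, j] = True
    masked = truth.where(~mask)
    return (
        DailyEnvPanel.from_values(truth),
        DailyEnvPanel.from_values(masked),
        pd.DataFrame(mask, index=truth.index, columns=truth.columns),
    )
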
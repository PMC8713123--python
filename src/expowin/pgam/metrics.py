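"""Fit metrics: concordance index and adjusted deviance R-squared."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def c_index(predictions, outcomes, n_boot: int = 0, seed: int = 0):
    """Concordance statistic (AUROC) with ties counted one half.

    Returns the point estimate, or ``(c, (lo, hi))`` when ``n_boot`` > 0
    (stratified bootstrap percentile interval).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")

    c = _auc(p, y, n1, n0)
    if n_boot <= 0:
        return c

    rng = np.random.default_rng(seed)
    cases = np.where(y == 1)[0]
    controls = np.where(y == 0)[0]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(cases, size=n1, replace=True),
             rng.choice(controls, size=n0, replace=True)]
        )
        stats[b] = _auc(p[idx], y[idx], n1, n0)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return c, (float(lo), float(hi))


def _auc(p: np.ndarray, y: np.ndarray, n1: int, n0: int) -> float:
    ranks = rankdata(p)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def adjusted_r2(fit) -> float:
    """1 - [resid deviance / (n - EDF)] / [null deviance / (n - 1)]."""
    n = fit.n
    if n <= fit.edf_total:
        raise ValueError("n must exceed the total effective degrees of freedom")
    if fit.null_deviance <= 0:
        return 0.0
    return float(
        1.0 - (fit.deviance / (n - fit.edf_total)) / (fit.null_deviance / (n - 1))
    )
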
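"""Model assembly and penalized fitting.

Inner loop: penalized IRLS (binomial) or penalized weighted least squares
(Gaussian) for fixed smoothing parameters.  Outer loop: generalized
Fellner-Schall updates of each smoothing parameter, a fixed-point iteration
on the gradient of the Laplace-approximate restricted marginal likelihood
(exact REML in the Gaussian case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from scipy.stats import norm

from expowin.pgam.basis import SmoothTermSpec, TermBasis, make_term_basis

FAMILIES = ("binomial", "gaussian")

_LAMBDA_MIN, _LAMBDA_MAX = 1e-7, 1e9


class ConvergenceError(RuntimeError):
    pass


class SeparationError(ConvergenceError):
    """Diverging coefficients under a binomial fit (complete separation)."""


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    smooth_terms: tuple = ()
    factor_terms: tuple = ()
    family: str = "binomial"

    def __post_init__(self) -> None:
        object.__setattr__(self, "smooth_terms", tuple(self.smooth_terms))
        object.__setattr__(self, "factor_terms", tuple(self.factor_terms))
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        seen = set()
        for t in self.smooth_terms:
            if t.name in seen:
                raise ValueError(f"covariate {t.name!r} appears twice")
            seen.add(t.name)
        for f in self.factor_terms:
            if f in seen:
                raise ValueError(f"covariate {f!r} appears twice")
            seen.add(f)

    @property
    def term_names(self) -> tuple:
        return tuple(t.name for t in self.smooth_terms) + tuple(self.factor_terms)

    def drop_term(self, name: str) -> "ModelSpec":
        if name in self.factor_terms:
            return replace(
                self, factor_terms=tuple(f for f in self.factor_terms if f != name)
            )
        if name in (t.name for t in self.smooth_terms):
            return replace(
                self,
                smooth_terms=tuple(t for t in self.smooth_terms if t.name != name),
            )
        raise KeyError(f"no term named {name!r}")

    def with_double_penalty(self, flag: bool = True) -> "ModelSpec":
        return replace(
            self, smooth_terms=tuple(t.with_double_penalty(flag) for t in self.smooth_terms)
        )

    def formula(self) -> str:
        parts = [f"s({t.name})" for t in self.smooth_terms]
        parts += [f"factor({f})" for f in self.factor_terms]
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitControl:
    max_pirls: int = 200
    pirls_tol: float = 1e-8
    max_outer: int = 100
    outer_tol: float = 1e-3          # on max |delta log lambda|
    lambda_init: float = 1.0
    separation_threshold: float = 15.0
    min_n: int = 30


@dataclass
class _Penalty:
    sl: slice              # column block in the full design
    S: np.ndarray
    label: str
    term: str              # owning term name
    lam: float = 1.0


@dataclass
class DesignInfo:
    columns: list
    term_slices: dict            # term name -> slice in X
    term_bases: dict             # smooth term name -> TermBasis
    factor_levels: dict          # factor name -> tuple(levels), first is reference
    penalties: list              # list[_Penalty]

    def build(self, data: pd.DataFrame, training: bool = False) -> np.ndarray:
        n = len(data)
        cols = [np.ones((n, 1))]
        for name, sl in self.term_slices.items():
            if name == "(intercept)":
                continue
            if name in self.term_bases:
                tb = self.term_bases[name]
                if not training:
                    for cov, lo, hi in zip(tb.spec.covariates, tb.xmin, tb.xmax):
                        x = np.asarray(data[cov], dtype=float)
                        if x.min() < lo or x.max() > hi:
                            warnings.warn(
                                f"{cov}: prediction values outside training range "
                                f"[{lo:.4g}, {hi:.4g}] (extrapolating)",
                                stacklevel=3,
                            )
                cols.append(tb.design(data))
            else:
                levels = self.factor_levels[name]
                vals = data[name].astype(str)
                unknown = set(vals) - set(levels)
                if unknown:
                    raise ValueError(f"unknown level(s) {sorted(unknown)} for factor {name!r}")
                dummies = np.column_stack(
                    [(vals == lev).to_numpy(dtype=float) for lev in levels[1:]]
                )
                cols.append(dummies)
        return np.hstack(cols)


def build_design(spec: ModelSpec, data: pd.DataFrame) -> DesignInfo:
    columns = ["(intercept)"]
    term_slices = {"(intercept)": slice(0, 1)}
    term_bases = {}
    factor_levels = {}
    penalties: list[_Penalty] = []
    pos = 1
    for t in spec.smooth_terms:
        tb = make_term_basis(t, data)
        sl = slice(pos, pos + tb.n_coef)
        term_slices[t.name] = sl
        term_bases[t.name] = tb
        for S, label in zip(tb.penalties, tb.penalty_labels):
            penalties.append(_Penalty(sl=sl, S=S, label=label, term=t.name))
        columns += [f"s({t.name}).{i}" for i in range(tb.n_coef)]
        pos += tb.n_coef
    for f in spec.factor_terms:
        levels = tuple(sorted(pd.unique(data[f].astype(str))))
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
        factor_levels[f] = levels
        sl = slice(pos, pos + len(levels) - 1)
        term_slices[f] = sl
        columns += [f"{f}[{lev}]" for lev in levels[1:]]
        pos += len(levels) - 1
    return DesignInfo(columns, term_slices, term_bases, factor_levels, penalties)


@dataclass
class PgamFit:
    spec: ModelSpec
    design: DesignInfo
    beta: np.ndarray
    Vb: np.ndarray               # Bayesian coefficient covariance (phi included)
    lambdas: dict                # penalty label -> lambda
    edf_by_term: dict
    edf_total: float
    loglik: float
    aic: float
    deviance: float
    null_deviance: float
    scale: float                 # phi (1 for binomial)
    fitted: np.ndarray           # response scale
    y: np.ndarray
    n: int
    pirls_deviance_trace: list = field(default_factory=list)
    outer_iterations: int = 0
    converged: bool = True

    @property
    def adjusted_r2(self) -> float:
        from expowin.pgam.metrics import adjusted_r2

        return adjusted_r2(self)

    def or_table(self) -> pd.DataFrame:
        """Factor-level odds ratios with 95% CI and Wald p-values (binomial)."""
        if self.spec.family != "binomial":
            raise ValueError("odds ratios are defined for binomial fits only")
        rows = []
        for f in self.spec.factor_terms:
            sl = self.design.term_slices[f]
            levels = self.design.factor_levels[f]
            rows.append((f, levels[0], np.nan, np.nan, np.nan, np.nan, True))
            for i, lev in enumerate(levels[1:]):
                idx = sl.start + i
                b = self.beta[idx]
                se = float(np.sqrt(self.Vb[idx, idx]))
                p = 2 * (1 - norm.cdf(abs(b) / se)) if se > 0 else np.nan
                rows.append(
                    (f, lev, float(np.exp(b)), float(np.exp(b - 1.96 * se)),
                     float(np.exp(b + 1.96 * se)), float(p), False)
                )
        return pd.DataFrame(
            rows, columns=["factor", "level", "OR", "ci_lo", "ci_hi", "p_value", "reference"]
        )

    def summary_dict(self) -> dict:
        return {
            "formula": self.spec.formula(),
            "family": self.spec.family,
            "n": self.n,
            "aic": self.aic,
            "loglik": self.loglik,
            "edf_total": self.edf_total,
            "edf_by_term": self.edf_by_term,
            "lambdas": self.lambdas,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "adjusted_r2": self.adjusted_r2,
        }


# ---------------------------------------------------------------------------
# deviance / likelihood helpers
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _binomial_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return -0.5 * _binomial_deviance(y, mu)


def _assemble_S(penalties, p: int) -> np.ndarray:
    S = np.zeros((p, p))
    for pen in penalties:
        S[pen.sl, pen.sl] += pen.lam * pen.S
    return S


def _inv_pd(A: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A, hermitian=True)


def _solve_pd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve a (near) positive-definite system, falling back to least squares
    when the penalized Hessian is numerically rank deficient."""
    try:
        return cho_solve(cho_factor(A), b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _pirls(X, y, penalties, family, control, beta0=None):
    """Penalized IRLS for fixed lambdas; returns beta, H (=X'WX), trace."""
    n, p = X.shape
    S = _assemble_S(penalties, p)
    if family == "gaussian":
        H = X.T @ X
        beta = _solve_pd(H + S, X.T @ y)
        mu = X @ beta
        dev = float(np.sum((y - mu) ** 2))
        return beta, H, mu, [dev + float(beta @ S @ beta)]

    beta = beta0 if beta0 is not None else np.zeros(p)
    eta = X @ beta
    mu = expit(eta)
    pendev = _binomial_deviance(y, mu) + float(beta @ S @ beta)
    trace = [pendev]
    H = None
    for _ in range(control.max_pirls):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        rhs = Xw.T @ z
        beta_new = _solve_pd(H + S, rhs)

        # step halving keeps the penalized deviance non-increasing
        step = 1.0
        for _ in range(40):
            cand = beta + step * (beta_new - beta)
            eta_c = X @ cand
            mu_c = expit(eta_c)
            pendev_c = _binomial_deviance(y, mu_c) + float(cand @ S @ cand)
            if pendev_c <= pendev + 1e-10:
                break
            step /= 2.0
        beta, eta, mu = cand, eta_c, mu_c
        delta = pendev - pendev_c
        pendev = pendev_c
        trace.append(pendev)
        if abs(delta) < control.pirls_tol * (abs(pendev) + 1.0):
            break
    else:
        raise ConvergenceError(
            f"PIRLS failed to converge in {control.max_pirls} iterations"
        )
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = X.T @ (X * w[:, None])
    return beta, H, mu, trace


def _block_pinv_traces(penalties):
    """tr(S_block^- S_i) per penalty, with S_block the lambda-weighted sum of
    penalties sharing the same column block."""
    groups: dict[tuple, list] = {}
    for idx, pen in enumerate(penalties):
        groups.setdefault((pen.sl.start, pen.sl.stop), []).append(idx)
    out = np.zeros(len(penalties))
    for idxs in groups.values():
        S_b = sum(penalties[i].lam * penalties[i].S for i in idxs)
        eigvals, eigvecs = np.linalg.eigh(S_b)
        tol = max(eigvals.max(), 1e-300) * 1e-10
        pos = eigvals > tol
        pinv = (eigvecs[:, pos] / eigvals[pos]) @ eigvecs[:, pos].T
        for i in idxs:
            out[i] = float(np.trace(pinv @ penalties[i].S))
    return out


def _laml(X, y, penalties, family, control, beta0=None):
    """Laplace-approximate restricted marginal likelihood at fixed lambdas
    (binomial, scale 1); used to compare discrete smoothing configurations."""
    beta, H, mu, _ = _pirls(X, y, penalties, family, control, beta0=beta0)
    p = X.shape[1]
    S = _assemble_S(penalties, p)
    lp = _binomial_loglik(y, mu) - 0.5 * float(beta @ S @ beta)
    logdet_s = 0.0
    groups: dict[tuple, list] = {}
    for pen in penalties:
        groups.setdefault((pen.sl.start, pen.sl.stop), []).append(pen)
    for pens in groups.values():
        S_b = sum(pen.lam * pen.S for pen in pens)
        eigvals = np.linalg.eigvalsh(S_b)
        tol = max(eigvals.max(), 1e-300) * 1e-10
        logdet_s += float(np.sum(np.log(eigvals[eigvals > tol])))
    sign, logdet_a = np.linalg.slogdet(H + S)
    return lp + 0.5 * logdet_s - 0.5 * logdet_a, beta


def _polish_shrinkage(X, y, design, control, beta):
    """Greedy per-term check: does pushing a term's lambdas to the cap (term
    effectively removed) improve the restricted likelihood?  Escapes local
    fixed points of the Fellner-Schall iteration on null terms."""
    current, beta = _laml(X, y, design.penalties, "binomial", control, beta0=beta)
    terms = {pen.term for pen in design.penalties}
    for term in sorted(terms):
        saved = [(pen, pen.lam) for pen in design.penalties if pen.term == term]
        if all(lam >= _LAMBDA_MAX for _, lam in saved):
            continue
        for pen, _ in saved:
            pen.lam = _LAMBDA_MAX
        candidate, beta_c = _laml(X, y, design.penalties, "binomial", control, beta0=beta)
        if candidate > current + 1e-6:
            current, beta = candidate, beta_c
        else:
            for pen, lam in saved:
                pen.lam = lam
    return beta


def _null_space_reduction(design: DesignInfo, p: int):
    """Block-diagonal transform onto the null spaces of infinite penalties."""
    blocks = []
    red_slices = {}
    red_penalties: list[_Penalty] = []
    pos = 0
    for name, sl in design.term_slices.items():
        w = sl.stop - sl.start
        inf_pens = [pen for pen in design.penalties
                    if pen.sl.start == sl.start and np.isinf(pen.lam)]
        fin_pens = [pen for pen in design.penalties
                    if pen.sl.start == sl.start and not np.isinf(pen.lam)]
        if inf_pens:
            S_inf = sum(pen.S for pen in inf_pens)
            eigvals, eigvecs = np.linalg.eigh(S_inf)
            tol = max(eigvals.max(), 1.0) * 1e-10
            N = eigvecs[:, eigvals < tol]
        else:
            N = np.eye(w)
        blocks.append(N)
        new_sl = slice(pos, pos + N.shape[1])
        red_slices[name] = new_sl
        for pen in fin_pens:
            red_penalties.append(
                _Penalty(sl=new_sl, S=N.T @ pen.S @ N, label=pen.label,
                         term=pen.term, lam=pen.lam)
            )
        pos += N.shape[1]
    T = np.zeros((p, pos))
    c = 0
    for (name, sl), N in zip(design.term_slices.items(), blocks):
        T[sl, c : c + N.shape[1]] = N
        c += N.shape[1]
    return T, red_slices, red_penalties


def fit_pgam(
    spec: ModelSpec,
    data: pd.DataFrame,
    control: FitControl | None = None,
    fixed_lambda=None,
) -> PgamFit:
    """Fit a penalized additive model; deterministic given data and control.

    ``fixed_lambda`` skips smoothing-parameter selection: a scalar applies to
    every penalty, or pass a dict keyed by penalty label.
    """
    control = control or FitControl()
    n = len(data)
    if n < control.min_n:
        raise ValueError(f"need n >= {control.min_n} observations, got {n}")
    y = np.asarray(data[spec.outcome], dtype=float)
    if spec.family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial outcome must be coded 0/1")
    if spec.family == "binomial" and len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")

    design = build_design(spec, data)
    X = design.build(data, training=True)
    p = X.shape[1]

    for pen in design.penalties:
        pen.lam = control.lambda_init
    if fixed_lambda is not None:
        for pen in design.penalties:
            pen.lam = (
                float(fixed_lambda[pen.label])
                if isinstance(fixed_lambda, dict)
                else float(fixed_lambda)
            )

    # exact lambda -> infinity limit: restrict each block to the null space of
    # its infinitely-penalized penalties (avoids catastrophic conditioning)
    T = None
    if any(np.isinf(pen.lam) for pen in design.penalties):
        T, red_slices, red_penalties = _null_space_reduction(design, p)
        X_full, slices_full, pens_full = X, design.term_slices, design.penalties
        X = X @ T
        design.term_slices = red_slices
        design.penalties = red_penalties
        p = X.shape[1]

    beta = None
    trace: list = []
    outer_used = 0
    phi = 1.0
    if fixed_lambda is not None or not design.penalties:
        beta, H, mu, trace = _pirls(X, y, design.penalties, spec.family, control)
    else:
        for outer in range(1, control.max_outer + 1):
            outer_used = outer
            beta, H, mu, trace = _pirls(
                X, y, design.penalties, spec.family, control, beta0=beta
            )
            S = _assemble_S(design.penalties, p)
            V = _inv_pd(H + S)
            if spec.family == "gaussian":
                edf = float(np.sum(V * H.T))
                phi = float(np.sum((y - mu) ** 2)) / max(n - edf, 1.0)
            t1 = _block_pinv_traces(design.penalties)
            max_change = 0.0
            for i, pen in enumerate(design.penalties):
                t2 = float(np.sum(V[pen.sl, pen.sl] * pen.S.T))
                num = max(t1[i] - t2, 1e-12)
                denom = float(beta[pen.sl] @ pen.S @ beta[pen.sl]) / phi
                ratio = num / denom if denom > 1e-12 else 50.0
                ratio = float(np.clip(ratio, 0.05, 50.0))
                new_lam = float(np.clip(pen.lam * ratio, _LAMBDA_MIN, _LAMBDA_MAX))
                max_change = max(max_change, abs(np.log(new_lam) - np.log(pen.lam)))
                pen.lam = new_lam
            if max_change < control.outer_tol:
                break
        if spec.family == "binomial" and any(
            t.double_penalty for t in spec.smooth_terms
        ):
            beta = _polish_shrinkage(X, y, design, control, beta)
        beta, H, mu, trace = _pirls(
            X, y, design.penalties, spec.family, control, beta0=beta
        )

    if spec.family == "binomial" and np.max(np.abs(beta)) > control.separation_threshold:
        raise SeparationError(
            f"coefficient magnitude {np.max(np.abs(beta)):.1f} exceeds "
            f"{control.separation_threshold}: possible complete separation"
        )

    S = _assemble_S(design.penalties, p)
    V = _inv_pd(H + S)
    edf_vec = np.sum(V * H.T, axis=1)  # diag(V @ H)
    edf_by_term = {
        name: float(np.sum(edf_vec[sl])) for name, sl in design.term_slices.items()
    }
    edf_total = float(np.sum(edf_vec))

    if T is not None:
        # expand back to the full parametrization for prediction/intervals
        beta = T @ beta
        V = T @ V @ T.T
        design.term_slices = slices_full
        design.penalties = pens_full

    if spec.family == "gaussian":
        rss = float(np.sum((y - mu) ** 2))
        phi = rss / max(n - edf_total, 1.0)
        sigma2_ml = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
        deviance = rss
        null_deviance = float(np.sum((y - y.mean()) ** 2))
        aic_val = -2.0 * loglik + 2.0 * (edf_total + 1.0)  # +1 for the scale
    else:
        phi = 1.0
        loglik = _binomial_loglik(y, mu)
        deviance = _binomial_deviance(y, mu)
        ybar = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        null_deviance = _binomial_deviance(y, np.full(n, ybar))
        aic_val = -2.0 * loglik + 2.0 * edf_total

    return PgamFit(
        spec=spec,
        design=design,
        beta=beta,
        Vb=V * phi,
        lambdas={pen.label: pen.lam for pen in design.penalties},
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        loglik=float(loglik),
        aic=float(aic_val),
        deviance=float(deviance),
        null_deviance=float(null_deviance),
        scale=phi,
        fitted=mu,
        y=y,
        n=n,
        pirls_deviance_trace=trace,
        outer_iterations=outer_used,
    )


def aic(fit: PgamFit) -> float:
    """Conditional AIC: -2 log-likelihood + 2 x total effective df."""
    return fit.aic


# ---------------------------------------------------------------------------
# prediction and partial effects
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    fit: np.ndarray          # response scale
    se: np.ndarray           # linear-predictor scale
    eta: np.ndarray
    ci_lo: np.ndarray        # response scale, from +-1.96 se on the link
    ci_hi: np.ndarray


def predict(fit: PgamFit, newdata: pd.DataFrame) -> Prediction:
    X = fit.design.build(newdata)
    eta = X @ fit.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.Vb, X), 0.0))
    lo, hi = eta - 1.96 * se, eta + 1.96 * se
    if fit.spec.family == "binomial":
        resp, rlo, rhi = expit(eta), expit(lo), expit(hi)
    else:
        resp, rlo, rhi = eta, lo, hi
    return Prediction(fit=resp, se=se, eta=eta, ci_lo=rlo, ci_hi=rhi)


@dataclass
class PartialEffect:
    term: str
    grid: np.ndarray
    effect: np.ndarray       # centered, linear-predictor scale
    lo: np.ndarray
    hi: np.ndarray
    significant: bool        # no horizontal line fits inside the band

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.term, "x": self.grid, "effect": self.effect,
             "lo": self.lo, "hi": self.hi}
        )


def partial_effect(fit: PgamFit, term: str, grid_size: int = 100) -> PartialEffect:
    """Centered smooth effect with a pointwise 95% band (univariate terms)."""
    if term not in fit.design.term_bases:
        raise KeyError(f"no smooth term named {term!r}")
    tb = fit.design.term_bases[term]
    if len(tb.spec.covariates) != 1:
        raise ValueError("partial_effect supports univariate smooths")
    sl = fit.design.term_slices[term]
    grid = np.linspace(tb.xmin[0], tb.xmax[0], grid_size)
    G = tb.design(pd.DataFrame({tb.spec.covariates[0]: grid}))
    # the sum-to-zero constraint already centers the term over training rows
    effect = G @ fit.beta[sl]
    Vb = fit.Vb[sl, sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, Vb, G), 0.0))
    lo, hi = effect - 1.96 * se, effect + 1.96 * se
    significant = bool(np.max(lo) > np.min(hi))
    return PartialEffect(term, grid, effect, lo, hi, significant)
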
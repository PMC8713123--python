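"""Smooth-term bases: B-spline design blocks, difference penalties, constraints.

Each smooth term is represented in a constrained basis: the raw B-spline
design (tensor product for bivariate terms) is post-multiplied by a null
space ``Z`` of its training column-sum vector, which absorbs the sum-to-zero
identifiability constraint into the block.  Penalties are transformed
accordingly.  The transform is frozen at build time so the same block can be
evaluated on new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from expowin._bspline import bspline_design, bspline_knots, difference_penalty


@dataclass(frozen=True)
class SmoothTermSpec:
    """Specification of one penalized smooth (1 covariate, or 2 for a surface)."""

    covariates: tuple
    k: int = 10                 # basis size (per margin for bivariate terms)
    penalty_order: int = 2
    double_penalty: bool = False

    def __post_init__(self) -> None:
        covs = tuple(self.covariates) if not isinstance(self.covariates, str) else (self.covariates,)
        object.__setattr__(self, "covariates", covs)
        if len(covs) not in (1, 2):
            raise ValueError("smooth terms take 1 or 2 covariates")
        if self.k < self.penalty_order + 2:
            raise ValueError(
                f"k must be >= penalty_order + 2 (got k={self.k}, order={self.penalty_order})"
            )

    @property
    def name(self) -> str:
        return ":".join(self.covariates)

    def with_double_penalty(self, flag: bool = True) -> "SmoothTermSpec":
        return SmoothTermSpec(self.covariates, self.k, self.penalty_order, flag)


@dataclass
class TermBasis:
    """Frozen design/penalty blocks for one smooth term."""

    spec: SmoothTermSpec
    knots: list            # one knot vector per covariate
    Z: np.ndarray          # raw-basis -> constrained-basis transform
    penalties: list        # constrained penalty matrices (1 or 2, +1 if double)
    penalty_labels: list   # parallel labels, e.g. "age", "lon:lat[1]", "age(null)"
    xmin: np.ndarray
    xmax: np.ndarray

    @property
    def n_coef(self) -> int:
        return self.Z.shape[1]

    def raw_design(self, data: pd.DataFrame) -> np.ndarray:
        mats = []
        for cov, kn in zip(self.spec.covariates, self.knots):
            x = np.asarray(data[cov], dtype=float)
            mats.append(bspline_design(x, kn))
        if len(mats) == 1:
            return mats[0]
        # row-wise tensor product
        n = mats[0].shape[0]
        return np.einsum("ij,ik->ijk", mats[0], mats[1]).reshape(n, -1)

    def design(self, data: pd.DataFrame) -> np.ndarray:
        return self.raw_design(data) @ self.Z


def build_basis(x, spec: SmoothTermSpec):
    """Convenience wrapper: (constrained design block, penalty blocks) for values ``x``.

    ``x`` is a 1-d array for univariate terms or a 2-column array/DataFrame
    for a surface.  Returns ``(X_block, penalties, term_basis)``.
    """
    if isinstance(x, pd.DataFrame):
        data = x
    else:
        arr = np.atleast_2d(np.asarray(x, dtype=float))
        if arr.shape[0] in (1, 2) and arr.shape[0] != len(spec.covariates):
            arr = arr.T if arr.shape[1] == len(spec.covariates) else arr
        if arr.shape[0] == len(spec.covariates):
            arr = arr.T
        data = pd.DataFrame(arr, columns=list(spec.covariates))
    tb = make_term_basis(spec, data)
    return tb.design(data), tb.penalties, tb


def make_term_basis(spec: SmoothTermSpec, data: pd.DataFrame) -> TermBasis:
    knots = []
    raw_penalties = []
    xmin, xmax = [], []
    for cov in spec.covariates:
        x = np.asarray(data[cov], dtype=float)
        if len(np.unique(x)) < spec.k:
            raise ValueError(
                f"{cov}: needs >= {spec.k} distinct values for a k={spec.k} basis"
            )
        lo, hi = float(x.min()), float(x.max())
        knots.append(bspline_knots(lo, hi, spec.k))
        xmin.append(lo)
        xmax.append(hi)
    S1 = difference_penalty(spec.k, spec.penalty_order)
    labels: list[str] = []
    if len(spec.covariates) == 1:
        raw_penalties = [S1]
        labels = [spec.name]
    else:
        S2 = difference_penalty(spec.k, spec.penalty_order)
        eye = np.eye(spec.k)
        raw_penalties = [np.kron(S1, eye), np.kron(eye, S2)]
        labels = [f"{spec.name}[1]", f"{spec.name}[2]"]

    tb = TermBasis(
        spec=spec,
        knots=knots,
        Z=np.empty(0),
        penalties=[],
        penalty_labels=labels,
        xmin=np.asarray(xmin),
        xmax=np.asarray(xmax),
    )
    B = tb.raw_design(data)
    c = B.sum(axis=0)
    Z = null_space(c[None, :])  # (k_total, k_total - 1)
    tb.Z = Z
    tb.penalties = [Z.T @ S @ Z for S in raw_penalties]

    if spec.double_penalty:
        total = sum(tb.penalties)
        eigvals, eigvecs = np.linalg.eigh(total)
        tol = max(eigvals.max(), 1.0) * 1e-9
        null_vecs = eigvecs[:, eigvals < tol]
        if null_vecs.shape[1] > 0:
            tb.penalties.append(null_vecs @ null_vecs.T)
            tb.penalty_labels = labels + [f"{spec.name}(null)"]
    return tb
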
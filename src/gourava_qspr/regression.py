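"""Curve estimation and multiple OLS with the classic SPSS statistics block.

Five single-predictor model forms plus an eight-predictor multiple linear
model, each reported with the full set of summary statistics: correlation
coefficient R (reported as +sqrt(R^2)), R^2, adjusted R^2, standard error
of estimate (SEE), the overall F statistic and its upper-tail p-value.

Forms
-----
linear        Y = a + b1*X
quadratic     Y = a + b1*X + b2*X^2
cubic         Y = a + b1*X + b2*X^2 + b3*X^3
logarithmic   Y = a + b1*ln(X)                (requires X > 0)
exponential   ln(Y) = ln(a) + b1*X            (requires Y > 0)
multiple      Y = a + b1*X1 + ... + bk*Xk

The exponential form is fitted by OLS on ln(Y) and all of its statistics
(R, SEE, F, p) are reported on the log-response scale, matching standard
curve-estimation software; the reported intercept ``a`` is exp(intercept)
so that the model reads Y = a * exp(b1*X).

Statistic identities (all hold exactly, by construction):

    R      = +sqrt(R^2)
    adjR^2 = 1 - (1 - R^2) (n - 1) / (n - k - 1)
    SEE    = sqrt(RSS / (n - k - 1))
    F      = (R^2 / k) / ((1 - R^2) / (n - k - 1))
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CURVE_FORMS",
    "MODEL_FORMS",
    "RegressionFit",
    "DegreesOfFreedomError",
    "DomainError",
    "RankError",
    "fit_curve",
    "fit_multiple",
    "f_pvalue",
    "format_p",
]

logger = logging.getLogger(__name__)

CURVE_FORMS = ("linear", "quadratic", "cubic", "logarithmic", "exponential")
MODEL_FORMS = CURVE_FORMS + ("multiple",)

#: Number of non-intercept predictors per single-x form.
_FORM_K = {"linear": 1, "quadratic": 2, "cubic": 3, "logarithmic": 1, "exponential": 1}

#: Condition number above which fit_multiple logs an ill-conditioning warning.
ILL_CONDITIONED = 1e8


class DegreesOfFreedomError(ValueError):
    """Too few observations for the requested number of predictors."""


class DomainError(ValueError):
    """Predictor or response outside the domain of the requested form."""


class RankError(ValueError):
    """Exactly collinear design matrix."""


@dataclass(frozen=True)
class RegressionFit:
    """One fitted model with its coefficient vector and statistics.

    ``coefficients`` holds (b1, ..., bk), excluding the intercept.  For the
    exponential form ``intercept`` is exp of the fitted log-intercept and
    ``see``/``r``/... refer to the log-response scale.  ``degenerate`` marks
    a constant response, for which correlation is undefined and R is
    reported as 0.
    """

    form: str
    intercept: float
    coefficients: tuple[float, ...]
    n: int
    k: int
    r: float
    r2: float
    adj_r2: float
    see: float
    f: float
    p: float
    response_scale: str = "linear"
    degenerate: bool = False
    condition_number: float | None = None

    def predict(self, x) -> np.ndarray:
        """Model prediction on the original response scale.

        ``x`` is a vector for single-predictor forms and an (n, k) matrix
        for the multiple form.
        """
        x = np.asarray(x, dtype=float)
        b = np.asarray(self.coefficients)
        if self.form == "multiple":
            return self.intercept + x @ b
        if self.form == "logarithmic":
            return self.intercept + b[0] * np.log(x)
        if self.form == "exponential":
            return self.intercept * np.exp(b[0] * x)
        powers = np.arange(1, len(b) + 1)
        return self.intercept + (x[:, None] ** powers) @ b


def _design(x: np.ndarray, form: str) -> np.ndarray:
    ones = np.ones_like(x)
    if form == "linear" or form == "exponential":
        return np.column_stack([ones, x])
    if form == "quadratic":
        return np.column_stack([ones, x, x ** 2])
    if form == "cubic":
        return np.column_stack([ones, x, x ** 2, x ** 3])
    if form == "logarithmic":
        return np.column_stack([ones, np.log(x)])
    raise ValueError(f"unknown model form {form!r}; expected one of {CURVE_FORMS}")


#: Relative singular-value cutoff below which a (column-normalized) design
#: is treated as *exactly* collinear.  Deliberately tiny: polynomial designs
#: in raw powers of large predictors are legitimately ill-conditioned and
#: must still fit; only true duplicates (e.g. a constant predictor next to
#: the intercept) should trip this.
_COLLINEARITY_RTOL = 1e-12


def _normalize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    return X / norms, norms


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    Xs, _ = _normalize_columns(X)
    s = np.linalg.svd(Xs, compute_uv=False)
    if s[-1] > _COLLINEARITY_RTOL * s[0]:
        return
    # walk the columns to name the first one that adds no rank
    def _rank(M):
        sv = np.linalg.svd(M, compute_uv=False)
        return int(np.sum(sv > _COLLINEARITY_RTOL * sv[0]))

    for j in range(1, X.shape[1]):
        if _rank(Xs[:, : j + 1]) == _rank(Xs[:, :j]):
            raise RankError(f"design matrix is exactly collinear at column {labels[j]!r}")
    raise RankError("design matrix is rank deficient")


def _solve_scaled(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares via a column-normalized design (scale-robust)."""
    Xs, norms = _normalize_columns(X)
    beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    return beta / norms


def _statistics(form, beta, X, y, *, response_scale, cond=None) -> RegressionFit:
    n = len(y)
    k = X.shape[1] - 1
    yhat = X @ beta
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    see = math.sqrt(rss / (n - k - 1))
    if tss <= 0.0:
        # constant response: correlation undefined, flag and report 0
        return RegressionFit(form, float(beta[0]), tuple(map(float, beta[1:])), n, k,
                             0.0, 0.0, 0.0, see, 0.0, 1.0,
                             response_scale=response_scale, degenerate=True,
                             condition_number=cond)
    r2 = 1.0 - rss / tss
    r2 = min(max(r2, 0.0), 1.0)  # guard numerical round-off at the edges
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    if r2 < 1.0:
        f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
        p = f_pvalue(f, k, n)
    else:
        f, p = math.inf, 0.0
    intercept = float(beta[0])
    coefs = tuple(map(float, beta[1:]))
    if form == "exponential":
        intercept = math.exp(intercept)
    return RegressionFit(form, intercept, coefs, n, k, math.sqrt(r2), r2, adj, see,
                         f, p, response_scale=response_scale,
                         condition_number=cond)


def fit_curve(x, y, form: str) -> RegressionFit:
    """Ordinary least squares of ``y`` on one predictor under ``form``.

    Raises :class:`DegreesOfFreedomError` when n < k + 2,
    :class:`DomainError` for non-positive x (logarithmic) or y
    (exponential), and :class:`RankError` for an exactly collinear design.
    """
    if form not in CURVE_FORMS:
        raise ValueError(f"unknown model form {form!r}; expected one of {CURVE_FORMS}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"x and y length mismatch: {x.shape[0]} != {y.shape[0]}")
    k = _FORM_K[form]
    n = len(x)
    if n < k + 2:
        raise DegreesOfFreedomError(
            f"{form} needs at least {k + 2} observations, got {n}"
        )
    if form == "logarithmic" and np.any(x <= 0):
        raise DomainError("logarithmic form requires all x > 0")
    if form == "exponential" and np.any(y <= 0):
        raise DomainError("exponential form requires all y > 0")
    y_used = np.log(y) if form == "exponential" else y
    X = _design(x, form)
    labels = ["intercept"] + [f"x^{j}" for j in range(1, X.shape[1])]
    if form == "logarithmic":
        labels[1] = "ln(x)"
    _check_rank(X, labels)
    beta = _solve_scaled(X, y_used)
    scale = "log" if form == "exponential" else "linear"
    return _statistics(form, beta, X, y_used, response_scale=scale)


def fit_multiple(X, y, labels=None) -> RegressionFit:
    """Multiple linear OLS of ``y`` on the columns of ``X`` (plus intercept).

    Uses the minimum-norm least-squares solution (Moore-Penrose
    pseudo-inverse), so a severely collinear design — routine when several
    related graph indices are used jointly — yields a well-defined fit; the
    design's condition number is recorded on the result and logged as a
    warning when it exceeds ``ILL_CONDITIONED``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix of predictor columns")
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if len(y) != n:
        raise ValueError(f"X and y length mismatch: {n} != {len(y)}")
    if n < k + 2:
        raise DegreesOfFreedomError(
            f"multiple regression with k={k} needs at least {k + 2} observations "
            f"(adjusted R^2 and F are undefined otherwise), got {n}"
        )
    design = np.column_stack([np.ones(n), X])
    cond = float(np.linalg.cond(design))
    if cond > ILL_CONDITIONED:
        logger.warning(
            "ill-conditioned multiple-regression design (condition number %.3g)", cond
        )
    Xs, norms = _normalize_columns(design)
    beta = (np.linalg.pinv(Xs) @ y) / norms
    return _statistics("multiple", beta, design, y, response_scale="linear", cond=cond)


def f_pvalue(f: float, k: int, n: int) -> float:
    """Upper-tail probability of F(k, n - k - 1) at the observed statistic."""
    if k < 1 or n <= k + 1:
        raise DegreesOfFreedomError(f"invalid degrees of freedom: k={k}, n={n}")
    if f < 0:
        raise ValueError(f"F statistic must be non-negative, got {f}")
    return float(_sps.f.sf(f, k, n - k - 1))


def format_p(p: float) -> str:
    """Render a p-value the way regression tables print it."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"
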
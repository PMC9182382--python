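"""Multiple linear regression with a complete validation-statistic block.

This is the modelling core: ordinary least squares of one endpoint on a
small set of descriptors, reported the way chemometric QSAR practice
expects —

* coefficients with standard errors (unbiased residual variance,
  denominator n - k - 1),
* the multiple correlation coefficient R = sqrt(1 - SSE/SST) and its
  adjusted counterpart,
* residual standard deviation sd with sd^2 equal to the residual mean
  square MSE,
* the overall F statistic, equal to (R^2/k) / ((1-R^2)/(n-k-1)), with its
  p-value,
* hat-matrix leverages h_ii,
* leave-one-out PRESS via the hat-matrix shortcut
  PRESS = sum_i (e_i / (1 - h_ii))^2,
* variance inflation factors VIF_j = 1/(1 - R_j^2),
* standardized (dimensionless) coefficients beta_j = b_j s_xj / s_y.

Estimation is delegated to :mod:`statsmodels`; the validation block is
assembled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import CompoundTable
from .exceptions import (
    DegenerateColumnError,
    DegenerateModelError,
    InsufficientDataError,
    LeverageOneError,
    SingularDesignError,
)

__all__ = [
    "RegressionSpec",
    "QSARModel",
    "QSARResults",
    "QuadraticResults",
    "fit_ols",
    "loo_press",
    "vif",
    "standardized_coefficients",
    "quadratic_fit",
]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class RegressionSpec:
    """Which endpoint is regressed on which descriptors."""

    response_name: str
    predictor_names: tuple[str, ...]
    include_intercept: bool = True

    def __post_init__(self) -> None:
        preds = tuple(self.predictor_names)
        object.__setattr__(self, "predictor_names", preds)
        if not preds:
            raise ValueError("predictor_names must be non-empty")
        if len(set(preds)) != len(preds):
            raise ValueError("duplicate predictor names")
        if self.response_name in preds:
            raise ValueError("response cannot also be a predictor")


@dataclass
class QSARResults:
    """Fitted linear model with the full validation-statistic block."""

    response_name: str
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray        # intercept first
    standard_errors: np.ndarray
    n: int
    k: int
    R: float
    R_adj: float
    sd: float
    F: float
    p_value: float
    sse: float
    sst: float
    MSE: float
    PRESS: float
    PRESS_cv: float
    MSE_cv: float
    fitted: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    standardized_coefficients: np.ndarray
    vif: np.ndarray
    _x: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    def predict(self, data: pd.DataFrame | CompoundTable) -> np.ndarray:
        frame = data.frame if isinstance(data, CompoundTable) else data
        X = np.column_stack(
            [frame[c].to_numpy(dtype=float) for c in self.predictor_names]
        )
        return self.intercept + X @ self.slopes

    def applicability_domain(self, residual_limit: float = 3.0,
                             studentized: bool = False):
        """Leverage/residual applicability-domain assessment (Williams plot)."""
        from .domain import assess_domain

        return assess_domain(self, residual_limit=residual_limit,
                             studentized=studentized)

    def equation(self, digits: int = 3) -> str:
        """One-line equation with standard errors in parentheses."""
        terms = [f"{self.coefficients[0]:.{digits}f}"
                 f"({self.standard_errors[0]:.{digits}f})"]
        for b, se, name in zip(self.coefficients[1:],
                               self.standard_errors[1:],
                               self.predictor_names):
            sign = "-" if b < 0 else "+"
            terms.append(f"{sign} {abs(b):.{digits}f}({se:.{digits}f}) {name}")
        return f"{self.response_name} = " + " ".join(terms)

    def summary(self) -> str:
        lines = [
            self.equation(),
            f"n = {self.n}; R = {self.R:.4f}; R_adj = {self.R_adj:.4f}; "
            f"sd = {self.sd:.4g}; F = {self.F:.1f}; p = {self.p_value:.2g}",
            f"PRESS = {self.PRESS:.4g}; MSE = {self.MSE:.4g}; "
            f"max VIF = {np.max(self.vif):.2f}",
            "standardized coefficients: "
            + ", ".join(f"{name}: {b:.3f}" for name, b in
                        zip(self.predictor_names,
                            self.standardized_coefficients)),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "predictors": list(self.predictor_names),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "n": self.n,
            "k": self.k,
            "R": self.R,
            "R_adj": self.R_adj,
            "sd": self.sd,
            "F": self.F,
            "p_value": self.p_value,
            "PRESS": self.PRESS,
            "MSE": self.MSE,
            "PRESS_cv": self.PRESS_cv,
            "MSE_cv": self.MSE_cv,
            "vif": self.vif.tolist(),
            "standardized_coefficients":
                self.standardized_coefficients.tolist(),
            "leverages": self.leverages.tolist(),
            "residuals": self.residuals.tolist(),
        }


class QSARModel:
    """OLS regression of one endpoint on descriptor columns.

    Parameters
    ----------
    table
        Source table; descriptor and endpoint columns are pulled by name
        (missing values fail loudly).
    spec
        Response / predictor column selection.
    """

    def __init__(self, table: CompoundTable, spec: RegressionSpec):
        self.table = table
        self.spec = spec

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str,
                       predictors: list[str] | tuple[str, ...]) -> "QSARModel":
        preds = tuple(predictors)
        ids = tuple(c for c in ("compound_id", "group")
                    if c in frame.columns)
        keep = list(ids) + list(preds) + [response]
        table = CompoundTable(frame[keep].copy(), descriptor_names=preds,
                              endpoint_names=(response,),
                              identifier_names=ids)
        return cls(table, RegressionSpec(response, preds))

    def fit(self) -> QSARResults:
        spec = self.spec
        y = self.table.column(spec.response_name)
        X = np.column_stack([self.table.column(c)
                             for c in spec.predictor_names])
        return _fit_core(y, X, spec.response_name, spec.predictor_names)


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _dependent_columns(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Predictors (near-)perfectly explained by the remaining ones."""
    bad = []
    for j, name in enumerate(names):
        others = np.delete(X, j, axis=1)
        A = _design(others)
        xj = X[:, j]
        coef, *_ = np.linalg.lstsq(A, xj, rcond=None)
        resid = xj - A @ coef
        denom = np.sum((xj - xj.mean()) ** 2)
        if denom == 0 or np.sum(resid**2) <= _RANK_TOL * max(denom, 1.0):
            bad.append(name)
    return bad


def _fit_core(y: np.ndarray, X: np.ndarray, response: str,
              names: tuple[str, ...]) -> QSARResults:
    n, k = X.shape
    if n <= k + 1:
        raise InsufficientDataError(
            f"n = {n} observations cannot support {k} predictors "
            "plus an intercept with a residual degree of freedom"
        )
    A = _design(X)
    if np.linalg.matrix_rank(A, tol=None) < A.shape[1]:
        culprits = _dependent_columns(X, names)
        raise SingularDesignError(
            "design matrix is rank deficient"
            + (f"; dependent columns: {culprits}" if culprits else "")
        )

    ols = sm.OLS(y, A).fit()
    coef = np.asarray(ols.params, dtype=float)
    se = np.asarray(ols.bse, dtype=float)
    resid = np.asarray(ols.resid, dtype=float)
    fitted = np.asarray(ols.fittedvalues, dtype=float)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, 1.0 - sse / sst) if sst > 0 else 1.0
    R = float(np.sqrt(r2))
    radj2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    R_adj = float(np.sqrt(max(0.0, radj2)))
    mse = sse / (n - k - 1)
    sd = float(np.sqrt(mse))

    # leverages from the thin-QR factor of the design matrix
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q**2, axis=1)

    # PRESS is NaN when an observation is self-determining (h_ii = 1);
    # loo_press() raises explicitly in that case
    if np.any(h >= 1.0 - 1e-12):
        press = float("nan")
    else:
        press = _press_from_hat(resid, h)

    sy = float(np.std(y, ddof=1))
    std_coef = np.empty(k)
    for j in range(k):
        sx = float(np.std(X[:, j], ddof=1))
        if sx == 0:
            raise DegenerateColumnError(
                f"predictor {names[j]!r} has zero sample variance"
            )
        std_coef[j] = coef[j + 1] * sx / sy if sy > 0 else np.nan

    return QSARResults(
        response_name=response,
        predictor_names=tuple(names),
        coefficients=coef,
        standard_errors=se,
        n=n,
        k=k,
        R=R,
        R_adj=R_adj,
        sd=sd,
        F=float(ols.fvalue),
        p_value=float(ols.f_pvalue),
        sse=sse,
        sst=sst,
        MSE=float(mse),
        PRESS=press,
        PRESS_cv=press,
        MSE_cv=press / n,
        fitted=fitted,
        residuals=resid,
        leverages=h,
        standardized_coefficients=std_coef,
        vif=_vif_matrix(X),
        _x=X,
        _y=np.asarray(y, dtype=float),
    )


def _press_from_hat(resid: np.ndarray, leverages: np.ndarray) -> float:
    if np.any(leverages >= 1.0 - 1e-12):
        raise LeverageOneError(
            "an observation has leverage 1; its deleted prediction is "
            "undefined"
        )
    return float(np.sum((resid / (1.0 - leverages)) ** 2))


def _vif_matrix(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R_j^2) from auxiliary regressions; inf on perfect
    collinearity (sentinel, not an exception)."""
    n, k = X.shape
    if k < 2:
        return np.ones(k)
    out = np.empty(k)
    for j in range(k):
        xj = X[:, j]
        A = _design(np.delete(X, j, axis=1))
        coefs, *_ = np.linalg.lstsq(A, xj, rcond=None)
        resid = xj - A @ coefs
        sst_j = float(np.sum((xj - xj.mean()) ** 2))
        sse_j = float(resid @ resid)
        if sst_j == 0:
            out[j] = np.inf
            continue
        r2_j = 1.0 - sse_j / sst_j
        out[j] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return out


# -- functional surface ----------------------------------------------------

def fit_ols(table: CompoundTable, spec: RegressionSpec) -> QSARResults:
    """Fit an intercept OLS model of ``spec.response_name`` on
    ``spec.predictor_names`` over ``table``."""
    return QSARModel(table, spec).fit()


def loo_press(model: QSARResults) -> tuple[float, float]:
    """Leave-one-out PRESS and the cross-validated mean square PRESS/n.

    Uses the hat-matrix identity e_i,loo = e_i / (1 - h_ii); equal to an
    explicit delete-one refit loop for any full-rank design.
    """
    press = _press_from_hat(model.residuals, model.leverages)
    return press, press / model.n


def vif(table: CompoundTable, predictor_names) -> np.ndarray:
    """Variance inflation factors for a predictor set.

    VIF_j = 1/(1 - R_j^2), R_j^2 from regressing predictor j on the others
    (with intercept).  Perfect collinearity yields ``inf``.
    """
    names = tuple(predictor_names)
    if len(names) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = np.column_stack([table.column(c) for c in names])
    return _vif_matrix(X)


def standardized_coefficients(model: QSARResults,
                              table: CompoundTable | None = None,
                              ) -> np.ndarray:
    """Dimensionless effect sizes beta_j = b_j * s_xj / s_y (ddof = 1).

    ``table`` is accepted for symmetry with the other operations but the
    fitted design stored on the results is authoritative.
    """
    return model.standardized_coefficients


@dataclass
class QuadraticResults:
    """Parabolic fit y = a + b x + c x^2 with its multiple correlation."""

    a: float
    b: float
    c: float
    R: float
    ols: QSARResults = field(repr=False)

    @property
    def vertex(self) -> float | None:
        """Stationary point -b/(2c): the descriptor value of extremal
        response (an optimal-lipophilicity location when c < 0 maximises,
        c > 0 minimises)."""
        return None if self.c == 0 else -self.b / (2.0 * self.c)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b * x + self.c * x**2

    def derivative(self, x: float) -> float:
        return self.b + 2.0 * self.c * x


def quadratic_fit(x, y) -> QuadraticResults:
    """OLS parabola through (x, y); reduces to the linear engine on the
    design (x, x^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("quadratic fit needs at least 4 points")
    if len(np.unique(x)) < 3:
        raise SingularDesignError(
            "quadratic fit needs at least 3 distinct x values"
        )
    res = _fit_core(y, np.column_stack([x, x**2]), "y", ("x", "x2"))
    return QuadraticResults(a=float(res.coefficients[0]),
                            b=float(res.coefficients[1]),
                            c=float(res.coefficients[2]),
                            R=res.R, ols=res)
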
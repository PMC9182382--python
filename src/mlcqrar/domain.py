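"""Applicability-domain assessment from leverages (Williams plot contents).

A regression model should only be trusted inside the descriptor-space
region it was trained on.  The standard leverage-based assessment plots
standardized residuals against hat-matrix leverages h_ii and flags

* structural outliers: h_ii above the warning leverage h* = 3(k+1)/n,
* response outliers: |standardized residual| above a band (default 3).

With n = 15 compounds and k = 4 descriptors, h* = 1.0 — the theoretical
upper bound of a leverage — so no compound can be a structural outlier in
the study-sized models; the model is valid across its whole training
domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .exceptions import DegenerateModelError
from .regression import QSARResults

__all__ = ["warning_leverage", "assess_domain", "ADAssessment"]


def warning_leverage(k: int, n: int) -> float:
    """Warning leverage h* = 3(k+1)/n.

    ``k`` is the number of descriptors in the model and ``n`` the number
    of compounds.  Computed in exact rational arithmetic before float
    conversion so that e.g. (4, 15) yields exactly 1.0.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(Fraction(3 * (k + 1), n))


@dataclass
class ADAssessment:
    """Leverages, standardized residuals and outlier flags for one model."""

    compound_ids: np.ndarray
    leverages: np.ndarray
    std_residuals: np.ndarray
    h_star: float
    residual_limit: float
    studentized: bool

    @property
    def leverage_outliers(self) -> list:
        return self.compound_ids[self.leverages > self.h_star].tolist()

    @property
    def residual_outliers(self) -> list:
        mask = np.abs(self.std_residuals) > self.residual_limit
        return self.compound_ids[mask].tolist()

    @property
    def in_domain(self) -> np.ndarray:
        return ((self.leverages <= self.h_star)
                & (np.abs(self.std_residuals) <= self.residual_limit))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound_id": self.compound_ids,
            "leverage": self.leverages,
            "std_residual": self.std_residuals,
            "in_domain": self.in_domain,
        })

    def summary(self) -> str:
        lines = [
            f"Applicability domain: h* = {self.h_star:.4g}, "
            f"residual band = +/-{self.residual_limit:g}",
            f"  leverage outliers (h > h*): "
            f"{self.leverage_outliers or 'none'}",
            f"  residual outliers (|r| > {self.residual_limit:g}): "
            f"{self.residual_outliers or 'none'}",
        ]
        return "\n".join(lines)


def assess_domain(model: QSARResults, residual_limit: float = 3.0,
                  studentized: bool = False,
                  compound_ids=None) -> ADAssessment:
    """Assess which training observations lie inside the model's domain.

    Standardized residuals are e_i / sd by default (plain standardization);
    ``studentized=True`` switches to the internally studentized form
    e_i / (sd * sqrt(1 - h_ii)).

    Raises
    ------
    DegenerateModelError
        If the residual standard deviation is zero (perfect fit).
    """
    if model.sd == 0 or model.sse <= 1e-12 * max(model.sst,
                                                 np.finfo(float).tiny):
        raise DegenerateModelError(
            "residual sd is zero (perfect fit); standardized residuals "
            "undefined"
        )
    h = model.leverages
    if studentized:
        std_resid = model.residuals / (model.sd * np.sqrt(1.0 - h))
    else:
        std_resid = model.residuals / model.sd
    if compound_ids is None:
        compound_ids = np.arange(1, model.n + 1)
    return ADAssessment(
        compound_ids=np.asarray(compound_ids),
        leverages=h,
        std_residuals=std_resid,
        h_star=warning_leverage(model.k, model.n),
        residual_limit=residual_limit,
        studentized=studentized,
    )
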
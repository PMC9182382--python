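"""Property screens and univariate retention-activity relationships.

Two kinds of desk screening around the regression engine:

* Lipinski rule-of-five style threshold flags per compound (log P <= 5,
  MW <= 500 g/mol, HBA <= 10, HBD <= 5) plus the polarity/flexibility and
  distribution checks used for pesticide-likeness (TPSA < 90 A^2,
  2 <= NRB <= 5, V_d < 7 L/kg).
* Univariate retention-activity fits: straight lines of endpoints on a
  micellar lipophilicity descriptor, group-wise lipophilicity calibrations,
  and parabolic fits for the endpoints that peak or trough at intermediate
  lipophilicity (V_d, plant-cuticle partitioning, unbound fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CompoundTable
from .exceptions import InsufficientDataError
from .regression import (
    QSARModel,
    QSARResults,
    QuadraticResults,
    RegressionSpec,
    quadratic_fit,
)

__all__ = [
    "ScreenReport",
    "rule_of_five_screen",
    "groupwise_linear",
    "qrar_suite",
    "QRARFit",
    "LINEAR_QRAR_ENDPOINTS",
    "QUADRATIC_QRAR_ENDPOINTS",
]

#: endpoints that vary linearly with the lipophilicity descriptors
LINEAR_QRAR_ENDPOINTS = ("log_Ksc", "log_PwHSA")
#: endpoints with a parabolic lipophilicity dependence
QUADRATIC_QRAR_ENDPOINTS = ("Vd", "log_Pwpc", "fu_brain", "fu_plasma")

#: (column, flag name, predicate) — boundary semantics follow the usual
#: phrasing: "not greater than" is <=, "below" is strict <.
_SCREEN_RULES = (
    ("log_P", "ro5_logP_ok", lambda v: v <= 5.0),
    ("MW", "ro5_MW_ok", lambda v: v <= 500.0),
    ("HBA", "ro5_HBA_ok", lambda v: v <= 10),
    ("HBD", "ro5_HBD_ok", lambda v: v <= 5),
    ("TPSA", "tpsa_ok", lambda v: v < 90.0),
    ("NRB", "nrb_in_range", lambda v: 2 <= v <= 5),
    ("Vd", "vd_moderate", lambda v: v < 7.0),
)


@dataclass
class ScreenReport:
    """Per-compound threshold flags and summary pass counts."""

    flags: pd.DataFrame  # indexed by compound_id, one bool column per flag

    @property
    def summary_counts(self) -> pd.Series:
        """Number of compounds passing each flag."""
        return self.flags.sum(axis=0)

    def failing(self, flag: str) -> list[int]:
        """Compound ids failing one flag."""
        return self.flags.index[~self.flags[flag]].tolist()

    def all_pass(self, flag: str) -> bool:
        return bool(self.flags[flag].all())

    def to_frame(self) -> pd.DataFrame:
        return self.flags.reset_index()


def rule_of_five_screen(table: CompoundTable) -> ScreenReport:
    """Apply the drug/pesticide-likeness threshold flags to every compound.

    Deterministic: each flag is a pure threshold function of one field.
    Missing descriptor values raise :class:`MissingFieldError` naming the
    column and rows.
    """
    ids = table.column("compound_id").astype(int)
    out = {}
    for column, flag, predicate in _SCREEN_RULES:
        values = table.column(column)
        out[flag] = np.array([bool(predicate(v)) for v in values])
    frame = pd.DataFrame(out, index=pd.Index(ids, name="compound_id"))
    return ScreenReport(frame)


def groupwise_linear(table: CompoundTable, x: str, y: str,
                     group_by: str = "group") -> dict[str, QSARResults]:
    """One single-predictor OLS fit of ``y`` on ``x`` per group label."""
    results: dict[str, QSARResults] = {}
    labels = table.frame[group_by]
    for label in pd.unique(labels):
        sub = table.subset((labels == label).to_numpy())
        if len(sub) < 3:
            raise InsufficientDataError(
                f"group {label!r} has only {len(sub)} members; "
                "need at least 3 for a straight-line fit"
            )
        results[str(label)] = QSARModel(sub, RegressionSpec(y, (x,))).fit()
    return results


@dataclass
class QRARFit:
    """One endpoint's retention-activity relationship."""

    endpoint: str
    form: str  # "linear" | "quadratic"
    fit: QSARResults | QuadraticResults

    @property
    def R(self) -> float:
        return self.fit.R


def qrar_suite(table: CompoundTable, descriptor: str) -> list[QRARFit]:
    """Fit the full univariate retention-activity suite for one descriptor.

    ``descriptor`` must be one of the micellar lipophilicity descriptors
    (log_km or log_KAM).  Dermal absorption (log_Ksc) and water/albumin
    partitioning (log_PwHSA) are fitted as straight lines; V_d, the
    plant-cuticle partition coefficient and the unbound fractions as
    parabolas, whose vertex locates the extremal-response lipophilicity.
    """
    if descriptor not in ("log_km", "log_KAM"):
        raise ValueError(
            f"descriptor must be log_km or log_KAM, got {descriptor!r}"
        )
    x = table.column(descriptor)
    fits: list[QRARFit] = []
    for endpoint in LINEAR_QRAR_ENDPOINTS:
        res = QSARModel(table, RegressionSpec(endpoint, (descriptor,))).fit()
        fits.append(QRARFit(endpoint, "linear", res))
    for endpoint in QUADRATIC_QRAR_ENDPOINTS:
        res = quadratic_fit(x, table.column(endpoint))
        fits.append(QRARFit(endpoint, "quadratic", res))
    return fits
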
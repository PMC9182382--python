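"""Micellar-retention model: estimating k_m and K_AM from retention series.

In micellar liquid chromatography the retention factor k of a solute
decreases with the micellar concentration [M] (total surfactant minus the
critical micellization concentration) according to

    1/k = 1/k_m + (K_AM / k_m) [M]

where k_m is the retention parameter extrapolated to zero micellar
concentration and K_AM the solute-micelle binding constant (L/mol).  Both
are evaluated from the slope and intercept of the straight line 1/k vs [M]:
k_m = 1/intercept and K_AM = slope/intercept.  log10 k_m and log10 K_AM
serve as lipophilicity descriptors.

The fit is unweighted ordinary least squares in reciprocal space, the
classical evaluation route for this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import (
    BelowCmcError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidFitError,
    ValidationError,
)

__all__ = [
    "micellar_concentration",
    "RetentionSeries",
    "FoleyModel",
    "FoleyResults",
    "fit_foley",
]


def micellar_concentration(total_surfactant: float, cmc: float) -> float:
    """Micellar (pseudophase) concentration: total surfactant minus cmc.

    Raises
    ------
    BelowCmcError
        If the total surfactant concentration is below the cmc — no
        micellar pseudophase exists and the retention model does not apply.
    """
    if cmc < 0:
        raise ValidationError("cmc must be non-negative")
    if total_surfactant < cmc:
        raise BelowCmcError(
            f"total surfactant {total_surfactant} mol/L is below the "
            f"cmc {cmc} mol/L; no micellar pseudophase"
        )
    return total_surfactant - cmc


@dataclass
class RetentionSeries:
    """Retention factors of one solute across micellar concentrations.

    ``concentrations`` are micellar concentrations [M] in mol/L (already
    cmc-corrected); ``cmc`` is carried as metadata only.  The series is
    stored sorted by concentration.
    """

    concentrations: np.ndarray
    k_values: np.ndarray
    cmc: float | None = None
    solute_id: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        k = np.asarray(self.k_values, dtype=float)
        if c.ndim != 1 or k.ndim != 1 or len(c) != len(k):
            raise ValidationError(
                "concentrations and k_values must be 1-d and equal length"
            )
        if len(c) < 3:
            raise InsufficientDataError(
                f"need at least 3 points to fit two parameters, got {len(c)}"
            )
        if np.any(k <= 0):
            raise ValidationError("retention factors must be positive")
        if np.any(c < 0):
            raise ValidationError("micellar concentrations must be >= 0")
        if len(np.unique(c)) < 2:
            raise DegenerateDesignError(
                "need at least two distinct micellar concentrations"
            )
        order = np.argsort(c, kind="stable")
        self.concentrations = c[order]
        self.k_values = k[order]

    @classmethod
    def from_total_surfactant(cls, totals, k_values, cmc: float,
                              solute_id: str | None = None,
                              ) -> "RetentionSeries":
        """Build a series from total surfactant concentrations and the cmc."""
        m = [micellar_concentration(t, cmc) for t in np.asarray(totals, float)]
        return cls(np.asarray(m), np.asarray(k_values, float), cmc=cmc,
                   solute_id=solute_id)


@dataclass
class FoleyResults:
    """Fitted retention model for one solute.

    ``km = 1/intercept`` and ``KAM = slope/intercept`` hold by construction.
    ``log_KAM`` is NaN when KAM <= 0 (possible on noisy data; the fit is
    then flagged via ``binding_nonpositive`` rather than rejected).
    """

    km: float
    KAM: float
    log_km: float
    log_KAM: float
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    r: float
    series: RetentionSeries = field(repr=False)

    @property
    def binding_nonpositive(self) -> bool:
        """True when the estimated binding constant is not positive."""
        return self.KAM <= 0

    def predict(self, M) -> np.ndarray:
        """Predicted retention factor at micellar concentration(s) M."""
        M = np.asarray(M, dtype=float)
        return self.km / (1.0 + self.KAM * M)

    def summary(self) -> str:
        sid = self.series.solute_id or "solute"
        lines = [
            f"Retention model fit: {sid}",
            f"  k_m    = {self.km:.6g}   (log10: {self.log_km:.4f})",
            f"  K_AM   = {self.KAM:.6g} L/mol"
            + ("" if self.binding_nonpositive
               else f"   (log10: {self.log_KAM:.4f})"),
            f"  1/k = {self.intercept:.6g} ({self.intercept_se:.2g}) "
            f"+ {self.slope:.6g} ({self.slope_se:.2g}) [M]",
            f"  r = {self.r:.4f}   n = {len(self.series.k_values)}",
        ]
        if self.binding_nonpositive:
            lines.append("  warning: K_AM <= 0; log K_AM undefined")
        return "\n".join(lines)


class FoleyModel:
    """Reciprocal-space regression estimator for one retention series.

    ``fit()`` regresses y = 1/k on x = [M] by unweighted OLS and converts
    the line back to (k_m, K_AM).
    """

    def __init__(self, series: RetentionSeries):
        self.series = series

    def fit(self) -> FoleyResults:
        x = self.series.concentrations
        y = 1.0 / self.series.k_values
        res = stats.linregress(x, y)
        intercept, slope = float(res.intercept), float(res.slope)
        if intercept <= 0:
            raise InvalidFitError(
                f"reciprocal regression intercept {intercept:.4g} <= 0; "
                "k_m undefined"
            )
        km = 1.0 / intercept
        kam = slope / intercept
        with np.errstate(divide="ignore", invalid="ignore"):
            log_kam = float(np.log10(kam)) if kam > 0 else float("nan")
        return FoleyResults(
            km=km,
            KAM=kam,
            log_km=float(np.log10(km)),
            log_KAM=log_kam,
            intercept=intercept,
            slope=slope,
            intercept_se=float(res.intercept_stderr),
            slope_se=float(res.stderr),
            r=float(res.rvalue),
            series=self.series,
        )


def fit_foley(series: RetentionSeries) -> FoleyResults:
    """Convenience wrapper: ``FoleyModel(series).fit()``."""
    return FoleyModel(series).fit()
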
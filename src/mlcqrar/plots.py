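"""Optional matplotlib views of fitted models.

Numbers, not figures, are the package's primary output; these helpers
reproduce the three standard QSAR panels — standardized-coefficient bars,
actual-vs-predicted response, and the Williams plot — for inspection.
"""

from __future__ import annotations

import numpy as np

from .domain import ADAssessment
from .regression import QSARResults

__all__ = ["standardized_coefficient_bars", "response_plot", "williams_plot"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def standardized_coefficient_bars(results: QSARResults, ax=None):
    """Bar chart of dimensionless standardized coefficients."""
    ax = _get_ax(ax)
    names = results.predictor_names
    ax.bar(range(len(names)), results.standardized_coefficients)
    ax.set_xticks(range(len(names)), names)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_ylabel("standardized coefficient")
    ax.set_title(results.response_name)
    return ax


def response_plot(results: QSARResults, ax=None):
    """Actual vs predicted response with the identity line."""
    ax = _get_ax(ax)
    y = results.fitted + results.residuals
    ax.scatter(y, results.fitted)
    lo, hi = float(np.min(y)), float(np.max(y))
    ax.plot([lo, hi], [lo, hi], color="grey", linewidth=0.8)
    ax.set_xlabel(f"actual {results.response_name}")
    ax.set_ylabel(f"predicted {results.response_name}")
    return ax


def williams_plot(assessment: ADAssessment, ax=None):
    """Standardized residuals vs leverages with h* and residual bands."""
    ax = _get_ax(ax)
    ax.scatter(assessment.leverages, assessment.std_residuals)
    ax.axvline(assessment.h_star, color="red", linestyle="--",
               label=f"h* = {assessment.h_star:.3g}")
    for sign in (+1, -1):
        ax.axhline(sign * assessment.residual_limit, color="grey",
                   linestyle=":")
    ax.set_xlabel("leverage $h_{ii}$")
    ax.set_ylabel("standardized residual")
    ax.legend()
    return ax
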
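"""Synthetic retention series and compound tables with known ground truth.

Two generators make every stage testable without measured data:

* retention series follow the micellar model k = k_m / (1 + K_AM [M]) on a
  four-level surfactant grid, with multiplicative lognormal noise —
  retention factors are strictly positive, so additive Gaussian noise
  (which could produce invalid k <= 0) is deliberately avoided;
* compound tables follow a known linear model y = X beta + eps with one or
  more continuous lipophilicity-like predictors (multivariate normal with
  controllable equicorrelation) plus small-integer count predictors
  (hydrogen-bond donors/acceptors, rotatable bonds), the statistical
  structure the four-descriptor QSAR models assume.

All randomness flows through one integer seed per config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CompoundTable
from .exceptions import ConfigError
from .foley import RetentionSeries

__all__ = [
    "RetentionSimConfig",
    "QsarSimConfig",
    "simulate_retention",
    "simulate_qsar_table",
]

#: study surfactant grid (total SDS, mol/L) and the nominal cmc subtracted
#: from it to form the default micellar-concentration grid
_SDS_GRID = (0.04, 0.06, 0.08, 0.10)
_NOMINAL_CMC = 0.008


@dataclass
class RetentionSimConfig:
    """Ground-truth sampling ranges and noise level for retention series.

    Defaults mirror the study conditions: four surfactant levels (the SDS
    grid minus a nominal cmc), and (k_m, K_AM) ranges spanning the
    descriptor ranges observed across the 15 study compounds
    (log k_m 0.4-4.3, log K_AM -0.48-4.0).  ``noise_cv`` is the
    multiplicative coefficient of variation on k.
    """

    km_range: tuple[float, float] = (2.5, 2.0e4)
    KAM_range: tuple[float, float] = (0.33, 1.0e4)
    concentrations: tuple[float, ...] = tuple(
        round(c - _NOMINAL_CMC, 6) for c in _SDS_GRID
    )
    noise_cv: float = 0.02
    n_series: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.km_range, self.KAM_range):
            if not (0 < lo <= hi):
                raise ConfigError("sampling ranges must be positive and "
                                  "ordered")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_series < 1:
            raise ConfigError("n_series must be >= 1")
        if any(c < 0 for c in self.concentrations):
            raise ConfigError("micellar concentrations must be >= 0")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float,
                 size: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def simulate_retention(config: RetentionSimConfig,
                       ) -> list[tuple[RetentionSeries, float, float]]:
    """Draw retention series with known (k_m, K_AM).

    Noise is lognormal with unit mean and coefficient of variation
    ``noise_cv``:  sigma^2 = ln(1 + cv^2), mu = -sigma^2/2.
    """
    rng = np.random.default_rng(config.seed)
    M = np.asarray(config.concentrations, dtype=float)
    kms = _log_uniform(rng, *config.km_range, config.n_series)
    kams = _log_uniform(rng, *config.KAM_range, config.n_series)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    out = []
    for i, (km, kam) in enumerate(zip(kms, kams)):
        k = km / (1.0 + kam * M)
        if sigma > 0:
            k = k * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                  size=M.shape)
        series = RetentionSeries(M.copy(), k, cmc=_NOMINAL_CMC,
                                 solute_id=f"sim-{i + 1}")
        out.append((series, float(km), float(kam)))
    return out


@dataclass
class QsarSimConfig:
    """A known linear model over mixed continuous/count predictors.

    ``beta`` is (intercept, continuous coefficients..., count coefficients
    in ``count_predictor_ranges`` order).  Defaults emulate the study
    geometry: 15 compounds, one continuous lipophilicity descriptor
    centred like the observed log k_m values, three count descriptors on
    their observed integer ranges, coefficients and residual sd of the
    skin-permeability model's order of magnitude.
    """

    n_compounds: int = 15
    beta: tuple[float, ...] = (-5.3, 0.6, -0.67, -0.35, 0.2)
    predictor_means: tuple[float, ...] = (2.6,)
    predictor_sds: tuple[float, ...] = (1.0,)
    collinearity: float = 0.0
    count_predictor_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"HBD": (0, 1), "HBA": (2, 5),
                                 "NRB": (2, 5)})
    count_correlation: float = 0.0
    noise_sd: float = 0.11
    seed: int = 0

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(f"x{i + 1}" for i in range(len(self.predictor_means)))

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return self.continuous_names + tuple(self.count_predictor_ranges)

    def __post_init__(self) -> None:
        m = len(self.predictor_means)
        if len(self.predictor_sds) != m:
            raise ConfigError("predictor_means and predictor_sds lengths "
                              "differ")
        k = m + len(self.count_predictor_ranges)
        if len(self.beta) != k + 1:
            raise ConfigError(
                f"beta has {len(self.beta)} entries; need intercept plus "
                f"{k} predictors"
            )
        if self.n_compounds <= k + 1:
            raise ConfigError("n_compounds must exceed predictor count + 1")
        if not (0.0 <= self.collinearity <= 0.95):
            raise ConfigError("collinearity must lie in [0, 0.95]")
        if not (0.0 <= abs(self.count_correlation) <= 0.95):
            raise ConfigError("count_correlation must lie in [-0.95, 0.95]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if any(lo > hi for lo, hi in self.count_predictor_ranges.values()):
            raise ConfigError("count ranges must be ordered (lo, hi)")


def simulate_qsar_table(config: QsarSimConfig,
                        ) -> tuple[CompoundTable, np.ndarray]:
    """Draw a compound table from the configured linear model.

    Continuous predictors are multivariate normal with pairwise
    correlation ``collinearity``; count predictors are uniform on their
    integer ranges, independent by default (``count_correlation`` couples
    them to the first continuous predictor through a Gaussian copula).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    m = len(config.predictor_means)

    corr = np.full((m, m), config.collinearity)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(f"infeasible correlation matrix: {exc}")
    z = rng.standard_normal((n, m))
    cont = np.asarray(config.predictor_means) + (
        z @ chol.T) * np.asarray(config.predictor_sds)

    columns: dict[str, np.ndarray] = {
        name: cont[:, j] for j, name in enumerate(config.continuous_names)
    }
    rho = config.count_correlation
    for name, (lo, hi) in config.count_predictor_ranges.items():
        if rho == 0.0:
            counts = rng.integers(lo, hi + 1, size=n)
        else:
            latent = rho * z[:, 0] + np.sqrt(1 - rho**2) * \
                rng.standard_normal(n)
            from scipy.stats import norm

            u = norm.cdf(latent)
            counts = lo + np.floor(u * (hi - lo + 1)).astype(int)
            counts = np.clip(counts, lo, hi)
        columns[name] = counts

    X = np.column_stack([columns[c] for c in config.predictor_names])
    beta = np.asarray(config.beta, dtype=float)
    y = beta[0] + X @ beta[1:]
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=n)

    frame = pd.DataFrame({"compound_id": np.arange(1, n + 1), **columns,
                          "y": y})
    table = CompoundTable(frame,
                          descriptor_names=config.predictor_names,
                          endpoint_names=("y",),
                          identifier_names=("compound_id",))
    return table, beta
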
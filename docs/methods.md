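# Methods

## Retention model

For a solute in micellar liquid chromatography the retention factor obeys
`1/k = 1/k_m + (K_AM/k_m)[M]`, with [M] the micellar concentration (total
surfactant minus cmc, mol/L), `k_m` the retention at zero micellar
concentration and `K_AM` the solute–micelle binding constant (L/mol). The
estimator is unweighted ordinary least squares in reciprocal space
(y = 1/k on x = [M]) — the classical slope/intercept evaluation route —
followed by the algebraic inversion `k_m = 1/intercept`,
`K_AM = slope/intercept`. A weighted variant is deliberately out of scope.

Conventions and degenerate cases:

* A series needs ≥ 3 points and ≥ 2 distinct concentrations (two
  parameters plus one residual degree of freedom); typical series have the
  four surfactant levels of the study design.
* A non-positive reciprocal intercept makes `k_m` undefined and raises
  `InvalidFitError`. This is a real identifiability limit, not a numeric
  artifact: when `k_m` and `K_AM` are both large, the intercept `1/k_m` is
  a vanishing fraction of the observed 1/k signal and measurement noise
  can flip its sign. At 2% multiplicative noise roughly a tenth of series
  sampled across the full descriptor range of the study compounds hit this
  regime.
* A negative-but-finite `K_AM` estimate on a noisy series is recorded, not
  rejected; `log K_AM` is then NaN and the fit is flagged
  (`binding_nonpositive`). Small positive binding constants legitimately
  give negative `log K_AM` (one study compound has log K_AM = −0.48).
* No outlier rejection within a series.

## Regression engine

All models are intercept OLS fits. Parameter estimates, standard errors
and the F statistic come from statsmodels; the surrounding validation
block is assembled in-package:

* `R = sqrt(1 − SSE/SST)` — the multiple correlation coefficient. The
  published tables label this "coefficient of determination", but internal
  consistency of the printed statistics (R = 0.9861, n = 15, k = 1,
  F = 456) holds under the closed form
  `F = (R²/k)/((1−R²)/(n−k−1))` only if R is the correlation, not R²; the
  package follows the numbers.
* `sd = sqrt(SSE/(n−k−1))`, so `sd² = MSE` (the residual mean square).
* Leverages are the diagonal of the hat matrix, computed from the thin-QR
  factor of the design.
* `PRESS = Σ(eᵢ/(1−hᵢᵢ))²` via the hat-matrix identity; the test suite
  verifies agreement with an explicit delete-one refit loop to 1e−10
  relative. An observation with hᵢᵢ = 1 makes the deleted prediction
  undefined: the fitted results then carry `PRESS = NaN` and `loo_press`
  raises. `PRESS_cv` is the same quantity (the published tables duplicate
  it); `MSE_cv` is reported as PRESS/n. The published cross-validated MSE
  follows no convention reproducible from PRESS and n (for the lethal-dose
  models it is neither PRESS/n nor PRESS/(n−k−1)), so printed MSE_cv is
  excluded from comparisons.
* `VIF_j = 1/(1−R_j²)` from auxiliary regressions of each predictor on
  the rest; perfect collinearity yields an `inf` sentinel rather than an
  exception.
* Standardized coefficients are `bⱼ·s_xⱼ/s_y` with n−1 denominators,
  identical to refitting on z-scored columns (tested). The published
  figure panels carry a "PLS" label while the models themselves are
  ordinary MLR fits; this package computes standardized OLS coefficients
  throughout and makes no latent-variable fit.
* Parabolic retention–activity fits reduce to the same engine on the
  design (x, x²); the vertex −b/(2c) locates the extremal-response
  lipophilicity.

## Applicability domain

Warning leverage `h* = 3(k+1)/n`, computed in exact rational arithmetic so
the study geometry (k = 4, n = 15) gives exactly 1.0 — the theoretical
maximum of a leverage, hence structural outliers are impossible in the
study-sized models and every model is valid across its training domain.
Standardized residuals default to the plain form e/sd (the published plots
say "standardized residuals" without further specification); internally
studentized residuals e/(sd·√(1−h)) are available behind a flag. The
residual band defaults to ±3, the conventional Williams-plot choice; the
published plots draw bands without stating the value.

## Embedded dataset and published-statistics fixture

The 15-compound table is transcribed at its printed precision (two
decimals for the chromatographic descriptors) and never re-derived.
Whether the original regressions used more decimal places than printed is
unknowable, so replication tolerances must absorb input rounding: a ±half
unit-in-the-last-digit perturbation of the chromatographic columns
propagates to roughly ±0.005 on the calibration slope/intercept, ±0.002 on
R, ±3% on sd and ±5% on F (Monte Carlo over the rounding interval). The
default comparison tolerance is therefore the larger of two units in the
last printed digit and a relative slack of 1% (coefficients), 2% (sd) or
3% (F, PRESS, MSE), with 0.002 absolute for the R family; the calibration
line, whose response is itself a two-decimal column, uses the propagated
±0.005 / ±0.002 / ±0.005 / 5% band in the tests.

Published standard errors are displayed in the replication report but not
gated: one printed value (the H-bond-donor SE of the lethal-dose model on
log K_AM) disagrees with recomputation by ~4% while every neighbouring
value agrees, consistent with a transcription slip in the source table.

Screen thresholds follow the usual boundary semantics: "not greater
than" is ≤ (log P ≤ 5, MW ≤ 500, HBA ≤ 10, HBD ≤ 5), "below" is strict
(TPSA < 90 Å², V_d < 7 L/kg), count ranges are inclusive (2 ≤ NRB ≤ 5).

## Synthetic data

The generators define the conditions under which the machinery is tested:

* Retention series use the study's four surfactant levels (0.04–0.10
  mol/L SDS) minus a nominal cmc of 0.008 mol/L; the cmc under the study's
  20% acetonitrile co-modifier is not published, so configured
  concentrations are treated as already cmc-corrected. Ground-truth
  (k_m, K_AM) are drawn log-uniformly over ranges spanning the observed
  descriptor range of the study compounds (log k_m 0.4–4.3, log K_AM
  −0.48–4.0). Noise is multiplicative lognormal with unit mean
  (σ² = ln(1+cv²), μ = −σ²/2), default cv 2%; additive Gaussian noise is
  avoided because it could generate invalid non-positive retention
  factors.
* Compound tables follow y = Xβ + ε with one (or more) continuous
  lipophilicity-like predictors — multivariate normal with configurable
  equicorrelation up to 0.95 — plus integer count predictors uniform on
  the observed ranges (HBD 0–1, HBA 2–5, NRB 2–5), independent of the
  continuous block by default (a Gaussian-copula coupling to the first
  continuous predictor exists behind `count_correlation`). Defaults mirror
  the study geometry: 15 compounds, 4 predictors, coefficients and
  residual sd of the skin-permeability model's magnitude.

What the synthetic data does not emulate: the correlation structure among
real molecular descriptors, chromatographic drift, peak integration, pH or
co-modifier effects. Passing the recovery and coverage tests shows the
estimators are correct under the assumed model, not that the model
describes any particular instrument.

Problem sizes in the test and acceptance runs — 200 retention series for
the noisy-recovery check, 200 replicate tables of 20 compounds for the
±2 SE coverage check — keep the whole suite at a few seconds while leaving
the stochastic bands (coverage in [90%, 99%]) well resolved.

## Known limitations

* Only the reciprocal-OLS retention estimator is provided; other micellar
  retention models and weighted fits are out of scope.
* No variable selection, regularization or genuine PLS; the QSAR models
  are fixed four-descriptor fits by design.
* No chemical-structure handling: compounds are rows of descriptor
  values, not molecules.
* The applicability-domain toolkit is leverage-based only (no
  distance-to-model or kNN variants).
* p-values are reported from the F distribution but are not a comparison
  surface (the source tables print only inequalities).
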
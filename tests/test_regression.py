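"""Regression engine: published-value replication, brute-force oracles for
the leave-one-out and collinearity machinery, and algebraic invariants."""

import numpy as np
import pandas as pd
import pytest

from mlcqrar import (
    QSARModel,
    RegressionSpec,
    fit_ols,
    loo_press,
    quadratic_fit,
    vif,
)
from mlcqrar.exceptions import (
    InsufficientDataError,
    LeverageOneError,
    SingularDesignError,
)
from mlcqrar.regression import _fit_core

FOUR_DESCRIPTORS = ("log_km", "HBD", "HBA", "NRB")


def fit_xy(x_columns: dict, y: np.ndarray):
    """Fit through the public engine on a plain dataframe."""
    frame = pd.DataFrame(x_columns)
    names = tuple(frame.columns)
    frame["y"] = y
    return QSARModel.from_dataframe(frame, "y", names).fit()


class TestFixtureReplication:
    """Published statistic blocks re-emerge from the printed data.

    Tolerances allow for the printed two-decimal precision of the
    chromatographic descriptors propagating through the fit.
    """

    def test_lipophilicity_calibration(self, table):
        res = fit_ols(table, RegressionSpec("log_km", ("log_KAM",)))
        assert res.intercept == pytest.approx(0.585, abs=0.005)
        assert res.slopes[0] == pytest.approx(0.932, abs=0.005)
        assert res.R == pytest.approx(0.9861, abs=0.002)
        assert res.sd == pytest.approx(0.1612, abs=0.005)
        assert res.F == pytest.approx(456, rel=0.05)

    def test_skin_permeability_model(self, table):
        res = fit_ols(table, RegressionSpec("log_Kp", FOUR_DESCRIPTORS))
        expected = (-5.329, 0.597, -0.669, -0.345, 0.197)
        assert res.coefficients == pytest.approx(expected, abs=0.002)
        assert res.standard_errors == pytest.approx(
            (0.156, 0.041, 0.075, 0.061, 0.044), abs=0.002)
        assert res.R == pytest.approx(0.9893, abs=0.001)
        assert res.PRESS == pytest.approx(0.276, abs=0.003)
        assert res.MSE == pytest.approx(0.012, abs=0.001)

    def test_sd_squared_equals_mse(self, table):
        res = fit_ols(table, RegressionSpec("log_Kp", FOUR_DESCRIPTORS))
        assert res.sd**2 == pytest.approx(res.MSE, rel=1e-12)


class TestExactData:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        res = fit_xy({"x": x}, 2.0 * x + 1.0)
        assert res.coefficients == pytest.approx((1.0, 2.0), abs=1e-10)
        assert res.R == pytest.approx(1.0, abs=1e-12)
        assert res.sd == pytest.approx(0.0, abs=1e-10)
        assert res.PRESS == pytest.approx(0.0, abs=1e-18)

    def test_noise_free_multivariate_recovery(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        beta = np.array([0.5, -1.0, 2.0, 0.25])
        y = beta[0] + X @ beta[1:]
        res = fit_xy({f"x{i}": X[:, i] for i in range(3)}, y)
        assert res.coefficients == pytest.approx(beta, abs=1e-9)


class TestLooPress:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hat_identity_equals_delete_one_refit(self, seed):
        """The hat-matrix shortcut must agree with an explicit refit loop."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        res = fit_xy({f"x{i}": X[:, i] for i in range(4)}, y)
        press, mse_cv = loo_press(res)

        brute = 0.0
        A = np.column_stack([np.ones(15), X])
        for i in range(15):
            mask = np.arange(15) != i
            coef, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
            brute += (y[i] - A[i] @ coef) ** 2
        assert press == pytest.approx(brute, rel=1e-10)
        assert mse_cv == pytest.approx(press / 15, rel=1e-12)

    def test_press_dominates_sse(self, table):
        for endpoint in ("log_Kp", "log_BB", "LD50"):
            res = fit_ols(table, RegressionSpec(endpoint, FOUR_DESCRIPTORS))
            assert res.PRESS >= res.sse

    def test_leverage_one_raises(self):
        # the only observation with x1 = 1 is self-determining: the x1
        # coefficient absorbs its response exactly, so h = 1 there
        x1 = np.array([0.0, 0.0, 0.0, 1.0])
        x2 = np.array([0.0, 1.0, 2.0, 0.0])
        y = np.array([0.0, 1.1, 1.9, 3.0])
        res = _fit_core(y, np.column_stack([x1, x2]), "y", ("a", "b"))
        assert res.leverages.max() == pytest.approx(1.0)
        assert np.isnan(res.PRESS)
        with pytest.raises(LeverageOneError):
            loo_press(res)


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        x1 = np.array([-1.5, -0.5, 0.5, 1.5, -1.5, -0.5, 0.5, 1.5])
        x2 = np.array([-1.0, -1.0, -1.0, -1.0, 1.0, 1.0, 1.0, 1.0])
        res = fit_xy({"x1": x1, "x2": x2},
                     x1 + x2 + np.linspace(0, 1, 8))
        assert res.vif == pytest.approx((1.0, 1.0), abs=1e-12)

    def test_fixture_collinearity_is_mild(self, table):
        v = vif(table, FOUR_DESCRIPTORS)
        assert np.all(v >= 1.0)
        assert np.max(v) < 3.6

    def test_self_consistency_with_auxiliary_fits(self, table):
        """VIF_j must equal 1/(1-R_j^2) with R_j^2 from independent calls
        to the fitting engine."""
        v = vif(table, FOUR_DESCRIPTORS)
        sub = pd.DataFrame(
            {c: table.column(c) for c in FOUR_DESCRIPTORS})
        for j, name in enumerate(FOUR_DESCRIPTORS):
            others = tuple(c for c in FOUR_DESCRIPTORS if c != name)
            aux = QSARModel.from_dataframe(sub, name, others).fit()
            assert v[j] == pytest.approx(1.0 / (1.0 - aux.R**2), rel=1e-9)

    def test_perfect_collinearity_yields_inf_sentinel(self):
        from mlcqrar import CompoundTable

        x = np.arange(8.0)
        t = CompoundTable(pd.DataFrame({"x1": x, "x2": 2 * x}),
                          descriptor_names=("x1", "x2"),
                          endpoint_names=(), identifier_names=())
        assert np.isinf(vif(t, ("x1", "x2"))).all()


class TestStandardizedCoefficients:
    def test_perfect_univariate_fit_gives_unit_beta(self):
        x = np.arange(8.0)
        res = fit_xy({"x": x}, 2.0 * x)
        assert res.standardized_coefficients[0] == pytest.approx(1.0)

    def test_zscore_refit_oracle(self, table):
        """Standardized coefficients equal raw OLS slopes on z-scored
        columns."""
        res = fit_ols(table, RegressionSpec("log_Kp", FOUR_DESCRIPTORS))
        z = {f"z{i}": (table.column(c) - table.column(c).mean())
             / table.column(c).std(ddof=1)
             for i, c in enumerate(FOUR_DESCRIPTORS)}
        y = table.column("log_Kp")
        zres = fit_xy(z, (y - y.mean()) / y.std(ddof=1))
        assert res.standardized_coefficients == pytest.approx(
            zres.coefficients[1:], rel=1e-9)

    def test_fixture_sign_pattern(self, table):
        """Lipophilicity raises, H-bond donor count lowers, skin
        permeability."""
        res = fit_ols(table, RegressionSpec("log_Kp", FOUR_DESCRIPTORS))
        beta = dict(zip(res.predictor_names,
                        res.standardized_coefficients))
        assert beta["log_km"] > 0
        assert beta["HBD"] < 0
        assert np.all(np.sign(res.standardized_coefficients)
                      == np.sign(res.slopes))


class TestQuadraticFit:
    def test_exact_parabola(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = quadratic_fit(x, (x - 2.0) ** 2)
        assert (fit.a, fit.b, fit.c) == pytest.approx((4.0, -4.0, 1.0),
                                                      abs=1e-10)
        assert fit.R == pytest.approx(1.0)
        assert fit.vertex == pytest.approx(2.0)

    def test_reduces_to_linear_engine(self, table):
        x = table.column("log_km")
        y = table.column("Vd")
        fit = quadratic_fit(x, y)
        res = fit_xy({"x": x, "x2": x**2}, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx(
            tuple(res.coefficients), rel=1e-12)
        assert fit.R == pytest.approx(res.R, rel=1e-12)

    def test_fixture_distribution_volume_is_well_fit(self, table):
        fit = quadratic_fit(table.column("log_km"), table.column("Vd"))
        assert fit.R > 0.8

    def test_degenerate_x_rejected(self):
        with pytest.raises(SingularDesignError):
            quadratic_fit([0.0, 1.0, 0.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestInvariants:
    def test_anova_decomposition(self, table):
        for endpoint in ("log_Kp", "LD50"):
            res = fit_ols(table, RegressionSpec(endpoint, FOUR_DESCRIPTORS))
            ssr = res.sst - res.sse
            assert res.sst == pytest.approx(
                ssr + res.sse, rel=1e-9)
            assert np.sum(res.residuals) == pytest.approx(0.0, abs=1e-8 *
                                                          res.sst)

    def test_f_closed_form_from_r(self, table):
        res = fit_ols(table, RegressionSpec("log_km", ("log_KAM",)))
        r2 = res.R**2
        closed = (r2 / res.k) / ((1 - r2) / (res.n - res.k - 1))
        assert res.F == pytest.approx(closed, rel=1e-9)

    def test_leverage_sum_and_bounds(self, table):
        res = fit_ols(table, RegressionSpec("log_Kp", FOUR_DESCRIPTORS))
        assert np.sum(res.leverages) == pytest.approx(res.k + 1, rel=1e-10)
        assert np.all(res.leverages >= 1.0 / res.n - 1e-12)
        assert np.all(res.leverages <= 1.0 + 1e-12)

    def test_r_family_ordering(self, table):
        res = fit_ols(table, RegressionSpec("log_KHSA", FOUR_DESCRIPTORS))
        assert 0.0 <= res.R_adj <= res.R <= 1.0

    def test_row_permutation_changes_no_statistic(self, table):
        res = fit_ols(table, RegressionSpec("log_BB", FOUR_DESCRIPTORS))
        from mlcqrar import CompoundTable

        rng = np.random.default_rng(5)
        perm = rng.permutation(len(table))
        shuffled = CompoundTable(
            table.frame.iloc[perm].reset_index(drop=True),
            table.descriptor_names, table.endpoint_names,
            table.identifier_names)
        res2 = fit_ols(shuffled, RegressionSpec("log_BB", FOUR_DESCRIPTORS))
        for stat in ("R", "R_adj", "sd", "F", "PRESS"):
            assert getattr(res2, stat) == pytest.approx(
                getattr(res, stat), rel=1e-9)
        assert res2.coefficients == pytest.approx(res.coefficients,
                                                  rel=1e-9)

    def test_predictor_permutation_permutes_aligned_vectors(self, table):
        a = fit_ols(table, RegressionSpec("log_BB", FOUR_DESCRIPTORS))
        rev = tuple(reversed(FOUR_DESCRIPTORS))
        b = fit_ols(table, RegressionSpec("log_BB", rev))
        assert b.coefficients[1:][::-1] == pytest.approx(
            a.coefficients[1:], rel=1e-9)
        assert b.vif[::-1] == pytest.approx(a.vif, rel=1e-9)
        assert b.R == pytest.approx(a.R, rel=1e-12)


class TestErrors:
    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        with pytest.raises(SingularDesignError, match="x2"):
            fit_xy({"x1": x, "x2": 3.0 * x}, x + 1.0)

    def test_insufficient_observations(self):
        with pytest.raises(InsufficientDataError):
            fit_xy({"x1": np.array([1.0, 2.0, 3.0]),
                    "x2": np.array([2.0, 1.0, 5.0])},
                   np.array([1.0, 2.0, 1.0]))
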
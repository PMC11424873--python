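"""Box-Behnken design construction and quadratic response-surface fitting."""

from collections import Counter

import numpy as np
import pytest

from phytosynergy import FormulationPoint, ResponseSurfaceModel, bbd_design, load_fixtures
from phytosynergy.rsm import observed_optimum, quadratic_design_matrix
from phytosynergy.datasets import load_response_table

#: Published polynomial for ethanol-extraction percent yield
#: (intercept, GM, CC, AE, GM^2, CC^2, AE^2, GM*CC, GM*AE, CC*AE).
YIELD_COEFFS = np.array(
    [10.38, -0.432, -0.733, -0.445, 0.0564, 0.0730, 0.0468, -0.0325, -0.0157, -0.0223]
)
PHENOLIC_COEFFS = np.array(
    [-18.2, 17.42, -2.80, 6.49, -0.628, 0.962, -0.380, -0.504, 0.958, -0.632]
)


class TestBBDDesign:
    def test_matches_fixture_point_multiset(self, bundle):
        design = Counter(p.as_tuple() for p in bbd_design((5, 10, 15)))
        fixture = Counter(
            tuple(r) for r in bundle.table1[["gm_g", "cc_g", "ae_g"]].to_numpy()
        )
        assert design == fixture
        assert design[(10, 10, 10)] == 3

    def test_no_cube_corners(self):
        pts = {p.as_tuple() for p in bbd_design((5, 10, 15))}
        for corner in [(5, 5, 5), (15, 15, 15), (5, 5, 15), (15, 5, 5)]:
            assert corner not in pts

    def test_non_center_runs_have_exactly_one_mid_factor(self):
        for p in bbd_design((5, 10, 15)):
            n_mid = sum(1 for v in p.as_tuple() if v == 10)
            assert n_mid in (1, 3)

    def test_degenerate_levels_rejected(self):
        with pytest.raises(ValueError):
            bbd_design((5, 5, 15))


class TestQuadraticFit:
    def test_reproduces_published_yield_polynomial(self, ethanol_fits):
        res = ethanol_fits["yield"]
        assert res.params["Intercept"] == pytest.approx(10.38, abs=0.005)
        assert res.params["GM"] == pytest.approx(-0.432, abs=0.0005)
        assert res.params["GM*CC"] == pytest.approx(-0.0325, abs=5e-6)
        assert res.rsquared_pct == pytest.approx(97.37, abs=0.05)
        assert res.residual_df == 5

    def test_reproduces_published_phenolic_gm_coefficient(self, ethanol_fits):
        res = ethanol_fits["phenolic"]
        assert res.params["GM"] == pytest.approx(17.42, abs=0.005)
        assert res.rsquared_pct == pytest.approx(94.80, abs=0.05)

    def test_noise_free_surface_recovered_to_numerical_precision(self):
        points = bbd_design((5, 10, 15))
        X = quadratic_design_matrix(points).to_numpy()
        y = X @ YIELD_COEFFS
        res = ResponseSurfaceModel(y, points).fit()
        np.testing.assert_allclose(res.params.to_numpy(), YIELD_COEFFS, rtol=1e-8)

    def test_matches_normal_equations_oracle(self, bundle):
        df = bundle.table1
        X = quadratic_design_matrix(df[["gm_g", "cc_g", "ae_g"]].to_numpy()).to_numpy()
        y = df["flavonoid_ethanol"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = ResponseSurfaceModel.from_dataframe(df, "flavonoid_ethanol").fit()
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-8)

    def test_residuals_orthogonal_to_model_columns(self, ethanol_fits):
        res = ethanol_fits["yield"]
        X = res.model.exog.to_numpy()
        assert np.abs(X.T @ res.resid).max() < 1e-8

    def test_r2_invariant_under_response_shift(self, bundle):
        df = bundle.table1.copy()
        base = ResponseSurfaceModel.from_dataframe(df, "yield_ethanol").fit()
        df["shifted"] = df["yield_ethanol"] + 100.0
        shifted = ResponseSurfaceModel.from_dataframe(df, "shifted").fit()
        assert shifted.rsquared_pct == pytest.approx(base.rsquared_pct, abs=1e-9)

    def test_too_few_runs_rejected(self):
        points = bbd_design((5, 10, 15))[:9]
        with pytest.raises(ValueError):
            ResponseSurfaceModel(np.ones(9), points)

    def test_rank_deficient_design_rejected(self):
        # all runs at a single point: quadratic terms collinear
        points = [FormulationPoint(10, 10, 10)] * 12
        with pytest.raises(ValueError, match="rank"):
            ResponseSurfaceModel(np.ones(12), points).fit()


class TestPredict:
    def test_zero_coefficients_predict_zero(self):
        points = bbd_design((5, 10, 15))
        res = ResponseSurfaceModel(np.zeros(15), points).fit()
        assert res.predict((7.3, 11.1, 9.9)) == pytest.approx(0.0, abs=1e-10)

    def test_published_yield_polynomial_at_center(self):
        """Printed coefficients evaluated at 10:10:10 give 4.85, matching
        the 4.857 mean of the three center replicates within rounding."""
        points = bbd_design((5, 10, 15))
        X = quadratic_design_matrix(points).to_numpy()
        res = ResponseSurfaceModel(X @ YIELD_COEFFS, points).fit()
        assert res.predict((10, 10, 10)) == pytest.approx(4.85, abs=1e-6)

    def test_published_phenolic_polynomial_at_center(self):
        points = bbd_design((5, 10, 15))
        X = quadratic_design_matrix(points).to_numpy()
        res = ResponseSurfaceModel(X @ PHENOLIC_COEFFS, points).fit()
        assert res.predict((10, 10, 10)) == pytest.approx(170.5, abs=1e-6)

    def test_center_fit_equals_center_replicate_mean_projection(self, bundle, ethanol_fits):
        t1 = bundle.table1
        center_mean = t1[(t1.gm_g == 10) & (t1.cc_g == 10) & (t1.ae_g == 10)][
            "yield_ethanol"
        ].mean()
        assert ethanol_fits["yield"].predict((10, 10, 10)) == pytest.approx(
            center_mean, abs=1e-9
        )


class TestStandardizedEffects:
    def test_threshold_is_t_quantile_at_five_df(self, ethanol_fits):
        ranking = ethanol_fits["yield"].standardized_effects(alpha=0.05)
        assert ranking.threshold == pytest.approx(2.571, abs=1e-3)
        assert ranking.residual_df == 5

    def test_phenolic_top_term_is_gm_linear(self, ethanol_fits):
        ranking = ethanol_fits["phenolic"].standardized_effects()
        assert ranking.effects[0][0] == "GM"

    def test_sorted_descending(self, ethanol_fits):
        effects = [e for _, e in ethanol_fits["flavonoid"].standardized_effects().effects]
        assert effects == sorted(effects, reverse=True)

    def test_dominant_synthetic_coefficient_ranks_first(self):
        rng = np.random.default_rng(3)
        points = bbd_design((5, 10, 15))
        X = quadratic_design_matrix(points).to_numpy()
        beta = np.zeros(10)
        beta[3] = 50.0  # huge AE linear effect
        y = X @ beta + rng.normal(0, 0.5, 15)
        ranking = ResponseSurfaceModel(y, points).fit().standardized_effects()
        assert ranking.effects[0][0] == "AE"


class TestOptima:
    def test_constant_surface_tie_breaks_lexicographically(self):
        points = bbd_design((5, 10, 15))
        res = ResponseSurfaceModel(np.full(15, 7.0), points).fit()
        point, _ = res.grid_optimum(levels=(5, 10, 15), total_mass=30.0)
        assert point.as_tuple() == (5.0, 10.0, 15.0)

    def test_unsatisfiable_constraint_rejected(self, ethanol_fits):
        with pytest.raises(ValueError):
            ethanol_fits["yield"].grid_optimum(levels=(5, 10, 15), total_mass=7.0)

    def test_flavonoid_surface_optimum_at_design_levels(self, ethanol_fits):
        point, _ = ethanol_fits["flavonoid"].grid_optimum(
            levels=(5, 10, 15), total_mass=30.0
        )
        assert point.as_tuple() == (15.0, 5.0, 10.0)

    @pytest.mark.parametrize("response,expected,value", [
        ("yield", (10.0, 15.0, 5.0), 9.17),
        ("phenolic", (15.0, 5.0, 10.0), 231.67),
        ("flavonoid", (15.0, 5.0, 10.0), 143.60),
    ])
    def test_observed_optimum_matches_published_recommendation(
        self, response, expected, value
    ):
        """The published recommended ratios follow the best observed runs."""
        point, best = observed_optimum(load_response_table("ethanol", response))
        assert point.as_tuple() == expected
        assert best == pytest.approx(value)


class TestSlices:
    def test_zero_surface_slice_is_zero(self):
        points = bbd_design((5, 10, 15))
        res = ResponseSurfaceModel(np.zeros(15), points).fit()
        grid = res.surface_slice("GM", 10.0, step=5.0)
        assert (grid["prediction"].abs() < 1e-10).all()

    def test_slice_consistent_with_predict(self, ethanol_fits):
        res = ethanol_fits["yield"]
        grid = res.surface_slice("GM", 10.0, step=5.0)
        for _, row in grid.iterrows():
            assert row["prediction"] == pytest.approx(
                res.predict((10.0, row["CC"], row["AE"])), abs=1e-12
            )

    def test_step_five_grid_has_nine_rows(self, ethanol_fits):
        grid = ethanol_fits["yield"].surface_slice("AE", 10.0, step=5.0)
        assert len(grid) == 9
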
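"""Composite index, Min-Max normalization, and Monte-Carlo cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oxymap as ox
from oxymap.errors import DegenerateBoundsError, ParameterError
from oxymap.estimation import PLATEAU_MODEL, PLATEAU_WEIGHTS

from conftest import design_matrix

finite = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestBoundsAndNormalize:
    def test_bounds_are_observed_min_max(self):
        b = ox.fit_minmax_bounds([2000, 3000, 4000], [5, 10, 0], [0.5, 2.0, 1.0])
        assert b.elevation == (2000, 4000)
        assert b.temperature == (0, 10)
        assert b.lai == (0.5, 2.0)

    def test_reference_fixture_elevation_bounds(self, reference_table):
        elev = [r.elevation for r in reference_table]
        temp = [r.temperature for r in reference_table]
        b = ox.fit_minmax_bounds(elev, temp, np.linspace(0, 2, 13))
        assert b.elevation == (2294, 3831)

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateBoundsError):
            ox.fit_minmax_bounds([3000], [5], [1.0])

    def test_constant_variable_degenerate(self):
        with pytest.raises(DegenerateBoundsError):
            ox.fit_minmax_bounds([2000, 3000], [5, 5], [0.5, 1.0])

    @pytest.mark.parametrize(
        "value,bounds,expected",
        [(0, (0, 10), 0.0), (10, (0, 10), 1.0), (5, (0, 10), 0.5), (12, (0, 10), 1.0)],
    )
    def test_normalize_endpoints_midpoint_clamp(self, value, bounds, expected):
        assert ox.normalize(value, bounds) == pytest.approx(expected)

    def test_normalize_unclamped_extrapolates(self):
        assert ox.normalize(12, (0, 10), clamp=False) == pytest.approx(1.2)


class TestCompositeIndex:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((1, 0, 0), -0.3958),
            ((0, 1, 0), 0.3550),
            ((0, 0, 1), 0.2492),
            ((0, 0, 0), 0.0),
            ((0.5, 0.5, 0.5), 0.1042),
        ],
    )
    def test_weighted_sum(self, p, expected):
        assert ox.composite_index(*p) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ne=finite, nt=finite, nl=finite, alpha=st.floats(0, 2, allow_nan=False))
    def test_linearity_against_dot_product(self, ne, nt, nl, alpha):
        """index(alpha*p) == alpha*index(p), and index equals the dot product."""
        w = PLATEAU_WEIGHTS.as_array()
        direct = float(w @ np.array([ne, nt, nl]))
        assert ox.composite_index(ne, nt, nl) == pytest.approx(direct, abs=1e-12)
        assert ox.composite_index(alpha * ne, alpha * nt, alpha * nl) == pytest.approx(
            alpha * direct, abs=1e-9
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ne=finite, nt=finite, nl=finite)
    def test_index_and_prediction_within_interval_bounds(self, ne, nt, nl):
        """With unit-interval predictors the index sits in [w_E, w_T + w_L] and
        the predicted OC in the matching interval-arithmetic band."""
        tmp = ox.composite_index(ne, nt, nl)
        assert -0.3958 - 1e-12 <= tmp <= 0.6042 + 1e-12
        oc = ox.predict_oxygen(tmp)
        assert 19.8439 - 1e-4 <= oc <= 20.8722 + 1e-4

    def test_prediction_monotone_in_index_and_elevation(self):
        assert ox.predict_oxygen(0.2) > ox.predict_oxygen(0.1)
        # holding N_T, N_L fixed, higher normalized elevation lowers OC
        lo = ox.predict_oxygen(ox.composite_index(0.2, 0.5, 0.5))
        hi = ox.predict_oxygen(ox.composite_index(0.8, 0.5, 0.5))
        assert hi < lo


class TestPredictOxygen:
    def test_published_intercept_at_zero_index(self):
        assert ox.predict_oxygen(0.0, PLATEAU_MODEL) == pytest.approx(20.2509, abs=1e-12)

    def test_unit_index(self):
        assert ox.predict_oxygen(1.0) == pytest.approx(21.2792, abs=1e-12)

    def test_zero_model(self):
        assert ox.predict_oxygen(0.0, ox.LinearModel(slope=0.0, intercept=0.0)) == 0.0


class TestCrossValidate:
    def test_noise_free_line_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-0.4, 0.6, 60)
        y = 1.0283 * x + 20.2509
        (res,) = ox.cross_validate(x, y, m_values=[20], n_reps=50, seed=0)
        assert res.rmse_mean <= 1e-10
        assert res.mean_slope == pytest.approx(1.0283, abs=1e-8)
        assert res.mean_intercept == pytest.approx(20.2509, abs=1e-8)

    def test_held_out_rmse_estimates_noise_sd(self, synthetic_points):
        table, lai, truth = synthetic_points
        y = np.array([r.oxygen_concentration for r in table])
        (res,) = ox.cross_validate(truth.tmp, y, m_values=[76], n_reps=2000, seed=11)
        assert res.rmse_mean == pytest.approx(truth.noise_sd, rel=0.10)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 40)
        y = 1.0 * x + 20 + rng.normal(0, 0.1, 40)
        a = ox.cross_validate(x, y, m_values=[5, 10], n_reps=200, seed=123)
        b = ox.cross_validate(x, y, m_values=[5, 10], n_reps=200, seed=123)
        assert a == b

    def test_result_independent_of_m_order(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 40)
        y = x + rng.normal(0, 0.1, 40)
        fwd = ox.cross_validate(x, y, m_values=[5, 20], n_reps=100, seed=9)
        rev = ox.cross_validate(x, y, m_values=[20, 5], n_reps=100, seed=9)
        assert fwd[0] == rev[1] and fwd[1] == rev[0]

    def test_m_out_of_range_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ParameterError):
            ox.cross_validate(x, x, m_values=[2], n_reps=10, seed=0)
        with pytest.raises(ParameterError):
            ox.cross_validate(x, x, m_values=[10], n_reps=10, seed=0)

    def test_rmse_curve_shape(self, synthetic_points):
        """Held-out RMSE falls then plateaus with m; its spread blows up as the
        test set shrinks toward nothing."""
        table, lai, truth = synthetic_points
        y = np.array([r.oxygen_concentration for r in table])
        res = ox.cross_validate(truth.tmp, y, m_values=[10, 76, 300, 415], n_reps=400, seed=5)
        rmse = [r.rmse_mean for r in res]
        stds = [r.rmse_std for r in res]
        assert rmse[0] > rmse[1]  # early steep descent
        assert abs(rmse[2] - rmse[1]) < 0.01  # plateau
        assert stds[3] > stds[1]  # tiny test sets are unstable


class TestSelectRobustModel:
    @staticmethod
    def result(m, rmse_std, rmse_mean=0.1):
        return ox.CVResult(
            m=m, n_reps=100, mean_slope=1.0, mean_intercept=20.0,
            rmse_mean=rmse_mean, rmse_std=rmse_std,
        )

    def test_singleton(self):
        r = self.result(10, 0.01)
        best, model = ox.select_robust_model([r])
        assert best is r and model.slope == 1.0

    def test_minimum_std_wins(self):
        rs = [self.result(10, 0.005), self.result(76, 0.0019), self.result(150, 0.003)]
        best, _ = ox.select_robust_model(rs)
        assert best.m == 76 and best.rmse_std == 0.0019

    def test_ties_broken_by_smaller_m(self):
        rs = [self.result(80, 0.002), self.result(50, 0.002)]
        best, _ = ox.select_robust_model(rs)
        assert best.m == 50

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            ox.select_robust_model([])


class TestCompositeIndexRegressor:
    def test_parameter_recovery_within_3_se(self, synthetic_points):
        """Fitting the full pipeline on default-scale synthetic data lands
        within +/-3 closed-form standard errors of the generating line."""
        table, lai, truth = synthetic_points
        X = design_matrix(table, lai)
        y = np.array([r.oxygen_concentration for r in table])
        reg = ox.CompositeIndexRegressor(
            m_values=[10, 30, 76, 150, 300], n_reps=2000, random_state=1
        ).fit(X, y)
        tmp = reg.transform(X)
        n = len(y)
        sx = tmp.std()
        resid = y - (reg.slope_ * tmp + reg.intercept_)
        s = np.sqrt((resid**2).sum() / (n - 2))
        se_slope = s / (sx * np.sqrt(n))
        se_int = s * np.sqrt(1.0 / n + tmp.mean() ** 2 / (n * sx**2))
        assert abs(reg.slope_ - truth.model.slope) <= 3 * se_slope
        assert abs(reg.intercept_ - truth.model.intercept) <= 3 * se_int

    def test_sklearn_params_round_trip(self):
        reg = ox.CompositeIndexRegressor(n_reps=50, random_state=4)
        params = reg.get_params()
        assert params["n_reps"] == 50
        clone = ox.CompositeIndexRegressor(**params)
        assert clone.get_params() == params

    def test_predict_matches_scalar_path(self, synthetic_points):
        table, lai, _ = synthetic_points
        X = design_matrix(table, lai)[:50]
        y = np.array([r.oxygen_concentration for r in table])[:50]
        reg = ox.CompositeIndexRegressor(m_values=[10], n_reps=50, random_state=0).fit(X, y)
        manual = np.array(
            [
                ox.predict_oxygen(
                    ox.composite_index(
                        ox.normalize(e, reg.bounds_.elevation),
                        ox.normalize(t, reg.bounds_.temperature),
                        ox.normalize(l, reg.bounds_.lai),
                    ),
                    reg.model_,
                )
                for e, t, l in X
            ]
        )
        np.testing.assert_allclose(reg.predict(X), manual, atol=1e-12)
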
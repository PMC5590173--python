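import numpy as np
import pytest

from mmtmc.basis import (
    CrossBasisSpec,
    ExtrapolationError,
    InsufficientDataError,
    InvalidSpecError,
    SplineSpec,
    build_crossbasis,
    evaluate_spline,
    lag_basis_matrix,
    log_knots,
    reduce_coefficients,
)

from .oracles import crossbasis_triple_loop, lag_cumulated_curve, quadratic_bspline_design


def bs_spec(intercept=False, internal=(10.0, 22.5, 27.0), boundary=(0.0, 30.0)):
    return SplineSpec("quadratic_bspline", internal, boundary, intercept=intercept)


def ns_spec(intercept=True, internal=(1.0, 2.0, 4.0), boundary=(0.0, 7.0)):
    return SplineSpec("natural_cubic", internal, boundary, intercept=intercept)


class TestSplineSpec:
    def test_dimensions(self):
        assert bs_spec(intercept=True).dim == 6
        assert bs_spec(intercept=False).dim == 5
        assert ns_spec(intercept=True).dim == 5
        assert ns_spec(intercept=False).dim == 4

    @pytest.mark.parametrize(
        "internal,boundary",
        [((5.0, 5.0), (0, 10)), ((8.0, 3.0), (0, 10)), ((0.0, 5.0), (0, 10)), ((), (10, 10))],
    )
    def test_invalid_knots_rejected(self, internal, boundary):
        with pytest.raises(InvalidSpecError):
            SplineSpec("quadratic_bspline", internal, boundary)


class TestEvaluateSpline:
    def test_partition_of_unity(self):
        x = np.linspace(0, 30, 301)
        B = evaluate_spline(x, bs_spec(intercept=True)).values
        assert np.all(np.abs(B.sum(axis=1) - 1) < 1e-10)

    def test_matches_de_boor_recursion(self):
        x = np.linspace(0, 30, 101)
        ours = evaluate_spline(x, bs_spec(intercept=True)).values
        ref = quadratic_bspline_design(x, (10.0, 22.5, 27.0), (0.0, 30.0))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_dropping_intercept_drops_first_column(self):
        x = np.linspace(0, 30, 50)
        full = evaluate_spline(x, bs_spec(intercept=True)).values
        nointercept = evaluate_spline(x, bs_spec(intercept=False)).values
        np.testing.assert_allclose(nointercept, full[:, 1:])

    def test_natural_spline_second_derivative_vanishes_beyond_boundary(self):
        spec = ns_spec(boundary=(0.0, 10.0), internal=(3.0, 5.0, 7.0))
        h = 1e-4
        for edge, outside in [(0.0, -2.0), (10.0, 12.0)]:
            pts = np.array([edge - h, edge, edge + h, outside - h, outside, outside + h])
            B = evaluate_spline(pts, spec, extrapolate=True).values
            d2_edge = (B[0] - 2 * B[1] + B[2]) / h**2
            d2_out = (B[3] - 2 * B[4] + B[5]) / h**2
            assert np.all(np.abs(d2_edge) < 1e-4)
            assert np.all(np.abs(d2_out) < 1e-4)

    def test_empty_input_gives_empty_matrix(self):
        B = evaluate_spline(np.array([]), bs_spec())
        assert B.values.shape == (0, 5)

    def test_outside_boundary_raises_without_extrapolation(self):
        with pytest.raises(ExtrapolationError):
            evaluate_spline(np.array([31.0]), bs_spec())


class TestCrossBasis:
    def test_zero_lag_moving_average_equals_temperature_basis(self):
        temps = np.random.default_rng(0).uniform(0, 30, 40)
        spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=0, moving_average=True)
        cb = build_crossbasis(temps, spec)
        tb = evaluate_spline(temps, bs_spec())
        np.testing.assert_allclose(cb.values, tb.values)

    def test_constant_series_gives_identical_rows(self):
        temps = np.full(30, 17.0)
        lag = ns_spec(internal=(1.0, 2.0), boundary=(0.0, 3.0))
        spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=3, lag_spline=lag)
        cb = build_crossbasis(temps, spec)
        np.testing.assert_allclose(cb.values, cb.values[0][None, :].repeat(27, axis=0))

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(7)
        temps = rng.uniform(0, 30, 50)
        tspec = bs_spec()  # v_x = 5
        lag = SplineSpec("natural_cubic", (1.5,), (0.0, 3.0), intercept=False)  # v_l = 2
        spec = CrossBasisSpec(temp_spline=tspec, max_lag=3, lag_spline=lag)
        assert spec.v_x == 5 and spec.v_l == 2

        phi = lambda x, j: evaluate_spline(np.array([x]), tspec).values[0, j]
        psi = lambda l, k: evaluate_spline(np.array([float(l)]), lag, extrapolate=True).values[0, k]
        ref = crossbasis_triple_loop(temps, phi, psi, 3, 5, 2)
        ours = build_crossbasis(temps, spec)
        assert ours.first_row == 3
        np.testing.assert_allclose(ours.values, ref, atol=1e-10)

    def test_moving_average_applies_basis_to_window_mean(self):
        temps = np.random.default_rng(3).uniform(5, 25, 20)
        spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=2, moving_average=True)
        cb = build_crossbasis(temps, spec)
        ma = np.convolve(temps, np.ones(3) / 3, mode="valid")
        np.testing.assert_allclose(cb.values, evaluate_spline(ma, bs_spec()).values)

    def test_short_series_raises(self):
        spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=5, moving_average=True)
        with pytest.raises(InsufficientDataError):
            build_crossbasis(np.array([10.0, 12.0]), spec)


class TestReduction:
    def test_single_lag_is_identity(self):
        spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=0, moving_average=True)
        eta = np.arange(5.0)
        v = np.diag(np.arange(1.0, 6.0))
        fit = reduce_coefficients(eta, v, spec)
        np.testing.assert_allclose(fit.beta, eta)
        np.testing.assert_allclose(fit.vcov, v)

    def test_reduced_curve_matches_brute_force_lag_summation(self):
        rng = np.random.default_rng(11)
        tspec = bs_spec()
        lag = SplineSpec("natural_cubic", log_knots(5, 1), (0.0, 5.0), intercept=True)
        spec = CrossBasisSpec(temp_spline=tspec, max_lag=5, lag_spline=lag)
        assert spec.v_l == 3
        eta = rng.standard_normal(spec.dim)
        fit = reduce_coefficients(eta, np.eye(spec.dim), spec)

        phi = lambda x, j: evaluate_spline(np.array([x]), tspec).values[0, j]
        psi = lambda l, k: evaluate_spline(np.array([float(l)]), lag, extrapolate=True).values[0, k]
        for x in rng.uniform(0, 30, 20):
            q = evaluate_spline(np.array([x]), tspec).values[0]
            expected = lag_cumulated_curve(x, eta, phi, psi, 5, spec.v_x, spec.v_l)
            assert abs(q @ fit.beta - expected) < 1e-10

    def test_reduction_consistent_with_crossbasis_at_constant_temperature(self):
        # for constant temperature x the cross-basis row dotted with eta must
        # equal Q_x beta after reduction
        rng = np.random.default_rng(4)
        tspec = bs_spec()
        lag = SplineSpec("natural_cubic", (1.0, 2.0), (0.0, 4.0), intercept=True)
        spec = CrossBasisSpec(temp_spline=tspec, max_lag=4, lag_spline=lag)
        eta = rng.standard_normal(spec.dim)
        fit = reduce_coefficients(eta, np.eye(spec.dim), spec)
        for x in (3.0, 12.0, 28.5):
            cb = build_crossbasis(np.full(10, x), spec)
            q = evaluate_spline(np.array([x]), tspec).values[0]
            assert abs(cb.values[0] @ eta - q @ fit.beta) < 1e-10

    def test_reduction_preserves_psd(self):
        rng = np.random.default_rng(9)
        tspec = bs_spec()
        lag = SplineSpec("natural_cubic", (1.0, 2.0), (0.0, 4.0), intercept=True)
        spec = CrossBasisSpec(temp_spline=tspec, max_lag=4, lag_spline=lag)
        A = rng.standard_normal((spec.dim, spec.dim))
        v_eta = A @ A.T
        fit = reduce_coefficients(rng.standard_normal(spec.dim), v_eta, spec)
        np.testing.assert_allclose(fit.vcov, fit.vcov.T)
        w = np.linalg.eigvalsh(fit.vcov)
        assert w.min() >= -1e-8 * max(w.max(), 1e-12)

    def test_dimension_mismatch_raises(self):
        spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=0, moving_average=True)
        with pytest.raises(InvalidSpecError):
            reduce_coefficients(np.zeros(4), np.eye(4), spec)


def test_log_knots_equally_spaced_on_log_scale():
    knots = np.log(log_knots(21, 3))
    diffs = np.diff(np.concatenate([[np.log(1.0)], knots, [np.log(21.0)]]))
    np.testing.assert_allclose(diffs, diffs[0])


def test_lag_matrix_shape():
    lag = SplineSpec("natural_cubic", (1.0, 2.0, 4.0), (0.0, 21.0), intercept=True)
    spec = CrossBasisSpec(temp_spline=bs_spec(), max_lag=21, lag_spline=lag)
    C = lag_basis_matrix(spec)
    assert C.shape == (22, 5)
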
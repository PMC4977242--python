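"""Quadratic-plateau fitter: analytic identities, oracle equivalence,
equivariances and parameter recovery."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plateaulc as plc
from plateaulc.errors import DomainError, InsufficientDataError
from plateaulc.regression import QuadraticPlateauFit

from conftest import PRINTED_COEFFS, brute_force_fit


def _printed_fit():
    a, b, c = PRINTED_COEFFS
    knot, plateau = plc.knot_from_coefficients(a, b, c)
    return QuadraticPlateauFit(
        a=a, b=b, c=c, knot=knot, knot_index=round(knot), plateau=plateau,
        rss=0.0, n_subjects=120,
    )


class TestPredict:
    def test_below_knot_is_quadratic(self):
        # 19.73 - 1.614 + 0.03843 at I = 1
        assert plc.predict(_printed_fit(), 1.0) == pytest.approx(18.15443)

    def test_above_knot_is_plateau(self):
        fit = _printed_fit()
        assert plc.predict(fit, 100.0) == fit.plateau
        assert plc.predict(fit, 100.0) == pytest.approx(2.78, abs=5e-3)

    def test_pure_plateau_degenerate_quadratic(self):
        fit = QuadraticPlateauFit(a=4.0, b=0.0, c=1.0, knot=0.0, knot_index=0,
                                  plateau=4.0, rss=0.0, n_subjects=10)
        for i in (1.0, 7.0, 50.0):
            assert plc.predict(fit, i) == 4.0

    def test_index_below_one_rejected(self):
        with pytest.raises(DomainError):
            plc.predict(_printed_fit(), 0.5)


class TestKnotFromCoefficients:
    @pytest.mark.parametrize(
        "coeffs, knot, plateau",
        [
            ((4.0, -4.0, 1.0), 2.0, 0.0),   # perfect square (I-2)^2
            ((5.0, 0.0, 0.1), 0.0, 5.0),    # vertex at the origin
        ],
    )
    def test_exact_vertices(self, coeffs, knot, plateau):
        k, p = plc.knot_from_coefficients(*coeffs)
        assert k == pytest.approx(knot, abs=1e-12)
        assert p == pytest.approx(plateau, abs=1e-12)

    def test_reference_coefficients(self):
        k, p = plc.knot_from_coefficients(*PRINTED_COEFFS)
        assert round(k) == 21
        assert round(p, 2) == 2.78

    @pytest.mark.parametrize("c", [0.0, -0.5])
    def test_nonpositive_curvature_rejected(self, c):
        with pytest.raises(DomainError):
            plc.knot_from_coefficients(1.0, -1.0, c)


class TestFit:
    def test_noiseless_recovery(self, printed_curve):
        series = plc.simulate_variance_series(printed_curve, 120, 0.0, seed=0)
        fit = plc.fit_quadratic_plateau(series)
        assert not fit.degenerate
        assert fit.knot == pytest.approx(printed_curve.knot, rel=1e-6)
        assert fit.plateau == pytest.approx(printed_curve.plateau, rel=1e-6)
        assert fit.c == pytest.approx(printed_curve.curvature, rel=1e-6)

    def test_constant_series_degenerates(self):
        arr = np.column_stack([np.arange(1, 21), np.full(20, 5.0)])
        fit = plc.fit_quadratic_plateau(arr)
        assert fit.degenerate
        assert fit.plateau == pytest.approx(5.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_increasing_series_degenerates(self):
        arr = np.column_stack([np.arange(1, 21), np.linspace(1, 10, 20)])
        fit = plc.fit_quadratic_plateau(arr)
        assert fit.degenerate

    def test_insufficient_data(self):
        arr = np.column_stack([np.arange(1, 4), np.ones(3)])
        with pytest.raises(InsufficientDataError):
            plc.fit_quadratic_plateau(arr)

    def test_nonfinite_rejected(self):
        arr = np.column_stack([np.arange(1, 6), [1, 2, np.nan, 4, 5]])
        with pytest.raises(ValueError):
            plc.fit_quadratic_plateau(arr)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed, printed_curve):
        """On small instances the profile fit is as good as exhaustive search."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        curve = plc.LearningCurve(
            plateau=float(rng.uniform(1, 5)),
            curvature=float(rng.uniform(0.01, 0.2)),
            knot=float(rng.uniform(3, n - 2)),
        )
        index = np.arange(1, n + 1, dtype=float)
        y = np.maximum(0.0, curve(index) + rng.normal(0, 0.6, n))
        fit = plc.fit_quadratic_plateau(
            np.column_stack([index, y]), refine=False
        )
        oracle_rss = brute_force_fit(index, y)[0]
        assert fit.rss <= oracle_rss + 1e-8
        # refinement can only improve
        refined = plc.fit_quadratic_plateau(np.column_stack([index, y]))
        assert refined.rss <= fit.rss + 1e-12

    @pytest.mark.parametrize("seed", [3, 17])
    def test_scale_equivariance(self, seed, printed_curve):
        rng = np.random.default_rng(seed)
        index = np.arange(1, 61, dtype=float)
        y = np.maximum(0.0, printed_curve(index) + rng.normal(0, 0.5, 60))
        s = 7.5
        base = plc.fit_quadratic_plateau(np.column_stack([index, y]))
        scaled = plc.fit_quadratic_plateau(np.column_stack([index, s * y]))
        assert scaled.knot == pytest.approx(base.knot, abs=1e-5)
        assert scaled.plateau == pytest.approx(s * base.plateau, rel=1e-6)
        assert scaled.c == pytest.approx(s * base.c, rel=1e-6)
        assert scaled.a == pytest.approx(s * base.a, rel=1e-6)

    def test_appending_plateau_points_leaves_knot(self, printed_curve):
        """Extra plateau-level observations beyond K do not move the knot."""
        series_60 = plc.simulate_variance_series(printed_curve, 60, 0.0, seed=0)
        series_120 = plc.simulate_variance_series(printed_curve, 120, 0.0, seed=0)
        k60 = plc.fit_quadratic_plateau(series_60).knot
        k120 = plc.fit_quadratic_plateau(series_120).knot
        assert k120 == pytest.approx(k60, abs=1e-5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        knot=st.floats(min_value=5, max_value=35),
        noise=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_smooth_join_identities(self, seed, knot, noise):
        """K = -b/(2c) and P = a - b^2/(4c) on every non-degenerate fit."""
        rng = np.random.default_rng(seed)
        curve = plc.LearningCurve(plateau=2.5, curvature=0.05, knot=knot)
        index = np.arange(1, 61, dtype=float)
        y = np.maximum(0.0, curve(index) + rng.normal(0, noise, 60))
        fit = plc.fit_quadratic_plateau(np.column_stack([index, y]))
        if fit.degenerate:
            return
        assert fit.knot == pytest.approx(-fit.b / (2 * fit.c), rel=1e-9)
        assert fit.plateau == pytest.approx(
            fit.a - fit.b**2 / (4 * fit.c), rel=1e-9, abs=1e-12
        )
        # the plateau is the curve's minimum and the curve never rises before K
        grid = np.linspace(1, 60, 300)
        pred = plc.predict(fit, grid)
        assert pred.min() >= fit.plateau - 1e-9
        before = pred[grid <= fit.knot]
        assert np.all(np.diff(before) <= 1e-9)

    def test_parameter_recovery_rate(self):
        """|estimated - true knot| <= 2 in at least 90% of noisy replicates.

        Noise sd is 5% of the curve's range: the regime where the knot is
        statistically identifiable to +-2 subjects at all (the least-squares
        optimum itself loses that precision well before sd reaches ~10% of
        the range, because absolute noise grows with the knot while the
        curvature that localises it stays fixed).
        """
        rng = np.random.default_rng(2016)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            true_k = float(rng.uniform(10, 40))
            curve = plc.LearningCurve(plateau=2.78, curvature=0.03843, knot=true_k)
            index = np.arange(1, 121, dtype=float)
            rng_range = curve(index).max() - curve(index).min()
            y = np.maximum(0.0, curve(index) + rng.normal(0, 0.05 * rng_range, 120))
            fit = plc.fit_quadratic_plateau(np.column_stack([index, y]))
            if not fit.degenerate and abs(fit.knot - true_k) <= 2:
                hits += 1
        assert hits / n_rep >= 0.90


class TestFittedCurveTable:
    def test_row_count_and_residual_definition(self, printed_curve):
        series = plc.simulate_variance_series(printed_curve, 120, 0.4, seed=9)
        fit = plc.fit_quadratic_plateau(series)
        table = plc.fitted_curve_table(fit, series)
        assert len(table) == 120
        np.testing.assert_allclose(
            table["residual"], table["observed"] - table["fitted"], atol=0
        )

    def test_noiseless_residuals_zero(self, printed_curve):
        series = plc.simulate_variance_series(printed_curve, 120, 0.0, seed=0)
        fit = plc.fit_quadratic_plateau(series)
        table = plc.fitted_curve_table(fit, series)
        np.testing.assert_allclose(table["residual"], 0.0, atol=1e-7)
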
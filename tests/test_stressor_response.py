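"""Regression engines against independent oracles and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecocrit import (
    check_linearity,
    fit_logistic,
    fit_ols_line,
    fit_plane,
    fit_rma,
    loess_smooth,
)
from ecocrit.exceptions import (
    CollinearityError,
    DegenerateDataError,
    ExtrapolationError,
    InsufficientDataError,
    SeparationError,
)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately separate from the implementation)
# ---------------------------------------------------------------------------


def rma_oracle(x, y):
    """Ranged major axis via explicit eigen-decomposition.

    Centre, divide by ranges, build the 2x2 covariance, take the leading
    eigenvector, back-scale its direction by the range ratio.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rx, ry = np.ptp(x), np.ptp(y)
    xs = (x - x.mean()) / rx
    ys = (y - y.mean()) / ry
    cov = np.cov(np.vstack([xs, ys]), ddof=1)
    w, v = np.linalg.eigh(cov)
    lead = v[:, np.argmax(w)]
    slope_std = lead[1] / lead[0]
    if np.sign(slope_std) != np.sign(cov[0, 1]) and cov[0, 1] != 0:
        slope_std = -slope_std  # eigenvector sign is arbitrary
    slope = slope_std * ry / rx
    return slope, y.mean() - slope * x.mean()


def plane_oracle(u, v, z):
    """Normal equations for z = a0 + a1 u + a2 v, solved explicitly."""
    X = np.column_stack([np.ones_like(u), u, v])
    return np.linalg.solve(X.T @ X, X.T @ z)


def loess_oracle(xs, ys, x0, span=0.75, degree=2):
    """Tricube-weighted local polynomial regression at one point."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    k = max(degree + 1, int(np.ceil(span * len(xs))))
    d = np.abs(xs - x0)
    h = np.sort(d)[k - 1]
    w = np.where(d < h, (1 - (d / h) ** 3) ** 3, 0.0) if h > 0 else (d == 0) * 1.0
    A = np.vander(xs - x0, degree + 1, increasing=True)
    W = np.diag(w)
    beta = np.linalg.pinv(A.T @ W @ A) @ (A.T @ W @ ys)
    return beta[0]


# ---------------------------------------------------------------------------
# ranged major axis
# ---------------------------------------------------------------------------


class TestRMA:
    def test_collinear_points_recover_exact_line(self):
        f = fit_rma([0, 1, 2], [0, 2, 4])
        assert f.slope == pytest.approx(2.0)
        assert f.intercept == pytest.approx(0.0)
        assert f.r2 == pytest.approx(1.0)

    def test_axis_swap_gives_reciprocal_slope(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(scale=0.5, size=30)
        f_xy = fit_rma(x, y)
        f_yx = fit_rma(y, x)
        assert f_yx.slope == pytest.approx(1.0 / f_xy.slope, abs=1e-9)

    def test_matches_eigen_oracle_on_small_example(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 3.0])
        slope, intercept = rma_oracle(x, y)
        f = fit_rma(x, y)
        assert f.slope == pytest.approx(slope, abs=1e-12)
        assert f.intercept == pytest.approx(intercept, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_eigen_oracle_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        x = rng.normal(rng.uniform(-3, 3), rng.uniform(0.2, 3), size=n)
        y = rng.uniform(-2, 2) * x + rng.normal(scale=rng.uniform(0.1, 2), size=n)
        slope, intercept = rma_oracle(x, y)
        f = fit_rma(x, y)
        assert f.slope == pytest.approx(slope, abs=1e-9)
        assert f.intercept == pytest.approx(intercept, abs=1e-9)

    def test_line_passes_through_centroid(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = -0.7 * x + rng.normal(scale=0.3, size=40)
        f = fit_rma(x, y)
        assert f.predict(x.mean()) == pytest.approx(y.mean(), abs=1e-9)

    @given(c=st.floats(0.01, 100), seed=st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = 2.0 * x + rng.normal(scale=0.5, size=20)
        base = fit_rma(x, y).slope
        assert fit_rma(c * x, y).slope == pytest.approx(base / c, rel=1e-9)
        assert fit_rma(x, c * y).slope == pytest.approx(base * c, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_slope_bracketed_by_ols_slopes(self, seed):
        rng = np.random.default_rng(seed + 100)
        x = rng.normal(size=50)
        y = -1.3 * x + rng.normal(scale=0.8, size=50)
        f = fit_rma(x, y)
        if not (0 < f.r2 < 1):
            pytest.skip("degenerate draw")
        b_yx = abs(fit_ols_line(x, y).slope)
        b_xy_inv = 1.0 / abs(fit_ols_line(y, x).slope)
        lo, hi = sorted([b_yx, b_xy_inv])
        assert lo - 1e-9 <= abs(f.slope) <= hi + 1e-9

    def test_degenerate_and_insufficient_data(self):
        with pytest.raises(DegenerateDataError):
            fit_rma([1, 1, 1], [0, 1, 2])
        with pytest.raises(InsufficientDataError):
            fit_rma([0, 1], [0, 1])


# ---------------------------------------------------------------------------
# OLS line and plane
# ---------------------------------------------------------------------------


class TestOLS:
    def test_exact_line(self):
        f = fit_ols_line([0, 1, 2], [0, 1, 2])
        assert (f.slope, f.intercept) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_constant_response(self):
        f = fit_ols_line([0, 1, 2], [0.4, 0.4, 0.4])
        assert f.slope == 0.0
        assert f.r2 == 0.0

    def test_hand_computed_normal_equations(self):
        # x=(0,1,2), y=(0,2,2): slope = 1, intercept = 1/3
        f = fit_ols_line([0, 1, 2], [0, 2, 2])
        assert f.slope == pytest.approx(1.0)
        assert f.intercept == pytest.approx(1.0 / 3.0)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        f = fit_ols_line(x, y)
        assert float(np.sum(f.residuals)) == pytest.approx(0.0, abs=1e-9)


class TestPlane:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        u = rng.normal(2, 0.5, 50)
        v = rng.normal(0, 0.3, 50)
        z = 2.0 - 0.5 * u - 0.5 * v
        f = fit_plane(u, v, z)
        assert f.a0 == pytest.approx(2.0, abs=1e-9)
        assert f.a1 == pytest.approx(-0.5, abs=1e-9)
        assert f.a2 == pytest.approx(-0.5, abs=1e-9)
        assert f.R2 == pytest.approx(1.0)

    def test_constant_response(self):
        rng = np.random.default_rng(1)
        f = fit_plane(rng.normal(size=10), rng.normal(size=10), np.full(10, 0.7))
        assert f.a1 == pytest.approx(0.0, abs=1e-9)
        assert f.a2 == pytest.approx(0.0, abs=1e-9)
        assert f.R2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        u = rng.normal(2, 0.4, 6)
        v = rng.normal(0.5, 0.3, 6)
        z = 1.8 - 0.4 * u - 0.2 * v + rng.normal(scale=0.05, size=6)
        a = plane_oracle(u, v, z)
        f = fit_plane(u, v, z)
        assert (f.a0, f.a1, f.a2) == pytest.approx(tuple(a), abs=1e-9)

    def test_collinearity_rejected(self):
        u = np.linspace(0, 1, 20)
        with pytest.raises(CollinearityError):
            fit_plane(u, 2 * u + 1e-9, u)

    @pytest.mark.parametrize("seed", range(50))
    def test_r2_never_below_nested_univariate(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        u = rng.normal(2, 0.4, n)
        v = 0.5 * u + rng.normal(scale=0.3, size=n)
        z = 1.8 - 0.4 * u - 0.2 * v + rng.normal(scale=0.2, size=n)
        f = fit_plane(u, v, z)
        r2u = fit_ols_line(u, z).r2
        r2v = fit_ols_line(v, z).r2
        assert f.R2 >= max(r2u, r2v) - 1e-12


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


class TestLogistic:
    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(2, 0.8, 2000)
        p = 1 / (1 + np.exp(-(4 - 2 * x)))
        labels = rng.random(2000) < p
        f = fit_logistic(x, labels)
        se = np.sqrt(np.diag(f.cov))
        assert abs(f.beta0 - 4.0) < 3 * se[0]
        assert abs(f.beta1 - (-2.0)) < 3 * se[1]

    def test_permuted_labels_rarely_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 0.5, 200)
        base = (x + rng.normal(scale=0.5, size=200)) > 2
        n_insignificant = 0
        for seed in range(1, 101):
            perm = np.random.default_rng(seed).permutation(base)
            f = fit_logistic(x, perm)
            wald_z = f.beta1 / np.sqrt(f.cov[1, 1])
            p_val = 2 * stats.norm.sf(abs(wald_z))
            n_insignificant += p_val > 0.05
        assert n_insignificant >= 90

    def test_uniform_labels_rejected(self):
        with pytest.raises(SeparationError):
            fit_logistic(np.arange(12, dtype=float), np.ones(12))

    def test_complete_separation_detected(self):
        x = np.arange(20, dtype=float)
        labels = (x >= 10).astype(int)
        with pytest.raises(SeparationError):
            fit_logistic(x, labels)

    @pytest.mark.parametrize("seed", range(20))
    def test_returned_fit_is_local_likelihood_optimum(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 80)
        labels = rng.random(80) < 1 / (1 + np.exp(-(0.5 + 1.5 * x)))
        if labels.min() == labels.max():
            pytest.skip("degenerate draw")
        f = fit_logistic(x, labels)

        def loglik(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(labels * eta - np.log1p(np.exp(eta))))

        best = loglik(f.beta0, f.beta1)
        pert = rng.normal(scale=0.3, size=(100, 2))
        for db0, db1 in pert:
            assert best >= loglik(f.beta0 + db0, f.beta1 + db1) - 1e-8


# ---------------------------------------------------------------------------
# segmented linearity check
# ---------------------------------------------------------------------------


class TestCheckLinearity:
    def test_exactly_linear_data_keep_full_range(self):
        x = np.linspace(0, 2, 60)
        y = 1 - 0.5 * x
        seg = check_linearity(x, y)
        assert seg.delta_ic < 4
        assert seg.linear_region == (pytest.approx(0.0), pytest.approx(2.0))

    def test_recovers_known_breakpoint(self):
        rng = np.random.default_rng(99)
        x = np.sort(rng.uniform(0, 2, 200))
        y = np.where(x < 1, 1 - (x - 1), 1.0) + rng.normal(scale=0.01, size=200)
        seg = check_linearity(x, y)
        assert seg.delta_ic > 4
        assert abs(seg.breakpoint - 1.0) < 0.1
        # steeper (declining) segment is the recommended linear region
        assert seg.linear_region[1] == pytest.approx(seg.breakpoint)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            check_linearity(np.arange(8.0), np.arange(8.0))


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------


class TestLoess:
    def test_constant_preserved(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 5, 30))
        sm = loess_smooth(x, np.full(30, 0.4))
        for x0 in (x[0], 1.7, 3.2, x[-1]):
            assert sm(x0) == pytest.approx(0.4, abs=1e-9)

    def test_linear_data_reproduced(self):
        x = np.linspace(0, 3, 40)
        sm = loess_smooth(x, x.copy())
        grid = np.linspace(0.1, 2.9, 17)
        np.testing.assert_allclose(sm(grid), grid, atol=1e-6)

    def test_matches_independent_tricube_oracle(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 2 * np.pi, 60))
        y = np.sin(x) + rng.normal(scale=0.1, size=60)
        sm = loess_smooth(x, y, span=0.75)
        for x0 in np.linspace(0.5, 5.5, 9):
            assert sm(x0) == pytest.approx(
                loess_oracle(x, y, x0, span=0.75), abs=1e-6
            )

    def test_extrapolation_rejected(self):
        x = np.linspace(0, 1, 20)
        sm = loess_smooth(x, x)
        with pytest.raises(ExtrapolationError):
            sm(1.5)

    def test_invalid_span_rejected(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            loess_smooth(x, x, span=1.5)
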
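"""Regression engines for stressor-response modelling.

Fitting machinery shared by the criteria-derivation modules:

* :func:`fit_rma` — ranged major axis (RMA) regression, a type II method
  appropriate when both the nutrient concentration and the biological EQR
  carry error.  Each centred variable is divided by its observed range, the
  major-axis (leading principal direction) slope is computed on the
  range-standardized pairs, and the slope is back-scaled by the ratio of
  ranges.  The line passes through the centroid.
* :func:`fit_ols_line` / :func:`fit_plane` — ordinary least squares line and
  plane (EQR on log10 TP and log10 TN), the nested baselines and the
  bivariate criteria model.
* :func:`fit_logistic` — binomial logistic regression of an impairment label
  on log10 concentration (maximum likelihood via statsmodels, with
  observed-information covariance and complete-separation detection).
* :func:`check_linearity` — segmented (two-piece continuous) regression by
  breakpoint grid search, used to confirm the linear region of the response
  before a linear fit is trusted.
* :func:`loess_smooth` — locally weighted quadratic regression with tricube
  weights, the smoother used for the classification-mismatch curves and for
  visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    CollinearityError,
    ConvergenceError,
    DegenerateDataError,
    ExtrapolationError,
    InsufficientDataError,
    SeparationError,
)

__all__ = [
    "LinearFit",
    "PlaneFit",
    "LogisticFit",
    "SegmentedFit",
    "LoessSmooth",
    "fit_rma",
    "fit_ols_line",
    "fit_plane",
    "fit_logistic",
    "check_linearity",
    "loess_smooth",
]

#: |beta| beyond which a logistic fit is treated as diverging (separation).
_SEPARATION_BETA_LIMIT = 50.0


@dataclass
class LinearFit:
    """A fitted straight line y = intercept + slope * x."""

    slope: float
    intercept: float
    r2: float
    residuals: np.ndarray  # ordinate-direction: y - predicted y
    method_tag: str  # "RMA" | "OLS"
    n: int
    x_role: str = "x"
    y_role: str = "y"
    x_range: tuple[float, float] = (float("-inf"), float("inf"))

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "method": self.method_tag,
            "n": self.n,
            "x_role": self.x_role,
            "y_role": self.y_role,
            "residual_q25": float(np.percentile(self.residuals, 25)),
            "residual_q75": float(np.percentile(self.residuals, 75)),
        }


@dataclass
class PlaneFit:
    """A fitted plane eqr = a0 + a1 * log10(TP) + a2 * log10(TN)."""

    a0: float
    a1: float
    a2: float
    R2: float
    residuals: np.ndarray
    n: int

    def predict(self, log_tp, log_tn):
        return (
            self.a0
            + self.a1 * np.asarray(log_tp, dtype=float)
            + self.a2 * np.asarray(log_tn, dtype=float)
        )

    def to_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
            "R2": self.R2,
            "n": self.n,
            "residual_q25": float(np.percentile(self.residuals, 25)),
            "residual_q75": float(np.percentile(self.residuals, 75)),
        }


@dataclass
class LogisticFit:
    """Logistic regression logit P(label=1) = beta0 + beta1 * x."""

    beta0: float
    beta1: float
    cov: np.ndarray  # 2x2 parameter covariance, order (beta0, beta1)
    n: int
    converged: bool
    x_range: tuple[float, float] = (float("-inf"), float("inf"))

    def linear_predictor(self, x):
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)

    def predict_proba(self, x):
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(x)))

    def linear_predictor_se(self, x):
        """Delta-method standard error of the linear predictor at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        var = (
            self.cov[0, 0]
            + 2.0 * x * self.cov[0, 1]
            + x**2 * self.cov[1, 1]
        )
        se = np.sqrt(np.maximum(var, 0.0))
        return se if se.size > 1 else float(se[0])


@dataclass
class SegmentedFit:
    """Result of the two-segment linearity check."""

    breakpoint: float
    slopes: tuple[float, float]  # (left, right)
    delta_ic: float  # AIC(one segment) - AIC(two segments); > 0 favours two
    linear_region: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# type II line fitting
# ---------------------------------------------------------------------------


def _check_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < min_n:
        raise InsufficientDataError(f"need at least {min_n} points, got {len(x)}")
    return x, y


def fit_rma(x, y) -> LinearFit:
    """Ranged major axis regression of y on x.

    The slope is orientation-symmetric: swapping x and y yields the exact
    reciprocal.  Residuals are nevertheless reported in the ordinate
    direction, because criteria ranges are drawn as EQR-direction offset
    lines parallel to the fit.  ``r2`` is the squared Pearson correlation.
    """
    x, y = _check_xy(x, y, 3)
    rx = np.ptp(x)
    ry = np.ptp(y)
    if rx == 0 or ry == 0:
        raise DegenerateDataError("RMA requires non-zero range in both variables")

    xs = (x - x.mean()) / rx
    ys = (y - y.mean()) / ry
    sxx = np.var(xs, ddof=1)
    syy = np.var(ys, ddof=1)
    sxy = np.cov(xs, ys, ddof=1)[0, 1]

    if sxy == 0.0:
        # no covariance: major axis of the standardized cloud is ambiguous in
        # sign; report slope along the larger-variance axis with sign +.
        b_std = 0.0 if sxx >= syy else np.inf
    else:
        # closed-form major-axis slope (leading eigenvector of the 2x2
        # covariance of the range-standardized pairs)
        d = syy - sxx
        b_std = (d + np.sqrt(d * d + 4.0 * sxy * sxy)) / (2.0 * sxy)
    slope = b_std * ry / rx
    intercept = y.mean() - slope * x.mean()
    if not np.isfinite(slope):
        raise DegenerateDataError("RMA slope is not finite (vertical major axis)")

    r = np.corrcoef(x, y)[0, 1]
    residuals = y - (intercept + slope * x)
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r * r),
        residuals=residuals,
        method_tag="RMA",
        n=len(x),
        x_range=(float(x.min()), float(x.max())),
    )


def fit_ols_line(x, y, x_role: str = "x", y_role: str = "y") -> LinearFit:
    """Ordinary least-squares line of y on x (nested baseline for the plane)."""
    x, y = _check_xy(x, y, 3)
    if np.ptp(x) == 0:
        raise DegenerateDataError("OLS requires non-zero range in x")
    if np.ptp(y) == 0:
        # constant response: flat line, r2 = 0 by convention
        res = y - y.mean()
        return LinearFit(0.0, float(y.mean()), 0.0, res, "OLS", len(x),
                         x_role, y_role, (float(x.min()), float(x.max())))
    lr = stats.linregress(x, y)
    residuals = y - (lr.intercept + lr.slope * x)
    return LinearFit(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r2=float(lr.rvalue**2),
        residuals=residuals,
        method_tag="OLS",
        n=len(x),
        x_role=x_role,
        y_role=y_role,
        x_range=(float(x.min()), float(x.max())),
    )


# ---------------------------------------------------------------------------
# bivariate plane
# ---------------------------------------------------------------------------


def fit_plane(log_tp, log_tn, eqr, collinearity_limit: float = 0.999) -> PlaneFit:
    """OLS fit of EQR on log10 TP and log10 TN."""
    u = np.asarray(log_tp, dtype=float).ravel()
    v = np.asarray(log_tn, dtype=float).ravel()
    z = np.asarray(eqr, dtype=float).ravel()
    if not (len(u) == len(v) == len(z)):
        raise ValueError("log_tp, log_tn and eqr must have the same length")
    if len(u) < 4:
        raise InsufficientDataError(f"plane fit needs >= 4 points, got {len(u)}")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise DegenerateDataError("plane fit requires variation in both predictors")
    r_uv = float(np.corrcoef(u, v)[0, 1])
    if abs(r_uv) >= collinearity_limit:
        raise CollinearityError(r_uv)

    X = sm.add_constant(np.column_stack([u, v]))
    res = sm.OLS(z, X).fit()
    r2 = float(res.rsquared) if np.ptp(z) > 0 else 0.0
    return PlaneFit(
        a0=float(res.params[0]),
        a1=float(res.params[1]),
        a2=float(res.params[2]),
        R2=max(0.0, r2),
        residuals=np.asarray(res.resid, dtype=float),
        n=len(z),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def fit_logistic(x, labels, max_iter: int = 100) -> LogisticFit:
    """Binomial logistic regression of a 0/1 label on log10 concentration.

    Raises :class:`SeparationError` when the classes are completely (or
    quasi-completely) separated along x, in which case no finite MLE exists;
    the criterion can still be bracketed by the data but not estimated.
    """
    x = np.asarray(x, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if x.shape != labels.shape:
        raise ValueError("x and labels must have the same length")
    if len(x) < 10:
        raise InsufficientDataError(f"logistic fit needs >= 10 points, got {len(x)}")
    if labels.min() == labels.max():
        raise SeparationError("labels are all identical; both classes required")
    # complete separation: the two classes occupy disjoint x intervals
    x1 = x[labels == 1]
    x0 = x[labels == 0]
    if x1.min() > x0.max() or x1.max() < x0.min():
        raise SeparationError(
            "classes are completely separated along the concentration axis"
        )

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(labels, X).fit(disp=0, maxiter=max_iter, method="newton")
        except Exception as exc:  # statsmodels raises on perfect separation
            if "separat" in str(exc).lower():
                raise SeparationError(str(exc)) from exc
            raise ConvergenceError(str(exc)) from exc
    params = np.asarray(res.params, dtype=float)
    if np.max(np.abs(params)) > _SEPARATION_BETA_LIMIT:
        raise SeparationError(
            f"diverging coefficients |beta| > {_SEPARATION_BETA_LIMIT}: "
            "quasi-complete separation"
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"logistic fit did not converge in {max_iter} iterations")
    cov = np.asarray(res.cov_params(), dtype=float)
    if not np.all(np.isfinite(cov)):
        cov = np.full((2, 2), np.nan)
    return LogisticFit(
        beta0=float(params[0]),
        beta1=float(params[1]),
        cov=cov,
        n=len(x),
        converged=True,
        x_range=(float(x.min()), float(x.max())),
    )


# ---------------------------------------------------------------------------
# segmented (two-piece) linearity check
# ---------------------------------------------------------------------------


def _gaussian_aic(sse: float, n: int, k: int) -> float:
    # Gaussian log-likelihood profile in sigma; constant terms cancel in deltas
    sse = max(sse, 1e-300)
    return n * np.log(sse / n) + 2.0 * k


def check_linearity(
    x,
    y,
    n_grid: int = 50,
    ic_threshold: float = 4.0,
) -> SegmentedFit:
    """Confirm the linear region of a response via segmented regression.

    Grid-searches candidate breakpoints across the 10th–90th percentile of x,
    fitting at each a continuous two-segment least-squares model
    ``y = b0 + b1 x + b2 (x - c)+``.  When the two-segment model does not
    improve the Gaussian AIC by at least ``ic_threshold``, the whole x range
    is recommended for linear fitting; otherwise the segment with the steeper
    response is.
    """
    x, y = _check_xy(x, y, 10)
    lo, hi = np.percentile(x, [10, 90])
    if lo >= hi:
        raise DegenerateDataError("x has no spread between its 10th and 90th percentiles")
    candidates = np.linspace(lo, hi, n_grid)

    # one-segment baseline
    X1 = np.column_stack([np.ones_like(x), x])
    beta1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse1 = float(np.sum((y - X1 @ beta1) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sse1 <= 1e-12 * max(sst, 1.0):
        # already (numerically) exactly linear: a second segment can only
        # chase rounding noise and the Gaussian AIC is undefined at SSE ~ 0
        return SegmentedFit(
            breakpoint=float(0.5 * (lo + hi)),
            slopes=(float(beta1[1]), float(beta1[1])),
            delta_ic=0.0,
            linear_region=(float(x.min()), float(x.max())),
            diagnostics={"exact_linear": True, "n": len(x)},
        )
    aic1 = _gaussian_aic(sse1, len(x), 2)

    best = None
    for c in candidates:
        hinge = np.maximum(x - c, 0.0)
        X2 = np.column_stack([np.ones_like(x), x, hinge])
        beta2, *_ = np.linalg.lstsq(X2, y, rcond=None)
        sse2 = float(np.sum((y - X2 @ beta2) ** 2))
        if best is None or sse2 < best[0]:
            best = (sse2, float(c), beta2)
    sse2, c_best, beta2 = best
    # two-segment model estimates 4 quantities: b0, b1, b2 and the breakpoint
    aic2 = _gaussian_aic(sse2, len(x), 4)
    delta_ic = aic1 - aic2

    left_slope = float(beta2[1])
    right_slope = float(beta2[1] + beta2[2])
    x_lo, x_hi = float(x.min()), float(x.max())
    if delta_ic < ic_threshold:
        region = (x_lo, x_hi)
    elif abs(left_slope) >= abs(right_slope):
        region = (x_lo, c_best)
    else:
        region = (c_best, x_hi)
    return SegmentedFit(
        breakpoint=c_best,
        slopes=(left_slope, right_slope),
        delta_ic=float(delta_ic),
        linear_region=region,
        diagnostics={"aic_one": aic1, "aic_two": aic2, "n": len(x)},
    )


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------


class LoessSmooth:
    """Locally weighted polynomial smoother (tricube weights).

    Callable on scalars or arrays inside the fitted x range; evaluation
    outside the range raises :class:`ExtrapolationError` — local regression
    has no business extrapolating.
    """

    def __init__(self, x, y, span: float = 0.75, degree: int = 2):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if len(x) < 10:
            raise InsufficientDataError(f"loess needs >= 10 points, got {len(x)}")
        if not (0.0 < span <= 1.0):
            raise ValueError(f"span must be in (0, 1], got {span}")
        order = np.argsort(x)
        self.x = x[order]
        self.y = y[order]
        self.span = span
        self.degree = int(degree)
        self.k = max(self.degree + 1, int(np.ceil(span * len(x))))

    @property
    def x_range(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def _fit_at(self, x0: float) -> float:
        d = np.abs(self.x - x0)
        # bandwidth = distance to the k-th nearest neighbour
        h = np.partition(d, self.k - 1)[self.k - 1]
        if h == 0:
            # all nearest points coincide with x0: average them
            return float(self.y[d == 0].mean())
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        xw = self.x[use] - x0  # centre for conditioning
        yw = self.y[use]
        ww = w[use]
        X = np.vander(xw, self.degree + 1, increasing=True)
        sw = np.sqrt(ww)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yw * sw, rcond=None)
        return float(beta[0])

    def __call__(self, grid):
        scalar = np.isscalar(grid) or np.ndim(grid) == 0
        pts = np.atleast_1d(np.asarray(grid, dtype=float))
        lo, hi = self.x_range
        if np.any(pts < lo) or np.any(pts > hi):
            raise ExtrapolationError(
                f"evaluation outside fitted range [{lo:g}, {hi:g}]"
            )
        out = np.array([self._fit_at(p) for p in pts])
        return float(out[0]) if scalar else out


def loess_smooth(x, y, span: float = 0.75, degree: int = 2) -> LoessSmooth:
    """Fit a locally weighted quadratic (by default) smoother to (x, y)."""
    return LoessSmooth(x, y, span=span, degree=degree)
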
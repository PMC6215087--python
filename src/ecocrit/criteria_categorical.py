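"""Derive nutrient criteria from categorical status.

Two categorical constructions complement the regression approaches; they are
less constrained by linearity and short gradients and are easy to explain to
managers:

* **Logistic inversion** — the fitted logistic curve of P(impaired) against
  log10 concentration is inverted at a chosen probability (50% by default;
  25% and 75% express different levels of precaution).  Uncertainty comes
  from the crossings of the pointwise Wald confidence band with the
  horizontal line at that probability.

* **Classification-mismatch minimisation** — for every candidate criterion
  the percentage of water bodies that would pass on biology but fail on
  nutrients is plotted against the percentage failing on biology but passing
  on nutrients; the criterion is where the (smoothed) curves intersect, i.e.
  where the two misclassification rates balance and total mismatch is low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import stats

from .criteria_regression import Boundary, CriteriaEstimate, Nutrient
from .data_model import ClassBoundaries, Dataset, back_transform, binarize
from .exceptions import (
    FlatCurveError,
    NoIntersectionError,
)
from .stressor_response import LogisticFit, loess_smooth

__all__ = [
    "MismatchCurves",
    "IntersectionResult",
    "derive_logistic",
    "mismatch_curves",
    "find_intersection",
    "derive_mismatch",
]


@dataclass
class MismatchCurves:
    """Raw and smoothed classification-mismatch curves.

    ``grid`` holds ascending candidate concentrations; the two percentage
    arrays are computed with all records in the dataset as denominator.
    ``smooth_good_fail`` / ``smooth_mod_pass`` are callables of log10
    concentration (loess smooths, or linear interpolants of the raw step
    curves when smoothing is disabled with ``span=None``).
    """

    grid: np.ndarray
    pct_bio_good_nut_fail: np.ndarray
    pct_bio_mod_nut_pass: np.ndarray
    smooth_good_fail: Callable
    smooth_mod_pass: Callable
    nutrient: Nutrient
    split: Literal["GM", "HG"]
    n: int
    span: float | None = 0.75


@dataclass
class IntersectionResult:
    """Crossings of the two smoothed mismatch curves."""

    crossings: list[float]
    mean_crossing: float
    range: tuple[float, float]
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# logistic inversion
# ---------------------------------------------------------------------------


def derive_logistic(
    fit: LogisticFit,
    p: float = 0.5,
    confidence: float = 0.95,
    nutrient: Nutrient = "TP",
    boundary: Boundary = "GM",
) -> CriteriaEstimate:
    """Invert a logistic impairment curve at probability ``p``.

    The central criterion is ``10**((logit(p) - beta0) / beta1)``.  The
    lower/upper bounds are the concentrations at which the pointwise Wald
    confidence band on the linear predictor (delta method, transformed
    through the logistic) crosses the horizontal line at ``p``.  When a band
    never crosses ``p`` inside the fitted data range, that bound is reported
    as the data-range end and flagged open in the diagnostics.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if fit.beta1 == 0:
        raise FlatCurveError("logistic slope is zero; no concentration maps to p")
    target = float(np.log(p / (1.0 - p)))  # logit
    x_central = (target - fit.beta0) / fit.beta1
    value = back_transform(x_central)

    diagnostics: dict = {
        "n": fit.n,
        "p": p,
        "beta0": fit.beta0,
        "beta1": fit.beta1,
        "confidence": confidence,
    }
    lo, hi = fit.x_range
    if not np.all(np.isfinite(fit.cov)):
        # no usable covariance: return the central value with a flag
        diagnostics["uncertainty_unavailable"] = True
        return CriteriaEstimate(
            nutrient=nutrient, boundary=boundary, method="logistic",
            value=value, lower=value, upper=value, diagnostics=diagnostics,
        )

    z = float(stats.norm.ppf(0.5 + confidence / 2.0))

    def band(x: float, sign: float) -> float:
        return fit.linear_predictor(x) + sign * z * fit.linear_predictor_se(x) - target

    bounds_x = []
    for sign in (+1.0, -1.0):
        g_lo, g_hi = band(lo, sign), band(hi, sign)
        if g_lo == 0.0:
            bounds_x.append(lo)
        elif g_hi == 0.0:
            bounds_x.append(hi)
        elif g_lo * g_hi < 0:
            from scipy.optimize import brentq

            bounds_x.append(float(brentq(lambda x: band(x, sign), lo, hi)))
        else:
            # band never reaches p inside the data range: open bound
            diagnostics["open_bound"] = True
            # the band sits entirely above or below the target; the missing
            # crossing lies beyond the data range on the side the curve's
            # direction implies, so report that range end
            bounds_x.append(hi if g_lo * fit.beta1 < 0 else lo)
    ends = sorted(back_transform(bx) for bx in bounds_x)
    return CriteriaEstimate(
        nutrient=nutrient,
        boundary=boundary,
        method="logistic",
        value=value,
        lower=min(ends[0], value),
        upper=max(ends[1], value),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# classification-mismatch curves
# ---------------------------------------------------------------------------


def mismatch_curves(
    dataset: Dataset,
    boundaries: ClassBoundaries,
    nutrient: Nutrient,
    split: Literal["GM", "HG"] = "GM",
    span: float | None = 0.75,
    min_count: int = 5,
) -> MismatchCurves:
    """Build the two classification-mismatch curves for one nutrient.

    The candidate grid is the sorted unique observed concentrations
    augmented with geometric midpoints between neighbours.  At each
    candidate c the raw curves are, as percentages of *all* records:

    * biology on the good side of the boundary AND concentration > c
      (would fail on nutrients despite passing on biology);
    * biology on the impaired side AND concentration <= c
      (would pass on nutrients despite failing on biology).

    Smoothing is loess on log10 concentration (``span=None`` disables it,
    leaving linear interpolation of the raw step curves, which is what the
    brute-force toy constructions use).
    """
    labels = binarize(dataset, boundaries, split, min_count=min_count)
    conc = dataset.nutrient(nutrient)
    n = len(conc)

    uniq = np.unique(conc)
    if len(uniq) > 1:
        mids = np.sqrt(uniq[:-1] * uniq[1:])  # geometric midpoints
        grid = np.unique(np.concatenate([uniq, mids]))
    else:
        grid = uniq

    good = labels == 0
    bad = labels == 1
    pct_good_fail = np.array(
        [100.0 * np.sum(good & (conc > c)) / n for c in grid]
    )
    pct_mod_pass = np.array(
        [100.0 * np.sum(bad & (conc <= c)) / n for c in grid]
    )

    log_grid = np.log10(grid)
    if span is None or len(grid) < 10:
        def _interp(vals):
            return lambda lx: np.interp(lx, log_grid, vals)

        smooth_a = _interp(pct_good_fail)
        smooth_b = _interp(pct_mod_pass)
        used_span = None
    else:
        smooth_a = loess_smooth(log_grid, pct_good_fail, span=span)
        smooth_b = loess_smooth(log_grid, pct_mod_pass, span=span)
        used_span = span

    return MismatchCurves(
        grid=grid,
        pct_bio_good_nut_fail=pct_good_fail,
        pct_bio_mod_nut_pass=pct_mod_pass,
        smooth_good_fail=smooth_a,
        smooth_mod_pass=smooth_b,
        nutrient=nutrient,
        split=split,
        n=n,
        span=used_span,
    )


def _bisect(f: Callable[[float], float], a: float, b: float, tol: float) -> float:
    """Bisection on the log10 abscissa for f(a), f(b) of opposite (or zero) sign."""
    fa = f(a)
    for _ in range(80):
        if (b - a) <= tol:
            break
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            # walk to the boundary of a potential zero-run: keep bisecting
            # toward the side where f is still nonzero
            if fa != 0.0:
                b = m
            else:
                a, fa = m, fm
        elif (fa > 0) == (fm > 0):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


def find_intersection(
    curves: MismatchCurves,
    n_grid: int = 500,
    rel_tol: float = 1e-4,
) -> IntersectionResult:
    """Locate the crossings of the two smoothed mismatch curves.

    The difference of the smoothed curves is sampled on ``n_grid``
    log-spaced concentrations across the data range; every sign change is
    refined by bisection.  A run of exact zeros flanked by opposite signs
    (a tie interval of the raw step curves) counts as one crossing at the
    start of the run.  All crossings are kept; the criterion is their mean
    and the range ends are the extreme crossings.
    """
    lo, hi = float(curves.grid[0]), float(curves.grid[-1])
    if lo == hi:
        raise NoIntersectionError("degenerate concentration grid", {})
    lx = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    # rel_tol on the concentration scale == rel_tol / ln(10) on log10 scale
    tol_log = rel_tol / np.log(10.0)

    def diff(log_c):
        return np.asarray(curves.smooth_good_fail(log_c)) - np.asarray(
            curves.smooth_mod_pass(log_c)
        )

    d = diff(lx)
    crossings_log: list[float] = []
    i = 0
    while i < len(d) - 1:
        a, b = d[i], d[i + 1]
        if a == 0.0 and b == 0.0:
            i += 1
            continue
        if a == 0.0:
            # start of grid or interior zero already handled as run boundary
            i += 1
            continue
        if b == 0.0:
            # find the end of the zero run and the next nonzero sign
            j = i + 1
            while j < len(d) and d[j] == 0.0:
                j += 1
            if j < len(d) and (d[j] > 0) != (a > 0):
                # tie interval between opposite signs: crossing at run start
                crossings_log.append(
                    _bisect(lambda v: diff(float(v)), lx[i], lx[i + 1], tol_log)
                )
            i = j
            continue
        if (a > 0) != (b > 0):
            crossings_log.append(
                _bisect(lambda v: diff(float(v)), lx[i], lx[i + 1], tol_log)
            )
        i += 1

    if not crossings_log:
        if np.all(d == 0.0):
            raise NoIntersectionError(
                "curves are tied over the whole range",
                {"tie": True, "range": (lo, hi)},
            )
        k = int(np.argmin(np.abs(d)))
        raise NoIntersectionError(
            "mismatch curves never cross",
            {
                "closest_approach": float(10 ** lx[k]),
                "closest_gap_pct": float(abs(d[k])),
            },
        )

    crossings = [float(10**c) for c in crossings_log]
    return IntersectionResult(
        crossings=crossings,
        mean_crossing=float(np.mean(crossings)),
        range=(min(crossings), max(crossings)),
        diagnostics={"n_grid": n_grid, "n_crossings": len(crossings)},
    )


def derive_mismatch(
    dataset: Dataset,
    boundaries: ClassBoundaries,
    nutrient: Nutrient,
    split: Literal["GM", "HG"] = "GM",
    span: float | None = 0.75,
    min_count: int = 5,
) -> CriteriaEstimate:
    """End-to-end mismatch-minimisation criterion for one nutrient/boundary."""
    curves = mismatch_curves(
        dataset, boundaries, nutrient, split, span=span, min_count=min_count
    )
    inter = find_intersection(curves)
    value = inter.mean_crossing
    log_v = np.log10(value)
    mismatch_at = float(
        np.asarray(curves.smooth_good_fail(log_v))
        + np.asarray(curves.smooth_mod_pass(log_v))
    )
    return CriteriaEstimate(
        nutrient=nutrient,
        boundary=split,
        method="mismatch",
        value=value,
        lower=min(inter.range[0], value),
        upper=max(inter.range[1], value),
        diagnostics={
            "n": curves.n,
            "n_crossings": len(inter.crossings),
            "total_mismatch_pct": mismatch_at,
            "span": curves.span,
        },
    )
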
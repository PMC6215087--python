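"""Derive nutrient criteria from fitted regressions.

Two constructions are implemented:

* **Univariate inversion** — the fitted RMA (or OLS) line of EQR on log10
  concentration is solved for the concentration at which the line reaches a
  class-boundary EQR.  The 25th/75th percentiles of the regression residuals
  define two lines parallel to the fit; inverting those gives a criteria
  range that, by construction, brackets 50% of the observations.

* **Bivariate contour intersection** — on the (log10 TN, log10 TP) plane the
  fitted EQR plane's boundary contour is a straight line; the reported
  criteria pair is its intersection with the RMA regression of log10 TP on
  log10 TN, i.e. the point on the contour that respects the observed TP–TN
  covariation.  Residual-quartile offsets of the plane shift the contour and
  give the range pair.

All criteria are returned as :class:`CriteriaEstimate` objects carrying the
central value and the lower/upper range on the concentration scale (μg/l for
TP, mg/l for TN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_model import back_transform
from .exceptions import (
    DirectionError,
    NoIntersectionError,
    UnstableInversionError,
)
from .stressor_response import LinearFit, PlaneFit

__all__ = [
    "CriteriaEstimate",
    "residual_offsets",
    "derive_univariate",
    "derive_bivariate",
]

Nutrient = Literal["TP", "TN"]
Boundary = Literal["GM", "HG"]

#: CSV serialization header for criteria rows.
CRITERIA_CSV_COLUMNS = [
    "type_code",
    "nutrient",
    "boundary",
    "method",
    "value",
    "lower",
    "upper",
    "n",
    "r2",
    "extrapolated",
]


@dataclass
class CriteriaEstimate:
    """A derived nutrient criterion with its uncertainty range.

    ``value`` is the central estimate, ``lower``/``upper`` the range ends,
    all on the concentration scale (μg/l TP, mg/l TN).  The invariant
    ``0 < lower <= value <= upper`` is enforced on construction.
    """

    nutrient: Nutrient
    boundary: Boundary
    method: str  # rma_univariate | ols_bivariate | logistic | mismatch
    value: float
    lower: float
    upper: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.lower <= self.value <= self.upper):
            raise ValueError(
                f"criteria range must satisfy 0 < lower <= value <= upper; got "
                f"lower={self.lower}, value={self.value}, upper={self.upper}"
            )

    def to_row(self, type_code: str) -> dict:
        return {
            "type_code": type_code,
            "nutrient": self.nutrient,
            "boundary": self.boundary,
            "method": self.method,
            "value": self.value,
            "lower": self.lower,
            "upper": self.upper,
            "n": self.diagnostics.get("n"),
            "r2": self.diagnostics.get("r2", self.diagnostics.get("R2")),
            "extrapolated": bool(self.diagnostics.get("extrapolated", False)),
        }


def residual_offsets(fit: LinearFit | PlaneFit) -> tuple[float, float]:
    """25th and 75th percentiles of a fit's residuals (EQR-direction offsets).

    Linear-interpolation quantile definition; for centred residuals
    q25 <= 0 <= q75.  These offsets, added to the fitted surface, enclose
    50% of the observations.
    """
    res = np.asarray(fit.residuals, dtype=float)
    if len(res) < 4:
        raise ValueError(f"need >= 4 residuals for quartiles, got {len(res)}")
    q25, q75 = np.percentile(res, [25, 75])
    return float(q25), float(q75)


def _invert_line(fit: LinearFit, target_eqr: float) -> float:
    """log10 concentration at which the fitted line reaches target_eqr."""
    return (target_eqr - fit.intercept) / fit.slope


def derive_univariate(
    fit: LinearFit,
    boundary_eqr: float,
    offsets: tuple[float, float],
    nutrient: Nutrient,
    boundary: Boundary,
) -> CriteriaEstimate:
    """Invert a univariate EQR ~ log10 concentration fit at a boundary EQR.

    The central criterion is ``10**((boundary_eqr - intercept) / slope)``;
    the range ends come from inverting the two residual-offset lines.  With
    a negative slope the +q75 line gives the upper concentration.  The
    estimate is flagged ``extrapolated`` when the inverted log concentration
    falls outside the observed abscissa range (typical for high/good
    boundaries that sit in poorly populated regions of the gradient).
    """
    if fit.slope >= 0:
        raise DirectionError(
            f"EQR must decline with enrichment; slope = {fit.slope:g}"
        )
    if abs(fit.slope) < 1e-6:
        raise UnstableInversionError(f"slope {fit.slope:g} too small to invert")
    q25, q75 = offsets
    x_central = _invert_line(fit, boundary_eqr)
    x_ends = [
        (boundary_eqr - fit.intercept - q) / fit.slope for q in (q25, q75)
    ]
    value = back_transform(x_central)
    ends = sorted(back_transform(xe) for xe in x_ends)
    lo, hi = fit.x_range
    extrapolated = not (lo <= x_central <= hi)
    return CriteriaEstimate(
        nutrient=nutrient,
        boundary=boundary,
        method="rma_univariate" if fit.method_tag == "RMA" else "ols_univariate",
        value=value,
        lower=min(ends[0], value),
        upper=max(ends[1], value),
        diagnostics={
            "r2": fit.r2,
            "n": fit.n,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "q25": q25,
            "q75": q75,
            "boundary_eqr": boundary_eqr,
            "extrapolated": extrapolated,
        },
    )


def _solve_contour_rma(
    plane: PlaneFit, tp_tn_fit: LinearFit, target_eqr: float
) -> tuple[float, float]:
    """Solve {a0 + a1 u + a2 v = target ; u = c + m v} for (u, v).

    u = log10 TP, v = log10 TN; the TP–TN line has log10 TP as ordinate.
    """
    m = tp_tn_fit.slope
    c = tp_tn_fit.intercept
    denom = plane.a1 * m + plane.a2
    if abs(denom) < 1e-9:
        raise NoIntersectionError(
            "boundary contour is parallel to the TP-TN regression line",
            {"determinant": denom},
        )
    v = (target_eqr - plane.a0 - plane.a1 * c) / denom
    u = c + m * v
    return u, v


def derive_bivariate(
    plane: PlaneFit,
    tp_tn_fit: LinearFit,
    boundary_eqr: float,
    offsets: tuple[float, float],
    boundary: Boundary,
) -> tuple[CriteriaEstimate, CriteriaEstimate]:
    """Intersect the plane's boundary contour with the TP–TN RMA line.

    Returns the (TP, TN) criteria pair.  Offset contours (plane residual
    quartiles added to the boundary EQR) give the range pair; after
    back-transforming, the smaller concentration is reported as the lower
    bound regardless of slope-sign conventions.
    """
    if abs(plane.a1) < 1e-12 and abs(plane.a2) < 1e-12:
        raise UnstableInversionError("plane has no nutrient dependence")
    q25, q75 = offsets
    u0, v0 = _solve_contour_rma(plane, tp_tn_fit, boundary_eqr)
    ends_u, ends_v = [], []
    for q in (q25, q75):
        uq, vq = _solve_contour_rma(plane, tp_tn_fit, boundary_eqr - q)
        ends_u.append(uq)
        ends_v.append(vq)

    diagnostics = {
        "R2": plane.R2,
        "n": plane.n,
        "plane": (plane.a0, plane.a1, plane.a2),
        "tp_tn_slope": tp_tn_fit.slope,
        "tp_tn_intercept": tp_tn_fit.intercept,
        "q25": q25,
        "q75": q75,
        "boundary_eqr": boundary_eqr,
    }
    if plane.a1 > 1e-12 or plane.a2 > 1e-12:
        # enrichment should lower EQR; a positive coefficient means the
        # boundary contour moves criteria the wrong way with worsening status
        diagnostics["direction_warning"] = (
            "positive nutrient coefficient in plane fit"
        )

    tp_val = back_transform(u0)
    tn_val = back_transform(v0)
    tp_ends = sorted(back_transform(u) for u in ends_u)
    tn_ends = sorted(back_transform(v) for v in ends_v)
    tp_est = CriteriaEstimate(
        nutrient="TP",
        boundary=boundary,
        method="ols_bivariate",
        value=tp_val,
        lower=min(tp_ends[0], tp_val),
        upper=max(tp_ends[1], tp_val),
        diagnostics=dict(diagnostics),
    )
    tn_est = CriteriaEstimate(
        nutrient="TN",
        boundary=boundary,
        method="ols_bivariate",
        value=tn_val,
        lower=min(tn_ends[0], tn_val),
        upper=max(tn_ends[1], tn_val),
        diagnostics=dict(diagnostics),
    )
    return tp_est, tn_est
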
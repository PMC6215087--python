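"""Worked example: published per-method criteria for two Central Baltic lake types.

Reported per-method nutrient criteria for the two major high-alkalinity
shallow lake types of lowland Europe — LCB1 (mean depth 3–15 m) and LCB2
(very shallow, mean depth < 3 m) — derived from macrophyte common-metric
EQR data.  TP in μg/l, TN in mg/l.  These serve as ready-made inputs for
the compilation stage (:func:`ecocrit.reporting.select_best_model` and
:func:`ecocrit.reporting.compile_summary`): the underlying multi-country
observation dataset is not public, but the per-method central values, the
residual-quartile ranges of the best model and the model R² values are, so
the cross-method summary can be reproduced from them.

Only the good/moderate (GM) rows list all four methods; for the high/good
(HG) boundary the bivariate and mismatch values were not reported.
"""

from __future__ import annotations

__all__ = [
    "PER_METHOD_CRITERIA",
    "MODEL_R2",
    "BEST_MODEL_RANGES",
]

#: Central per-method criteria, keyed by (type_code, nutrient, boundary).
PER_METHOD_CRITERIA: dict[tuple[str, str, str], dict[str, float]] = {
    ("LCB1", "TP", "GM"): {
        "rma_univariate": 53.0,
        "ols_bivariate": 51.0,
        "logistic": 48.0,
        "mismatch": 50.0,
    },
    ("LCB1", "TN", "GM"): {
        "rma_univariate": 1.12,
        "ols_bivariate": 1.15,
        "logistic": 1.08,
        "mismatch": 1.11,
    },
    ("LCB2", "TP", "GM"): {
        "rma_univariate": 60.0,
        "ols_bivariate": 58.0,
        "logistic": 61.0,
        "mismatch": 78.0,
    },
    ("LCB2", "TN", "GM"): {
        "rma_univariate": 1.30,
        "ols_bivariate": 1.23,
        "logistic": 1.00,
        "mismatch": 1.41,
    },
    ("LCB1", "TP", "HG"): {"rma_univariate": 27.0, "logistic": 16.0},
    ("LCB1", "TN", "HG"): {"rma_univariate": 0.63, "logistic": 0.30},
    ("LCB2", "TP", "HG"): {"rma_univariate": 30.0, "logistic": 18.0},
    ("LCB2", "TN", "HG"): {"rma_univariate": 0.89, "logistic": 0.59},
}

#: Coefficients of determination of the candidate regression models.
MODEL_R2: dict[str, dict[str, float]] = {
    "LCB1": {
        "rma_univariate_tp": 0.46,
        "rma_univariate_tn": 0.29,
        "ols_bivariate": 0.50,
    },
    "LCB2": {
        "rma_univariate_tp": 0.41,
        "rma_univariate_tn": 0.37,
        "ols_bivariate": 0.49,
    },
}

#: Residual-quartile (25th–75th) ranges around the per-method centrals, GM
#: boundary, for the regression models where reported.
BEST_MODEL_RANGES: dict[tuple[str, str, str], dict[str, tuple[float, float]]] = {
    ("LCB1", "TP", "GM"): {
        "rma_univariate": (38.0, 80.0),
        "ols_bivariate": (37.0, 78.0),
    },
    ("LCB1", "TN", "GM"): {
        "rma_univariate": (0.87, 1.70),
        "ols_bivariate": (0.87, 1.69),
    },
    ("LCB2", "TP", "GM"): {
        "rma_univariate": (33.0, 104.0),
        "ols_bivariate": (34.0, 99.0),
    },
    ("LCB2", "TN", "GM"): {
        "rma_univariate": (0.94, 1.75),
        "ols_bivariate": (0.84, 1.78),
    },
}
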
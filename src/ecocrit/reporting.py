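"""Orchestration: run every derivation method, pick the best model, summarise.

The analysis driver applies, per nutrient and per class boundary, the four
derivation methods (univariate RMA inversion, bivariate contour
intersection, logistic inversion, mismatch minimisation) and compiles a
summary in the style the field reports criteria:

* the most likely criterion, from the "best" regression model — the one
  with the highest coefficient of determination;
* the range defined by the 25th/75th residual percentiles of that model;
* the cross-method range: the spread of central values across all methods
  that ran.

A method that errors (e.g. insufficient class contrast for the categorical
methods on a one-sided dataset) is logged and omitted rather than aborting
the run, since different boundaries legitimately support different method
subsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .criteria_categorical import derive_logistic, derive_mismatch
from .criteria_regression import (
    CRITERIA_CSV_COLUMNS,
    CriteriaEstimate,
    derive_bivariate,
    derive_univariate,
    residual_offsets,
)
from .data_model import ClassBoundaries, Dataset, Split, binarize
from .exceptions import ConsistencyError, EcocritError, SelectionError
from .stressor_response import (
    check_linearity,
    fit_logistic,
    fit_ols_line,
    fit_plane,
    fit_rma,
)

__all__ = [
    "AnalysisConfig",
    "CriteriaSummary",
    "select_best_model",
    "compile_summary",
    "run_analysis",
    "load_config",
    "present",
]

logger = logging.getLogger("ecocrit")

#: tie-break order for best-model selection: simpler models first
_MODEL_COMPLEXITY = {
    "rma_univariate_tp": 0,
    "rma_univariate_tn": 0,
    "ols_bivariate": 1,
}


@dataclass
class AnalysisConfig:
    """Knobs of the end-to-end analysis."""

    boundaries: ClassBoundaries
    probabilities: tuple[float, ...] = (0.5,)
    confidence: float = 0.95
    span: float = 0.75
    min_class_count: int = 5
    linearity_ic_threshold: float = 4.0

    @classmethod
    def from_mapping(cls, mapping: dict, type_code: str) -> "AnalysisConfig":
        b = mapping["boundaries"][type_code]
        return cls(
            boundaries=ClassBoundaries(
                hg_eqr=float(b["hg_eqr"]), gm_eqr=float(b["gm_eqr"])
            ),
            probabilities=tuple(mapping.get("probabilities", (0.5,))),
            confidence=float(mapping.get("confidence", 0.95)),
            span=float(mapping.get("span", 0.75)),
            min_class_count=int(mapping.get("min_class_count", 5)),
            linearity_ic_threshold=float(mapping.get("linearity_ic_threshold", 4.0)),
        )


@dataclass
class CriteriaSummary:
    """Compiled criteria for one type/nutrient/boundary combination."""

    type_code: str
    nutrient: str
    boundary: str
    best_model: str
    best_model_value: float
    best_model_range: tuple[float, float]
    cross_method_range: tuple[float, float]
    per_method: list[CriteriaEstimate] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "type_code": self.type_code,
            "nutrient": self.nutrient,
            "boundary": self.boundary,
            "best_model": self.best_model,
            "best_model_value": self.best_model_value,
            "best_model_range": list(self.best_model_range),
            "cross_method_range": list(self.cross_method_range),
            "per_method": {
                e.method: {"value": e.value, "lower": e.lower, "upper": e.upper}
                for e in self.per_method
            },
        }


def select_best_model(fits: dict[str, float]) -> str:
    """Pick the regression model with the highest coefficient of determination.

    ``fits`` maps method tags to their r²/R².  Ties are broken toward the
    simpler (univariate) model.
    """
    if not fits:
        raise SelectionError("no regression fits supplied")
    items = list(fits.items())
    best_r2 = max(r2 for _, r2 in items)
    tied = [tag for tag, r2 in items if r2 == best_r2]
    tied.sort(key=lambda t: (_MODEL_COMPLEXITY.get(t, 99), list(fits).index(t)))
    return tied[0]


def compile_summary(
    estimates: list[CriteriaEstimate],
    best: str,
    type_code: str = "",
) -> CriteriaSummary:
    """Compile per-method estimates into the reporting summary.

    The cross-method range spans the central values of all supplied methods;
    the best-model value and residual-quartile range come from the estimate
    whose method tag matches ``best``.  Univariate best tags may carry a
    nutrient suffix (e.g. ``rma_univariate_tp``) which is matched against the
    plain ``rma_univariate`` estimate tag.
    """
    if len(estimates) < 2:
        raise ConsistencyError(
            f"need >= 2 methods to compile a summary, got {len(estimates)}"
        )
    nutrients = {e.nutrient for e in estimates}
    boundaries = {e.boundary for e in estimates}
    if len(nutrients) != 1 or len(boundaries) != 1:
        raise ConsistencyError(
            "estimates mix nutrients or boundaries: "
            f"{sorted(nutrients)}, {sorted(boundaries)}"
        )
    base_best = best
    for suffix in ("_tp", "_tn"):
        if best.endswith(suffix):
            base_best = best[: -len(suffix)]
    chosen = [e for e in estimates if e.method == base_best]
    if not chosen:
        raise ConsistencyError(f"best model {best!r} absent from estimates")
    best_est = chosen[0]
    centrals = [e.value for e in estimates]
    return CriteriaSummary(
        type_code=type_code,
        nutrient=best_est.nutrient,
        boundary=best_est.boundary,
        best_model=best,
        best_model_value=best_est.value,
        best_model_range=(best_est.lower, best_est.upper),
        cross_method_range=(min(centrals), max(centrals)),
        per_method=list(estimates),
    )


def present(value: float) -> float:
    """Presentation rounding: 2 significant figures at >= 10, 2 decimals below."""
    if value >= 10:
        from math import floor, log10

        digits = int(floor(log10(value))) + 1
        return float(round(value, 2 - digits))
    return float(round(value, 2))


def run_analysis(dataset: Dataset, config: AnalysisConfig) -> dict:
    """Run all derivation methods for both nutrients and both boundaries.

    Returns a dict with per-method estimates, compiled summaries, fitted
    model parameters and an error log; every stage failure is recorded and
    skipped rather than raised.
    """
    result: dict = {
        "type_code": dataset.type_code,
        "n": len(dataset),
        "fits": {},
        "linearity": {},
        "estimates": [],
        "summaries": [],
        "errors": [],
    }

    def _guard(stage: str):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except EcocritError as exc:
                logger.warning("%s failed: %s", stage, exc)
                result["errors"].append({"stage": stage, "error": str(exc)})
                return None
        return wrap

    log_x = {"TP": dataset.log_tp, "TN": dataset.log_tn}

    # --- regression fits (boundary-independent) ----------------------
    uni_fits = {}
    for nutrient in ("TP", "TN"):
        seg = _guard(f"linearity[{nutrient}]")(
            check_linearity, log_x[nutrient], dataset.eqr,
            ic_threshold=config.linearity_ic_threshold,
        )
        if seg is not None:
            result["linearity"][nutrient] = {
                "breakpoint": seg.breakpoint,
                "delta_ic": seg.delta_ic,
                "linear_region": seg.linear_region,
            }
        fit = _guard(f"rma[{nutrient}]")(fit_rma, log_x[nutrient], dataset.eqr)
        if fit is not None:
            uni_fits[nutrient] = fit
            result["fits"][f"rma_univariate_{nutrient.lower()}"] = fit.to_dict()

    plane = _guard("plane")(fit_plane, dataset.log_tp, dataset.log_tn, dataset.eqr)
    tp_tn = _guard("tp_tn_rma")(fit_rma, dataset.log_tn, dataset.log_tp)
    if plane is not None:
        result["fits"]["ols_bivariate"] = plane.to_dict()
    if tp_tn is not None:
        result["fits"]["tp_tn_rma"] = {
            "slope": tp_tn.slope, "intercept": tp_tn.intercept, "r2": tp_tn.r2,
        }

    r2_by_model = {}
    for nutrient, fit in uni_fits.items():
        r2_by_model[f"rma_univariate_{nutrient.lower()}"] = fit.r2
    if plane is not None:
        r2_by_model["ols_bivariate"] = plane.R2
    best = None
    if r2_by_model:
        best = select_best_model(r2_by_model)
        result["best_model"] = best

    # --- per-boundary derivations ------------------------------------
    estimates: dict[tuple[str, str], list[CriteriaEstimate]] = {}

    def add(est: CriteriaEstimate | None):
        if est is not None:
            estimates.setdefault((est.nutrient, est.boundary), []).append(est)
            result["estimates"].append(est)

    for split in ("GM", "HG"):
        split: Split
        target = config.boundaries.boundary_eqr(split)

        for nutrient, fit in uni_fits.items():
            add(
                _guard(f"univariate[{nutrient},{split}]")(
                    derive_univariate, fit, target, residual_offsets(fit),
                    nutrient, split,
                )
            )
        if plane is not None and tp_tn is not None:
            pair = _guard(f"bivariate[{split}]")(
                derive_bivariate, plane, tp_tn, target,
                residual_offsets(plane), split,
            )
            if pair is not None:
                add(pair[0])
                add(pair[1])
        for nutrient in ("TP", "TN"):
            logi = _guard(f"logistic[{nutrient},{split}]")(
                _logistic_estimate, dataset, config, nutrient, split
            )
            add(logi)
            add(
                _guard(f"mismatch[{nutrient},{split}]")(
                    derive_mismatch, dataset, config.boundaries, nutrient,
                    split, span=config.span, min_count=config.min_class_count,
                )
            )

    # --- summaries ----------------------------------------------------
    for (nutrient, split), ests in sorted(estimates.items()):
        if best is None or len(ests) < 2:
            continue
        eligible = best
        base = best.replace("_tp", "").replace("_tn", "")
        if base not in {e.method for e in ests}:
            continue
        try:
            summary = compile_summary(ests, eligible, dataset.type_code)
        except ConsistencyError as exc:
            result["errors"].append({"stage": f"summary[{nutrient},{split}]",
                                     "error": str(exc)})
            continue
        result["summaries"].append(summary)
    return result


def _logistic_estimate(
    dataset: Dataset, config: AnalysisConfig, nutrient: str, split: Split
) -> CriteriaEstimate:
    labels = binarize(dataset, config.boundaries, split,
                      min_count=config.min_class_count)
    fit = fit_logistic(dataset.log_nutrient_column(nutrient), labels)
    return derive_logistic(
        fit, p=config.probabilities[0], confidence=config.confidence,
        nutrient=nutrient, boundary=split,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_outputs(result: dict, out_dir) -> None:
    """Write criteria.csv and summary.json for one analysis run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [e.to_row(result["type_code"]) for e in result["estimates"]]
    pd.DataFrame(rows, columns=CRITERIA_CSV_COLUMNS).to_csv(
        out / "criteria.csv", index=False
    )
    payload = {
        "type_code": result["type_code"],
        "n": result["n"],
        "best_model": result.get("best_model"),
        "fits": result["fits"],
        "linearity": result["linearity"],
        "summaries": [s.to_dict() for s in result["summaries"]],
        "errors": result["errors"],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path) -> dict:
    """Load the YAML/JSON analysis configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh)
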
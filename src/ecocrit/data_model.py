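"""Domain types and table ingestion for lake-year stressor-response data.

The unit of analysis is one *lake-year*: an annual mean total phosphorus
(TP, μg/l), an annual mean total nitrogen (TN, mg/l), and a harmonized
Ecological Quality Ratio (EQR) for the macrophyte community, scaled so that
~1 is near-natural and 0 the worst condition.  Common-metric EQRs may
slightly exceed 1 and are retained uncapped (capping would bias fits).

Status classes are assigned from the EQR against intercalibrated class
boundaries: ``high`` (EQR at or above the high/good boundary), ``good``
(between the boundaries) and ``moderate_or_worse`` below the good/moderate
boundary.  A value exactly on a boundary belongs to the upper (better)
class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    EmptyDatasetError,
    InsufficientContrastError,
    SchemaError,
)

__all__ = [
    "StatusClass",
    "ClassBoundaries",
    "LakeRecord",
    "ValidationReport",
    "Dataset",
    "Split",
    "log_nutrient",
    "back_transform",
    "assign_class",
    "binarize",
    "read_dataset",
    "CSV_COLUMNS",
]

#: Documented input CSV schema (header names, in order).
CSV_COLUMNS = ["lake_id", "type_code", "year", "tp_ugl", "tn_mgl", "eqr"]

#: Maximum EQR accepted — common metrics may slightly exceed 1.
EQR_MAX = 1.5

Split = Literal["GM", "HG"]


class StatusClass(enum.IntEnum):
    """Ordered ecological status classes (higher value = better status)."""

    MODERATE_OR_WORSE = 0
    GOOD = 1
    HIGH = 2


@dataclass(frozen=True)
class ClassBoundaries:
    """EQR cut-offs for the high/good and good/moderate class boundaries."""

    hg_eqr: float
    gm_eqr: float

    def __post_init__(self) -> None:
        if not (0.0 < self.gm_eqr < self.hg_eqr <= EQR_MAX):
            raise DomainError(
                f"boundaries must satisfy 0 < gm_eqr < hg_eqr <= {EQR_MAX}; "
                f"got gm={self.gm_eqr}, hg={self.hg_eqr}"
            )

    def boundary_eqr(self, split: Split) -> float:
        """EQR value of the boundary named by ``split`` ('GM' or 'HG')."""
        if split == "GM":
            return self.gm_eqr
        if split == "HG":
            return self.hg_eqr
        raise ValueError(f"split must be 'GM' or 'HG', got {split!r}")


@dataclass(frozen=True)
class LakeRecord:
    """One lake-year observation."""

    lake_id: str
    type_code: str
    year: int
    tp: float  # μg/l
    tn: float  # mg/l
    eqr: float

    def __post_init__(self) -> None:
        if not self.tp > 0:
            raise DomainError(f"tp must be > 0, got {self.tp}")
        if not self.tn > 0:
            raise DomainError(f"tn must be > 0, got {self.tn}")
        if not (0.0 <= self.eqr <= EQR_MAX):
            raise DomainError(f"eqr must be in [0, {EQR_MAX}], got {self.eqr}")
        if not (1900 <= self.year <= 2100):
            raise DomainError(f"year out of plausible range: {self.year}")


@dataclass
class ValidationReport:
    """Row accounting from CSV ingestion."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    def add_drop(self, reason: str, count: int = 1) -> None:
        self.n_dropped += count
        self.reasons[reason] = self.reasons.get(reason, 0) + count


class Dataset:
    """A homogeneous collection of lake-years of one lake type.

    Stores the observations in a pandas DataFrame with cached base-10 log
    nutrient columns (``log_tp``, ``log_tn``) alongside the raw values.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        type_code: str,
        report: ValidationReport | None = None,
    ):
        required = {"lake_id", "type_code", "year", "tp", "tn", "eqr"}
        missing = required - set(frame.columns)
        if missing:
            raise SchemaError(f"dataset frame missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise EmptyDatasetError("dataset has zero usable rows")
        if not (frame["type_code"] == type_code).all():
            raise SchemaError("all records must share the dataset type_code")
        frame = frame.reset_index(drop=True).copy()
        frame["log_tp"] = np.log10(frame["tp"].to_numpy(dtype=float))
        frame["log_tn"] = np.log10(frame["tn"].to_numpy(dtype=float))
        self.frame = frame
        self.type_code = type_code
        self.report = report if report is not None else ValidationReport(
            n_read=len(frame), n_kept=len(frame)
        )

    # -- constructors -------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[LakeRecord], report: ValidationReport | None = None
    ) -> "Dataset":
        records = list(records)
        if not records:
            raise EmptyDatasetError("no records supplied")
        type_codes = {r.type_code for r in records}
        if len(type_codes) != 1:
            raise SchemaError(f"records mix type codes: {sorted(type_codes)}")
        frame = pd.DataFrame(
            {
                "lake_id": [r.lake_id for r in records],
                "type_code": [r.type_code for r in records],
                "year": [r.year for r in records],
                "tp": [r.tp for r in records],
                "tn": [r.tn for r in records],
                "eqr": [r.eqr for r in records],
            }
        )
        return cls(frame, type_codes.pop(), report)

    # -- accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[LakeRecord]:
        return [
            LakeRecord(
                lake_id=str(row.lake_id),
                type_code=str(row.type_code),
                year=int(row.year),
                tp=float(row.tp),
                tn=float(row.tn),
                eqr=float(row.eqr),
            )
            for row in self.frame.itertuples(index=False)
        ]

    @property
    def tp(self) -> np.ndarray:
        return self.frame["tp"].to_numpy(dtype=float)

    @property
    def tn(self) -> np.ndarray:
        return self.frame["tn"].to_numpy(dtype=float)

    @property
    def eqr(self) -> np.ndarray:
        return self.frame["eqr"].to_numpy(dtype=float)

    @property
    def log_tp(self) -> np.ndarray:
        return self.frame["log_tp"].to_numpy(dtype=float)

    @property
    def log_tn(self) -> np.ndarray:
        return self.frame["log_tn"].to_numpy(dtype=float)

    def nutrient(self, which: Literal["TP", "TN"]) -> np.ndarray:
        return self.tp if which == "TP" else self.tn

    def log_nutrient_column(self, which: Literal["TP", "TN"]) -> np.ndarray:
        return self.log_tp if which == "TP" else self.log_tn

    # -- io -----------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the dataset back out in the standard input schema."""
        out = pd.DataFrame(
            {
                "lake_id": self.frame["lake_id"],
                "type_code": self.frame["type_code"],
                "year": self.frame["year"],
                "tp_ugl": self.frame["tp"],
                "tn_mgl": self.frame["tn"],
                "eqr": self.frame["eqr"],
            }
        )
        out.to_csv(path, index=False)


def log_nutrient(value):
    """Base-10 log of a nutrient concentration (scalar or array).

    Raises :class:`DomainError` for non-positive input.  The inverse is
    :func:`back_transform`; the round trip is exact to machine precision.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr > 0)):
        raise DomainError("nutrient concentrations must be > 0 to log-transform")
    out = np.log10(arr)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def back_transform(x):
    """Inverse of :func:`log_nutrient`: 10**x."""
    out = np.power(10.0, np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) or out.ndim == 0 else out


def assign_class(eqr: float, boundaries: ClassBoundaries) -> StatusClass:
    """Map an EQR to its status class; boundary values go to the upper class."""
    if eqr >= boundaries.hg_eqr:
        return StatusClass.HIGH
    if eqr >= boundaries.gm_eqr:
        return StatusClass.GOOD
    return StatusClass.MODERATE_OR_WORSE


def assign_classes(eqr: np.ndarray, boundaries: ClassBoundaries) -> np.ndarray:
    """Vectorised :func:`assign_class` returning an int array of StatusClass values."""
    eqr = np.asarray(eqr, dtype=float)
    out = np.full(eqr.shape, int(StatusClass.MODERATE_OR_WORSE))
    out[eqr >= boundaries.gm_eqr] = int(StatusClass.GOOD)
    out[eqr >= boundaries.hg_eqr] = int(StatusClass.HIGH)
    return out


def binarize(
    dataset: Dataset,
    boundaries: ClassBoundaries,
    split: Split,
    min_count: int = 5,
) -> np.ndarray:
    """Binary labels per record: 1 = the impaired side of the chosen boundary.

    ``split='GM'`` labels 1 records of moderate-or-worse biological status;
    ``split='HG'`` labels 1 records of good-or-worse status (i.e. anything
    below high).  The label-1 group is the one whose probability the logistic
    criterion curve models.

    Raises :class:`InsufficientContrastError` when fewer than ``min_count``
    records fall on either side.
    """
    classes = assign_classes(dataset.eqr, boundaries)
    if split == "GM":
        labels = (classes < int(StatusClass.GOOD)).astype(int)
    elif split == "HG":
        labels = (classes < int(StatusClass.HIGH)).astype(int)
    else:
        raise ValueError(f"split must be 'GM' or 'HG', got {split!r}")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if min(n0, n1) < min_count:
        raise InsufficientContrastError(
            f"need >= {min_count} records on each side of the {split} boundary; "
            f"got {n0} better / {n1} worse"
        )
    return labels


def read_dataset(path, type_code: str) -> Dataset:
    """Read the standard lake-year CSV and return validated records of one type.

    Rows with missing or non-positive nutrient values, missing EQR, EQR
    outside [0, 1.5] or an implausible year are dropped and counted in the
    dataset's :class:`ValidationReport`.
    """
    try:
        raw = pd.read_csv(path)
    except FileNotFoundError:
        raise
    missing = set(CSV_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"input CSV missing required columns: {sorted(missing)}")

    report = ValidationReport(n_read=int((raw["type_code"] == type_code).sum()))
    sub = raw[raw["type_code"] == type_code].copy()

    def _drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            report.add_drop(reason, n)
        return sub[~mask]

    for col in ("tp_ugl", "tn_mgl", "eqr"):
        sub[col] = pd.to_numeric(sub[col], errors="coerce")
    sub["year"] = pd.to_numeric(sub["year"], errors="coerce")

    sub = _drop(sub["tp_ugl"].isna() | ~(sub["tp_ugl"] > 0), "non-positive or missing tp")
    sub = _drop(sub["tn_mgl"].isna() | ~(sub["tn_mgl"] > 0), "non-positive or missing tn")
    sub = _drop(sub["eqr"].isna(), "missing eqr")
    sub = _drop(~((sub["eqr"] >= 0) & (sub["eqr"] <= EQR_MAX)), "eqr out of range")
    sub = _drop(
        sub["year"].isna() | ~((sub["year"] >= 1900) & (sub["year"] <= 2100)),
        "implausible year",
    )

    report.n_kept = len(sub)
    if len(sub) == 0:
        raise EmptyDatasetError(
            f"no usable rows of type {type_code!r} "
            f"({report.n_dropped} dropped of {report.n_read} read)"
        )
    frame = pd.DataFrame(
        {
            "lake_id": sub["lake_id"].astype(str),
            "type_code": sub["type_code"].astype(str),
            "year": sub["year"].astype(int),
            "tp": sub["tp_ugl"].astype(float),
            "tn": sub["tn_mgl"].astype(float),
            "eqr": sub["eqr"].astype(float),
        }
    )
    return Dataset(frame, type_code, report)
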
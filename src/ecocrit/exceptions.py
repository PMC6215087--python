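"""Exception hierarchy for the toolkit.

All toolkit-specific failures derive from :class:`EcocritError` so callers
(notably the analysis driver, which degrades gracefully when a single method
fails) can catch one base class.
"""


class EcocritError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(EcocritError):
    """Input table does not match the documented CSV schema."""


class EmptyDatasetError(EcocritError):
    """No usable rows remain after validation/filtering."""


class DomainError(EcocritError, ValueError):
    """A value is outside its mathematical domain (e.g. log of a non-positive)."""


class InsufficientDataError(EcocritError):
    """Too few observations for the requested fit."""


class DegenerateDataError(EcocritError):
    """Data carry no usable variation (zero range, constant variable)."""


class InsufficientContrastError(EcocritError):
    """Too few records on one side of a class boundary to model the contrast."""


class CollinearityError(EcocritError):
    """Predictors are (near-)perfectly collinear."""

    def __init__(self, correlation: float):
        self.correlation = correlation
        super().__init__(
            f"predictors are collinear (|r| = {abs(correlation):.6f})"
        )


class SeparationError(EcocritError):
    """Logistic regression data are completely separated; no finite MLE."""


class ConvergenceError(EcocritError):
    """Iterative fit failed to converge within the configured iterations."""


class DirectionError(EcocritError):
    """The fitted response runs in the wrong direction for criteria derivation."""


class UnstableInversionError(EcocritError):
    """Slope too close to zero to invert the regression at a boundary."""


class FlatCurveError(EcocritError):
    """Logistic curve is flat (zero slope); no concentration maps to p."""


class NoIntersectionError(EcocritError):
    """Mismatch curves (or contour and regression line) never intersect."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)


class ExtrapolationError(EcocritError):
    """Evaluation requested outside the fitted data range."""


class SelectionError(EcocritError):
    """Best-model selection got no regression fits."""


class ConsistencyError(EcocritError):
    """Summary compilation inputs are inconsistent or insufficient."""
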
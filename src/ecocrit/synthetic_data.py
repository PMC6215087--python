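"""Synthetic lake-year datasets with analytically known true criteria.

The generator emulates the statistical structure the criteria-derivation
methods assume: log10 TP and log10 TN drawn from a correlated bivariate
normal, and an EQR that declines linearly with both log nutrients plus
homoscedastic Gaussian noise (truncated below at 0; EQR > 1 is allowed, as
common-metric EQRs can exceed 1).

Because the generating plane and the population nutrient distribution are
known, the "true" criteria are available in closed form: the noiseless
boundary contour ``a0 + a1·log10 TP + a2·log10 TN = boundary EQR``
intersected with the population major axis of the log-nutrient
distribution.  This mirrors the bivariate estimator's contour–RMA
construction, so recovery error measures estimation noise rather than a
definitional mismatch.

Default parameters describe a eutrophic, shallow, high-alkalinity lake
population: mean concentrations around 316 μg/l TP and 6.3 mg/l TN with
decade-scale spread, log-nutrient correlation 0.6, and EQR noise chosen so
the population bivariate R² is ≈ 0.49 — the strength of relationship
typical of macrophyte–nutrient data at this scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import ClassBoundaries, Dataset, Split
from .exceptions import DomainError, NoIntersectionError

__all__ = ["SyntheticConfig", "TrueCriteria", "generate", "true_criteria"]


def _default_boundaries() -> ClassBoundaries:
    return ClassBoundaries(hg_eqr=0.8, gm_eqr=0.6)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic lake-year generator.

    ``plane`` is ``(a0, a1, a2)`` in ``EQR = a0 + a1·log10 TP + a2·log10 TN``
    with ``a1, a2 <= 0`` (enrichment lowers EQR).  ``mu``/``sd``/``rho``
    describe the bivariate normal of (log10 TP, log10 TN).
    """

    n: int = 1000
    mu: tuple[float, float] = (2.5, 0.8)
    sd: tuple[float, float] = (0.35, 0.30)
    rho: float = 0.6
    plane: tuple[float, float, float] = (1.8, -0.35, -0.25)
    noise_sd: float = 0.18
    boundaries: ClassBoundaries = field(default_factory=_default_boundaries)
    seed: int = 0
    type_code: str = "SYN1"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if not all(s > 0 for s in self.sd):
            raise DomainError("sd components must be > 0")
        if not (-1.0 < self.rho < 1.0):
            raise DomainError(f"rho must be in (-1, 1), got {self.rho}")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.plane[1] > 0 or self.plane[2] > 0:
            raise DomainError("plane nutrient coefficients must be <= 0")

    @property
    def covariance(self) -> np.ndarray:
        """Population covariance of (log10 TP, log10 TN)."""
        s1, s2 = self.sd
        c = self.rho * s1 * s2
        return np.array([[s1 * s1, c], [c, s2 * s2]])


class TrueCriteria(NamedTuple):
    """Analytic truth; a component is None when that nutrient plays no role."""

    tp: float | None
    tn: float | None


def generate(config: SyntheticConfig) -> Dataset:
    """Draw one synthetic dataset; byte-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    logs = rng.multivariate_normal(
        mean=np.asarray(config.mu, dtype=float),
        cov=config.covariance,
        size=config.n,
        method="cholesky",
    )
    log_tp, log_tn = logs[:, 0], logs[:, 1]
    a0, a1, a2 = config.plane
    eqr = a0 + a1 * log_tp + a2 * log_tn
    if config.noise_sd > 0:
        eqr = eqr + rng.normal(0.0, config.noise_sd, size=config.n)
    eqr = np.clip(eqr, 0.0, None)

    frame = pd.DataFrame(
        {
            "lake_id": [f"{config.type_code}-{i:05d}" for i in range(config.n)],
            "type_code": config.type_code,
            "year": 2005 + (np.arange(config.n) % 10),
            "tp": np.power(10.0, log_tp),
            "tn": np.power(10.0, log_tn),
            "eqr": eqr,
        }
    )
    return Dataset(frame, config.type_code)


def _population_major_axis(config: SyntheticConfig) -> np.ndarray:
    """Leading eigenvector of the population log-nutrient covariance."""
    w, v = np.linalg.eigh(config.covariance)
    e = v[:, int(np.argmax(w))]
    # orient along increasing log TP for reproducibility
    return e if e[0] >= 0 else -e


def true_criteria(config: SyntheticConfig, boundary: Split) -> TrueCriteria:
    """Analytic criteria implied by the generator at a class boundary.

    The truth is the point where the noiseless boundary contour crosses the
    population major axis of the log-nutrient distribution, back-transformed
    to concentrations.  When one plane coefficient is zero the construction
    degenerates to the univariate inversion for the other nutrient and the
    unused nutrient's truth is None.
    """
    a0, a1, a2 = config.plane
    if a1 == 0 and a2 == 0:
        raise DomainError("plane has no nutrient dependence; no criteria exist")
    target = config.boundaries.boundary_eqr(boundary)

    if a2 == 0:
        return TrueCriteria(tp=float(10 ** ((target - a0) / a1)), tn=None)
    if a1 == 0:
        return TrueCriteria(tp=None, tn=float(10 ** ((target - a0) / a2)))

    e = _population_major_axis(config)
    denom = a1 * e[0] + a2 * e[1]
    if abs(denom) < 1e-12:
        raise NoIntersectionError(
            "boundary contour is parallel to the population major axis",
            {"eigenvector": e.tolist()},
        )
    mu = np.asarray(config.mu, dtype=float)
    t = (target - a0 - a1 * mu[0] - a2 * mu[1]) / denom
    u, v = mu + t * e
    return TrueCriteria(tp=float(10**u), tn=float(10**v))
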
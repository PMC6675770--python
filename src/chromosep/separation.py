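"""Class-conditional RGB statistics and the Mahalanobis color-separation
distance.

The per-image color difference between cancerous and non-cancerous mucosa is
quantified as the Mahalanobis distance between the two class mean colors,
normalized by the pooled within-class covariance:

    D = sqrt( (μ1 − μ2)ᵀ Σp⁻¹ (μ1 − μ2) ),   Σp = (Σ1 + Σ2) / 2

with μ and Σ estimated from the luminance-matched pixel samples of each
class.  The unweighted pooled average is symmetric in the classes and
coincides with count-weighted pooling when the class sizes are equal (as in
the 2000-per-class protocol).  Near-singular pooled covariances (condition
number above 1e8, as arise from degenerate synthetic inputs) receive a small
trace-scaled ridge, flagged in the result rather than applied silently.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .base import DegenerateCovarianceError, InsufficientSampleError
from .sampling import SampleSet

__all__ = ["ClassStatistics", "SeparationResult", "estimate_class_stats",
           "mahalanobis_distance"]

#: Condition-number threshold beyond which the pooled covariance is ridged.
CONDITION_LIMIT = 1e8
#: Ridge size as a fraction of the mean diagonal variance.
RIDGE_FRACTION = 1e-6


@dataclasses.dataclass(frozen=True)
class ClassStatistics:
    """Sample mean vector and unbiased covariance of one class's RGB samples."""

    mean: np.ndarray        # (3,)
    covariance: np.ndarray  # (3,3), n−1 denominator
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, float).reshape(3))
        cov = np.asarray(self.covariance, float).reshape(3, 3)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(cov) < -1e-12):
            raise ValueError("covariance diagonal must be non-negative")
        object.__setattr__(self, "covariance", cov)
        if self.n < 4:
            raise InsufficientSampleError(f"need n >= 4 samples, got {self.n}")


@dataclasses.dataclass(frozen=True)
class SeparationResult:
    """Mahalanobis separation with numerical diagnostics."""

    distance: float
    pooled_covariance_condition_number: float
    regularized: bool


def estimate_class_stats(samples: "SampleSet | np.ndarray") -> ClassStatistics:
    """Estimate mean and unbiased (n−1) covariance of one class's RGB values."""
    rgb = samples.rgb if isinstance(samples, SampleSet) else np.asarray(samples, float)
    n = len(rgb)
    if n < 4:
        raise InsufficientSampleError(f"need n >= 4 samples, got {n}")
    mean = rgb.mean(axis=0)
    cov = np.cov(rgb, rowvar=False, ddof=1)
    return ClassStatistics(mean=mean, covariance=cov, n=n)


def mahalanobis_distance(a: ClassStatistics, b: ClassStatistics,
                         pooled_weighting: str = "unweighted"
                         ) -> SeparationResult:
    """Mahalanobis distance between two class-statistics objects.

    ``pooled_weighting='unweighted'`` uses Σp = (Σa + Σb)/2; ``'by_n'`` pools
    weighted by (nᵢ−1), the classical pooled estimator (identical when
    na == nb).  Symmetric in its arguments; zero iff the means are equal.
    """
    if pooled_weighting == "unweighted":
        pooled = 0.5 * (a.covariance + b.covariance)
    elif pooled_weighting == "by_n":
        wa, wb = a.n - 1, b.n - 1
        pooled = (wa * a.covariance + wb * b.covariance) / (wa + wb)
    else:
        raise ValueError(f"unknown pooled_weighting {pooled_weighting!r}")

    dmu = a.mean - b.mean
    cond = float(np.linalg.cond(pooled))
    regularized = False
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        eps = RIDGE_FRACTION * float(np.trace(pooled)) / 3.0
        if eps > 0.0:
            pooled = pooled + eps * np.eye(3)
            regularized = True

    if np.allclose(dmu, 0.0):
        return SeparationResult(0.0, cond, regularized)

    try:
        sol = np.linalg.solve(pooled, dmu)
        dist2 = float(dmu @ sol)
        if dist2 < 0:
            raise np.linalg.LinAlgError("negative quadratic form")
    except np.linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            "pooled covariance singular after regularization with unequal "
            f"means (condition number {cond:.3g})") from exc
    return SeparationResult(float(np.sqrt(dist2)), cond, regularized)
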
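"""Pipeline configuration: sampling sizes, SVM hyperparameters, luminance weights.

A flat YAML mapping round-trips to :class:`PipelineConfig`; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .base import ConfigError

__all__ = ["PipelineConfig", "LUMINANCE_WEIGHTS"]

#: Standard RGB→luminance weight conventions.  BT.601 is the default; BT.709
#: is selectable via the ``luminance_weights`` config key.
LUMINANCE_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "bt601": (0.299, 0.587, 0.114),
    "bt709": (0.2126, 0.7152, 0.0722),
}


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the assessment pipeline.

    Attributes
    ----------
    n_per_class:
        Luminance-matched pixels drawn per class per image (study protocol: 2000).
    n_bins:
        Equal-width luminance histogram bins used for matching.
    n_train_per_class:
        Training samples per class for the per-image SVM (study protocol: 100).
    svm_c:
        Soft-margin cost parameter C.
    svm_gamma:
        RBF kernel width; ``"scale"`` is the 1/(d·Var(X)) heuristic, or a
        positive float.
    luminance_weights:
        ``"bt601"`` or ``"bt709"``.
    boundary_erode:
        Pixels of binary erosion applied to the cancer mask before extraction
        (0 disables; excludes uncertain boundary pixels when positive).
    pooled_weighting:
        ``"unweighted"`` averages the two class covariances; ``"by_n"`` pools
        them weighted by sample count (identical when n1 == n2).
    """

    n_per_class: int = 2000
    n_bins: int = 32
    n_train_per_class: int = 100
    svm_c: float = 1.0
    svm_gamma: "str | float" = "scale"
    luminance_weights: str = "bt601"
    boundary_erode: int = 0
    pooled_weighting: str = "unweighted"

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        if not (1 <= self.n_train_per_class < self.n_per_class):
            raise ConfigError("need 1 <= n_train_per_class < n_per_class")
        if self.svm_c <= 0:
            raise ConfigError("svm_c must be positive")
        if isinstance(self.svm_gamma, str):
            if self.svm_gamma != "scale":
                raise ConfigError("svm_gamma must be 'scale' or a positive float")
        elif self.svm_gamma <= 0:
            raise ConfigError("svm_gamma must be positive")
        if self.luminance_weights not in LUMINANCE_WEIGHTS:
            raise ConfigError(f"luminance_weights must be one of {sorted(LUMINANCE_WEIGHTS)}")
        if self.boundary_erode < 0:
            raise ConfigError("boundary_erode must be >= 0")
        if self.pooled_weighting not in ("unweighted", "by_n"):
            raise ConfigError("pooled_weighting must be 'unweighted' or 'by_n'")

    @property
    def rgb_weights(self) -> tuple[float, float, float]:
        return LUMINANCE_WEIGHTS[self.luminance_weights]

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: "str | Path") -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )
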
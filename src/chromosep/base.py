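"""Shared vocabulary for the chromoendoscopy assessment pipeline.

Defines the imaging-modality enum, the exception hierarchy, and the
deterministic seed-derivation scheme that every stochastic stage uses.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "Modality",
    "RegionLabel",
    "ChromosepError",
    "ConfigError",
    "GeometryError",
    "FormatError",
    "EmptyRegionError",
    "InfeasibleSpecError",
    "InfeasibleSamplingError",
    "InsufficientSampleError",
    "DegenerateCovarianceError",
    "SplitError",
    "TrainingError",
    "EvaluationError",
    "CompletenessError",
    "derive_rng",
    "derive_seed",
]


class Modality(str, enum.Enum):
    """Endoscopic imaging modality.

    WL — white-light endoscopy; INDIGO — 0.2% indigo carmine dye spray;
    AIM — acetic acid plus indigo carmine chromoendoscopy.
    """

    WL = "WL"
    INDIGO = "Indigo"
    AIM = "AIM"

    @classmethod
    def from_string(cls, value: "str | Modality") -> "Modality":
        if isinstance(value, Modality):
            return value
        for m in cls:
            if value.lower() in (m.value.lower(), m.name.lower()):
                return m
        raise ConfigError(f"unknown modality {value!r}; expected one of "
                          f"{[m.value for m in cls]}")


#: Stable ordinal used in seed derivation and report ordering.
MODALITY_ORDER: tuple[Modality, ...] = (Modality.WL, Modality.INDIGO, Modality.AIM)


class RegionLabel(str, enum.Enum):
    """Pixel class label: cancerous vs non-cancerous mucosa."""

    CANCER = "cancer"
    NONCANCER = "noncancer"


class ChromosepError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ChromosepError):
    """Invalid configuration value."""


class GeometryError(ChromosepError):
    """Image/mask dimension mismatch or invalid raster geometry."""


class FormatError(ChromosepError):
    """Unsupported raster format (e.g. 16-bit or non-RGB image)."""


class EmptyRegionError(ChromosepError):
    """A mask region (cancer or non-cancer) contains no pixels."""


class InfeasibleSpecError(ChromosepError):
    """A synthetic lesion spec cannot satisfy the minimum region areas."""


class InfeasibleSamplingError(ChromosepError):
    """Luminance-matched sampling cannot reach the requested per-class n."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"luminance-matched sampling infeasible: requested {requested} "
            f"per class but joint bin capacity allows at most {achievable}"
        )


class InsufficientSampleError(ChromosepError):
    """Too few samples to estimate class statistics."""


class DegenerateCovarianceError(ChromosepError):
    """Pooled covariance singular even after regularization, means unequal."""


class SplitError(ChromosepError):
    """Train/test split request incompatible with the sample-set size."""


class TrainingError(ChromosepError):
    """Degenerate training data (classifier cannot be fit)."""


class EvaluationError(ChromosepError):
    """Prediction/truth sequence mismatch."""


class CompletenessError(ChromosepError):
    """Study records are missing one or more (lesion, modality) cells."""


# --- seed derivation -------------------------------------------------------
#
# Every random stage derives its generator from the master seed plus a stable
# address: (master, lesion ordinal, modality ordinal, stage code).  Stage
# codes: 0 = image generation, 1 = luminance-matched sampling, 2 = train/test
# split, 3 = per-lesion model perturbation.  SeedSequence mixing guarantees
# independent streams; the same address always replays the same stream.

STAGE_GENERATE = 0
STAGE_SAMPLE = 1
STAGE_SPLIT = 2
STAGE_PERTURB = 3


def derive_rng(master_seed: int, *address: int) -> np.random.Generator:
    """Return an independent Generator for (master seed, address…)."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), *map(int, address))))


def derive_seed(master_seed: int, *address: int) -> int:
    """Return a single 31-bit integer seed for (master seed, address…)."""
    ss = np.random.SeedSequence((int(master_seed), *map(int, address)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
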
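"""Luminance-matched random pixel sampling.

Brightness is a confounder when comparing tissue colors: the cancerous blob
and the surrounding mucosa may sit under different illumination, so a
classifier could separate them on luminance alone.  The study's protocol
removes this by drawing, from each image, the same number of pixels per class
at equivalent luminance (2000 per class, 4000 in total).  "Equivalent" is
operationalized here as equal-width histogram matching: the luminance range
[0, 255] is split into ``n_bins`` bins, each bin contributes
min(cancer count, non-cancer count) joint capacity, and the per-class quota
is allocated across bins proportionally to joint capacity (largest-remainder
rounding, ties to the lower bin), then drawn uniformly without replacement
within each class and bin.  Both returned sets therefore have identical
per-bin luminance counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .base import (
    ChromosepError,
    InfeasibleSamplingError,
    RegionLabel,
)

__all__ = ["PixelSample", "SampleSet", "luminance", "luminance_matched_sample"]

BT601 = (0.299, 0.587, 0.114)


@dataclasses.dataclass(frozen=True)
class PixelSample:
    """One pixel: an RGB 3-vector with derived luminance, label, coordinate."""

    rgb: tuple[float, float, float]
    luminance: float
    label: RegionLabel
    coord: tuple[int, int]


@dataclasses.dataclass(frozen=True)
class SampleSet:
    """A labeled collection of pixel samples from one region of one image.

    ``rgb`` is n×3 float, ``luminances`` length-n, ``coords`` n×2 int
    (row, col).  Array form keeps downstream statistics vectorized; the
    ``samples`` property materializes :class:`PixelSample` records on demand.
    """

    label: RegionLabel
    rgb: np.ndarray
    luminances: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.rgb) == len(self.luminances) == len(self.coords)):
            raise ChromosepError("sample arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.rgb)

    @property
    def samples(self) -> list[PixelSample]:
        return [PixelSample(tuple(map(float, c)), float(l), self.label,
                            (int(r), int(col)))
                for c, l, (r, col) in zip(self.rgb, self.luminances, self.coords)]


def luminance(rgb: np.ndarray, weights: tuple[float, float, float] = BT601
              ) -> np.ndarray:
    """Weighted RGB→luminance, BT.601 luma by default (0.299R+0.587G+0.114B).

    Accepts a single 3-vector or an N×3 array; components must lie in
    [0, 255].  The weights sum to 1, so the result is also in [0, 255].
    """
    arr = np.asarray(rgb, dtype=float)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ChromosepError("RGB components must lie in [0, 255]")
    out = arr @ np.asarray(weights, dtype=float)
    return out if arr.ndim > 1 else float(out)


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Round fractional quotas to integers summing to ``total``.

    Floors every quota, then distributes the remaining units to the largest
    fractional remainders; ties go to the lower bin index (np.argsort is
    stable, so sorting by descending remainder keeps lower indices first
    among ties).
    """
    floors = np.floor(quotas).astype(int)
    short = total - int(floors.sum())
    if short > 0:
        remainders = quotas - floors
        order = np.argsort(-remainders, kind="stable")
        floors[order[:short]] += 1
    return floors


def luminance_matched_sample(cancer_rgb: np.ndarray, cancer_coords: np.ndarray,
                             noncancer_rgb: np.ndarray,
                             noncancer_coords: np.ndarray,
                             n_per_class: int, n_bins: int = 32,
                             seed: int = 0,
                             weights: tuple[float, float, float] = BT601,
                             ) -> tuple[SampleSet, SampleSet]:
    """Draw luminance-matched random samples of both classes.

    Returns ``(cancer_set, noncancer_set)``, each with exactly
    ``n_per_class`` samples, identical per-bin luminance counts, and no pixel
    repeated within a class.  Deterministic under ``seed``.

    Raises
    ------
    InfeasibleSamplingError
        If the summed per-bin joint capacity is below ``n_per_class`` —
        e.g. when the two regions' luminance supports barely overlap.
    """
    if n_per_class < 1:
        raise ChromosepError("n_per_class must be >= 1")
    if len(cancer_rgb) == 0 or len(noncancer_rgb) == 0:
        raise ChromosepError("both pixel collections must be non-empty")

    lum_c = np.atleast_1d(luminance(cancer_rgb, weights))
    lum_n = np.atleast_1d(luminance(noncancer_rgb, weights))
    edges = np.linspace(0.0, 255.0, n_bins + 1)
    # right-inclusive top bin so luminance exactly 255 is kept
    bin_c = np.clip(np.digitize(lum_c, edges[1:-1]), 0, n_bins - 1)
    bin_n = np.clip(np.digitize(lum_n, edges[1:-1]), 0, n_bins - 1)
    count_c = np.bincount(bin_c, minlength=n_bins)
    count_n = np.bincount(bin_n, minlength=n_bins)
    capacity = np.minimum(count_c, count_n)
    total_capacity = int(capacity.sum())
    if total_capacity < n_per_class:
        raise InfeasibleSamplingError(n_per_class, total_capacity)

    quotas = n_per_class * capacity / total_capacity
    alloc = _largest_remainder(quotas, n_per_class)
    # proportional quotas never exceed capacity (quota <= capacity since
    # n_per_class <= total), and ceil(quota) <= capacity for fractional quotas
    assert np.all(alloc <= capacity)

    rng = np.random.default_rng(seed)
    pick_c: list[np.ndarray] = []
    pick_n: list[np.ndarray] = []
    for b in range(n_bins):
        k = int(alloc[b])
        if k == 0:
            continue
        idx_c = np.nonzero(bin_c == b)[0]
        idx_n = np.nonzero(bin_n == b)[0]
        pick_c.append(rng.choice(idx_c, size=k, replace=False))
        pick_n.append(rng.choice(idx_n, size=k, replace=False))
    sel_c = np.concatenate(pick_c)
    sel_n = np.concatenate(pick_n)

    def _build(label: RegionLabel, rgb: np.ndarray, coords: np.ndarray,
               lum: np.ndarray, sel: np.ndarray) -> SampleSet:
        return SampleSet(label=label,
                         rgb=np.asarray(rgb, float)[sel],
                         luminances=lum[sel],
                         coords=np.asarray(coords)[sel])

    return (_build(RegionLabel.CANCER, cancer_rgb, cancer_coords, lum_c, sel_c),
            _build(RegionLabel.NONCANCER, noncancer_rgb, noncancer_coords,
                   lum_n, sel_n))
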
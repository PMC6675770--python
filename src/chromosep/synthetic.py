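"""Synthetic lesion-image generator with known ground-truth color structure.

The study this package operationalizes compared three endoscopic imaging
modalities on still images of early gastric cancer; those patient images are
not publicly available.  This module stands in for them: it renders image/mask
pairs whose cancerous and non-cancerous regions are drawn from known 3-D
Gaussian RGB distributions, so every downstream stage (sampling, Mahalanobis
separation, SVM diagnosability, modality comparison) can be validated against
closed-form ground truth.

Model
-----
A lesion is a star-convex blob (an ellipse whose radius is perturbed by a
radial sinusoid) on a larger mucosa field.  Pixels inside the blob are i.i.d.
draws from the cancer color model, outside from the non-cancer model; an
optional radial luminance gradient is added to all channels before clipping
to [0, 255] and rounding to 8-bit.  Modalities differ only in how far apart
the two class means sit: each modality multiplies the base mean separation by
its separation scale, emulating the contrast enhancement of dye spraying.

All randomness flows from one master seed through the address scheme in
:mod:`chromosep.base`.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .base import (
    MODALITY_ORDER,
    STAGE_GENERATE,
    STAGE_PERTURB,
    ConfigError,
    InfeasibleSpecError,
    Modality,
    derive_seed,
)

__all__ = [
    "RegionColorModel",
    "LesionSpec",
    "StudySpec",
    "MIN_REGION_AREA",
    "generate_lesion_image",
    "generate_study",
    "closed_form_separation",
    "write_study",
]

#: Minimum pixels per region so the 2000-per-class sampling protocol is feasible.
MIN_REGION_AREA = 2000


@dataclasses.dataclass(frozen=True)
class RegionColorModel:
    """Ground-truth 3-D Gaussian RGB distribution of one tissue region.

    ``mean_rgb`` is the mean color (components in [0, 255]); ``covariance_rgb``
    is the 3×3 symmetric positive semi-definite covariance in intensity².
    """

    mean_rgb: np.ndarray
    covariance_rgb: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean_rgb, dtype=float).reshape(3)
        cov = np.asarray(self.covariance_rgb, dtype=float).reshape(3, 3)
        if np.any(mean < 0) or np.any(mean > 255):
            raise ConfigError(f"mean_rgb components must lie in [0,255]; got {mean}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ConfigError("covariance_rgb must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-8 * max(1.0, abs(eigvals).max()):
            raise ConfigError("covariance_rgb must be positive semi-definite")
        object.__setattr__(self, "mean_rgb", mean)
        object.__setattr__(self, "covariance_rgb", cov)


@dataclasses.dataclass(frozen=True)
class MaskGeometry:
    """Star-convex blob: ellipse radii modulated by a radial sinusoid.

    The blob boundary at polar angle θ (about ``center``) is
    ``r(θ) = r_ellipse(θ) · (1 + irregularity · sin(n_lobes·θ + phase))``.
    """

    center: tuple[float, float]  # (row, col), fractions of image size in (0,1)
    radii: tuple[float, float]   # (row, col) semi-axes in pixels
    irregularity: float = 0.0    # amplitude of the radial sinusoid, in [0, 0.5]
    n_lobes: int = 5
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.irregularity <= 0.5):
            raise ConfigError("irregularity must lie in [0, 0.5]")
        if min(self.radii) <= 0:
            raise ConfigError("blob radii must be positive")


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    """Everything needed to render one synthetic image/mask pair."""

    lesion_id: str
    modality: Modality
    cancer_model: RegionColorModel
    noncancer_model: RegionColorModel
    image_size: tuple[int, int] = (256, 256)
    mask_geometry: MaskGeometry = MaskGeometry(center=(0.5, 0.5), radii=(80.0, 70.0),
                                               irregularity=0.15)
    luminance_gradient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ConfigError(f"image_size must be at least 64×64; got {h}×{w}")
        if self.luminance_gradient_amplitude < 0:
            raise ConfigError("luminance_gradient_amplitude must be >= 0")


@dataclasses.dataclass(frozen=True)
class StudySpec:
    """Design of a full synthetic study: n lesions × three modalities.

    ``separation_scales`` multiplies the base cancer/non-cancer mean separation
    per modality (all must be positive and all three modalities present).
    Per-lesion variation: a common baseline color offset (s.d.
    ``baseline_offset_sd`` per channel) shifts both class means equally, and a
    log-normal factor (σ = ``lesion_factor_sigma``) scales the separation of
    all three modalities of that lesion equally — so the ground-truth modality
    ordering is preserved within every lesion, as in a paired design.
    """

    n_lesions: int = 18
    separation_scales: dict = dataclasses.field(
        default_factory=lambda: {Modality.WL: 1.52, Modality.INDIGO: 1.32,
                                 Modality.AIM: 2.53})
    base_mean_rgb: tuple[float, float, float] = (140.0, 90.0, 85.0)
    #: Unit-Mahalanobis separation direction in RGB; chosen nearly
    #: luminance-neutral so brightness carries almost no class signal.
    separation_direction: tuple[float, float, float] = (0.8165, -0.4082, -0.4082)
    noise_sd: float = 12.0
    baseline_offset_sd: float = 8.0
    lesion_factor_sigma: float = 0.12
    image_size: tuple[int, int] = (256, 256)
    luminance_gradient_amplitude: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ConfigError("n_lesions must be >= 1")
        scales = {Modality.from_string(k): float(v)
                  for k, v in self.separation_scales.items()}
        if set(scales) != set(MODALITY_ORDER):
            raise ConfigError("separation_scales must cover exactly WL, Indigo, AIM")
        if any(v <= 0 for v in scales.values()):
            raise ConfigError("separation scales must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        object.__setattr__(self, "separation_scales", scales)


# --- rendering -------------------------------------------------------------

def _blob_mask(image_size: tuple[int, int], geom: MaskGeometry) -> np.ndarray:
    """Rasterize the star-convex blob as a boolean mask."""
    h, w = image_size
    cr, cc = geom.center[0] * h, geom.center[1] * w
    rows = np.arange(h)[:, None] - cr
    cols = np.arange(w)[None, :] - cc
    theta = np.arctan2(cols, rows)
    # ellipse radius along theta, then sinusoidal modulation
    ar, ac = geom.radii
    denom = np.sqrt((np.cos(theta) / ar) ** 2 + (np.sin(theta) / ac) ** 2)
    boundary = (1.0 + geom.irregularity * np.sin(geom.n_lobes * theta + geom.phase)) / denom
    rho = np.hypot(rows, cols)
    return rho <= boundary


def generate_lesion_image(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one synthetic endoscopic still image and its cancer mask.

    Returns ``(image, mask)``: image is H×W×3 uint8, mask is H×W uint8 with
    255 inside the cancerous blob and 0 outside.  Identical specs (including
    the seed) render bit-identical output.

    Raises
    ------
    InfeasibleSpecError
        If either region covers fewer than :data:`MIN_REGION_AREA` pixels.
    """
    h, w = spec.image_size
    mask = _blob_mask(spec.image_size, spec.mask_geometry)
    n_cancer = int(mask.sum())
    n_noncancer = h * w - n_cancer
    if n_cancer < MIN_REGION_AREA:
        raise InfeasibleSpecError(
            f"cancer region has {n_cancer} pixels (< {MIN_REGION_AREA})")
    if n_noncancer < MIN_REGION_AREA:
        raise InfeasibleSpecError(
            f"non-cancer region has {n_noncancer} pixels (< {MIN_REGION_AREA})")

    rng = np.random.default_rng(spec.seed)
    img = np.empty((h, w, 3), dtype=float)
    # cancer pixels first, then non-cancer: draw order is fixed so output is
    # reproducible regardless of mask layout
    img[mask] = rng.multivariate_normal(
        spec.cancer_model.mean_rgb, spec.cancer_model.covariance_rgb,
        size=n_cancer, method="cholesky" if _is_pd(spec.cancer_model) else "svd")
    img[~mask] = rng.multivariate_normal(
        spec.noncancer_model.mean_rgb, spec.noncancer_model.covariance_rgb,
        size=n_noncancer, method="cholesky" if _is_pd(spec.noncancer_model) else "svd")

    if spec.luminance_gradient_amplitude > 0:
        # radial vignetting-like gradient: brightest at center, fading outward
        rows = (np.arange(h) - (h - 1) / 2)[:, None]
        cols = (np.arange(w) - (w - 1) / 2)[None, :]
        rho = np.hypot(rows, cols)
        grad = spec.luminance_gradient_amplitude * (1.0 - rho / rho.max())
        img += grad[:, :, None]

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask.astype(np.uint8) * 255


def _is_pd(model: RegionColorModel) -> bool:
    try:
        np.linalg.cholesky(model.covariance_rgb)
        return True
    except np.linalg.LinAlgError:
        return False


# --- analytic oracle -------------------------------------------------------

def closed_form_separation(cancer: RegionColorModel,
                           noncancer: RegionColorModel) -> float:
    """Population Mahalanobis distance between the two true color models.

    Computes ``sqrt(Δμᵀ Σp⁻¹ Δμ)`` with ``Σp = (Σ_cancer + Σ_noncancer)/2``
    from the model parameters themselves — the ground-truth value that
    downstream sample-based estimates should recover.
    """
    dmu = cancer.mean_rgb - noncancer.mean_rgb
    pooled = 0.5 * (cancer.covariance_rgb + noncancer.covariance_rgb)
    if np.allclose(dmu, 0.0):
        return 0.0
    try:
        sol = np.linalg.solve(pooled, dmu)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"pooled true covariance is singular: {exc}") from exc
    return float(np.sqrt(dmu @ sol))


# --- study generation ------------------------------------------------------

def _lesion_specs(study: StudySpec) -> Iterator[LesionSpec]:
    h, w = study.image_size
    direction = np.asarray(study.separation_direction, float)
    direction = direction / np.linalg.norm(direction)
    base_mean = np.asarray(study.base_mean_rgb, float)
    cov = (study.noise_sd ** 2) * np.eye(3)

    for li in range(study.n_lesions):
        prng = np.random.default_rng(
            derive_seed(study.master_seed, li, 0, STAGE_PERTURB))
        offset = prng.normal(0.0, study.baseline_offset_sd, size=3)
        factor = float(np.exp(prng.normal(0.0, study.lesion_factor_sigma)))
        mid = np.clip(base_mean + offset, 40.0, 215.0)
        geom = MaskGeometry(
            center=(0.5 + prng.uniform(-0.05, 0.05),
                    0.5 + prng.uniform(-0.05, 0.05)),
            radii=(min(h, w) * prng.uniform(0.26, 0.34),
                   min(h, w) * prng.uniform(0.26, 0.34)),
            irregularity=prng.uniform(0.05, 0.2),
            n_lobes=int(prng.integers(4, 8)),
            phase=prng.uniform(0.0, 2 * np.pi),
        )
        for mi, modality in enumerate(MODALITY_ORDER):
            # Mahalanobis separation = scale × lesion factor (Σ = σ²I, so
            # |Δμ| = σ·D); split symmetrically about the lesion midpoint
            d = study.separation_scales[modality] * factor
            half = 0.5 * study.noise_sd * d * direction
            yield LesionSpec(
                lesion_id=f"L{li + 1:02d}",
                modality=modality,
                cancer_model=RegionColorModel(mid + half, cov),
                noncancer_model=RegionColorModel(mid - half, cov),
                image_size=study.image_size,
                mask_geometry=geom,
                luminance_gradient_amplitude=study.luminance_gradient_amplitude,
                seed=derive_seed(study.master_seed, li, mi, STAGE_GENERATE),
            )


def generate_study(study: StudySpec) -> list[tuple[LesionSpec, np.ndarray, np.ndarray]]:
    """Generate the full synthetic study: one (spec, image, mask) triple per
    lesion × modality, deterministic under the master seed."""
    return [(spec, *generate_lesion_image(spec)) for spec in _lesion_specs(study)]


def write_study(study: StudySpec, out_dir: "str | Path") -> Path:
    """Render the study to disk: PNG images, PNG masks, and a manifest CSV.

    The manifest lists lesion_id, modality, image/mask paths (relative to the
    manifest) and the ground-truth closed-form separation of that image's
    color models.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lesion_id", "modality", "image_path", "mask_path",
                         "true_separation"])
        for spec, image, mask in generate_study(study):
            stem = f"{spec.lesion_id}_{spec.modality.value}"
            img_name, mask_name = f"{stem}.png", f"{stem}_mask.png"
            iio.imwrite(out / img_name, image)
            iio.imwrite(out / mask_name, mask)
            truth = closed_form_separation(spec.cancer_model, spec.noncancer_model)
            writer.writerow([spec.lesion_id, spec.modality.value, img_name,
                             mask_name, f"{truth:.12g}"])
    return manifest
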
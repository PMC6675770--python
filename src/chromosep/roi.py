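"""Reading image/mask pairs and extracting per-region pixel collections.

The unit of input is a still endoscopic image plus a binary mask tracing the
cancerous area (in the original study the mask came from an expert circling
the tumor using post-resection histopathology; here masks are simply inputs).
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .base import (
    EmptyRegionError,
    FormatError,
    GeometryError,
    Modality,
    RegionLabel,
)

__all__ = ["LabeledImage", "load_labeled_image", "extract_region_pixels",
           "read_manifest"]


@dataclasses.dataclass(frozen=True)
class LabeledImage:
    """An 8-bit RGB image with a binary cancer mask and study identifiers."""

    pixels: np.ndarray  # H×W×3 uint8
    mask: np.ndarray    # H×W uint8 in {0,1}; 1 = cancer
    lesion_id: str
    modality: Modality

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"expected H×W×3 RGB pixels; got shape {self.pixels.shape}")
        if self.mask.shape != self.pixels.shape[:2]:
            raise GeometryError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{self.pixels.shape[:2]}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError(f"mask must be binary {{0,1}}; found values {vals}")
        if 1 not in vals:
            raise EmptyRegionError(f"{self.lesion_id}/{self.modality.value}: "
                                   "mask marks no cancerous pixels")
        if 0 not in vals:
            raise EmptyRegionError(f"{self.lesion_id}/{self.modality.value}: "
                                   "mask marks no non-cancerous pixels")

    @property
    def n_cancer(self) -> int:
        return int(self.mask.sum())

    @property
    def n_noncancer(self) -> int:
        return int(self.mask.size - self.mask.sum())


def load_labeled_image(image_path: "str | Path", mask_path: "str | Path",
                       lesion_id: str, modality: "str | Modality",
                       boundary_erode: int = 0) -> LabeledImage:
    """Load an image/mask pair from PNG or TIFF files.

    Mask semantics on read are 0/nonzero (any nonzero value becomes cancer);
    RGBA images have the alpha channel dropped; 16-bit rasters are rejected.
    ``boundary_erode`` optionally erodes the cancer mask by that many pixels
    to exclude uncertain tumor-boundary pixels (default keeps every pixel).
    """
    image = iio.imread(Path(image_path))
    mask = iio.imread(Path(mask_path))

    if image.dtype != np.uint8:
        raise FormatError(f"{image_path}: expected 8-bit image, got {image.dtype}")
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[:, :, :3]
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"{image_path}: expected an RGB image, got shape "
                          f"{image.shape}")
    if mask.ndim == 3:  # tolerate RGB-encoded masks
        mask = mask[:, :, 0]
    if mask.shape != image.shape[:2]:
        raise GeometryError(f"mask shape {mask.shape} does not match image "
                            f"shape {image.shape[:2]}")
    mask = (mask != 0).astype(np.uint8)
    if boundary_erode > 0:
        mask = ndimage.binary_erosion(mask, iterations=boundary_erode).astype(np.uint8)
    return LabeledImage(pixels=image, mask=mask, lesion_id=lesion_id,
                        modality=Modality.from_string(modality))


def extract_region_pixels(img: LabeledImage, region: RegionLabel
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Return every pixel of one region, in deterministic row-major order.

    Returns ``(rgb, coords)``: an N×3 float array of RGB values and an N×2
    int array of 0-based (row, column) coordinates.
    """
    want = 1 if region is RegionLabel.CANCER else 0
    rows, cols = np.nonzero(img.mask == want)  # np.nonzero is row-major
    if rows.size == 0:
        raise EmptyRegionError(f"{img.lesion_id}/{img.modality.value}: region "
                               f"{region.value!r} is empty")
    rgb = img.pixels[rows, cols].astype(float)
    return rgb, np.column_stack([rows, cols])


def read_manifest(manifest_path: "str | Path") -> list[dict]:
    """Read a study manifest CSV (as written by the simulator).

    Paths are resolved relative to the manifest's directory.  Returns a list
    of dicts with keys lesion_id, modality, image_path, mask_path and, when
    present, true_separation (float).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    out: list[dict] = []
    with manifest_path.open(newline="") as fh:
        for row in csv.DictReader(fh):
            entry = {
                "lesion_id": row["lesion_id"],
                "modality": Modality.from_string(row["modality"]),
                "image_path": base / row["image_path"],
                "mask_path": base / row["mask_path"],
            }
            if row.get("true_separation"):
                entry["true_separation"] = float(row["true_separation"])
            out.append(entry)
    return out
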
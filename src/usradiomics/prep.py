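"""Image/mask I/O, isotropic resampling with pixel caps, and fixed-bin-number
(FBN) grey-level discretization of ROI intensities.

These are the preprocessing steps that sit between raw B-mode frames and the
texture-matrix feature families: every textural family operates on integer
grey levels ``1..n_bins`` obtained by FBN discretization over the ROI's own
intensity range, after the image/mask pair has been resampled to isotropic
pixel spacing (down-sampling only, with an upper cap on the resampled mask
size).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage
import tifffile

logger = logging.getLogger("usradiomics")

#: Mask-size cap (pixels) when resampling for texture-matrix features.
TEXTURE_PIXEL_CAP = 10_000_000
#: Mask-size cap (pixels) when resampling for all other feature families.
OTHER_PIXEL_CAP = 1_000_000


@dataclass
class GrayImage:
    """A 2D grayscale intensity grid with physical pixel spacing.

    Parameters
    ----------
    values : ndarray
        2D float array of non-negative, finite intensities.
    pixel_spacing : tuple of float
        (row_mm, col_mm), both positive.
    bit_depth : int
        Native bit depth (8 or 16); defines the nominal intensity maximum
        ``2**bit_depth - 1`` used by intensity-rescaling filters.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("GrayImage requires a 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("GrayImage values must be finite")
        r, c = self.pixel_spacing
        if r <= 0 or c <= 0:
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing = (float(r), float(c))

    @property
    def intensity_max(self) -> float:
        return float(2**self.bit_depth - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ROIMask:
    """Binary region-of-interest mask; shape must match its image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 2:
            raise ValueError("ROIMask requires a 2D array")
        if not self.values.any():
            raise ValueError("ROIMask has no foreground pixels")

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PrepConfig:
    """Preprocessing parameters: grey-level count and resampling caps."""

    n_bins: int = 64
    texture_pixel_cap: int = TEXTURE_PIXEL_CAP
    other_pixel_cap: int = OTHER_PIXEL_CAP

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.texture_pixel_cap <= 0 or self.other_pixel_cap <= 0:
            raise ValueError("pixel caps must be positive")

    def cap_for(self, purpose: str) -> int:
        if purpose == "texture":
            return self.texture_pixel_cap
        if purpose == "other":
            return self.other_pixel_cap
        raise ValueError(f"unknown resampling purpose {purpose!r}")


@dataclass
class DiscretizedROI:
    """ROI intensities mapped to integer grey levels ``1..n_bins``.

    ``levels`` keeps the 2D layout (0 outside the ROI) so that the
    spatial texture families can read neighbourhood structure directly;
    ``mask`` marks the in-ROI pixels.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    roi_min: float
    roi_max: float

    @property
    def roi_levels(self) -> np.ndarray:
        """1D array of the in-ROI grey levels."""
        return self.levels[self.mask]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: GrayImage, path: str | Path) -> None:
    """Write a grayscale image as 8-bit PNG or 8/16-bit TIFF with a JSON
    sidecar manifest recording pixel spacing and bit depth."""
    path = Path(path)
    arr = np.clip(np.rint(image.values), 0, image.intensity_max)
    if path.suffix.lower() in {".tif", ".tiff"}:
        dtype = np.uint16 if image.bit_depth == 16 else np.uint8
        tifffile.imwrite(path, arr.astype(dtype))
    else:
        if image.bit_depth != 8:
            raise ValueError("PNG output supports 8-bit images only; use TIFF")
        PILImage.fromarray(arr.astype(np.uint8), mode="L").save(path)
    manifest = {
        "pixel_spacing_mm": list(image.pixel_spacing),
        "bit_depth": image.bit_depth,
    }
    _sidecar_path(path).write_text(json.dumps(manifest))


def read_image(path: str | Path) -> GrayImage:
    """Read an 8/16-bit grayscale PNG or TIFF.

    Pixel spacing comes from the JSON sidecar manifest written next to the
    image; if the sidecar is absent, spacing defaults to 1.0 mm isotropic
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim != 2:
            raise ValueError(f"{path}: grayscale required, got shape {arr.shape}")
    else:
        img = PILImage.open(path)
        if img.mode not in {"L", "I;16", "I"}:
            raise ValueError(f"{path}: grayscale required, got mode {img.mode}")
        arr = np.asarray(img)
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    spacing = (1.0, 1.0)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        manifest = json.loads(sidecar.read_text())
        spacing = tuple(manifest["pixel_spacing_mm"])
        bit_depth = int(manifest.get("bit_depth", bit_depth))
    else:
        logger.warning("no sidecar manifest for %s; assuming 1.0 mm spacing", path)
        warnings.warn(f"no sidecar manifest for {path}; assuming 1.0 mm spacing")
    return GrayImage(arr.astype(np.float64), spacing, bit_depth)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    """Write a binary mask as a 0/255 8-bit PNG."""
    arr = np.where(mask.values, 255, 0).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(Path(path))


def read_mask(path: str | Path) -> ROIMask:
    """Read a 0/255 PNG mask (any non-zero pixel is foreground)."""
    img = PILImage.open(Path(path))
    if img.mode != "L":
        img = img.convert("L")
    return ROIMask(np.asarray(img) > 0)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_isotropic(
    image: GrayImage,
    mask: ROIMask,
    cfg: PrepConfig | None = None,
    purpose: str = "texture",
) -> tuple[GrayImage, ROIMask]:
    """Resample an image/mask pair to isotropic pixel spacing with a cap on
    the resampled mask size.

    The target spacing is the coarser of the two input spacings
    (down-sampling only). If the resampled mask would still exceed the cap
    for ``purpose`` (10^7 pixels for texture features, 10^6 otherwise), the
    target spacing is uniformly coarsened by the smallest factor that brings
    the mask pixel count under the cap. The image is interpolated bilinearly,
    the mask by nearest neighbour (stays strictly binary).
    """
    cfg = cfg or PrepConfig()
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    cap = cfg.cap_for(purpose)
    ry, rx = image.pixel_spacing
    target = max(ry, rx)
    n_fg = mask.n_foreground
    # uniform coarsening until the resampled mask fits under the cap
    pred = n_fg * (ry * rx) / target**2
    if pred > cap:
        target *= math.sqrt(pred / cap)
    if math.isclose(target, ry) and math.isclose(target, rx):
        return image, mask  # already isotropic and under cap

    for _ in range(8):  # discretization of shape can overshoot the estimate
        zoom = (ry / target, rx / target)
        new_img = ndimage.zoom(image.values, zoom, order=1, mode="nearest",
                               grid_mode=True)
        new_mask = ndimage.zoom(mask.values.astype(np.uint8), zoom, order=0,
                                mode="nearest", grid_mode=True).astype(bool)
        if not new_mask.any():
            raise ValueError("mask became empty after resampling")
        if new_mask.sum() <= cap:
            break
        # shape rounding can leave the count a hair over the cap; enforce a
        # minimum coarsening step so the loop always terminates
        target *= max(math.sqrt(new_mask.sum() / cap), 1.005)
    return (
        GrayImage(new_img, (target, target), image.bit_depth),
        ROIMask(new_mask),
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize_fbn(
    image: GrayImage, mask: ROIMask, cfg: PrepConfig | None = None
) -> DiscretizedROI:
    """Fixed-bin-number discretization of ROI intensities.

    ``level(x) = floor(n_bins * (x - roi_min) / (roi_max - roi_min)) + 1``,
    with ``x = roi_max`` mapped to ``n_bins``. A constant ROI maps every
    pixel to level 1. Levels are invariant under positive affine rescaling
    of the ROI intensities.
    """
    cfg = cfg or PrepConfig()
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    m = mask.values
    roi = image.values[m]
    roi_min, roi_max = float(roi.min()), float(roi.max())
    levels = np.zeros(image.shape, dtype=np.int64)
    if roi_max > roi_min:
        lv = np.floor(
            cfg.n_bins * (image.values[m] - roi_min) / (roi_max - roi_min)
        ).astype(np.int64) + 1
        np.clip(lv, 1, cfg.n_bins, out=lv)
        levels[m] = lv
    else:
        levels[m] = 1
    return DiscretizedROI(levels, m.copy(), cfg.n_bins, roi_min, roi_max)


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

def write_labels(rows: list[dict], path: str | Path) -> None:
    """Write a case-label table (case_id,label,split) as CSV."""
    import pandas as pd

    pd.DataFrame(rows, columns=["case_id", "label", "split"]).to_csv(
        Path(path), index=False
    )


def read_labels(path: str | Path):
    import pandas as pd

    df = pd.read_csv(Path(path), dtype={"case_id": str})
    missing = {"case_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return df
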
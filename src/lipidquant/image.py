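"""Calibrated greyscale images and the preprocessing primitives shared by the
droplet and nuclei pipelines.

All processing operates on :class:`GrayImage`: a 2-D float field normalised to
``[0, 1]`` with a physical calibration (microns per pixel) attached.  Intensity
is always normalised by the *container's* nominal maximum (255 for 8-bit,
65535 for 16-bit), never by the observed maximum, so that intensities remain
comparable across images of one experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters

__all__ = [
    "GrayImage",
    "BinaryImage",
    "load_image",
    "clahe",
    "gaussian_blur",
    "binarize",
]

# BT.709 luminance weights, the scikit-image rgb2gray convention.
_LUMA_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


@dataclass(frozen=True)
class GrayImage:
    """A single-channel micrograph with intensities in ``[0, 1]``.

    Parameters
    ----------
    pixels
        2-D float array, every value in ``[0, 1]``.
    microns_per_pixel
        Physical calibration (µm/px), strictly positive.  Size classes are
        defined in microns, so this is a required user input — it is never
        inferred from file metadata.
    source_bit_depth
        8, 16 or the string ``"float"``; records the container the image was
        loaded from.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    source_bit_depth: int | str = "float"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("pixels contain non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"intensities must lie in [0, 1]; observed range "
                f"[{px.min():.4g}, {px.max():.4g}]"
            )
        if not (self.microns_per_pixel > 0):
            raise ValueError(f"microns_per_pixel must be > 0, got {self.microns_per_pixel}")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same calibration/provenance, new pixel data."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class BinaryImage:
    """A foreground mask: values strictly in ``{0, 1}``."""

    pixels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("binary image values must be in {0, 1}")
            px = px.astype(bool)
        if not (self.microns_per_pixel > 0):
            raise ValueError(f"microns_per_pixel must be > 0, got {self.microns_per_pixel}")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_image(path: str | Path, microns_per_pixel: float) -> GrayImage:
    """Load an 8/16-bit greyscale or 8-bit RGB raster (TIFF/PNG) as a
    :class:`GrayImage`.

    RGB is collapsed to luminance; intensities are rescaled linearly from the
    container's nominal range to ``[0, 1]``.
    """
    if not (microns_per_pixel > 0):
        raise ValueError(f"microns_per_pixel must be > 0, got {microns_per_pixel}")
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio plugins raise a mix of error types
        raise OSError(f"could not read image file {path}: {exc}") from exc

    if raw.dtype == np.uint8:
        arr, depth = raw.astype(float) / 255.0, 8
    elif raw.dtype == np.uint16:
        arr, depth = raw.astype(float) / 65535.0, 16
    elif np.issubdtype(raw.dtype, np.floating):
        arr, depth = np.clip(raw.astype(float), 0.0, 1.0), "float"
    else:
        raise OSError(f"unsupported pixel type {raw.dtype} in {path}")

    if arr.ndim == 3:
        if arr.shape[-1] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[-1] != 3:
            raise OSError(f"unsupported channel layout {raw.shape} in {path}")
        arr = arr @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise OSError(f"expected a single 2-D image in {path}, got shape {raw.shape}")

    return GrayImage(np.clip(arr, 0.0, 1.0), microns_per_pixel, depth)


def clahe(
    img: GrayImage,
    clip_limit: float = 0.03,
    tile_grid: tuple[int, int] = (8, 8),
) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``tile_grid`` (rows, cols) tiles; each tile's
    histogram is equalized with its peak clipped at ``clip_limit`` (a fraction
    of the tile's histogram mass), and the per-tile mappings are interpolated
    bilinearly.  The default clip limit is 0.03, the value used throughout the
    droplet pipeline.
    """
    if not (0.0 < clip_limit <= 1.0):
        raise ValueError(f"clip_limit must be in (0, 1], got {clip_limit}")
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ValueError(f"tile_grid entries must be >= 1, got {tile_grid}")
    if rows > img.height_px or cols > img.width_px:
        raise ValueError(
            f"tile grid {tile_grid} implies tiles smaller than one pixel for "
            f"image of shape {img.shape}"
        )
    kernel = (
        max(1, math.ceil(img.height_px / rows)),
        max(1, math.ceil(img.width_px / cols)),
    )
    if np.ptp(img.pixels) == 0:
        # Degenerate histogram: no local contrast to redistribute.
        return img.with_pixels(img.pixels.copy())
    out = exposure.equalize_adapthist(img.pixels, kernel_size=kernel, clip_limit=clip_limit)
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def gaussian_blur(img: GrayImage, sigma_px: float) -> GrayImage:
    """Gaussian smoothing with reflective boundaries (total intensity is
    conserved).  ``sigma_px = 0`` returns the input unchanged."""
    if sigma_px < 0:
        raise ValueError(f"sigma_px must be >= 0, got {sigma_px}")
    if sigma_px == 0:
        return img
    out = ndi.gaussian_filter(img.pixels, sigma=sigma_px, mode="reflect")
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def binarize(img: GrayImage, threshold: float | str = "auto") -> BinaryImage:
    """Threshold to a foreground mask: pixel -> 1 iff intensity > threshold.

    ``"auto"`` selects Otsu's threshold on the image histogram; a constant
    image has no foreground under the automatic mode.
    """
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"threshold must be a number in [0, 1] or 'auto', got {threshold!r}")
        if np.ptp(img.pixels) == 0:
            return BinaryImage(np.zeros(img.shape, dtype=bool), img.microns_per_pixel)
        thr = float(filters.threshold_otsu(img.pixels))
    else:
        thr = float(threshold)
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"threshold must lie in [0, 1], got {thr}")
    return BinaryImage(img.pixels > thr, img.microns_per_pixel)
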
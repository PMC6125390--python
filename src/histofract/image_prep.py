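"""Image loading and ImageJ-style preprocessing for single-stain histology.

The pipeline operates on one immunostain channel at a time (stain
decomposition is upstream).  This module reproduces the classic ImageJ
contract: 8-bit grayscale conversion by the unweighted channel mean,
automatic binarization by the IsoData iterative-intermeans threshold, and
contour extraction.  The foreground convention is fixed throughout the
package: stained structures absorb light, so foreground = dark pixels
(intensity at or below the threshold).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: physical pixel edge length of the reference acquisition setup, micrometres
DEFAULT_PIXEL_SIZE_UM = 0.145

MIN_IMAGE_DIM = 8


class ImageFormatError(ValueError):
    """Raised when a file decodes but is not a usable 1- or 3-channel raster."""


class ImageInputError(IOError):
    """Raised when an image file cannot be read at all."""


def _check_raster(pixels: np.ndarray) -> None:
    if pixels.ndim != 2:
        raise ImageFormatError(f"expected a 2D raster, got shape {pixels.shape}")
    if pixels.shape[0] < MIN_IMAGE_DIM or pixels.shape[1] < MIN_IMAGE_DIM:
        raise ImageFormatError(
            f"image {pixels.shape} smaller than the {MIN_IMAGE_DIM}-px minimum"
        )


@dataclass(frozen=True)
class GrayImage:
    """A single-channel 8-bit image with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Graylevel intensities in [0, 255].
    pixel_size : float
        Physical edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageFormatError("GrayImage pixels must be integer-valued")
        _check_raster(px)
        if px.min() < 0 or px.max() > 255:
            raise ImageFormatError("graylevels must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinImage:
    """A boolean foreground mask (True = stained structure = dark pixels)."""

    mask: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        _check_raster(m)
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class OutlineImage:
    """A boolean contour mask (True = foreground pixel on a structure border)."""

    mask: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        _check_raster(m)
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def to_gray(pixels: np.ndarray, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Reduce a decoded raster to an 8-bit single-channel :class:`GrayImage`.

    3-channel input is averaged over channels (unweighted mean, the ImageJ
    "8-bit" conversion), rounded half-up and clamped to [0, 255]; 2D 8-bit
    input passes through unchanged.  An RGBA raster is treated as RGB after
    dropping a fully opaque alpha channel.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3 and arr.shape[2] == 4 and np.all(arr[..., 3] == arr[0, 0, 3]):
        arr = arr[..., :3]
    if arr.ndim == 2:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ImageFormatError("single-channel input must be integer 8-bit")
        return GrayImage(arr, pixel_size)
    if arr.ndim == 3 and arr.shape[2] == 3:
        mean = arr.astype(np.float64).mean(axis=2)
        gray = np.floor(mean + 0.5)  # round half-up, as ImageJ does
        gray = np.clip(gray, 0, 255).astype(np.uint8)
        return GrayImage(gray, pixel_size)
    raise ImageFormatError(
        f"unsupported channel layout: shape {arr.shape} (need 1 or 3 channels)"
    )


def load_gray(path: str | os.PathLike, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> GrayImage:
    """Read a TIFF/PNG image and convert it to 8-bit grayscale."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except ImageFormatError:
        raise
    except Exception as exc:  # backend-specific decode errors vary widely
        raise ImageInputError(f"cannot read image file {str(path)!r}: {exc}") from exc
    return to_gray(arr, pixel_size)


def isodata_threshold(hist: np.ndarray) -> int:
    """IsoData (iterative intermeans) threshold on a 256-bin histogram.

    Returns the integer graylevel T such that T is the fixed point of
    T <- floor((mean of levels <= T) + (mean of levels > T)) / 2.
    Pixels with intensity <= T are classified as foreground (dark/stained).
    For a constant histogram (single occupied bin) returns -1, meaning
    "no foreground".
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    occupied = np.nonzero(hist)[0]
    if occupied.size <= 1:
        return -1
    levels = np.arange(256, dtype=np.float64)
    t = int(np.floor((hist * levels).sum() / hist.sum()))
    for _ in range(256):
        low, high = hist[: t + 1], hist[t + 1 :]
        mu_low = (low * levels[: t + 1]).sum() / low.sum() if low.sum() else float(t)
        mu_high = (
            (high * levels[t + 1 :]).sum() / high.sum() if high.sum() else float(t + 1)
        )
        t_new = int(np.floor((mu_low + mu_high) / 2.0))
        if t_new == t:
            return t
        t = t_new
    return t  # cycle guard; iteration virtually always converges in < 10 steps


def binarize(img: GrayImage) -> BinImage:
    """Automatic threshold by IsoData; foreground = intensity <= T (dark).

    A constant image yields an all-background mask (no stain present).
    """
    hist = np.bincount(img.pixels.ravel(), minlength=256)
    t = isodata_threshold(hist)
    if t < 0:
        return BinImage(np.zeros(img.shape, dtype=bool), img.pixel_size)
    return BinImage(img.pixels <= t, img.pixel_size)


def extract_outline(bin_img: BinImage) -> OutlineImage:
    """Contour pixels: foreground with >= 1 background 4-neighbour.

    The image border counts as background, so structures touching the edge
    keep a closed contour.
    """
    m = bin_img.mask
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    has_bg_neighbour = ~(
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return OutlineImage(m & has_bg_neighbour, bin_img.pixel_size)


def render_mask(bin_img: BinImage, foreground_level: int = 0) -> GrayImage:
    """Render a mask back to graylevels (foreground dark by default)."""
    bg = 255 - foreground_level
    px = np.where(bin_img.mask, foreground_level, bg).astype(np.uint8)
    return GrayImage(px, bin_img.pixel_size)


def save_mask(bin_img: BinImage, path: str | os.PathLike) -> None:
    """Serialize a mask as PNG with foreground = 255."""
    import imageio.v3 as iio

    iio.imwrite(path, np.where(bin_img.mask, 255, 0).astype(np.uint8))
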
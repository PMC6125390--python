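"""Staining-intensity features: mean pixel intensity and total stained area.

Mean intensity is taken over the whole image (stained and unstained pixels
alike), matching the whole-image "measure" convention; lower values mean
darker, i.e. heavier, staining.  Total area counts every thresholded
foreground pixel with no minimum-particle-size filter, reported both in
pixels and in square micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_prep import BinImage, GrayImage


@dataclass(frozen=True)
class IntensityFeatures:
    mean_intensity: float
    total_area_px: int
    total_area_um2: float


def mean_intensity(img: GrayImage) -> float:
    """Arithmetic mean graylevel over all pixels, in [0, 255]."""
    return float(img.pixels.mean(dtype=np.float64))


def total_area(bin_img: BinImage) -> tuple[int, float]:
    """Foreground pixel count and physical area (pixel_size**2 per pixel)."""
    n = int(bin_img.mask.sum())
    return n, n * bin_img.pixel_size**2


def intensity_features(img: GrayImage, bin_img: BinImage) -> IntensityFeatures:
    n, um2 = total_area(bin_img)
    return IntensityFeatures(mean_intensity(img), n, um2)
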
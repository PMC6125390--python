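"""Monofractal texture analysis: box counting, differential box counting,
fractal dimension and lacunarity.

Binary images are analysed by regular non-overlapping box counting: the
raster is tiled by an origin-anchored grid of eps x eps boxes (partial boxes
at the right/bottom edges included) and N(eps) is the number of boxes holding
at least one foreground pixel.  The fractal dimension is the OLS slope of
log N(eps) versus log(1/eps).

Grayscale images are analysed by differential box counting (DBC, after
Sarkar & Chaudhuri): intensity is treated as surface height; for box size
eps the intensity axis is divided into cells of height
``h = eps * 256 / min(rows, cols)`` and each box contributes
``floor((max - min) / h) + 1`` cells.  A flat surface gives dimension 2,
rough surfaces approach 3.

Lacunarity is the scale-averaged squared coefficient of variation of the
per-box mass (foreground pixel count for binary, DBC cell count for
grayscale), computed over all grid boxes, empty ones included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image_prep import BinImage, GrayImage, OutlineImage

#: largest box edge as a fraction of the smaller image dimension
SCALE_CAP_FRACTION = 0.45
MIN_SCALES = 3


class DegenerateInputError(ValueError):
    """The image or series carries no usable signal (e.g. empty mask)."""


class ConfigurationError(ValueError):
    """The requested analysis cannot be set up (e.g. image too small)."""


@dataclass(frozen=True)
class ScaleSeries:
    """Per-scale box statistics.

    Attributes
    ----------
    scales : tuple of int
        Box edge lengths eps (pixels), strictly increasing, each >= 2.
    counts : ndarray
        N(eps): non-empty box count (binary) or summed DBC cell count
        (grayscale).
    box_masses : tuple of ndarray
        For each scale, the flattened per-box mass over the full grid,
        empty boxes included.
    """

    scales: tuple[int, ...]
    counts: np.ndarray
    box_masses: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        sc = tuple(int(s) for s in self.scales)
        if len(sc) < MIN_SCALES:
            raise ConfigurationError(f"need >= {MIN_SCALES} scales, got {len(sc)}")
        if any(s < 2 for s in sc) or any(b >= a for a, b in zip(sc[1:], sc)):
            raise ConfigurationError("scales must be strictly increasing and >= 2")
        object.__setattr__(self, "scales", sc)
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.float64))

    def mass_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-scale mean and (population) SD of per-box mass, all boxes."""
        mu = np.array([m.mean() for m in self.box_masses])
        sd = np.array([m.std() for m in self.box_masses])
        return mu, sd


@dataclass(frozen=True)
class MonofractalFeatures:
    fd: float
    fd_outline: float
    lacunarity: float
    r_squared: float
    modality: str  # "binary" | "grayscale"


def make_scales(shape: tuple[int, int]) -> list[int]:
    """Default dyadic scale grid: powers of two up to 45% of the min dimension."""
    cap = int(np.floor(SCALE_CAP_FRACTION * min(shape)))
    scales = []
    eps = 2
    while eps <= cap:
        scales.append(eps)
        eps *= 2
    if len(scales) < MIN_SCALES:
        raise ConfigurationError(
            f"image {shape} too small for a {MIN_SCALES}-point scale series "
            f"(only {len(scales)} dyadic scales fit below {cap})"
        )
    return scales


def _block_reduce(arr: np.ndarray, eps: int, ufunc: np.ufunc) -> np.ndarray:
    """Reduce over an origin-anchored eps-grid; partial edge boxes included."""
    rows = np.arange(0, arr.shape[0], eps)
    cols = np.arange(0, arr.shape[1], eps)
    return ufunc.reduceat(ufunc.reduceat(arr, rows, axis=0), cols, axis=1)


def mass_series(field: np.ndarray, scales: list[int] | None = None) -> ScaleSeries:
    """Box-sum a nonnegative mass field over the scale grid.

    The generic entry point shared by binary counting (mass = indicator) and
    grayscale multifractal measures (mass = inverted intensity); counts are
    the number of boxes with positive mass.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.min() < 0:
        raise ValueError("mass field must be nonnegative")
    if scales is None:
        scales = make_scales(field.shape)
    masses, counts = [], []
    for eps in scales:
        m = _block_reduce(field, int(eps), np.add).ravel()
        masses.append(m)
        counts.append(int((m > 0).sum()))
    return ScaleSeries(tuple(scales), np.array(counts, dtype=np.float64), tuple(masses))


def box_counts_binary(
    img: BinImage | OutlineImage, scales: list[int] | None = None
) -> ScaleSeries:
    """Regular non-overlapping box counting of a foreground mask."""
    if not img.mask.any():
        raise DegenerateInputError("empty mask: fractal dimension is undefined")
    return mass_series(img.mask.astype(np.float64), scales)


def dbc_counts_gray(img: GrayImage, scales: list[int] | None = None) -> ScaleSeries:
    """Differential box counting of a grayscale intensity surface."""
    px = img.pixels.astype(np.float64)
    if scales is None:
        scales = make_scales(px.shape)
    side = min(px.shape)
    masses, counts = [], []
    for eps in scales:
        h = eps * 256.0 / side  # intensity-cell height for this box size
        box_max = _block_reduce(px, int(eps), np.maximum)
        box_min = _block_reduce(px, int(eps), np.minimum)
        n = np.floor((box_max - box_min) / h) + 1.0
        masses.append(n.ravel())
        counts.append(float(n.sum()))
    return ScaleSeries(tuple(scales), np.array(counts, dtype=np.float64), tuple(masses))


def fit_dimension(series: ScaleSeries) -> tuple[float, float]:
    """OLS fit of log N(eps) on log(1/eps): returns (fd, r_squared)."""
    usable = series.counts > 0
    if usable.sum() < MIN_SCALES:
        raise DegenerateInputError("fewer than 3 scales with positive counts")
    x = -np.log(np.asarray(series.scales, dtype=np.float64)[usable])
    y = np.log(series.counts[usable])
    if np.ptp(y) == 0.0:  # constant counts: zero-dimensional point set
        return 0.0, 1.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


def lacunarity(series: ScaleSeries) -> float:
    """Lambda = mean over scales of (sigma(eps) / mu(eps))**2."""
    mu, sd = series.mass_stats()
    if np.any(mu <= 0):
        raise DegenerateInputError("zero mean box mass at some scale")
    return float(np.mean((sd / mu) ** 2))


def monofractal_features(
    gray: GrayImage,
    bin_img: BinImage,
    outline: OutlineImage,
    scales: list[int] | None = None,
) -> tuple[MonofractalFeatures, MonofractalFeatures]:
    """FD, outline FD and lacunarity for both modalities.

    Binary: box counting on the mask and its outline.  Grayscale: DBC on the
    full image; the grayscale outline variant applies DBC to the image with
    all non-outline pixels zeroed, so only contour relief contributes.
    """
    if scales is None:
        scales = make_scales(gray.shape)

    bin_series = box_counts_binary(bin_img, scales)
    bin_fd, bin_r2 = fit_dimension(bin_series)
    if outline.mask.any():
        out_fd, _ = fit_dimension(box_counts_binary(outline, scales))
    else:
        out_fd = float("nan")
    binary = MonofractalFeatures(
        fd=bin_fd,
        fd_outline=out_fd,
        lacunarity=lacunarity(bin_series),
        r_squared=bin_r2,
        modality="binary",
    )

    gray_series = dbc_counts_gray(gray, scales)
    gray_fd, gray_r2 = fit_dimension(gray_series)
    masked = GrayImage(
        np.where(outline.mask, gray.pixels, 0).astype(np.uint8), gray.pixel_size
    )
    gray_out_fd, _ = fit_dimension(dbc_counts_gray(masked, scales))
    grayscale = MonofractalFeatures(
        fd=gray_fd,
        fd_outline=gray_out_fd,
        lacunarity=lacunarity(gray_series),
        r_squared=gray_r2,
        modality="grayscale",
    )
    return binary, grayscale
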
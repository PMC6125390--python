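"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here with an analytic
answer attached:

* binary masks with known box-counting dimension (lines, filled squares,
  Sierpinski triangle/carpet, Mandelbrot-percolation random carpets),
* grayscale fractional-Brownian surfaces with DBC dimension 3 - H,
* blob-cluster images that mimic pan-cytokeratin-stained malignant cell
  clusters (dark textured blobs on a white background),
* 2D binomial multiplicative cascades with a closed-form multifractal
  spectrum, and
* survival cohorts with planted per-feature log-hazard effects, emulating
  the reference study frame (n = 73, ~25% metastasis events, per-risk-group
  feature distributions).

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .image_prep import BinImage, GrayImage, DEFAULT_PIXEL_SIZE_UM

MASK_KINDS = (
    "sierpinski_triangle",
    "sierpinski_carpet",
    "random_carpet",
    "filled",
    "line",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ImageSpec:
    kind: str
    size: int = 256
    depth: int | None = None
    hurst: float | None = None
    density: float | None = None
    retention: float | None = None
    seed: int = 0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM


# ---------------------------------------------------------------- binary masks


def _sierpinski_triangle(size: int, depth: int) -> np.ndarray:
    if size & (size - 1):
        raise ConfigurationError("triangle size must be a power of two")
    base = 2**depth
    if base > size:
        raise ConfigurationError(f"depth {depth} exceeds size {size}")
    i, j = np.indices((base, base))
    mask = (i & j) == 0
    return np.kron(mask, np.ones((size // base, size // base), dtype=bool))


def _sierpinski_carpet(depth: int) -> np.ndarray:
    mask = np.ones((1, 1), dtype=bool)
    centre = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
    for _ in range(depth):
        mask = np.kron(mask, centre)
    return mask


def _random_carpet(size: int, retention: float, rng: np.random.Generator) -> np.ndarray:
    # Mandelbrot percolation: at each dyadic refinement every surviving cell
    # splits in four and each child survives independently with prob p.
    # E[dimension] = log2(4p) for p > 1/4.
    if size & (size - 1):
        raise ConfigurationError("random carpet size must be a power of two")
    if not 0 < retention <= 1:
        raise ConfigurationError("retention probability must be in (0, 1]")
    mask = np.ones((1, 1), dtype=bool)
    while mask.shape[0] < size:
        mask = np.kron(mask, np.ones((2, 2), dtype=bool))
        mask &= rng.random(mask.shape) < retention
    return mask


def gen_mask(spec: ImageSpec) -> tuple[BinImage, float]:
    """Generate a binary mask and its theoretical box-counting dimension."""
    if spec.kind not in MASK_KINDS:
        raise ConfigurationError(f"unknown mask kind {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "filled":
        mask = np.ones((spec.size, spec.size), dtype=bool)
        fd = 2.0
    elif spec.kind == "line":
        mask = np.zeros((spec.size, spec.size), dtype=bool)
        mask[spec.size // 2, :] = True
        fd = 1.0
    elif spec.kind == "sierpinski_triangle":
        depth = spec.depth if spec.depth is not None else int(np.log2(spec.size))
        mask = _sierpinski_triangle(spec.size, depth)
        fd = np.log(3) / np.log(2)
    elif spec.kind == "sierpinski_carpet":
        depth = spec.depth if spec.depth is not None else 5
        mask = _sierpinski_carpet(depth)
        fd = np.log(8) / np.log(3)
    else:  # random_carpet
        if spec.retention is None:
            raise ConfigurationError("random_carpet needs a retention probability")
        mask = _random_carpet(spec.size, spec.retention, rng)
        fd = float(np.clip(np.log2(4 * spec.retention), 0.0, 2.0))
    return BinImage(mask, spec.pixel_size), float(fd)


# ------------------------------------------------------------ grayscale fields


def gen_gray(spec: ImageSpec, oversample: int = 2) -> tuple[GrayImage, float]:
    """Fractional Brownian surface by spectral synthesis; surface dimension 3 - H.

    White complex Gaussian noise is shaped by an isotropic power-law filter
    with amplitude |f|^-(H+1), inverse-transformed and rescaled to [0, 255].
    The field is synthesized on an `oversample`-times finer grid and
    subsampled, which restores the small-lag increment roughness that plain
    truncated spectral synthesis smooths away (subsampling preserves fBm
    self-affinity).
    """
    if spec.hurst is None or not 0 < spec.hurst < 1:
        raise ConfigurationError("fbm surface needs hurst in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    n = spec.size * oversample
    fx = np.fft.fftfreq(n)
    f = np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)
    f[0, 0] = 1.0
    amp = f ** -(spec.hurst + 1.0)
    amp[0, 0] = 0.0
    noise = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    surf = np.fft.ifft2(noise * amp).real[::oversample, ::oversample]
    lo, hi = surf.min(), surf.max()
    pixels = np.round((surf - lo) / (hi - lo) * 255).astype(np.uint8)
    return GrayImage(pixels, spec.pixel_size), 3.0 - spec.hurst


def binomial_cascade(weights: np.ndarray, depth: int) -> np.ndarray:
    """2D binomial multiplicative cascade mass field.

    `weights` is a 2x2 array of positive probabilities summing to 1; at each
    of `depth` refinements every cell's mass is split among its four children
    in those proportions.  The analytic generalized-dimension spectrum is
    D_Q = log2(sum_i p_i^Q) / (1 - Q) (box scale factor 2).
    """
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (2, 2) or not np.isclose(w.sum(), 1.0) or (w <= 0).any():
        raise ConfigurationError("weights must be a positive 2x2 array summing to 1")
    mass = np.ones((1, 1))
    for _ in range(depth):
        mass = np.kron(mass, w)
    return mass


def cascade_dq_closed_form(weights: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Analytic D_Q of the binomial cascade (D_1 by the entropy limit)."""
    p = np.asarray(weights, dtype=np.float64).ravel()
    q = np.asarray(q, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        dq = np.log2((p[None, :] ** q[:, None]).sum(axis=1)) / (1.0 - q)
    d1 = -(p * np.log2(p)).sum()
    return np.where(np.isclose(q, 1.0), d1, dq)


# ------------------------------------------------------------- blob clusters


def gen_clusters(spec: ImageSpec) -> tuple[GrayImage, BinImage]:
    """Blob-cluster stain mimic: dark textured discs on a white background.

    Disc count is set from the target coverage via the Poisson-coverage
    identity density = 1 - exp(-n * E[pi r^2] / area); discs are stamped on a
    torus (periodic wrap) so the identity holds without edge loss and the
    realized coverage concentrates tightly around `density` for any seed.
    Grayscale texture is darker inside blobs, so mean intensity falls as
    coverage rises.
    """
    if spec.density is None or not 0 <= spec.density < 1:
        raise ConfigurationError("blob clusters need density in [0, 1)")
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    if spec.density == 0:
        mask = np.zeros((n, n), dtype=bool)
        gray = np.full((n, n), 255, dtype=np.uint8)
        return GrayImage(gray, spec.pixel_size), BinImage(mask, spec.pixel_size)

    r0 = n / 48.0
    er2 = r0**2 * (0.8**2 + 0.8 * 1.2 + 1.2**2) / 3.0  # radii ~ U(0.8, 1.2) * r0
    n_discs = max(1, int(round(-np.log(1 - spec.density) * n**2 / (np.pi * er2))))
    cy = rng.uniform(0, n, n_discs)
    cx = rng.uniform(0, n, n_discs)
    radii = rng.uniform(0.8 * r0, 1.2 * r0, n_discs)

    mask = np.zeros((n, n), dtype=bool)
    for y0, x0, r in zip(cy, cx, radii):
        ri = int(np.ceil(r))
        ys = np.arange(int(y0) - ri, int(y0) + ri + 2)
        xs = np.arange(int(x0) - ri, int(x0) + ri + 2)
        patch = (ys[:, None] - y0) ** 2 + (xs[None, :] - x0) ** 2
        mask[np.ix_(ys % n, xs % n)] |= patch <= r**2

    texture = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=3.0)
    texture = texture / max(texture.std(), 1e-12)
    inside = np.clip(120 + 30 * texture, 20, 230)
    gray = np.where(mask, inside, 255.0).astype(np.uint8)
    return GrayImage(gray, spec.pixel_size), BinImage(mask, spec.pixel_size)


# ------------------------------------------------------------------- cohorts

#: per-risk-group (mean, sd) of the imaging features in the reference frame:
#: high-risk tumors stain lighter (higher mean intensity) and show lower
#: binary fractal dimension than low-risk ones.
DEFAULT_FEATURE_GROUPS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "mean_intensity": ((244.5, 3.1), (234.4, 9.1)),
    "bin_fd": ((1.640, 0.10), (1.722, 0.09)),
}

#: planted log-hazard per pooled-SD unit; signs follow the reference finding
#: (lighter staining and lower FD carry higher metastasis risk).
DEFAULT_BETAS: dict[str, float] = {"mean_intensity": 1.1, "bin_fd": -1.1}


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 73
    event_rate: float = 0.25
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    feature_groups: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_GROUPS)
    )
    high_risk_frac: float = 0.5
    censor_window_months: tuple[float, float] = (77.0, 165.0)

    def __post_init__(self) -> None:
        if not 0 < self.event_rate < 1:
            raise ConfigurationError("event_rate must be in (0, 1)")
        if self.n_patients < 10:
            raise ConfigurationError("n_patients must be >= 10")
        a, b = self.censor_window_months
        if not 0 < a < b:
            raise ConfigurationError("censoring window must satisfy 0 < lo < hi")


def _mean_event_prob(lam0: float, mult: np.ndarray, a: float, b: float) -> float:
    """Mean P(T < C) for T ~ Exp(lam0 * mult_i), C ~ U(a, b)."""
    lam = lam0 * mult
    surv = (np.exp(-lam * a) - np.exp(-lam * b)) / (lam * (b - a))
    return float(1.0 - surv.mean())


def gen_survival_groups(
    n: int = 73,
    hr: float = 1.0,
    event_rate: float = 0.25,
    censor_window_months: tuple[float, float] = (77.0, 165.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group exponential survival data with a planted hazard ratio.

    Group 1 hazard = hr * group 0 hazard; the baseline is solved so the
    expected event fraction equals `event_rate` under uniform censoring.
    """
    rng = np.random.default_rng(seed)
    group = np.arange(n) % 2
    mult = np.where(group == 1, hr, 1.0)
    a, b = censor_window_months
    lam0 = optimize.brentq(
        lambda l: _mean_event_prob(l, mult, a, b) - event_rate, 1e-10, 1e4
    )
    t_event = rng.exponential(1.0 / (lam0 * mult))
    t_cens = rng.uniform(a, b, n)
    return pd.DataFrame(
        {
            "group": group,
            "time_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
        }
    )


def gen_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a patient cohort with planted feature effects.

    Each patient is drawn as latent high- or low-risk; imaging features come
    from the group-specific normals; event times are exponential with hazard
    lam0 * exp(sum_f beta_f * z_f) on pooled-standardized features, with lam0
    solved per cohort so the expected event fraction matches the target under
    the uniform censoring window.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_patients
    high = rng.random(n) < spec.high_risk_frac

    features: dict[str, np.ndarray] = {}
    for name, ((mu_hi, sd_hi), (mu_lo, sd_lo)) in spec.feature_groups.items():
        x = np.where(
            high,
            rng.normal(mu_hi, sd_hi, n),
            rng.normal(mu_lo, sd_lo, n),
        )
        features[name] = x

    eta = np.zeros(n)
    for name, beta in spec.betas.items():
        if beta == 0:
            continue
        if name not in features:  # a planted effect on a pure-noise feature
            features[name] = rng.standard_normal(n)
        x = features[name]
        sd = x.std()
        eta += beta * (x - x.mean()) / (sd if sd > 0 else 1.0)
    mult = np.exp(eta - eta.mean())

    a, b = spec.censor_window_months
    lam0 = optimize.brentq(
        lambda l: _mean_event_prob(l, mult, a, b) - spec.event_rate, 1e-10, 1e4
    )
    t_event = rng.exponential(1.0 / (lam0 * mult))
    t_cens = rng.uniform(a, b, n)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "time_months": np.minimum(t_event, t_cens),
            "event": (t_event <= t_cens).astype(int),
            "tumor_size_pT": rng.choice([1, 2], n),
            "er_status": np.round(np.exp(rng.normal(np.log(32.0), 0.8, n)), 1),
        }
    )
    for name, x in features.items():
        df[name] = x
    return df
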
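"""Multifractal spectrum estimation by the Chhabra-Jensen direct method.

A box measure mu_i(eps) (normalized per-box mass) is raised to a moment
order Q, renormalized into weights nu_i(Q, eps) = mu_i^Q / sum_j mu_j^Q, and
three Q-families of scaling exponents are obtained as OLS slopes over the
scale grid:

* alpha(Q): slope of sum_i nu_i ln mu_i      vs ln eps (Hoelder exponent)
* f(Q):     slope of sum_i nu_i ln nu_i      vs ln eps (singularity spectrum)
* tau(Q):   slope of ln sum_i mu_i^Q         vs ln eps (mass exponent)

Generalized dimensions are D_Q = tau(Q) / (Q - 1) for Q != 1 and
D_1 = alpha(1) (the information-dimension limit).  Only occupied boxes
(mu_i > 0) enter the sums, so negative Q never sees an empty box; all moment
sums are evaluated in log space to keep Q = -10 finite.

The moment grid is the half-open 200-point lattice -10.0, -9.9, ..., +9.9,
and 13 scalar features summarize each spectrum: the three base values at
Q = 0 plus ten derived extrema/slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .image_prep import BinImage, GrayImage
from .monofractal import DegenerateInputError, ScaleSeries, make_scales, mass_series

Q_STEP = 0.1
N_Q = 200


def make_qgrid() -> np.ndarray:
    """The 200-point moment-order grid: -10.0, -9.9, ..., +9.9."""
    q = np.round(np.arange(-100, 100) * Q_STEP, 10)
    assert q.size == N_Q and 0.0 in q and 1.0 in q
    return q


@dataclass(frozen=True)
class MultifractalSpectrum:
    q: np.ndarray
    d_q: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    tau: np.ndarray
    fit_r2: np.ndarray


@dataclass(frozen=True)
class MultifractalFeatures:
    """13 scalar features summarizing one spectrum (one modality)."""

    d_q0: float
    alpha_q0: float
    f_alpha_q0: float
    d_q_max: float
    f_alpha_min: float
    f_alpha_max: float
    alpha_at_f_min: float
    alpha_at_f_max: float
    slope_dq: float
    slope_alpha: float
    slope_falpha: float
    slope_dq_restricted: float
    f_alpha_sum_qpos: float
    modality: str

    def as_dict(self) -> dict[str, float]:
        d = {k: v for k, v in self.__dict__.items() if k != "modality"}
        assert len(d) == 13
        return d


def normalized_masses(series: ScaleSeries, scale: int) -> np.ndarray:
    """Occupied-box probability vector mu_i = m_i / sum_j m_j at one scale."""
    idx = series.scales.index(scale)
    m = series.box_masses[idx]
    m = m[m > 0]
    total = m.sum()
    if total <= 0:
        raise DegenerateInputError(f"zero total mass at scale {scale}")
    return m / total


def _slopes(x: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope and r^2 of each row of `ys` against `x` (vectorized)."""
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum()
    sxy = yc @ xc
    slope = sxy / sxx
    ss_tot = (yc**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, sxy**2 / (sxx * ss_tot), 1.0)
    return slope, r2


def estimate_spectrum(
    series: ScaleSeries, q: np.ndarray | None = None
) -> MultifractalSpectrum:
    """Chhabra-Jensen spectrum from per-scale box masses."""
    if q is None:
        q = make_qgrid()
    q = np.asarray(q, dtype=np.float64)

    log_eps = np.log(np.asarray(series.scales, dtype=np.float64))
    n_scales = len(series.scales)
    s_tau = np.empty((q.size, n_scales))
    s_alpha = np.empty((q.size, n_scales))
    s_f = np.empty((q.size, n_scales))

    for j, scale in enumerate(series.scales):
        mu = normalized_masses(series, scale)
        log_mu = np.log(mu)
        a = q[:, None] * log_mu[None, :]  # ln mu_i^Q
        ls = logsumexp(a, axis=1)  # ln sum mu^Q
        w = np.exp(a - ls[:, None])  # nu_i(Q)
        s_tau[:, j] = ls
        s_alpha[:, j] = w @ log_mu
        s_f[:, j] = np.einsum("ij,ij->i", w, a - ls[:, None])

    tau, fit_r2 = _slopes(log_eps, s_tau)
    alpha, _ = _slopes(log_eps, s_alpha)
    f_alpha, _ = _slopes(log_eps, s_f)

    d_q = np.empty_like(q)
    near_one = np.isclose(q, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_q = np.where(near_one, alpha, tau / np.where(near_one, 1.0, q - 1.0))
    return MultifractalSpectrum(q=q, d_q=d_q, alpha=alpha, f_alpha=f_alpha, tau=tau, fit_r2=fit_r2)


def derived_features(spec: MultifractalSpectrum, modality: str = "") -> MultifractalFeatures:
    """Reduce a spectrum to the 13 scalar features (3 base at Q=0 + 10 derived)."""
    for name, arr in (("D_Q", spec.d_q), ("alpha", spec.alpha), ("f(alpha)", spec.f_alpha)):
        bad = ~np.isfinite(arr)
        if bad.any():
            raise DegenerateInputError(
                f"non-finite {name} at Q = {spec.q[bad][0]:g}"
            )
    q = spec.q
    i0 = int(np.argmin(np.abs(q)))
    imin = int(np.argmin(spec.f_alpha))
    imax = int(np.argmax(spec.f_alpha))
    restricted = (q >= -1.0 - 1e-12) & (q <= 3.0 + 1e-12)
    qpos = q > 0

    def ols(mask: np.ndarray, y: np.ndarray) -> float:
        s, _ = _slopes(q[mask], y[mask][None, :])
        return float(s[0])

    full = np.ones_like(q, dtype=bool)
    return MultifractalFeatures(
        d_q0=float(spec.d_q[i0]),
        alpha_q0=float(spec.alpha[i0]),
        f_alpha_q0=float(spec.f_alpha[i0]),
        d_q_max=float(spec.d_q.max()),
        f_alpha_min=float(spec.f_alpha[imin]),
        f_alpha_max=float(spec.f_alpha[imax]),
        alpha_at_f_min=float(spec.alpha[imin]),
        alpha_at_f_max=float(spec.alpha[imax]),
        slope_dq=ols(full, spec.d_q),
        slope_alpha=ols(full, spec.alpha),
        slope_falpha=ols(full, spec.f_alpha),
        slope_dq_restricted=ols(restricted, spec.d_q),
        f_alpha_sum_qpos=float(spec.f_alpha[qpos].sum()),
        modality=modality,
    )


def multifractal_features(
    gray: GrayImage, bin_img: BinImage, scales: list[int] | None = None
) -> tuple[MultifractalFeatures, MultifractalFeatures]:
    """Spectrum features for both modalities of one image.

    Binary measure: per-box foreground pixel count.  Grayscale measure:
    per-box summed inverted intensity (255 - I), so dark (stained) regions
    carry the mass.
    """
    if scales is None:
        scales = make_scales(gray.shape)
    if not bin_img.mask.any():
        raise DegenerateInputError("empty mask: binary measure undefined")
    bin_series = mass_series(bin_img.mask.astype(np.float64), scales)
    inverted = 255.0 - gray.pixels.astype(np.float64)
    if inverted.sum() <= 0:
        raise DegenerateInputError("all-white image: grayscale measure undefined")
    gray_series = mass_series(inverted, scales)
    q = make_qgrid()
    return (
        derived_features(estimate_spectrum(bin_series, q), "binary"),
        derived_features(estimate_spectrum(gray_series, q), "grayscale"),
    )
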
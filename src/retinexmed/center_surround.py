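"""Center-surround Retinex: SSR, MSR, and MSRCR.

The single-scale Retinex (SSR) estimates the illumination at each pixel as a
Gaussian-weighted average of its surround and removes it in the log domain:

    log R(x, y) = log I(x, y) - log(F * I)(x, y)

where ``F(x, y) = K exp(-(x^2 + y^2) / sigma^2)`` is the normalized surround
kernel (note the exponent carries ``sigma^2``, not ``2 sigma^2``: the spread
of the surround in the usual Gaussian-sigma sense is ``sigma / sqrt(2)``).
Multi-scale Retinex (MSR) averages SSR outputs across several surround scales,
and MSRCR adds a per-channel color-restoration factor

    C_i(x, y) = beta * log(a * I_i(x, y) / sum_j I_j(x, y))

that counteracts the desaturation MSR causes on color images.

Because the kernel factorizes, ``exp(-(x^2+y^2)/s^2) = exp(-x^2/s^2) *
exp(-y^2/s^2)``, the surround convolution is run as two 1-D passes; the
normalized separable form is identical to the normalized 2-D kernel on its
square support.  Borders use reflect padding so the log-domain subtraction
does not create artificial halos at the image edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateRangeError, DomainError, ShapeError
from .image_model import DEFAULT_EPSILON, Image, safe_log

__all__ = [
    "SurroundKernel",
    "MSRConfig",
    "MSRCRConfig",
    "gaussian_surround",
    "ssr",
    "msr",
    "linear_stretch",
    "color_restoration",
    "msrcr",
]


@dataclass(frozen=True)
class SurroundKernel:
    """Normalized discrete Gaussian surround on a (2*radius+1)^2 window."""

    weights: np.ndarray
    sigma: float
    radius: int


@dataclass(frozen=True)
class MSRConfig:
    """Scales and weights of the multiscale average.

    Defaults follow the common three-scale split — one scale below 50 px,
    one between 50 and 100, one above 100 — with equal weights 1/3.
    """

    sigmas: tuple[float, ...] = (25.0, 75.0, 150.0)
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if len(self.sigmas) != len(self.weights):
            raise ConfigError(
                f"{len(self.sigmas)} sigmas but {len(self.weights)} weights"
            )
        if not self.sigmas:
            raise ConfigError("at least one scale is required")
        if any(s <= 0 for s in self.sigmas):
            raise DomainError(f"sigmas must be positive, got {self.sigmas}")
        if any(w < 0 for w in self.weights):
            raise ConfigError(f"weights must be nonnegative, got {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigError(f"weights must sum to 1, got sum {sum(self.weights)!r}")


@dataclass(frozen=True)
class MSRCRConfig:
    """MSR scales plus the color-restoration gain ``a`` and ``beta``.

    ``a`` scales the channel proportion inside the log and ``beta`` scales the
    restored log-chromaticity; the classic working values 125 and 46 are the
    defaults.
    """

    msr: MSRConfig = field(default_factory=MSRConfig)
    alpha_a: float = 125.0
    beta: float = 46.0

    def __post_init__(self) -> None:
        if self.alpha_a <= 0 or self.beta <= 0:
            raise DomainError("alpha_a and beta must be positive")


def _gaussian_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / sigma**2)
    return k / k.sum()


def default_radius(sigma: float) -> int:
    """Truncation radius: 3 sigma, rounded up (the kernel is defined on the
    continuous plane; normalization is re-applied after truncation)."""
    return max(1, math.ceil(3 * sigma))


def gaussian_surround(sigma: float, radius: int | None = None) -> SurroundKernel:
    """Build the normalized discrete surround kernel.

    The continuous kernel ``K exp(-(x^2+y^2)/sigma^2)`` integrates to 1; the
    discrete analogue chooses K so the truncated window sums to 1.
    """
    if sigma <= 0:
        raise DomainError(f"sigma must be positive, got {sigma}")
    if radius is None:
        radius = default_radius(sigma)
    if radius < 1:
        raise DomainError(f"radius must be >= 1, got {radius}")
    k1 = _gaussian_1d(sigma, radius)
    weights = np.outer(k1, k1)
    weights /= weights.sum()
    return SurroundKernel(weights=weights, sigma=float(sigma), radius=int(radius))


def _as_gray_array(img: Image | np.ndarray) -> np.ndarray:
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError(f"expected a single-channel image, got shape {arr.shape}")
    return arr


def surround_mean(arr: np.ndarray, sigma: float, radius: int | None = None) -> np.ndarray:
    """Convolution with the normalized surround, as two separable 1-D passes
    with reflect padding.  Equals direct 2-D convolution with
    :func:`gaussian_surround` weights because the normalized kernel factorizes.
    """
    if radius is None:
        radius = default_radius(sigma)
    k1 = _gaussian_1d(sigma, radius)
    out = ndimage.correlate1d(arr, k1, axis=0, mode="reflect")
    return ndimage.correlate1d(out, k1, axis=1, mode="reflect")


def ssr(
    img: Image | np.ndarray,
    sigma: float = 100.0,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Single-scale Retinex: ``log I - log(F * I)``.

    The default sigma of 100 sits at the midpoint of the usual working range
    [80, 120], balancing dynamic-range compression against local contrast.
    Output is a signed log-reflectance grid, finite everywhere; use
    :func:`linear_stretch` to map it to display intensities.
    """
    if sigma <= 0:
        raise DomainError(f"sigma must be positive, got {sigma}")
    arr = _as_gray_array(img)
    blur = surround_mean(arr, sigma)
    return safe_log(arr, epsilon) - safe_log(blur, epsilon)


def msr(img: Image | np.ndarray, cfg: MSRConfig | None = None) -> np.ndarray:
    """Multiscale Retinex: weighted average of SSR over ``cfg.sigmas``."""
    cfg = cfg or MSRConfig()
    arr = _as_gray_array(img)
    out = np.zeros_like(arr)
    for w, s in zip(cfg.weights, cfg.sigmas):
        out += w * ssr(arr, s)
    return out


def linear_stretch(values: np.ndarray, out_max: float = 255.0) -> np.ndarray:
    """Affine map of a log-reflectance grid onto the display range.

    ``out = out_max * (R - Rmin) / (Rmax - Rmin)``: the minimum maps to 0 and
    the maximum to ``out_max`` exactly.  A constant input has no range to
    stretch and raises :class:`DegenerateRangeError`.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise DegenerateRangeError("constant input: stretch range is degenerate")
    return out_max * (values - lo) / (hi - lo)


def color_restoration(
    img: Image | np.ndarray,
    cfg: MSRCRConfig | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Per-channel color restoration factor ``beta * log(a * I_i / sum_j I_j)``.

    The channel proportion is scale-free, so the factor depends only on
    chromaticity.  A small epsilon guards pixels whose channel sum is zero.
    """
    cfg = cfg or MSRCRConfig()
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 image, got shape {arr.shape}")
    total = arr.sum(axis=2, keepdims=True)
    proportion = (arr + epsilon) / (total + 3 * epsilon)
    return cfg.beta * np.log(cfg.alpha_a * proportion)


def msrcr(
    img: Image | np.ndarray,
    cfg: MSRCRConfig | None = None,
    restore: bool = True,
) -> Image:
    """Multiscale Retinex with color restoration.

    Per channel i: ``C_i * sum_n W_n (log I_i - log(F_n * I_i))`` followed by
    a per-channel :func:`linear_stretch` to the 8-bit display range.  With
    ``restore=False`` the restoration factor is forced to 1, reducing the
    operator to per-channel MSR plus stretch.
    """
    cfg = cfg or MSRCRConfig()
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 image, got shape {arr.shape}")
    c = color_restoration(arr, cfg) if restore else np.ones_like(arr)
    out = np.empty_like(arr)
    for i in range(3):
        out[:, :, i] = c[:, :, i] * msr(arr[:, :, i], cfg.msr)
    stretched = np.stack([linear_stretch(out[:, :, i]) for i in range(3)], axis=2)
    return Image(stretched, bit_depth=8)
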
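"""Objective image-quality metrics: MSE, PSNR, and components-form SSIM.

PSNR compares a test image M against a reference N through the mean squared
error, on the scale set by the declared bit depth n:

    PSNR = 10 * log10((2**n - 1)**2 / MSE)   [dB]

Larger PSNR means less distortion (identical images give an infinite PSNR).

SSIM combines three symmetric comparisons built from image moments —
luminance l, contrast c, and structure s — into ``SSIM = l * c * s``:

    l = (2 mu_M mu_N + C1) / (mu_M^2 + mu_N^2 + C1)
    c = (2 sd_M sd_N + C2) / (sd_M^2 + sd_N^2 + C2)
    s = (cov_MN + C3) / (sd_M sd_N + C3)

with the stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2 / 2 and the usual
constants K1 = 0.01, K2 = 0.03, L = 255.  Moments are population moments
(divide by the pixel count) over the whole image, giving a single global
SSIM per pair; a mean-pooled sliding-window variant (11×11 uniform window)
is available via ``windowed=True``.

The structure denominator ``sd_M * sd_N + C3`` is what makes SSIM(M, M) = 1
and keeps the index within [-1, 1]; an ``as_printed`` switch substitutes a
``mu_M * mu_N + C3`` denominator for fidelity experiments with the source
formulation, at the cost of both properties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ShapeError
from .image_model import Image

__all__ = ["SSIMConstants", "QualityReport", "mse", "psnr", "ssim", "evaluate_pair"]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizing constants of the SSIM components."""

    K1: float = 0.01
    K2: float = 0.03
    L: float = 255.0

    @property
    def C1(self) -> float:
        return (self.K1 * self.L) ** 2

    @property
    def C2(self) -> float:
        return (self.K2 * self.L) ** 2

    @property
    def C3(self) -> float:
        return self.C2 / 2


@dataclass(frozen=True)
class QualityReport:
    """All metrics for one image pair; ``psnr_db`` is ``inf`` for identical
    images."""

    mse: float
    psnr_db: float
    ssim: float
    luminance: float
    contrast: float
    structure: float

    def to_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "psnr_db": self.psnr_db,
            "ssim": self.ssim,
            "luminance": self.luminance,
            "contrast": self.contrast,
            "structure": self.structure,
        }


def _pair_arrays(M: Image | np.ndarray, N: Image | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = M.pixels if isinstance(M, Image) else np.asarray(M, dtype=np.float64)
    b = N.pixels if isinstance(N, Image) else np.asarray(N, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(M: Image | np.ndarray, N: Image | np.ndarray) -> float:
    """Mean squared error over all pixels."""
    a, b = _pair_arrays(M, N)
    return float(np.mean((a - b) ** 2))


def psnr(M: Image | np.ndarray, N: Image | np.ndarray, bit_depth: int = 8) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` when MSE is zero."""
    err = mse(M, N)
    if err == 0:
        return math.inf
    peak = float(2**bit_depth - 1)
    return 10.0 * math.log10(peak**2 / err)


def _components(
    mu_m: np.ndarray | float,
    mu_n: np.ndarray | float,
    var_m: np.ndarray | float,
    var_n: np.ndarray | float,
    cov: np.ndarray | float,
    consts: SSIMConstants,
    as_printed: bool,
):
    sd_m = np.sqrt(np.maximum(var_m, 0.0))
    sd_n = np.sqrt(np.maximum(var_n, 0.0))
    l = (2 * mu_m * mu_n + consts.C1) / (mu_m**2 + mu_n**2 + consts.C1)
    c = (2 * sd_m * sd_n + consts.C2) / (var_m + var_n + consts.C2)
    denom = (mu_m * mu_n + consts.C3) if as_printed else (sd_m * sd_n + consts.C3)
    s = (cov + consts.C3) / denom
    return l, c, s


def ssim(
    M: Image | np.ndarray,
    N: Image | np.ndarray,
    consts: SSIMConstants | None = None,
    as_printed: bool = False,
    windowed: bool = False,
    window: int = 11,
) -> QualityReport:
    """Structural similarity of two single-channel images.

    Returns a :class:`QualityReport` carrying SSIM, its three components, and
    the MSE/PSNR of the same pair (PSNR at the bit depth implied by
    ``consts.L``).  Global image moments by default; ``windowed=True``
    mean-pools the local SSIM map computed with a uniform window.
    """
    consts = consts or SSIMConstants()
    a, b = _pair_arrays(M, N)
    if a.ndim != 2:
        raise ShapeError(f"ssim expects single-channel images, got shape {a.shape}")
    if not as_printed and np.array_equal(a, b):
        # identical inputs: every component is exactly 1 with the standard
        # structure denominator; short-circuit past sqrt round-off
        return QualityReport(mse=0.0, psnr_db=math.inf, ssim=1.0,
                             luminance=1.0, contrast=1.0, structure=1.0)
    if windowed:
        mean = lambda x: ndimage.uniform_filter(x, size=window, mode="reflect")
        mu_m, mu_n = mean(a), mean(b)
        var_m = mean(a * a) - mu_m**2
        var_n = mean(b * b) - mu_n**2
        cov = mean(a * b) - mu_m * mu_n
        l, c, s = _components(mu_m, mu_n, var_m, var_n, cov, consts, as_printed)
        l, c, s = float(np.mean(l)), float(np.mean(c)), float(np.mean(s))
        index = float(np.mean(_prod3(*_components(mu_m, mu_n, var_m, var_n, cov, consts, as_printed))))
    else:
        mu_m, mu_n = float(a.mean()), float(b.mean())
        var_m = float(np.mean((a - mu_m) ** 2))
        var_n = float(np.mean((b - mu_n) ** 2))
        cov = float(np.mean((a - mu_m) * (b - mu_n)))
        l, c, s = _components(mu_m, mu_n, var_m, var_n, cov, consts, as_printed)
        l, c, s = float(l), float(c), float(s)
        index = l * c * s
    bit_depth = max(1, round(math.log2(consts.L + 1)))
    return QualityReport(
        mse=mse(a, b),
        psnr_db=psnr(a, b, bit_depth=bit_depth),
        ssim=index,
        luminance=l,
        contrast=c,
        structure=s,
    )


def _prod3(l, c, s):
    return l * c * s


def evaluate_pair(
    M: Image | np.ndarray,
    N: Image | np.ndarray,
    bit_depth: int = 8,
    consts: SSIMConstants | None = None,
) -> QualityReport:
    """MSE, PSNR at ``bit_depth``, and global SSIM for one pair.

    Multi-channel inputs are compared on MSE/PSNR directly and on SSIM after
    collapsing to luminance.
    """
    consts = consts or SSIMConstants()
    a, b = _pair_arrays(M, N)
    if a.ndim == 3:
        from .image_model import to_grayscale

        rep = ssim(to_grayscale(Image(a, bit_depth)).pixels,
                   to_grayscale(Image(b, bit_depth)).pixels, consts)
    else:
        rep = ssim(a, b, consts)
    return QualityReport(
        mse=mse(a, b),
        psnr_db=psnr(a, b, bit_depth=bit_depth),
        ssim=rep.ssim,
        luminance=rep.luminance,
        contrast=rep.contrast,
        structure=rep.structure,
    )
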
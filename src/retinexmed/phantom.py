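"""Synthetic bias-field phantoms: ground truth for the enhancement algorithms.

Real MRI slices suffer a smooth multiplicative intensity inhomogeneity (the
"bias field") on top of piecewise-smooth tissue contrast — exactly the
``I = S * R`` decomposition the Retinex algorithms assume.  This module
manufactures that decomposition explicitly:

* a *reflectance* map R: overlapping constant-intensity ellipses ("tissues")
  on a dark background, values in (0, 1];
* an *illumination* field S: Gaussian-filtered white noise rescaled to
  ``[1 - strength, 1 + strength]`` and renormalized to mean 1, so its
  smoothness and amplitude are each a single interpretable parameter;
* the *observed* image ``clip(S * R + noise, 0, 1)`` scaled to display units.

Because all three layers are retained, every enhancement result can be scored
against the true reflectance — the evaluation the source patient images do
not permit.  Additive Gaussian noise is the default so the multiplicative
algebra stays exact at zero noise; Rician noise (the magnitude-image noise
of MRI) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .errors import DomainError, ShapeError, SizeError
from .image_model import Image

__all__ = ["Phantom", "make_reflectance", "make_illumination", "compose", "generate"]

BACKGROUND = 0.05  #: reflectance of the non-tissue background


@dataclass
class Phantom:
    """Triple (reflectance, illumination, observed) with provenance.

    ``observed.pixels`` are in display units ``[0, 2**bit_depth - 1]``;
    ``reflectance`` is unit-scale in (0, 1]; ``illumination`` is a positive,
    mean-1 field.  ``params`` records every generation parameter plus the
    fraction of pixels clipped when forming the observed image.
    """

    reflectance: Image
    illumination: np.ndarray
    observed: Image
    params: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def reflectance_display(self) -> np.ndarray:
        """True reflectance on the observed image's display scale."""
        return self.reflectance.pixels * self.observed.max_value


def make_reflectance(
    height: int, width: int, n_structures: int = 6, seed: int = 0
) -> Image:
    """Piecewise-constant "tissue" map: ``n_structures`` random ellipses with
    distinct intensity levels in [0.1, 1.0] on a 0.05 background.

    Ellipse radii span 2-5% of the smaller dimension (with a 2-pixel floor),
    emulating focal lesions that are *finer* than any surround scale the
    enhancement algorithms use — the scale separation (structure scale <
    surround scale < bias scale) that makes the illumination/reflectance
    decomposition identifiable in the first place.  Centers stay inside the
    central 70% of the field so the background always survives.
    Deterministic given ``seed``.
    """
    if height < 32 or width < 32:
        raise SizeError(f"reflectance phantom must be at least 32×32, got {height}×{width}")
    if n_structures < 1:
        raise DomainError(f"n_structures must be >= 1, got {n_structures}")
    from skimage.draw import ellipse

    rng = np.random.default_rng(seed)
    levels = np.linspace(0.1, 1.0, n_structures)
    rng.shuffle(levels)
    out = np.full((height, width), BACKGROUND)
    small = min(height, width)
    r_lo, r_hi = max(2.0, 0.02 * small), max(4.0, 0.05 * small)
    for level in levels:
        cy = rng.uniform(0.15 * height, 0.85 * height)
        cx = rng.uniform(0.15 * width, 0.85 * width)
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=out.shape, rotation=rot)
        out[rr, cc] = level
    return Image(out, bit_depth=8)


def make_illumination(
    height: int,
    width: int,
    strength: float = 0.5,
    smoothness_sigma: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Smooth, strictly positive, mean-1 multiplicative bias field.

    Gaussian-filtered white noise is rescaled to ``[1 - strength,
    1 + strength]`` and divided by its mean.  ``smoothness_sigma`` (default:
    half the smaller dimension, i.e. an essentially global gradient, as MRI
    coil-sensitivity bias is) sets the spatial autocorrelation length;
    ``strength`` in [0, 1) sets the amplitude — 1 would allow a nonpositive
    field and is rejected.
    """
    if not 0 <= strength < 1:
        raise DomainError(f"strength must lie in [0, 1), got {strength}")
    if smoothness_sigma is None:
        smoothness_sigma = min(height, width) / 2
    if smoothness_sigma <= 0:
        raise DomainError(f"smoothness_sigma must be positive, got {smoothness_sigma}")
    if strength == 0:
        return np.ones((height, width))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    smooth = ndimage.gaussian_filter(noise, smoothness_sigma, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi <= lo:  # pathologically flat draw
        return np.ones((height, width))
    fieldv = (1 - strength) + 2 * strength * (smooth - lo) / (hi - lo)
    return fieldv / fieldv.mean()


def compose(
    R: Image | np.ndarray,
    S: np.ndarray,
    noise_sigma: float = 0.0,
    bit_depth: int = 8,
    seed: int = 0,
    noise_model: Literal["gaussian", "rician"] = "gaussian",
) -> Phantom:
    """Form the observed image ``clip(S * R + noise, 0, 1)`` in display units.

    ``noise_sigma`` is the noise standard deviation on the unit intensity
    scale.  The Rician option replaces the additive draw by the magnitude of
    the complex signal ``|S*R + n1 + i n2|``.  The clipped-pixel fraction is
    recorded in ``params["clipped_fraction"]`` so callers can demand
    clip-free phantoms.
    """
    r_arr = R.pixels if isinstance(R, Image) else np.asarray(R, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if r_arr.shape != S.shape:
        raise ShapeError(f"shape mismatch: reflectance {r_arr.shape} vs illumination {S.shape}")
    if noise_sigma < 0:
        raise DomainError(f"noise_sigma must be >= 0, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    clean = S * r_arr
    if noise_sigma == 0:
        noisy = clean
    elif noise_model == "gaussian":
        noisy = clean + rng.normal(0.0, noise_sigma, clean.shape)
    elif noise_model == "rician":
        noisy = np.hypot(clean + rng.normal(0.0, noise_sigma, clean.shape),
                         rng.normal(0.0, noise_sigma, clean.shape))
    else:
        raise DomainError(f"unknown noise model {noise_model!r}")
    clipped = float(np.mean((noisy < 0) | (noisy > 1)))
    peak = float(2**bit_depth - 1)
    observed = np.clip(noisy, 0.0, 1.0) * peak
    params = {
        "noise_sigma": noise_sigma,
        "noise_model": noise_model,
        "bit_depth": bit_depth,
        "clipped_fraction": clipped,
    }
    return Phantom(
        reflectance=Image(r_arr, bit_depth=bit_depth),
        illumination=S,
        observed=Image(observed, bit_depth=bit_depth),
        params=params,
        seed=seed,
    )


def generate(
    size: int = 256,
    n_structures: int = 6,
    strength: float = 0.5,
    smoothness_sigma: float | None = None,
    noise_sigma: float = 0.005,
    bit_depth: int = 8,
    seed: int = 0,
) -> Phantom:
    """One-call phantom: reflectance, bias field, and observed image.

    Sub-seeds for the three stochastic layers are derived from ``seed`` so a
    single integer reproduces the whole phantom.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    R = make_reflectance(size, size, n_structures, seed=seeds[0])
    S = make_illumination(size, size, strength, smoothness_sigma, seed=seeds[1])
    ph = compose(R, S, noise_sigma, bit_depth, seed=seeds[2])
    ph.params.update(
        size=size,
        n_structures=n_structures,
        strength=strength,
        smoothness_sigma=smoothness_sigma or size / 2,
    )
    ph.seed = seed
    return ph


def recovery_scores(ph: Phantom, log_reflectance: np.ndarray):
    """Score an enhancement output against the phantom's true reflectance.

    All images are compared in the same log display domain, the domain the
    Retinex estimators operate in: the observed image and the true
    reflectance pass through ``linear_stretch(safe_log(.))`` while the
    enhancement's log-reflectance output passes through ``linear_stretch``
    directly.  Returns ``(degraded, enhanced)`` quality reports, each
    measured against the true reflectance; enhancement succeeded when the
    enhanced SSIM (and PSNR) exceed the degraded ones.
    """
    from .center_surround import linear_stretch
    from .image_model import safe_log
    from .quality_metrics import evaluate_pair

    ref = linear_stretch(safe_log(ph.reflectance_display))
    degraded = evaluate_pair(linear_stretch(safe_log(ph.observed.pixels)), ref)
    enhanced = evaluate_pair(linear_stretch(np.asarray(log_reflectance)), ref)
    return degraded, enhanced
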
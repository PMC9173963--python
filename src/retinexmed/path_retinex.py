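"""Path-based Retinex: random-path, Frankle-McCann spiral, McCann99 pyramid.

Path-based Retinex estimates the lightness of a pixel by chaining brightness
ratios along a path from a reference pixel.  For a path through pixels
``p_1 ... p_n`` the lightness of the end pixel relative to the start is

    log(E / S) = sum_i T'(log p_i - log p_{i-1})

where ``T'`` thresholds each step ratio.  As printed in the source
formulation, the threshold *keeps* a ratio ``x`` when ``1 - T <= x <= 1 + T``
and replaces it by 1 otherwise — i.e. it discards large jumps and keeps
near-unity ratios.  Classic Retinex resets the *small* ratios (treating them
as gradual illumination change) and keeps the jumps; both behaviours are
implemented, with the printed form as the default (``mode="as-printed"``)
and the classic form behind ``mode="classic"``.

All three variants operate in the log domain and return a signed
log-reflectance grid expressed relative to the white reference (the image
maximum), which makes every output invariant under global rescaling of the
input: multiplying the image by k > 0 shifts every log uniformly and the
shift cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigError, DomainError, SizeError
from .image_model import DEFAULT_EPSILON, Image, safe_log

__all__ = [
    "PathConfig",
    "SpiralConfig",
    "PyramidConfig",
    "threshold_ratio",
    "path_log_ratio",
    "random_path_retinex",
    "conversion_operator",
    "spiral_offsets",
    "frankle_mccann",
    "mccann99",
]

ThresholdMode = Literal["as-printed", "classic"]


@dataclass(frozen=True)
class PathConfig:
    """Random-path parameters.

    threshold_T
        Half-width of the ratio band around 1 fed to the threshold function.
    n_paths
        Random paths averaged per pixel.
    path_length
        Maximum number of pixels per path; longer monotone paths are
        subsampled down to this many waypoints (the log-ratio chain
        telescopes through the retained waypoints).
    """

    threshold_T: float = 0.5
    n_paths: int = 8
    path_length: int = 64
    seed: int = 0
    mode: ThresholdMode = "as-printed"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_T < 1:
            raise ConfigError(f"threshold_T must lie in (0, 1), got {self.threshold_T}")
        if self.n_paths < 1:
            raise ConfigError(f"n_paths must be >= 1, got {self.n_paths}")
        if self.path_length < 2:
            raise ConfigError(f"path_length must be >= 2, got {self.path_length}")


@dataclass(frozen=True)
class SpiralConfig:
    """Frankle-McCann spiral parameters.

    max_value
        Reset ceiling in intensity units; defaults to the image maximum
        (white-patch reset).
    stop_threshold
        Iteration stops once the offset magnitude drops below this (1 pixel).
    """

    max_value: float | None = None
    stop_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.max_value is not None and self.max_value <= 0:
            raise ConfigError(f"max_value must be positive, got {self.max_value}")
        if self.stop_threshold <= 0:
            raise ConfigError("stop_threshold must be positive")


@dataclass(frozen=True)
class PyramidConfig:
    """McCann99 pyramid parameters; ``n_levels=None`` means as many 2×2
    halvings as the image size allows."""

    iterations_per_level: int = 4
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.iterations_per_level < 1:
            raise ConfigError("iterations_per_level must be >= 1")
        if self.n_levels is not None and self.n_levels < 1:
            raise ConfigError("n_levels must be >= 1")


def threshold_ratio(x: float, T: float, mode: ThresholdMode = "as-printed") -> float:
    """Threshold function on a brightness ratio ``x > 0``.

    as-printed: return ``x`` when ``1 - T <= x <= 1 + T``, else 1.
    classic: return 1 when in the band (gradual illumination is ignored),
    else ``x``.
    """
    if x <= 0:
        raise DomainError(f"ratio must be positive, got {x}")
    if T <= 0:
        raise DomainError(f"threshold T must be positive, got {T}")
    in_band = (1 - T) <= x <= (1 + T)
    if mode == "as-printed":
        return x if in_band else 1.0
    if mode == "classic":
        return 1.0 if in_band else x
    raise ConfigError(f"unknown threshold mode {mode!r}")


def _threshold_log_steps(d: np.ndarray, T: float, mode: ThresholdMode) -> np.ndarray:
    """Vectorized threshold applied to log-differences ``d = log(p_i/p_{i-1})``.

    Equivalent to ``log(threshold_ratio(exp(d)))``: a kept ratio contributes
    its log-difference, a reset ratio contributes log 1 = 0.
    """
    ratio = np.exp(d)
    in_band = ((1 - T) <= ratio) & (ratio <= (1 + T))
    if mode == "as-printed":
        return np.where(in_band, d, 0.0)
    if mode == "classic":
        return np.where(in_band, 0.0, d)
    raise ConfigError(f"unknown threshold mode {mode!r}")


def path_log_ratio(
    img: Image | np.ndarray,
    path: Sequence[tuple[int, int]],
    T: float,
    mode: ThresholdMode = "as-printed",
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Thresholded log-lightness of the last path pixel relative to the first.

    ``path`` is an ordered list of (row, col) pixels; each consecutive pair
    contributes ``T'(log p_i - log p_{i-1})``.
    """
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if len(path) < 2:
        raise ConfigError(f"path must contain at least 2 pixels, got {len(path)}")
    rows = np.array([p[0] for p in path])
    cols = np.array([p[1] for p in path])
    if (rows < 0).any() or (cols < 0).any() or (rows >= arr.shape[0]).any() or (
        cols >= arr.shape[1]
    ).any():
        raise IndexError("path leaves the image bounds")
    logs = np.log(arr[rows, cols] + epsilon)
    return float(_threshold_log_steps(np.diff(logs), T, mode).sum())


def _staircase_path(
    start: tuple[int, int], end: tuple[int, int], rng: np.random.Generator, max_pixels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random monotone lattice path from start to end, subsampled
    to at most ``max_pixels`` waypoints (endpoints always retained)."""
    dr = end[0] - start[0]
    dc = end[1] - start[1]
    steps = np.concatenate(
        [np.zeros(abs(dr), dtype=np.int64), np.ones(abs(dc), dtype=np.int64)]
    )
    rng.shuffle(steps)
    rr = np.concatenate([[start[0]], start[0] + np.cumsum((steps == 0) * np.sign(dr))])
    cc = np.concatenate([[start[1]], start[1] + np.cumsum((steps == 1) * np.sign(dc))])
    if rr.size > max_pixels:
        idx = np.unique(np.linspace(0, rr.size - 1, max_pixels).round().astype(int))
        rr, cc = rr[idx], cc[idx]
    return rr, cc


def random_path_retinex(img: Image | np.ndarray, cfg: PathConfig | None = None) -> np.ndarray:
    """Random-path Retinex over a single-channel image.

    For every pixel E, ``cfg.n_paths`` random monotone lattice paths are drawn
    from the brightest pixel (the white-patch reference) to E, and the
    thresholded log-ratio chains are averaged.  Deterministic given
    ``cfg.seed``; a uniform image maps to the all-zero log-reflectance.
    """
    cfg = cfg or PathConfig()
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise DomainError("random_path_retinex expects a single-channel image")
    rng = np.random.default_rng(cfg.seed)
    logs = np.log(arr + DEFAULT_EPSILON)
    start = np.unravel_index(int(np.argmax(arr)), arr.shape)
    out = np.zeros_like(arr)
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            if (r, c) == start:
                continue
            acc = 0.0
            for _ in range(cfg.n_paths):
                rr, cc = _staircase_path(start, (r, c), rng, cfg.path_length)
                d = np.diff(logs[rr, cc])
                acc += _threshold_log_steps(d, cfg.threshold_T, cfg.mode).sum()
            out[r, c] = acc / cfg.n_paths
    return out


def conversion_operator(rows: int, cols: int) -> int:
    """Initial spiral offset magnitude, ``2 ** (floor(log2(min(rows, cols))) - 1)``.

    The floor keeps the offset an integer pixel count for non-power-of-two
    image sizes.
    """
    if rows < 2 or cols < 2:
        raise DomainError(f"image dimensions must be >= 2, got {rows}×{cols}")
    return 2 ** (int(math.floor(math.log2(min(rows, cols)))) - 1)


def spiral_offsets(
    rows: int, cols: int, stop_threshold: float = 1.0
) -> list[tuple[int, int]]:
    """(row, col) offset sequence of the spiral comparison.

    Starts at magnitude :func:`conversion_operator`, rotating 90° clockwise
    and halving after each comparison, until the magnitude drops below
    ``stop_threshold``.
    """
    mag = float(conversion_operator(rows, cols))
    # 90° clockwise in (row-down, col-right) coordinates: (dr, dc) -> (dc, -dr)
    direction = (1, 0)
    offsets: list[tuple[int, int]] = []
    while mag >= stop_threshold:
        offsets.append((int(round(mag * direction[0])), int(round(mag * direction[1]))))
        direction = (direction[1], -direction[0])
        mag /= 2.0
    return offsets


def _compare_step(
    r: np.ndarray, l: np.ndarray, offset: tuple[int, int], log_max: float
) -> np.ndarray:
    """One proportion/product/reset/average sweep against a shifted copy.

    The candidate estimate propagates the shifted pixel's lightness through
    the brightness ratio of the compared pair (product step in the log
    domain), is clamped to the white reference (reset), and averaged with the
    previous estimate.
    """
    shift_r = np.roll(r, offset, axis=(0, 1))
    shift_l = np.roll(l, offset, axis=(0, 1))
    candidate = shift_r + (l - shift_l)
    np.minimum(candidate, log_max, out=candidate)
    return 0.5 * (r + candidate)


def frankle_mccann(img: Image | np.ndarray, cfg: SpiralConfig | None = None) -> np.ndarray:
    """Frankle-McCann spiral-path Retinex on a single-channel image.

    The estimate is initialized to the log-brightness image and refined by
    comparisons along a spiral of offsets: starting at the conversion-operator
    magnitude, each step rotates the offset 90° clockwise and halves its
    length, stopping below one pixel.  Each comparison runs the
    proportion/product/reset/average cycle with the reset ceiling at the
    image maximum.  Output is log-reflectance relative to that maximum.
    """
    cfg = cfg or SpiralConfig()
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise DomainError("frankle_mccann expects a single-channel image")
    l = safe_log(arr)
    log_max = float(l.max()) if cfg.max_value is None else math.log(cfg.max_value)
    r = np.minimum(l, log_max)  # estimates never start above the reset ceiling
    for offset in spiral_offsets(arr.shape[0], arr.shape[1], cfg.stop_threshold):
        r = _compare_step(r, l, offset, log_max)
    return r - log_max


def _halve(arr: np.ndarray) -> np.ndarray:
    """2×2 block mean (odd trailing row/column trimmed first)."""
    h, w = arr.shape[0] & ~1, arr.shape[1] & ~1
    a = arr[:h, :w]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def _upsample_to(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour 2× duplication, edge-padded/cropped to ``shape``."""
    up = np.repeat(np.repeat(arr, 2, axis=0), 2, axis=1)
    pad_r = max(0, shape[0] - up.shape[0])
    pad_c = max(0, shape[1] - up.shape[1])
    if pad_r or pad_c:
        up = np.pad(up, ((0, pad_r), (0, pad_c)), mode="edge")
    return up[: shape[0], : shape[1]]


_NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)


def mccann99(img: Image | np.ndarray, cfg: PyramidConfig | None = None) -> np.ndarray:
    """McCann99 pyramid Retinex on a single-channel image (both dims >= 4).

    A pyramid is built by 2×2 intensity averaging.  From the coarsest level
    down, the lightness estimate — initialized at the white reference — is
    refined by comparisons against all 8 neighbours in the 3×3 neighbourhood
    (the proportion/product/reset/average cycle, with the reset clamp at the
    image maximum), then duplicated up to the next finer level.  Output is
    log-reflectance relative to the image maximum at the full resolution.
    """
    cfg = cfg or PyramidConfig()
    arr = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise DomainError("mccann99 expects a single-channel image")
    if arr.shape[0] < 4 or arr.shape[1] < 4:
        raise SizeError(f"image must be at least 4×4, got {arr.shape}")
    levels = [arr]
    while min(levels[-1].shape) >= 4 and (cfg.n_levels is None or len(levels) < cfg.n_levels):
        levels.append(_halve(levels[-1]))
    levels.reverse()  # coarsest first
    log_max = float(safe_log(arr).max())
    r = np.full(levels[0].shape, log_max)
    for i, level in enumerate(levels):
        s = safe_log(level)
        for _ in range(cfg.iterations_per_level):
            for offset in _NEIGHBOR_OFFSETS:
                r = _compare_step(r, s, offset, log_max)
        if i + 1 < len(levels):
            r = _upsample_to(r, levels[i + 1].shape)
    return r - log_max


def image_pyramid(arr: np.ndarray, n_levels: int | None = None) -> list[np.ndarray]:
    """Fine-to-coarse 2×2 block-mean pyramid (exposed for inspection/tests)."""
    levels = [np.asarray(arr, dtype=np.float64)]
    while min(levels[-1].shape) >= 4 and (n_levels is None or len(levels) < n_levels):
        levels.append(_halve(levels[-1]))
    return levels
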
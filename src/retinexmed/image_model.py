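"""Core image container, raster I/O, and intensity conventions.

Every enhancement algorithm in this package works on the multiplicative
illumination-reflectance model ``I(x, y) = S(x, y) * R(x, y)``: the observed
intensity is a slowly varying ambient/illumination field ``S`` modulating the
reflectance ``R`` that carries the object (tissue) detail.  This module
defines the observed-image container, lossless integer round-tripping to PNG
and TIFF, and the guarded logarithm that moves images into the log domain
where the multiplicative model becomes additive.

Conventions: row-major arrays, origin at the top-left, 0-based indexing.
Processing happens in floating point; conversion to display integers happens
only when writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, RangeError, ShapeError, SizeError

__all__ = ["Image", "read_image", "write_image", "safe_log", "to_grayscale"]

#: Default guard added inside the logarithm so zero pixels stay finite.
DEFAULT_EPSILON = 1e-6

# ITU-R BT.601 luma weights, used when collapsing RGB to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class Image:
    """A 2-D (grayscale) or H×W×3 (RGB) nonnegative intensity grid.

    Parameters
    ----------
    pixels
        Float array of shape ``(H, W)`` or ``(H, W, 3)``; all values finite
        and >= 0.  Values live either in display units (``[0, 2**bit_depth - 1]``)
        or in unit scale for synthetic reflectance maps — the algorithms only
        ever use ratios, so the scale is not enforced until write time.
    bit_depth
        Declared bits per sample (8 for PNG, 16 for 16-bit TIFF).  Used for
        the PSNR peak and for the write-time range check.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    path: Path | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ShapeError(f"expected 2-D or H×W×3 pixels, got shape {self.pixels.shape}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ShapeError(f"3-D pixel arrays must have 3 channels, got {self.pixels.shape[2]}")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise SizeError(f"image must be at least 2×2, got {self.pixels.shape[:2]}")
        if not np.all(np.isfinite(self.pixels)):
            raise RangeError("image intensities must be finite")
        if np.any(self.pixels < 0):
            raise RangeError("image intensities must be nonnegative")
        if self.bit_depth < 1:
            raise RangeError(f"bit depth must be >= 1, got {self.bit_depth}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def max_value(self) -> float:
        """Largest representable display intensity, ``2**bit_depth - 1``."""
        return float(2**self.bit_depth - 1)


def to_grayscale(img: Image) -> Image:
    """Collapse an RGB image to a single luminance channel (BT.601 weights)."""
    if img.channels == 1:
        return img
    gray = img.pixels @ _LUMA
    return Image(gray, bit_depth=img.bit_depth, path=img.path)


def _slice_from_volume(data: np.ndarray) -> np.ndarray:
    """Middle axial slice of a 3-D volume, passed through for 2-D data."""
    if data.ndim == 3 and data.shape[2] not in (3, 4):
        return data[:, :, data.shape[2] // 2]
    if data.ndim > 3:
        data = np.squeeze(data)
        if data.ndim == 3:
            return data[:, :, data.shape[2] // 2]
    return data


def read_image(path: str | Path, force_gray: bool = False) -> Image:
    """Read a raster image into an :class:`Image`.

    PNG and TIFF are first-class; single-slice DICOM (``.dcm``) and NIfTI
    (``.nii``/``.nii.gz``) are supported read-only, taking the middle slice
    of a volume.  Bit depth is inferred from the stored sample width.

    Parameters
    ----------
    path
        File to read.
    force_gray
        If True, reduce a 3-channel image to BT.601 luminance.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = "".join(path.suffixes).lower()
    try:
        if suffix.endswith(".dcm"):
            import pydicom

            ds = pydicom.dcmread(str(path))
            data = ds.pixel_array.astype(np.float64)
            data = _slice_from_volume(data)
            bit_depth = int(getattr(ds, "BitsStored", 0)) or _infer_bit_depth(ds.pixel_array)
        elif suffix.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
            data = _slice_from_volume(vol)
            data = data - data.min()
            bit_depth = _infer_bit_depth(data)
        else:
            import imageio.v3 as iio

            raw = iio.imread(path)
            bit_depth = _infer_bit_depth(raw)
            data = np.asarray(raw, dtype=np.float64)
            if data.ndim == 3 and data.shape[2] == 4:  # drop alpha
                data = data[:, :, :3]
    except Exception as exc:  # backends raise a zoo of error types
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if data.size == 0:
        raise FormatError(f"zero-area image: {path}")
    img = Image(data, bit_depth=bit_depth, path=path)
    if force_gray:
        img = to_grayscale(img)
    return img


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8 or arr.dtype == np.int8:
        return 8
    if arr.dtype == np.uint16 or arr.dtype == np.int16:
        return 16
    if np.issubdtype(arr.dtype, np.integer):
        return int(arr.dtype.itemsize) * 8
    # float data (NIfTI): declare 16 bits unless it already fits 8-bit range
    return 8 if np.nanmax(arr, initial=0.0) <= 255 else 16


def write_image(img: Image, path: str | Path) -> Path:
    """Write an :class:`Image` to PNG or TIFF, losslessly for integer data.

    Raises :class:`RangeError` when intensities exceed ``2**bit_depth - 1``;
    callers are expected to display-stretch first (see
    :func:`retinexmed.center_surround.linear_stretch`).
    """
    import imageio.v3 as iio

    path = Path(path)
    rounded = np.rint(img.pixels)
    if np.any(rounded > img.max_value):  # rounded: tolerate stretch roundoff ulps
        raise RangeError(
            f"intensities up to {img.pixels.max():g} exceed the "
            f"{img.bit_depth}-bit ceiling {img.max_value:g}; stretch first"
        )
    dtype = np.uint8 if img.bit_depth <= 8 else np.uint16
    data = rounded.astype(dtype)
    iio.imwrite(path, data)
    return path


def safe_log(img: Image | np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Elementwise natural log with an additive guard: ``log(pixels + epsilon)``.

    The guard keeps zero pixels finite; ``epsilon`` must be positive.  Natural
    log is used throughout the package — only differences of logs reach any
    output, so the base cancels after display stretching.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    pixels = img.pixels if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    return np.log(pixels + epsilon)
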
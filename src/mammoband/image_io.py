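"""Reading and writing 8-bit grayscale rasters.

The whole pipeline operates on a single image domain, ``GrayImage``: a 2-D
``numpy.ndarray`` of dtype ``uint8`` with values in [0, 255], 0-based
(row, col) indexing, origin at the top-left.  All thresholds in the
correction algorithm (220 for the defect core, 170 for the streak mask)
assume this 8-bit domain, so deeper inputs are mapped down on load.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

__all__ = ["GrayImage", "as_gray_image", "load_image", "save_image"]

#: Type alias for documentation purposes: a 2-D uint8 array.
GrayImage = np.ndarray

# ITU-R BT.601 luma weights used to collapse RGB input.
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray_image(arr: np.ndarray) -> GrayImage:
    """Validate and coerce *arr* into the GrayImage domain.

    Raises ``ValueError`` if the array is not 2-D, is empty, or holds
    values outside [0, 255].
    """
    a = np.asarray(arr)
    if a.ndim != 2:
        raise ValueError(f"GrayImage must be 2-D, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("GrayImage must have height >= 1 and width >= 1")
    if a.dtype != np.uint8:
        if np.any(a < 0) or np.any(a > 255):
            raise ValueError("GrayImage values must lie in [0, 255]")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)):
                raise ValueError("GrayImage values must be integers")
        a = a.astype(np.uint8)
    return a


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the pipeline specifies half-up for
    # cross-platform reproducibility.
    return np.floor(x + 0.5)


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        return _round_half_up(rgb @ _LUMA)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[..., 0]
    raise ValueError(f"unsupported raster shape {arr.shape} (multi-frame input?)")


def load_image(path: str | os.PathLike, mode: str = "rescale-minmax") -> GrayImage:
    """Load a raster image and normalize it to 8-bit grayscale.

    Parameters
    ----------
    path
        PNG, TIFF, or (with the ``dicom`` extra installed) a single-frame
        monochrome DICOM file.
    mode
        ``"8bit-passthrough"``: the file must already be 8-bit; values are
        taken verbatim.  ``"rescale-minmax"`` (default): deeper integer
        data are mapped linearly so [min, max] spans [0, 255], rounded
        half-up; a constant image (max == min) maps to all zeros.  DICOM
        window/level is *not* applied.

    Raises
    ------
    IOError
        If the file cannot be read.
    ValueError
        For multi-frame input or an unknown *mode*.
    """
    if mode not in ("8bit-passthrough", "rescale-minmax"):
        raise ValueError(f"unknown mode {mode!r}")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        arr = _read_dicom(path)
    else:
        import imageio.v3 as iio

        try:
            arr = iio.imread(path)
        except FileNotFoundError:
            raise
        except Exception as exc:  # imageio raises various backend errors
            raise IOError(f"cannot read image {path}: {exc}") from exc
        if arr.ndim == 3 and arr.shape[2] not in (1, 3, 4):
            raise ValueError(f"multi-frame input not supported: {path}")
    arr = _collapse_channels(arr)

    if arr.dtype == np.uint8 or (arr.max(initial=0) <= 255 and arr.min(initial=0) >= 0):
        return as_gray_image(arr.astype(np.uint8))
    if mode == "8bit-passthrough":
        raise ValueError(f"{path} is not 8-bit; use mode='rescale-minmax'")
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return as_gray_image(np.zeros(arr.shape, dtype=np.uint8))
    scaled = _round_half_up((arr - lo) * (255.0 / (hi - lo)))
    return as_gray_image(np.clip(scaled, 0, 255).astype(np.uint8))


def _read_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise IOError("DICOM support requires pydicom (install the 'dicom' extra)") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"multi-frame DICOM not supported: {path}")
    return arr


def save_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write a GrayImage losslessly (PNG or TIFF, chosen by extension).

    ``load_image(save_image(img))`` round-trips bit-exactly.
    """
    img = as_gray_image(img)
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    import imageio.v3 as iio

    try:
        iio.imwrite(path, img)
    except Exception as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc
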
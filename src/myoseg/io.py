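"""Image, mask and contour I/O.

Conventions shared by the whole package:

* arrays are row-major with origin at the top-left, 0-based ``(row, col)``
  indexing, pixel centers at integer coordinates;
* images are ``float64`` grids linearly rescaled to the canonical ``[0, 255]``
  range at load time (constant images map to all zeros) — every intensity
  parameter elsewhere in the package assumes this range;
* binary masks are ``uint8`` grids with values in {0, 1}, written to disk as
  8-bit PNG with foreground 255.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import EmptyRegionError, InputError

__all__ = [
    "load_image",
    "save_mask",
    "load_mask",
    "contour_from_mask",
    "save_contour_csv",
    "load_contour_csv",
    "save_metrics_json",
]

INTENSITY_RANGE = (0.0, 255.0)


def as_image(values: np.ndarray) -> np.ndarray:
    """Validate an in-memory array as a 2-D image grid (no rescaling)."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InputError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise InputError(f"image too small for segmentation: {arr.shape}; need at least 8x8")
    if not np.all(np.isfinite(arr)):
        raise InputError("image contains non-finite values")
    return arr


def rescale_intensity(arr: np.ndarray) -> np.ndarray:
    """Affinely map an array onto [0, 255]; a constant array maps to zeros."""
    arr = np.asarray(arr, dtype=float)
    lo = float(arr.min())
    hi = float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) * (255.0 / (hi - lo))


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale or RGB image file into a [0, 255] float grid.

    RGB inputs are collapsed to a single channel by averaging the three
    channels.  Raises :class:`InputError` for unreadable or degenerate files.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises many backend-specific types
        raise InputError(f"could not read image {path}: {exc}") from exc
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    if raw.ndim != 2 or raw.size == 0:
        raise InputError(f"unsupported image layout {raw.shape} in {path}")
    if raw.shape[0] < 8 or raw.shape[1] < 8:
        raise InputError(f"image {path} too small: {raw.shape}; need at least 8x8")
    if not np.all(np.isfinite(raw)):
        raise InputError(f"image {path} contains non-finite values")
    return rescale_intensity(raw)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InputError(f"mask must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise InputError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit PNG (foreground 255, background 0)."""
    arr = _validate_mask(mask)
    path = Path(path)
    try:
        iio.imwrite(path, (arr * 255).astype(np.uint8), extension=".png")
    except OSError as exc:
        raise InputError(f"could not write mask to {path}: {exc}") from exc


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back into a {0,1} uint8 grid (threshold at 128)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such mask file: {path}")
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=-1)
    return (raw >= 128).astype(np.uint8)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def contour_from_mask(mask: np.ndarray) -> np.ndarray:
    """Boundary of a mask as an (n, 2) array of (row, col) pixel centers.

    The boundary is the set of foreground pixels 4-adjacent to background,
    where everything outside the image frame counts as background; points are
    returned in deterministic row-major order.
    """
    arr = _validate_mask(mask)
    if arr.sum() == 0:
        raise EmptyRegionError("cannot extract a contour from an empty mask")
    interior = ndimage.binary_erosion(arr.astype(bool), structure=_CROSS, border_value=0)
    boundary = arr.astype(bool) & ~interior
    return np.argwhere(boundary)


def save_contour_csv(points: np.ndarray, path: str | Path) -> None:
    """Write contour points as CSV with header ``row,col``."""
    pts = np.asarray(points)
    np.savetxt(path, pts.reshape(-1, 2), fmt="%.6g", delimiter=",", header="row,col", comments="")


def load_contour_csv(path: str | Path) -> np.ndarray:
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return pts.reshape(-1, 2)


def save_metrics_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
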
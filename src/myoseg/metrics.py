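"""Segmentation evaluation: Dice overlap, misclassification error and
Hausdorff distance between contours.

* DICE = 2|A intersect B| / (|A| + |B|) on foreground masks.
* ME   = 1 - (|B_m intersect B_a| + |F_m intersect F_a|) / (|B_m| + |F_m|),
  the fraction of pixels whose label disagrees with the manual reference.
* HD(A, B) = max(h(A, B), h(B, A)) with h the directed farthest
  nearest-neighbor Euclidean distance, computed between contour point sets
  (pixel centers) extracted with 4-adjacency.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, UndefinedMetricError
from .io import contour_from_mask

__all__ = [
    "MetricsReport",
    "dice",
    "misclassification_error",
    "hausdorff",
    "hausdorff_masks",
    "evaluate_masks",
]


@dataclass(frozen=True)
class MetricsReport:
    dice: float
    me: float
    hd: float

    def to_dict(self) -> dict:
        return asdict(self)


def _as_mask(m, name: str) -> np.ndarray:
    arr = np.asarray(m)
    if not np.isin(arr, (0, 1)).all():
        raise InputError(f"{name} must be a {{0,1}} mask")
    return arr.astype(bool)


def dice(f_manual: np.ndarray, f_auto: np.ndarray) -> float:
    """Dice overlap of two foreground masks (symmetric, in [0, 1])."""
    a = _as_mask(f_manual, "f_manual")
    b = _as_mask(f_auto, "f_auto")
    if a.shape != b.shape:
        raise InputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        raise UndefinedMetricError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / total


def misclassification_error(
    manual_fg: np.ndarray,
    manual_bg: np.ndarray,
    auto_fg: np.ndarray,
    auto_bg: np.ndarray,
) -> float:
    """Fraction of pixels labeled differently from the manual partition."""
    mf = _as_mask(manual_fg, "manual_fg")
    mb = _as_mask(manual_bg, "manual_bg")
    af = _as_mask(auto_fg, "auto_fg")
    ab = _as_mask(auto_bg, "auto_bg")
    for name, (fg, bg) in {"manual": (mf, mb), "auto": (af, ab)}.items():
        if fg.shape != bg.shape or fg.shape != mf.shape:
            raise InputError("all masks must share one shape")
        if not np.array_equal(fg ^ bg, np.ones_like(fg)):
            raise InputError(f"{name} foreground/background do not partition the grid")
    agree = int((mb & ab).sum()) + int((mf & af).sum())
    return 1.0 - agree / mf.size


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Hausdorff distance between two point sets of shape (n, 2)."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise UndefinedMetricError("Hausdorff distance undefined for an empty point set")
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def hausdorff_masks(f_manual: np.ndarray, f_auto: np.ndarray) -> float:
    """Hausdorff distance between the 4-adjacency contours of two masks."""
    return hausdorff(contour_from_mask(f_manual), contour_from_mask(f_auto))


def evaluate_masks(f_auto: np.ndarray, f_manual: np.ndarray) -> MetricsReport:
    """Full report comparing an automatic mask to a manual reference."""
    af = _as_mask(f_auto, "f_auto").astype(np.uint8)
    mf = _as_mask(f_manual, "f_manual").astype(np.uint8)
    return MetricsReport(
        dice=dice(mf, af),
        me=misclassification_error(mf, 1 - mf, af, 1 - af),
        hd=hausdorff_masks(mf, af),
    )
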
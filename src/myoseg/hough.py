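"""Circular Hough transform initialization.

On a short-axis black-blood slice both ventricular contours are nearly
circular, so circle detection gives a fully automatic initialization: edge
pixels vote in a (center_row, center_col, radius) accumulator, the two
strongest concentric peaks are taken as the epicardial (outer) and
endocardial (inner) circles, and each circle is turned into an exact
signed-distance level-set field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import sobel
from skimage.transform import hough_circle

from .errors import InitializationError
from .io import as_image

__all__ = [
    "Circle",
    "CircleInitialization",
    "detect_circles",
    "select_lv_pair",
    "levelset_from_circle",
    "initialize_from_image",
]

DEFAULT_EDGE_QUANTILE = 0.9
DEFAULT_CONCENTRICITY_TOL = 5.0
#: default circle-radius search range as fractions of min(H, W)
DEFAULT_RADIUS_FRACTIONS = (0.05, 0.45)


@dataclass(frozen=True)
class Circle:
    """A detected circle in pixel units, with its accumulator score."""

    center_row: float
    center_col: float
    radius: float
    votes: float = 0.0

    def center_distance(self, other: "Circle") -> float:
        return float(
            np.hypot(self.center_row - other.center_row, self.center_col - other.center_col)
        )


@dataclass(frozen=True)
class CircleInitialization:
    """The concentric pair used to initialize both level sets."""

    epicardial: Circle
    endocardial: Circle

    def __post_init__(self):
        if not self.endocardial.radius < self.epicardial.radius:
            raise InitializationError(
                "endocardial radius must be smaller than epicardial radius "
                f"({self.endocardial.radius} vs {self.epicardial.radius})"
            )

    def shifted(self, drow: float, dcol: float) -> "CircleInitialization":
        """Same pair with both centers displaced (robustness experiments)."""

        def mv(c: Circle) -> Circle:
            return Circle(c.center_row + drow, c.center_col + dcol, c.radius, c.votes)

        return CircleInitialization(mv(self.epicardial), mv(self.endocardial))


def _edge_points(image: np.ndarray, edge_quantile: float) -> np.ndarray:
    """Feature points: pixels in the top (1-q) fraction of gradient magnitude."""
    grad = sobel(image)
    if grad.max() <= 0:
        return np.zeros_like(image, dtype=bool)
    thr = np.quantile(grad, edge_quantile)
    return grad > thr  # strict: a constant image yields no feature points


def detect_circles(
    image: np.ndarray,
    radius_min: float | None = None,
    radius_max: float | None = None,
    n_peaks: int = 8,
    edge_quantile: float = DEFAULT_EDGE_QUANTILE,
) -> list[Circle]:
    """Detect up to ``n_peaks`` circles, strongest (most votes) first.

    Edge pixels vote for every (center, radius) combination consistent with
    them at integer radius steps; accumulator scores are normalized by
    perimeter so radii are comparable.  Peaks are extracted greedily with
    non-maximum suppression: a candidate within radius/2 of an accepted peak
    in both center and radius is suppressed, so one circle cannot occupy
    several slots while still allowing concentric circles of distinct radius.

    A blank image (no gradient anywhere) returns an empty list.
    """
    image = as_image(image)
    h, w = image.shape
    if radius_min is None:
        radius_min = DEFAULT_RADIUS_FRACTIONS[0] * min(h, w)
    if radius_max is None:
        radius_max = DEFAULT_RADIUS_FRACTIONS[1] * min(h, w)
    if not 0 < radius_min < radius_max < min(h, w) / 2:
        raise ValueError(
            f"invalid radius range ({radius_min}, {radius_max}) for image of shape {image.shape}"
        )
    if n_peaks < 1:
        raise ValueError(f"n_peaks must be >= 1, got {n_peaks}")

    edges = _edge_points(image, edge_quantile)
    if not edges.any():
        return []

    radii = np.arange(max(1, int(round(radius_min))), int(round(radius_max)) + 1)
    acc = hough_circle(edges, radii, normalize=True)  # (n_radii, H, W)

    def refine(ri: int, r: int, c: int) -> Circle:
        """Vote-weighted centroid around a peak (sub-bin center/radius).

        A ring thicker than one pixel saturates the normalized accumulator
        over several adjacent radii; the centroid of the near-peak votes
        recovers the fractional radius instead of an arbitrary tied bin.
        """
        peak = acc[ri, r, c]
        ri0, ri1 = max(0, ri - 3), min(acc.shape[0], ri + 4)
        r0, r1 = max(0, r - 2), min(acc.shape[1], r + 3)
        c0, c1 = max(0, c - 2), min(acc.shape[2], c + 3)
        block = acc[ri0:ri1, r0:r1, c0:c1]
        w = np.where(block >= 0.9 * peak, block, 0.0)
        rig, rg, cg = np.meshgrid(
            radii[ri0:ri1], np.arange(r0, r1), np.arange(c0, c1), indexing="ij"
        )
        total = w.sum()
        return Circle(
            float((w * rg).sum() / total),
            float((w * cg).sum() / total),
            float((w * rig).sum() / total),
            float(peak),
        )

    # Greedy 3-D non-maximum suppression over the top accumulator entries.
    n_top = min(acc.size, 4000)
    flat_idx = np.argpartition(acc.ravel(), -n_top)[-n_top:]
    order = flat_idx[np.argsort(acc.ravel()[flat_idx])[::-1]]
    accepted: list[Circle] = []
    for idx in order:
        ri, r, c = np.unravel_index(idx, acc.shape)
        votes = float(acc[ri, r, c])
        if votes <= 0:
            break
        cand = refine(int(ri), int(r), int(c))
        suppressed = False
        for kept in accepted:
            # Near-duplicate peaks of one circle share the center (within
            # radius/2) and sit a few radius steps apart; concentric circles
            # share the center but differ strongly in radius, so the radius
            # window must stay tight or the inner circle would be suppressed.
            if (
                cand.center_distance(kept) <= kept.radius / 2.0
                and abs(cand.radius - kept.radius) <= max(2.0, kept.radius / 8.0)
            ):
                suppressed = True
                break
        if not suppressed:
            accepted.append(cand)
            if len(accepted) >= n_peaks:
                break
    return accepted


def select_lv_pair(
    circles: list[Circle], concentricity_tol: float = DEFAULT_CONCENTRICITY_TOL
) -> CircleInitialization:
    """Pair the detected circles into (epicardial, endocardial).

    The epicardial circle is the strongest detection; the endocardial circle
    is the strongest remaining circle with a smaller radius whose center lies
    within ``concentricity_tol`` pixels of the epicardial center.  Raises
    :class:`InitializationError` when no concentric inner circle exists (the
    known failure mode on images with bright fat/muscle near the heart).
    """
    if len(circles) < 2:
        raise InitializationError(f"need at least 2 circles to pair, got {len(circles)}")
    ranked = sorted(circles, key=lambda c: c.votes, reverse=True)
    epi = ranked[0]
    for cand in ranked[1:]:
        if cand.radius < epi.radius and cand.center_distance(epi) <= concentricity_tol:
            return CircleInitialization(epicardial=epi, endocardial=cand)
    raise InitializationError(
        "no endocardial candidate: no smaller circle concentric with the "
        f"strongest detection (tol {concentricity_tol} px)"
    )


def levelset_from_circle(circle: Circle, shape: tuple[int, int]) -> np.ndarray:
    """Exact signed distance to a circle: phi = radius - dist(z, center).

    Positive inside, negative outside, zero on the circle.
    """
    h, w = shape
    if circle.radius <= 0:
        raise ValueError(f"circle radius must be > 0, got {circle.radius}")
    if not (0 <= circle.center_row < h and 0 <= circle.center_col < w):
        raise ValueError(f"circle center {circle} outside image of shape {shape}")
    rr, cc = np.ogrid[:h, :w]
    dist = np.sqrt((rr - circle.center_row) ** 2 + (cc - circle.center_col) ** 2)
    return circle.radius - dist


def initialize_from_image(
    image: np.ndarray,
    radius_min: float | None = None,
    radius_max: float | None = None,
    n_peaks: int = 8,
    edge_quantile: float = DEFAULT_EDGE_QUANTILE,
    concentricity_tol: float = DEFAULT_CONCENTRICITY_TOL,
) -> tuple[CircleInitialization, np.ndarray, np.ndarray]:
    """Full automatic initialization: (pair, phi_endo, phi_epi)."""
    circles = detect_circles(
        image,
        radius_min=radius_min,
        radius_max=radius_max,
        n_peaks=n_peaks,
        edge_quantile=edge_quantile,
    )
    if not circles:
        raise InitializationError("no circles detected (no edge features in image)")
    pair = select_lv_pair(circles, concentricity_tol=concentricity_tol)
    shape = np.asarray(image).shape
    return (
        pair,
        levelset_from_circle(pair.endocardial, shape),
        levelset_from_circle(pair.epicardial, shape),
    )
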
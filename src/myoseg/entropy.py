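"""Histogram density estimates and region entropies.

The homogeneity of an image region is quantified by the Shannon entropy of
its intensity histogram, E = -sum_b p_b log p_b (natural log, nats).  A
homogeneous region concentrates its mass in few bins and has low entropy.
During curve evolution the entropies of the interior and exterior regions
serve as adaptive weights on the two fitting terms: the side that is *less*
homogeneous receives the larger weight, so its misfit dominates the energy
until the homogeneity of the two sides balances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContourCollapseError, EmptyRegionError

__all__ = [
    "DensityEstimate",
    "estimate_density",
    "histogram_entropy",
    "region_entropy",
    "entropy_weights",
]

DEFAULT_N_BINS = 32
DEFAULT_RANGE = (0.0, 255.0)
DEFAULT_WEIGHT_FLOOR = 0.05


@dataclass(frozen=True)
class DensityEstimate:
    """Normalized equal-width histogram over a fixed intensity range."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def entropy(self) -> float:
        return histogram_entropy(self.probabilities)


def estimate_density(
    samples: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    intensity_range: tuple[float, float] = DEFAULT_RANGE,
) -> DensityEstimate:
    """Equal-width histogram density of a sample of intensities.

    Samples outside ``intensity_range`` are clipped into the end bins; the
    returned probabilities sum to 1.  Raises :class:`EmptyRegionError` for an
    empty sample.
    """
    lo, hi = float(intensity_range[0]), float(intensity_range[1])
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if not hi > lo:
        raise ValueError(f"invalid intensity range ({lo}, {hi})")
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size == 0:
        raise EmptyRegionError("cannot estimate a density from zero samples")
    counts, edges = np.histogram(np.clip(arr, lo, hi), bins=n_bins, range=(lo, hi))
    return DensityEstimate(bin_edges=edges, probabilities=counts / counts.sum())


def histogram_entropy(probabilities: np.ndarray) -> float:
    """-sum p log p in nats over the strictly positive entries."""
    p = np.asarray(probabilities, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log(p)).sum())


def region_entropy(
    image: np.ndarray,
    region: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    intensity_range: tuple[float, float] = DEFAULT_RANGE,
) -> float:
    """Entropy of the intensity histogram restricted to ``region`` pixels.

    ``region`` is a boolean/{0,1} mask of the same shape as ``image``.  A
    constant region has entropy 0 (all mass in one bin).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(region).astype(bool)
    if mask.shape != image.shape:
        raise ValueError(f"region shape {mask.shape} != image shape {image.shape}")
    samples = image[mask]
    if samples.size == 0:
        raise EmptyRegionError("region mask selects no pixels")
    return estimate_density(samples, n_bins=n_bins, intensity_range=intensity_range).entropy()


def entropy_weights(
    image: np.ndarray,
    phi: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    weight_floor: float = DEFAULT_WEIGHT_FLOOR,
    intensity_range: tuple[float, float] = DEFAULT_RANGE,
) -> tuple[float, float]:
    """Adaptive fitting weights (E_in, E_out) for a level-set field.

    E_in is the entropy of the interior {phi > 0}, E_out of the exterior
    {phi <= 0}; both are floored at ``weight_floor`` so a perfectly
    homogeneous side never zeroes out its fitting term and freezes the
    evolution.  Raises :class:`ContourCollapseError` when one side is empty.
    """
    phi = np.asarray(phi, dtype=float)
    inside = phi > 0
    if not inside.any() or inside.all():
        raise ContourCollapseError("level-set field is one-sided: the contour has vanished")
    e_in = region_entropy(image, inside, n_bins=n_bins, intensity_range=intensity_range)
    e_out = region_entropy(image, ~inside, n_bins=n_bins, intensity_range=intensity_range)
    return max(e_in, weight_floor), max(e_out, weight_floor)
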
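"""Synthetic cardiac phantoms and simple test images with ground truth.

``make_lv_phantom`` emulates a short-axis black-blood slice: a dark blood
pool (double inversion recovery suppresses the blood signal) surrounded by a
bright myocardial annulus inside a mid-gray background, optionally corrupted
by a multiplicative linear bias field (coil inhomogeneity surrogate),
additive Gaussian noise and bright distractor blobs standing in for
peri-cardiac fat and chest-wall muscle — the structures known to break both
global region statistics and Hough initialization.

Ground-truth masks always follow the noiseless analytic geometry, so metric
values against them isolate the segmentation error from the corruption.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .hough import Circle

__all__ = [
    "PhantomSpec",
    "make_lv_phantom",
    "make_circle_image",
    "make_bimodal_image",
    "disk_mask",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and corruption settings of an LV phantom.

    Default contrast follows the black-blood appearance on the canonical
    [0, 255] scale: dark blood pool (30), bright myocardium (150), mid-gray
    surroundings (80), brighter distractors (200).  Defaults describe the
    clean phantom; corruption (bias, noise, distractors) is opt-in.
    """

    shape: tuple[int, int] = (128, 128)
    center: tuple[float, float] = (64.0, 64.0)
    r_endo: float = 18.0
    r_epi: float = 30.0
    intensity_blood: float = 30.0
    intensity_myo: float = 150.0
    intensity_bg: float = 80.0
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    n_distractors: int = 0
    distractor_intensity: float = 200.0
    distractor_radius: tuple[float, float] = (4.0, 8.0)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.r_endo < self.r_epi < min(self.shape) / 2:
            raise ValueError(
                f"need 0 < r_endo < r_epi < min(shape)/2, got "
                f"r_endo={self.r_endo}, r_epi={self.r_epi}, shape={self.shape}"
            )
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError(f"bias_amplitude must be in [0, 1), got {self.bias_amplitude}")
        if self.noise_sigma < 0 or self.n_distractors < 0:
            raise ValueError("noise_sigma and n_distractors must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius**2).astype(np.uint8)


def _place_distractors(clean: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Draw bright blobs in the background, never overlapping the epicardial disk."""
    h, w = spec.shape
    placed = 0
    attempts = 0
    r_lo, r_hi = spec.distractor_radius
    while placed < spec.n_distractors and attempts < 200 * max(1, spec.n_distractors):
        attempts += 1
        rad = rng.uniform(r_lo, r_hi)
        r0 = rng.uniform(rad, h - 1 - rad)
        c0 = rng.uniform(rad, w - 1 - rad)
        sep = np.hypot(r0 - spec.center[0], c0 - spec.center[1])
        if sep <= spec.r_epi + rad + 2.0:  # keep clear of the epicardial disk
            continue
        blob = disk_mask(spec.shape, (r0, c0), rad).astype(bool)
        clean[blob] = spec.distractor_intensity
        placed += 1


def make_lv_phantom(
    spec: PhantomSpec = PhantomSpec(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build (image, endo_mask, epi_mask, myo_mask) from a spec.

    Construction order: paint constant regions and distractors; multiply by
    the linear column-wise bias field spanning [1-a, 1+a]; add Gaussian
    noise; clip to [0, 255].  The masks are the analytic disks (myocardium =
    epicardial minus endocardial) and never depend on the corruption.
    """
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    endo = disk_mask(spec.shape, spec.center, spec.r_endo)
    epi = disk_mask(spec.shape, spec.center, spec.r_epi)
    myo = (epi & ~endo).astype(np.uint8)

    clean = np.full(spec.shape, spec.intensity_bg, dtype=float)
    clean[myo.astype(bool)] = spec.intensity_myo
    clean[endo.astype(bool)] = spec.intensity_blood
    if spec.n_distractors:
        _place_distractors(clean, spec, rng)

    image = clean
    if spec.bias_amplitude > 0:
        cols = np.linspace(
            1.0 - spec.bias_amplitude, 1.0 + spec.bias_amplitude, w
        )
        image = image * cols[np.newaxis, :]
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return np.clip(image, 0.0, 255.0), endo, epi, myo


def make_circle_image(
    shape: tuple[int, int],
    circles: list[Circle],
    thickness: float = 2.0,
    fg: float = 255.0,
    bg: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Annular rings on a constant background (Hough-transform fixtures).

    Ring j is the set {| dist(z, center_j) - radius_j | <= thickness/2}.
    Deterministic; ``seed`` is accepted for interface uniformity.
    """
    del seed
    h, w = shape
    image = np.full(shape, bg, dtype=float)
    rr, cc = np.mgrid[:h, :w]
    for circ in circles:
        dist = np.hypot(rr - circ.center_row, cc - circ.center_col)
        image[np.abs(dist - circ.radius) <= thickness / 2.0] = fg
    return image


def make_bimodal_image(
    shape: tuple[int, int],
    object_mask: np.ndarray,
    mu_fg: float = 160.0,
    mu_bg: float = 60.0,
    sigma: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """High-contrast two-region image with Gaussian intensities per region."""
    mask = np.asarray(object_mask).astype(bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"object_mask shape {mask.shape} != {shape}")
    rng = np.random.default_rng(seed)
    image = np.where(mask, mu_fg, mu_bg).astype(float)
    if sigma > 0:
        image = image + rng.normal(0.0, sigma, size=tuple(shape))
    return np.clip(image, 0.0, 255.0)
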
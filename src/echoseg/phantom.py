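"""Synthetic ultrasound phantom generation.

Clinical breast ultrasound is characterised by three properties that make
lesion segmentation hard: heavy speckle noise, low lesion/background
contrast, and smooth intensity nonuniformity from beam attenuation and
time-gain compensation.  This module produces 2-D grayscale phantoms with
exactly known lesion masks that reproduce those three properties, so the
whole preprocess/train/evaluate pipeline can be exercised and validated
without clinical data.

Model per phantom:

    image = clip( bias_field * (background + lesion_signal) * (1 + sigma * n), 0, 1 )

where ``n`` is i.i.d. standard Gaussian (first-order multiplicative speckle
surrogate), the bias field is a broad Gaussian bump normalised to mean 1,
and each lesion is a rotated ellipse whose radius is perturbed by a few
random Fourier harmonics, giving irregular but exactly rasterised contours.
Lesions are hypoechoic: darker than background by ``contrast``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["PhantomConfig", "SegmentationPair", "generate_phantom", "generate_dataset"]

_BACKGROUND_LEVEL = 0.5
_BORDER_MARGIN = 2  # pixels kept lesion-free at every image edge


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic phantom.

    Defaults put the generator in the low-contrast, high-speckle regime:
    a 0.15 intensity gap is well below the per-pixel speckle standard
    deviation, so plain thresholding fails while a trained network does not.
    """

    height: int = 64
    width: int = 64
    lesion_count: int = 1
    lesion_area_fraction: float = 0.1
    contrast: float = 0.15
    speckle_sigma: float = 0.3
    bias_field_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise ConfigError(
                f"height/width must be >= 16, got {self.height}x{self.width}"
            )
        if self.lesion_count < 0:
            raise ConfigError(f"lesion_count must be >= 0, got {self.lesion_count}")
        if not 0.0 < self.lesion_area_fraction < 1.0:
            raise ConfigError(
                "lesion_area_fraction must be in (0, 1), "
                f"got {self.lesion_area_fraction}"
            )
        if not 0.0 < self.contrast <= 1.0:
            raise ConfigError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.speckle_sigma < 0.0:
            raise ConfigError(
                f"speckle_sigma must be >= 0, got {self.speckle_sigma}"
            )
        if self.bias_field_amplitude < 0.0:
            raise ConfigError(
                "bias_field_amplitude must be >= 0, "
                f"got {self.bias_field_amplitude}"
            )


@dataclass
class SegmentationPair:
    """A grayscale image in [0, 1] with its binary lesion mask."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must contain only {0, 1}")
        self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.image.shape


def _lesion_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Rasterise one perturbed-ellipse lesion that clears the border margin."""
    h, w = cfg.height, cfg.width
    target_area = cfg.lesion_area_fraction * h * w
    r0 = np.sqrt(target_area / np.pi)

    # Radial Fourier perturbation, 3-5 harmonics of modest amplitude.
    n_harm = int(rng.integers(3, 6))
    orders = np.arange(2, 2 + n_harm)
    amps = rng.uniform(0.02, 0.08, size=n_harm)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harm)

    aspect = rng.uniform(0.6, 1.0)          # ellipse axis ratio
    theta0 = rng.uniform(0.0, np.pi)        # orientation
    a_ax = r0 / np.sqrt(aspect)
    b_ax = r0 * np.sqrt(aspect)

    r_max = max(a_ax, b_ax) * (1.0 + amps.sum())
    # Shrink draws whose worst-case radius cannot clear the border margin;
    # large area fractions then come out slightly below target rather than
    # failing outright.
    allowed = 0.5 * min(h, w) - _BORDER_MARGIN - 1.0
    if allowed < 3.0:
        raise ConfigError(
            f"image {h}x{w} is too small to place a border-free lesion"
        )
    if r_max > allowed:
        scale = allowed / r_max
        a_ax *= scale
        b_ax *= scale
        r_max = allowed
    margin = r_max + _BORDER_MARGIN
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)

    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    # rotate into the ellipse frame and normalise the axes
    ur = (np.cos(theta0) * dx + np.sin(theta0) * dy) / a_ax
    vr = (-np.sin(theta0) * dx + np.cos(theta0) * dy) / b_ax
    rho = np.hypot(ur, vr)
    ang = np.arctan2(vr, ur)
    boundary = 1.0 + np.sum(
        amps[:, None, None]
        * np.cos(orders[:, None, None] * ang[None] + phases[:, None, None]),
        axis=0,
    )
    return (rho <= boundary).astype(np.uint8)


def _bias_field(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative nonuniformity, normalised to mean 1."""
    h, w = cfg.height, cfg.width
    if cfg.bias_field_amplitude == 0.0:
        return np.ones((h, w))
    cy = rng.uniform(0.0, h)
    cx = rng.uniform(0.0, w)
    sig = 0.75 * max(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sig**2))
    bump -= bump.mean()
    peak = np.abs(bump).max()
    if peak > 0:
        bump /= peak
    return 1.0 + cfg.bias_field_amplitude * bump


def generate_phantom(config: PhantomConfig) -> SegmentationPair:
    """Generate one phantom image/mask pair, deterministically from the config.

    The same config (including its seed) always yields bit-identical arrays.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    mask = np.zeros((h, w), dtype=np.uint8)
    for _ in range(config.lesion_count):
        mask |= _lesion_mask(config, rng)

    clean = np.full((h, w), _BACKGROUND_LEVEL)
    clean -= config.contrast * mask  # hypoechoic lesions

    bias = _bias_field(config, rng)
    speckle = 1.0 + config.speckle_sigma * rng.standard_normal((h, w))
    image = np.clip(bias * clean * speckle, 0.0, 1.0)
    return SegmentationPair(image=image, mask=mask)


def generate_dataset(config: PhantomConfig, n: int, seed: int) -> list[SegmentationPair]:
    """Generate ``n`` independent phantoms from per-item seeds derived from ``seed``.

    Item ``i`` equals ``generate_phantom`` called with the i-th spawned child
    seed, so any prefix of the dataset is reproducible from the top-level seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    child_seeds = derive_seeds(seed, n)
    pairs = []
    for s in child_seeds:
        cfg_i = PhantomConfig(
            height=config.height,
            width=config.width,
            lesion_count=config.lesion_count,
            lesion_area_fraction=config.lesion_area_fraction,
            contrast=config.contrast,
            speckle_sigma=config.speckle_sigma,
            bias_field_amplitude=config.bias_field_amplitude,
            seed=int(s),
        )
        pairs.append(generate_phantom(cfg_i))
    return pairs


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds from a top-level seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]
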
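"""Deterministic synthetic leaf-image generator.

Classes differ controllably along three axes — base color, vein texture
(frequency/orientation of an additive sinusoid), and contour shape
(super-ellipse elongation plus margin serration) — so fixtures can dial
in either easy color-separable sets or "look-alike" sets whose classes
share color and differ only in texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .imaging import LabelledDataset, load_dataset


@dataclass
class LeafClassSpec:
    """Generative recipe for one leaf class."""

    class_name: str
    base_color: tuple[int, int, int] = (60, 140, 70)
    color_jitter: float = 8.0
    blob_elongation: float = 1.6
    margin_serration: int = 0
    vein_frequency: float = 8.0  # cycles per image width
    vein_orientation: float = 45.0  # degrees in [0, 180)
    vein_amplitude: float = 30.0  # intensity units
    serration_depth: float = 0.08  # fraction of radius
    background_color: tuple[int, int, int] = (235, 235, 225)

    def __post_init__(self) -> None:
        self.base_color = tuple(self.base_color)
        self.background_color = tuple(self.background_color)
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color components must lie in [0, 255]")
        if self.vein_frequency <= 0:
            raise ValueError("vein_frequency must be positive")
        if self.blob_elongation <= 0:
            raise ValueError("blob_elongation must be positive")
        if self.margin_serration < 0:
            raise ValueError("margin_serration must be >= 0")


@dataclass
class SyntheticDatasetSpec:
    class_specs: list[LeafClassSpec]
    images_per_class: int = 20
    image_size: tuple[int, int] = (128, 128)
    seed: int = 0
    imbalance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.class_specs) < 2:
            raise ValueError("need at least 2 classes")
        if self.images_per_class < 1:
            raise ValueError("images_per_class must be >= 1")


def _leaf_mask(size: tuple[int, int], spec: LeafClassSpec, scale: float) -> np.ndarray:
    """Boolean silhouette: super-ellipse with sinusoidal margin serration."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    y = (yy - cy) / (h / 2.0)
    x = (xx - cx) / (w / 2.0)
    # semi-axes: minor axis shrinks with elongation
    a = 0.80 * scale / np.sqrt(spec.blob_elongation)
    b = 0.80 * scale * np.sqrt(spec.blob_elongation)
    phi = np.arctan2(y, x)
    # super-ellipse exponent 2.5 gives a broad leaf-like blob
    rho = (np.abs(x / a) ** 2.5 + np.abs(y / b) ** 2.5) ** (1 / 2.5)
    margin = 1.0
    if spec.margin_serration > 0:
        margin = 1.0 + spec.serration_depth * np.sin(spec.margin_serration * phi)
    return rho <= margin


def generate_leaf_image(spec: LeafClassSpec, size: tuple[int, int], seed: int) -> np.ndarray:
    """Render one seeded leaf image (h x w x 3 uint8).

    The silhouette is filled with ``base_color`` shifted by a per-image
    color jitter, modulated by an additive sinusoidal vein texture along
    ``vein_orientation`` at ``vein_frequency`` cycles per image width,
    plus per-pixel jitter noise.  Identical (spec, size, seed) inputs
    are bit-identical.
    """
    h, w = size
    if h < 32 or w < 32:
        raise ValueError(f"image size must be at least 32x32, got {size}")
    rng = np.random.default_rng(seed)
    scale = rng.uniform(0.75, 1.0)  # intra-class size variation
    shift = rng.normal(0.0, spec.color_jitter, size=3) if spec.color_jitter > 0 else np.zeros(3)

    mask = _leaf_mask(size, spec, scale)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_color, dtype=np.float64)

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(spec.vein_orientation)
    axis = xx * np.cos(theta) + yy * np.sin(theta)
    veins = spec.vein_amplitude * np.sin(2.0 * np.pi * spec.vein_frequency * axis / w)

    foreground = np.asarray(spec.base_color, dtype=np.float64) + shift
    if spec.color_jitter > 0:
        pixel_noise = rng.normal(0.0, spec.color_jitter / 2.0, size=(h, w, 3))
    else:
        pixel_noise = 0.0
    fg = foreground[None, None, :] + veins[..., None] + pixel_noise
    img[mask] = np.broadcast_to(fg, (h, w, 3))[mask]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticDatasetSpec, out_dir: str | Path) -> LabelledDataset:
    """Write the dataset as class-per-folder PNGs and return its index.

    Each image draws from an independent stream seeded by
    (dataset seed, class index, image index), so per-class outputs do
    not depend on generation order.  ``spec.imbalance`` maps class name
    -> reduced image count, for oversampling tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for class_idx, cls in enumerate(sorted(spec.class_specs, key=lambda c: c.class_name)):
        n = spec.imbalance.get(cls.class_name, spec.images_per_class)
        class_dir = out_dir / cls.class_name
        class_dir.mkdir(exist_ok=True)
        for img_idx in range(n):
            seed = np.random.SeedSequence([spec.seed, class_idx, img_idx]).generate_state(1)[0]
            img = generate_leaf_image(cls, spec.image_size, int(seed))
            Image.fromarray(img).save(class_dir / f"{cls.class_name}_{img_idx:03d}.png")
    return load_dataset(out_dir)


# ---------------------------------------------------------------------------
# Fixture recipes used across the test-suite and acceptance runs.

_HUES = [
    (200, 60, 60),
    (60, 170, 70),
    (60, 90, 200),
    (210, 190, 60),
    (160, 60, 190),
    (60, 190, 185),
    (230, 130, 40),
]


def make_separable_specs(k: int = 3, jitter: float = 6.0) -> list[LeafClassSpec]:
    """Classes with disjoint hues: separable on color histograms alone."""
    if k > len(_HUES):
        raise ValueError(f"at most {len(_HUES)} color-separable classes supported")
    return [
        LeafClassSpec(
            class_name=f"species_{chr(ord('a') + i)}",
            base_color=_HUES[i],
            color_jitter=jitter,
            blob_elongation=1.2 + 0.3 * i,
            margin_serration=3 * i,
            vein_frequency=5.0 + 3.0 * i,
            vein_orientation=(30.0 * i) % 180.0,
        )
        for i in range(k)
    ]


def make_lookalike_specs(jitter: float = 4.0) -> list[LeafClassSpec]:
    """Color-matched pair differing only in vein texture, plus one
    distinct-color outgroup — the high inter-class-similarity regime."""
    shared = (70, 150, 80)
    return [
        LeafClassSpec(
            class_name="twin_fine",
            base_color=shared,
            color_jitter=jitter,
            blob_elongation=1.5,
            margin_serration=0,
            vein_frequency=16.0,
            vein_orientation=30.0,
        ),
        LeafClassSpec(
            class_name="twin_coarse",
            base_color=shared,
            color_jitter=jitter,
            blob_elongation=1.5,
            margin_serration=9,
            vein_frequency=4.0,
            vein_orientation=120.0,
        ),
        LeafClassSpec(
            class_name="outgroup",
            base_color=(200, 80, 50),
            color_jitter=jitter,
            blob_elongation=0.8,
            margin_serration=5,
            vein_frequency=8.0,
            vein_orientation=75.0,
        ),
    ]
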
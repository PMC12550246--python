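"""Robustness harness: noise, rescaling, rotation and occlusion applied
to evaluation images only, with trained models re-scored on the
perturbed inputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd

from .imaging import resize_bilinear

ROTATION_ANGLES = (90, 180, 270)


@dataclass
class StressCondition:
    kind: str  # noise | scale | rotation | occlusion
    parameter: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind == "rotation" and int(self.parameter) not in ROTATION_ANGLES:
            raise ValueError(f"rotation angle must be one of {ROTATION_ANGLES}")
        if self.kind == "occlusion" and not (0 <= self.parameter < 1):
            raise ValueError("occlusion fraction must lie in [0, 1)")
        if self.kind == "noise" and self.parameter < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.kind == "scale" and self.parameter < 1:
            raise ValueError("scale target must be >= 1")
        if self.kind not in ("noise", "scale", "rotation", "occlusion"):
            raise ValueError(f"unknown stress kind {self.kind!r}")

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.parameter:g}"


def apply_noise(img: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Additive seeded zero-mean Gaussian noise per pixel per channel,
    rounded and clipped to [0, 255]; sigma 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    img = np.asarray(img)
    if sigma == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noisy = img.astype(np.float64) + rng.normal(0.0, sigma, size=img.shape)
    return np.clip(np.round(noisy), 0, 255).astype(np.uint8)


def apply_scale(img: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize to target x target; feature extraction resizes the
    result back to the working resolution, so downscaling models
    information loss."""
    return resize_bilinear(img, int(target), int(target))


def apply_rotation(img: np.ndarray, angle: int) -> np.ndarray:
    """Exact lossless grid rotation, clockwise, angle in {90, 180, 270}."""
    if int(angle) not in ROTATION_ANGLES:
        raise ValueError(f"angle must be one of {ROTATION_ANGLES}, got {angle}")
    return np.ascontiguousarray(np.rot90(np.asarray(img), k=-int(angle) // 90, axes=(0, 1)))


def apply_occlusion(
    img: np.ndarray, fraction: float, seed: int = 0, fill: tuple[int, int, int] = (0, 0, 0)
) -> np.ndarray:
    """Blank a seeded axis-aligned rectangle covering ~fraction of the area.

    The rectangle is near-square (side ~ sqrt(fraction) of each axis,
    rounding the width so the covered area lands within one row of the
    target); fraction 0 is the identity.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    img = np.asarray(img).copy()
    if fraction == 0:
        return img
    h, w = img.shape[:2]
    area = fraction * h * w
    rh = max(1, min(h, round(np.sqrt(area * h / w))))
    rw = max(1, min(w, round(area / rh)))
    rng = np.random.default_rng(seed)
    r0 = int(rng.integers(0, h - rh + 1))
    c0 = int(rng.integers(0, w - rw + 1))
    img[r0 : r0 + rh, c0 : c0 + rw] = np.asarray(fill, dtype=img.dtype) if img.ndim == 3 else fill[0]
    return img


def apply_condition(img: np.ndarray, cond: StressCondition) -> np.ndarray:
    if cond.kind == "noise":
        return apply_noise(img, cond.parameter, cond.seed)
    if cond.kind == "scale":
        return apply_scale(img, int(cond.parameter))
    if cond.kind == "rotation":
        return apply_rotation(img, int(cond.parameter))
    return apply_occlusion(img, cond.parameter, cond.seed)


def stress_suite(
    test_images: Sequence[np.ndarray],
    test_labels: np.ndarray,
    models: dict[str, Any],
    featurize: Callable[[np.ndarray], np.ndarray],
    conditions: Sequence[StressCondition],
) -> pd.DataFrame:
    """Accuracy table: one row per condition (clean baseline first),
    one column per trained classifier.

    *featurize* must be the identical train-time closure (descriptor
    config + train-fitted standardization); only evaluation images are
    perturbed, the training pipeline is untouched.
    """
    test_labels = np.asarray(test_labels)
    for name, model in models.items():
        if not hasattr(model, "predict"):
            raise ValueError(f"model {name!r} does not expose predict(); is it trained?")

    rows = []
    conditions_all: list[StressCondition | None] = [None, *conditions]
    for cond in conditions_all:
        imgs = test_images if cond is None else [apply_condition(im, cond) for im in test_images]
        X = np.stack([featurize(im) for im in imgs])
        row: dict[str, Any] = {"condition": "clean" if cond is None else cond.label}
        for name, model in models.items():
            pred = np.asarray(model.predict(X))
            row[name] = float(np.mean(pred == test_labels))
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")
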
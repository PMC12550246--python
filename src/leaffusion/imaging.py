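"""Image loading, resizing, grayscale conversion and dataset indexing."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

#: h x w x 3 uint8 array.
RgbImage = np.ndarray
#: h x w uint8 array.
GrayImage = np.ndarray

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}

#: Default working resolution applied before feature extraction.
DEFAULT_RESIZE = (128, 128)


@dataclass
class DatasetRecord:
    path: Path
    class_name: str
    group: str | None = None


@dataclass
class LabelledDataset:
    """Sorted index of a class-per-folder image directory."""

    records: list[DatasetRecord]
    label_map: dict[str, int]
    root: Path | None = None
    skipped: list[Path] = field(default_factory=list)

    @property
    def class_names(self) -> list[str]:
        return sorted(self.label_map, key=self.label_map.get)

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.label_map[r.class_name] for r in self.records], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.records)


def _validate_rgb(img: np.ndarray) -> None:
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected h x w x 3 RGB image, got shape {img.shape}")


def encode_labels(names: list[str]) -> dict[str, int]:
    """Map distinct class names to 0..k-1 in lexicographic order."""
    if not names:
        raise ValueError("cannot encode an empty label list")
    return {name: code for code, name in enumerate(sorted(set(names)))}


def load_image(path: str | Path) -> RgbImage:
    """Decode a JPEG/PNG file to an h x w x 3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def load_dataset(root: str | Path, group_manifest: str | Path | None = None) -> LabelledDataset:
    """Index a class-per-folder image tree.

    Folders directly under *root* are classes; files inside them with a
    recognised image extension become records, sorted by path so the
    ordering (and every downstream seeded choice) is platform-stable.
    Undecodable files are skipped with a warning rather than aborting.

    Parameters
    ----------
    root : path
        Directory with one sub-folder per class.
    group_manifest : path, optional
        YAML/JSON file mapping class name -> group id.

    Raises
    ------
    ValueError
        If fewer than 2 class folders exist, or a class folder contains
        no decodable image.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"dataset root {root} must contain at least 2 class folders, found {len(class_dirs)}")

    groups: dict[str, str] = {}
    if group_manifest is not None:
        import yaml

        with open(group_manifest) as fh:
            groups = {str(k): str(v) for k, v in yaml.safe_load(fh).items()}

    records: list[DatasetRecord] = []
    skipped: list[Path] = []
    for class_dir in class_dirs:
        files = sorted(p for p in class_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
        kept = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    im.verify()
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping unreadable image %s: %s", f, exc)
                skipped.append(f)
                continue
            records.append(DatasetRecord(path=f, class_name=class_dir.name, group=groups.get(class_dir.name)))
            kept += 1
        if kept == 0:
            raise ValueError(f"class folder {class_dir} contains no decodable image")

    label_map = encode_labels([d.name for d in class_dirs])
    return LabelledDataset(records=records, label_map=label_map, root=root, skipped=skipped)


def resize_bilinear(
    img: np.ndarray,
    target_h: int,
    target_w: int,
    *,
    align_corners: bool = False,
) -> np.ndarray:
    """Bilinear resize of a gray or RGB uint8 image.

    Each output pixel (i, j) samples the source at the floating
    coordinate ``i * src_h / target_h`` (or ``i * (src_h-1)/(target_h-1)``
    when *align_corners* is set) and takes the fractional-weight average
    of the 4 enclosing source pixels, with edge clamping.  Channels are
    handled independently; results are rounded half-up and clipped to
    [0, 255].
    """
    if target_h < 1 or target_w < 1:
        raise ValueError(f"target size must be positive, got {(target_h, target_w)}")
    img = np.asarray(img)
    src_h, src_w = img.shape[:2]
    if (src_h, src_w) == (target_h, target_w):
        return img.copy()

    def coords(n_out: int, n_src: int) -> np.ndarray:
        idx = np.arange(n_out, dtype=np.float64)
        if align_corners and n_out > 1:
            return idx * (n_src - 1) / (n_out - 1)
        return np.minimum(idx * n_src / n_out, n_src - 1)

    ys = coords(target_h, src_h)
    xs = coords(target_w, src_w)
    y0 = np.floor(ys).astype(np.intp)
    x0 = np.floor(xs).astype(np.intp)
    y1 = np.minimum(y0 + 1, src_h - 1)
    x1 = np.minimum(x0 + 1, src_w - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]

    src = img.astype(np.float64)
    if src.ndim == 3:
        fy = fy[..., None]
        fx = fx[..., None]
    top = src[y0][:, x0] * (1 - fx) + src[y0][:, x1] * fx
    bot = src[y1][:, x0] * (1 - fx) + src[y1][:, x1] * fx
    out = top * (1 - fy) + bot * fy
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def to_grayscale(img: RgbImage) -> GrayImage:
    """BT.601 luma: 0.299 R + 0.587 G + 0.114 B, rounded half-up."""
    _validate_rgb(img)
    f = img.astype(np.float64)
    gray = 0.299 * f[..., 0] + 0.587 * f[..., 1] + 0.114 * f[..., 2]
    return np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
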
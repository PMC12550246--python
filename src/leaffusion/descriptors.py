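"""The four handcrafted descriptors (C1-C4) and their fusion.

C1: joint 3-D RGB color histogram (default 8x8x8 = 512 bins, normalized).
C2: rotation-invariant uniform LBP histogram (P=24, R=3 -> 26 bins).
C3: Gabor filter-bank response statistics (4 orientations x 3 sigmas,
    mean and std per filter -> 24 values).
C4: HOG with 8x8 cells, 2x2 blocks, 9 unsigned orientation bins and
    L2-Hys block normalization (8100 values at 128x128).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Interpolated LBP neighbor values are quantized to this many decimals
#: before thresholding, so exact-tie geometry is not perturbed by float
#: round-off (a constant patch must threshold to all ones).
_LBP_DECIMALS = 8


@dataclass
class DescriptorConfig:
    """Descriptor parameters; defaults follow the fusion pipeline setup."""

    color_bins: tuple[int, int, int] = (8, 8, 8)
    color_mode: str = "joint"  # "joint" (b^3 bins) or "marginal" (3b bins)
    lbp_neighbors: int = 24
    lbp_radius: float = 3.0
    gabor_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gabor_frequency: float = 0.6  # cycles / pixel; wavelength = 1/frequency
    gabor_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0)
    gabor_phase: float = 0.0
    gabor_aspect: float = 0.5
    hog_orientations: int = 9
    hog_cell: int = 8
    hog_block: int = 2
    hog_norm: str = "L2-Hys"  # "L2-Hys" or "L2"
    hog_vote: str = "bilinear"  # "bilinear" or "hard"

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.color_bins):
            raise ValueError("color_bins must all be >= 1")
        if self.color_mode not in ("joint", "marginal"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")
        if self.lbp_neighbors < 4:
            raise ValueError("lbp_neighbors must be >= 4")
        if self.gabor_frequency <= 0:
            raise ValueError("gabor_frequency must be positive")
        if self.hog_norm not in ("L2-Hys", "L2"):
            raise ValueError(f"unknown hog_norm {self.hog_norm!r}")

    @property
    def lbp_bins(self) -> int:
        """riu2 mapping yields P + 2 bins."""
        return self.lbp_neighbors + 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FeatureVector:
    """Fused descriptor vector with a named segment map (C1..C4)."""

    values: np.ndarray
    segments: dict[str, tuple[int, int]] = field(default_factory=dict)

    def segment(self, name: str) -> np.ndarray:
        start, end = self.segments[name]
        return self.values[start:end]

    def __len__(self) -> int:
        return len(self.values)


def color_histogram_3d(img: np.ndarray, bins: tuple[int, int, int] = (8, 8, 8)) -> np.ndarray:
    """Joint (R, G, B) histogram over the discretized color cube.

    Channel value v falls in bin ``v * b // 256`` (so 255 -> b-1); the
    3-D histogram is flattened R-major then G then B and divided by the
    pixel count, so the entries sum to 1.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected RGB image, got shape {img.shape}")
    br, bg, bb = bins
    r = img[..., 0].astype(np.intp) * br // 256
    g = img[..., 1].astype(np.intp) * bg // 256
    b = img[..., 2].astype(np.intp) * bb // 256
    flat = (r * bg + g) * bb + b
    hist = np.bincount(flat.ravel(), minlength=br * bg * bb).astype(np.float64)
    return hist / img.shape[0] / img.shape[1]


def color_histogram_marginal(img: np.ndarray, bins: tuple[int, int, int] = (8, 8, 8)) -> np.ndarray:
    """Concatenated per-channel histograms (length 3b variant)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected RGB image, got shape {img.shape}")
    parts = []
    for c, b in enumerate(bins):
        q = img[..., c].astype(np.intp) * b // 256
        parts.append(np.bincount(q.ravel(), minlength=b).astype(np.float64))
    return np.concatenate(parts) / img.shape[0] / img.shape[1]


def _lbp_neighbor_offsets(P: int, R: float) -> np.ndarray:
    """(P, 2) array of (drow, dcol) sampling offsets on the circle."""
    n = np.arange(P)
    angles = 2.0 * np.pi * n / P
    # row axis points down; neighbor 0 sits at (0, +R), subsequent
    # neighbors proceed counter-clockwise in image coordinates.
    dr = -R * np.sin(angles)
    dc = R * np.cos(angles)
    # kill float fuzz so exact-integer offsets stay exact
    return np.round(np.stack([dr, dc], axis=1), _LBP_DECIMALS)


def lbp_riu2_histogram(img: np.ndarray, P: int = 24, R: float = 3.0) -> np.ndarray:
    """Rotation-invariant uniform LBP occupancy histogram (P + 2 bins).

    For every pixel whose full circular neighborhood fits in the image,
    P neighbors are sampled at radius R by bilinear interpolation and
    thresholded against the center (ties count as 1).  Patterns with at
    most 2 circular 0/1 transitions map to their ones-count (bins 0..P);
    all remaining patterns share the residual bin P+1.  The histogram is
    normalized to sum to 1.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a grayscale image, got shape {img.shape}")
    if P < 4:
        raise ValueError("P must be >= 4")
    h, w = img.shape
    margin = int(np.ceil(R))
    if h <= 2 * margin or w <= 2 * margin:
        raise ValueError(f"image {img.shape} too small for LBP radius {R}")

    center = img[margin : h - margin, margin : w - margin]
    bits = np.empty((P,) + center.shape, dtype=np.uint8)
    for k, (dr, dc) in enumerate(_lbp_neighbor_offsets(P, R)):
        # constant offset for every pixel -> interpolate via 4 shifted views
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        fr, fc = dr - r0, dc - c0
        # zero-weight partner rows/cols collapse onto the floor index so
        # exact-integer offsets never index outside the image
        r1 = r0 + 1 if fr > 0 else r0
        c1 = c0 + 1 if fc > 0 else c0
        win = lambda dy, dx: img[margin + dy : h - margin + dy, margin + dx : w - margin + dx]
        sample = (
            (1 - fr) * (1 - fc) * win(r0, c0)
            + (1 - fr) * fc * win(r0, c1)
            + fr * (1 - fc) * win(r1, c0)
            + fr * fc * win(r1, c1)
        )
        bits[k] = np.round(sample, _LBP_DECIMALS) >= center

    signed = bits.astype(np.int8)
    ones = signed.sum(axis=0, dtype=np.intp)
    transitions = np.abs(np.diff(signed, axis=0)).sum(axis=0, dtype=np.intp)
    transitions += np.abs(signed[0] - signed[-1])
    codes = np.where(transitions <= 2, ones, P + 1)
    hist = np.bincount(codes.ravel(), minlength=P + 2).astype(np.float64)
    return hist / codes.size


def gabor_kernel(
    sigma: float,
    theta_deg: float,
    wavelength: float,
    phase: float = 0.0,
    aspect: float = 0.5,
) -> np.ndarray:
    """Real Gabor kernel: oriented cosine carrier under a Gaussian envelope.

    Half-width is ceil(3 sigma) so the envelope is truncated at 3 sigma.
    """
    n = int(np.ceil(3.0 * sigma))
    y, x = np.mgrid[-n : n + 1, -n : n + 1].astype(np.float64)
    theta = np.deg2rad(theta_deg)
    xp = x * np.cos(theta) + y * np.sin(theta)
    yp = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-(xp**2 + (aspect**2) * yp**2) / (2.0 * sigma**2))
    return envelope * np.cos(2.0 * np.pi * xp / wavelength + phase)


def gabor_features(img: np.ndarray, cfg: DescriptorConfig | None = None) -> np.ndarray:
    """Mean and std of Gabor responses per (orientation, sigma) pair.

    Intensities are rescaled to [0, 1] before filtering; convolution uses
    reflect padding.  Output is ordered by orientation then sigma, mean
    before std: length 2 * n_orientations * n_sigmas.
    """
    cfg = cfg or DescriptorConfig()
    if not cfg.gabor_orientations or not cfg.gabor_sigmas:
        raise ValueError("gabor_orientations and gabor_sigmas must be non-empty")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a grayscale image, got shape {img.shape}")
    scaled = img / 255.0
    wavelength = 1.0 / cfg.gabor_frequency
    feats: list[float] = []
    for theta in cfg.gabor_orientations:
        for sigma in cfg.gabor_sigmas:
            kernel = gabor_kernel(sigma, theta, wavelength, cfg.gabor_phase, cfg.gabor_aspect)
            resp = ndimage.convolve(scaled, kernel, mode="reflect")
            feats.append(float(resp.mean()))
            feats.append(float(resp.std()))
    return np.array(feats, dtype=np.float64)


def _hog_cell_histograms(gray: np.ndarray, cfg: DescriptorConfig) -> np.ndarray:
    """Magnitude-weighted per-cell orientation histograms."""
    h, w = gray.shape
    cell = cfg.hog_cell
    nbins = cfg.hog_orientations

    padded = np.pad(gray, 1, mode="edge")
    grad_r = padded[2:, 1:-1] - padded[:-2, 1:-1]
    grad_c = padded[1:-1, 2:] - padded[1:-1, :-2]
    mag = np.hypot(grad_r, grad_c)
    # unsigned orientation in [0, 180)
    theta = np.rad2deg(np.arctan2(grad_r, grad_c)) % 180.0

    pos = theta * nbins / 180.0
    b0 = np.floor(pos).astype(np.intp) % nbins
    frac = pos - np.floor(pos)
    if cfg.hog_vote == "hard":
        w0, w1 = mag, np.zeros_like(mag)
    else:
        w0, w1 = mag * (1.0 - frac), mag * frac
    b1 = (b0 + 1) % nbins

    cells_r, cells_c = h // cell, w // cell
    hist = np.zeros((cells_r, cells_c, nbins), dtype=np.float64)
    cr = (np.arange(h) // cell)[:, None]
    cc = (np.arange(w) // cell)[None, :]
    cr = np.broadcast_to(cr, (h, w)).ravel()
    cc = np.broadcast_to(cc, (h, w)).ravel()
    np.add.at(hist, (cr, cc, b0.ravel()), w0.ravel())
    np.add.at(hist, (cr, cc, b1.ravel()), w1.ravel())
    return hist


def hog_features(img: np.ndarray, cfg: DescriptorConfig | None = None) -> np.ndarray:
    """HOG descriptor with overlapping block normalization.

    Gradients are central differences with replicated edges; each pixel
    votes its gradient magnitude into the two orientation bins bracketing
    its unsigned angle.  Blocks of ``hog_block`` x ``hog_block`` cells slide
    with 1-cell stride; each block vector is L2-normalized (L2-Hys
    additionally clips at 0.2 and re-normalizes; all-zero blocks stay
    zero) and blocks are concatenated row-major.
    """
    cfg = cfg or DescriptorConfig()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a grayscale image, got shape {img.shape}")
    h, w = img.shape
    cell, block = cfg.hog_cell, cfg.hog_block
    ch, cw = (h // cell) * cell, (w // cell) * cell
    if ch < block * cell or cw < block * cell:
        raise ValueError(f"image {img.shape} smaller than one {block}x{block}-cell block")
    if (ch, cw) != (h, w):
        logger.warning("HOG: cropping %s to %s (largest cell multiple)", (h, w), (ch, cw))
        img = img[:ch, :cw]

    hist = _hog_cell_histograms(img, cfg)
    cells_r, cells_c, nbins = hist.shape
    blocks = []
    for br in range(cells_r - block + 1):
        for bc in range(cells_c - block + 1):
            vec = hist[br : br + block, bc : bc + block].ravel()
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec = vec / norm
                if cfg.hog_norm == "L2-Hys":
                    vec = np.minimum(vec, 0.2)
                    norm2 = np.linalg.norm(vec)
                    if norm2 > 0:
                        vec = vec / norm2
            blocks.append(vec)
    return np.concatenate(blocks)


def fuse_features(c1: np.ndarray, c2: np.ndarray, c3: np.ndarray, c4: np.ndarray) -> FeatureVector:
    """Concatenate the four descriptors in fixed order C1, C2, C3, C4."""
    parts = {"C1": np.asarray(c1), "C2": np.asarray(c2), "C3": np.asarray(c3), "C4": np.asarray(c4)}
    segments: dict[str, tuple[int, int]] = {}
    offset = 0
    for name, vec in parts.items():
        if vec.size == 0:
            raise ValueError(f"descriptor component {name} is empty")
        segments[name] = (offset, offset + vec.size)
        offset += vec.size
    values = np.concatenate([v.astype(np.float64).ravel() for v in parts.values()])
    return FeatureVector(values=values, segments=segments)


def extract_features(rgb: np.ndarray, cfg: DescriptorConfig | None = None) -> FeatureVector:
    """Run all four descriptors on one RGB image and fuse them."""
    from .imaging import to_grayscale

    cfg = cfg or DescriptorConfig()
    gray = to_grayscale(rgb)
    if cfg.color_mode == "joint":
        c1 = color_histogram_3d(rgb, cfg.color_bins)
    else:
        c1 = color_histogram_marginal(rgb, cfg.color_bins)
    c2 = lbp_riu2_histogram(gray, cfg.lbp_neighbors, cfg.lbp_radius)
    c3 = gabor_features(gray, cfg)
    c4 = hog_features(gray, cfg)
    return fuse_features(c1, c2, c3, c4)


def riu2_bin_count(P: int) -> int:
    """Distinct riu2 output bins for P neighbors, by full enumeration.

    Every P-bit pattern is mapped with the rotation-invariant uniform
    rule (vectorized popcount over all 2^P codes) and the distinct bin
    indices are counted.  Closed form: P + 2.
    """
    codes = np.arange(1 << P, dtype=np.uint32)
    rotated = ((codes >> np.uint32(1)) | (codes << np.uint32(P - 1))) & np.uint32((1 << P) - 1)
    transitions = np.bitwise_count(codes ^ rotated)
    ones = np.bitwise_count(codes)
    bins = np.where(transitions <= 2, ones, P + 1)
    return int(np.unique(bins).size)
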
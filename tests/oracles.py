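"""Independent definition-level oracle implementations.

Deliberately naive (per-pixel loops, dense convolution, dict counting)
so they share no code path with the package implementations they check.
"""

from __future__ import annotations

import numpy as np


def color_histogram_oracle(img: np.ndarray, bins=(8, 8, 8)) -> np.ndarray:
    br, bg, bb = bins
    counts: dict[tuple[int, int, int], int] = {}
    h, w, _ = img.shape
    for r in range(h):
        for c in range(w):
            key = (
                int(img[r, c, 0]) * br // 256,
                int(img[r, c, 1]) * bg // 256,
                int(img[r, c, 2]) * bb // 256,
            )
            counts[key] = counts.get(key, 0) + 1
    out = np.zeros(br * bg * bb)
    for (i, j, k), n in counts.items():
        out[(i * bg + j) * bb + k] = n / (h * w)
    return out


def _interp(img: np.ndarray, rr: float, cc: float) -> float:
    r0, c0 = int(np.floor(rr)), int(np.floor(cc))
    fr, fc = rr - r0, cc - c0
    r1 = min(r0 + 1, img.shape[0] - 1)
    c1 = min(c0 + 1, img.shape[1] - 1)
    return (
        (1 - fr) * (1 - fc) * img[r0, c0]
        + (1 - fr) * fc * img[r0, c1]
        + fr * (1 - fc) * img[r1, c0]
        + fr * fc * img[r1, c1]
    )


def lbp_riu2_oracle(img: np.ndarray, P: int, R: float) -> np.ndarray:
    """Brute-force per-pixel pattern enumeration with the riu2 mapping."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    margin = int(np.ceil(R))
    hist = np.zeros(P + 2)
    total = 0
    for r in range(margin, h - margin):
        for c in range(margin, w - margin):
            center = img[r, c]
            bits = []
            for n in range(P):
                angle = 2.0 * np.pi * n / P
                dr = round(-R * np.sin(angle), 8)
                dc = round(R * np.cos(angle), 8)
                val = round(_interp(img, r + dr, c + dc), 8)
                bits.append(1 if val >= center else 0)
            ones = sum(bits)
            transitions = sum(abs(bits[i] - bits[(i + 1) % P]) for i in range(P))
            code = ones if transitions <= 2 else P + 1
            hist[code] += 1
            total += 1
    return hist / total


def gabor_kernel_oracle(sigma, theta_deg, wavelength, phase=0.0, aspect=0.5) -> np.ndarray:
    n = int(np.ceil(3 * sigma))
    kern = np.zeros((2 * n + 1, 2 * n + 1))
    th = np.deg2rad(theta_deg)
    for iy, y in enumerate(range(-n, n + 1)):
        for ix, x in enumerate(range(-n, n + 1)):
            xp = x * np.cos(th) + y * np.sin(th)
            yp = -x * np.sin(th) + y * np.cos(th)
            kern[iy, ix] = np.exp(-(xp**2 + aspect**2 * yp**2) / (2 * sigma**2)) * np.cos(
                2 * np.pi * xp / wavelength + phase
            )
    return kern


def gabor_features_oracle(img: np.ndarray, orientations, sigmas, frequency=0.6, phase=0.0, aspect=0.5) -> np.ndarray:
    """Dense direct spatial convolution (kernel flipped, symmetric padding)."""
    img = np.asarray(img, dtype=np.float64) / 255.0
    wavelength = 1.0 / frequency
    feats = []
    for theta in orientations:
        for sigma in sigmas:
            kern = gabor_kernel_oracle(sigma, theta, wavelength, phase, aspect)
            n = kern.shape[0] // 2
            padded = np.pad(img, n, mode="symmetric")
            flipped = kern[::-1, ::-1]
            resp = np.zeros_like(img)
            for r in range(img.shape[0]):
                for c in range(img.shape[1]):
                    resp[r, c] = np.sum(padded[r : r + 2 * n + 1, c : c + 2 * n + 1] * flipped)
            feats.append(resp.mean())
            feats.append(resp.std())
    return np.array(feats)


def hog_oracle(img: np.ndarray, orientations=9, cell=8, block=2, norm="L2-Hys", vote="bilinear") -> np.ndarray:
    """Definition-level per-pixel HOG."""
    img = np.asarray(img, dtype=np.float64)
    h, w = (img.shape[0] // cell) * cell, (img.shape[1] // cell) * cell
    img = img[:h, :w]
    cells_r, cells_c = h // cell, w // cell
    hist = np.zeros((cells_r, cells_c, orientations))
    for r in range(h):
        for c in range(w):
            rp, rm = min(r + 1, h - 1), max(r - 1, 0)
            cp, cm = min(c + 1, w - 1), max(c - 1, 0)
            gr = img[rp, c] - img[rm, c]
            gc = img[r, cp] - img[r, cm]
            mag = np.sqrt(gr * gr + gc * gc)
            theta = np.degrees(np.arctan2(gr, gc)) % 180.0
            pos = theta * orientations / 180.0
            b0 = int(np.floor(pos)) % orientations
            frac = pos - np.floor(pos)
            if vote == "hard":
                hist[r // cell, c // cell, b0] += mag
            else:
                hist[r // cell, c // cell, b0] += mag * (1 - frac)
                hist[r // cell, c // cell, (b0 + 1) % orientations] += mag * frac
    out = []
    for br in range(cells_r - block + 1):
        for bc in range(cells_c - block + 1):
            vec = hist[br : br + block, bc : bc + block].reshape(-1).copy()
            nrm = np.sqrt(np.sum(vec**2))
            if nrm > 0:
                vec = vec / nrm
                if norm == "L2-Hys":
                    vec = np.minimum(vec, 0.2)
                    nrm2 = np.sqrt(np.sum(vec**2))
                    if nrm2 > 0:
                        vec = vec / nrm2
            out.append(vec)
    return np.concatenate(out)
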
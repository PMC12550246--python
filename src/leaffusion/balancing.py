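"""SMOTE oversampling in fused feature space, plus z-score standardization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """n x d feature rows with integer labels and a synthetic-row flag."""

    X: np.ndarray
    y: np.ndarray
    class_names: list[str] = field(default_factory=list)
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != len(self.X):
            raise ValueError(f"X has {len(self.X)} rows but y has {len(self.y)} labels")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.y), dtype=bool)
        if not self.class_names:
            self.class_names = [str(c) for c in range(int(self.y.max(initial=-1)) + 1)]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.y == code)) for code, name in enumerate(self.class_names)}

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[idx], self.y[idx], list(self.class_names), self.synthetic[idx])


def smote_resample(data: FeatureMatrix, k_neighbors: int = 5, seed: int = 0) -> FeatureMatrix:
    """Oversample every minority class up to the majority count.

    Each synthetic row interpolates a seeded-random minority sample xi
    toward one of its k nearest same-class neighbors xz (Euclidean):
    ``x_new = xi + delta * (xz - xi)`` with one uniform delta per sample.
    Original rows are retained untouched; synthetic rows are flagged.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    counts = np.bincount(data.y, minlength=data.n_classes)
    target = counts.max()
    rng = np.random.default_rng(seed)

    new_X: list[np.ndarray] = []
    new_y: list[int] = []
    for code in range(data.n_classes):
        deficit = int(target - counts[code])
        if deficit == 0:
            continue
        idx = np.flatnonzero(data.y == code)
        if len(idx) < 2:
            raise ValueError(
                f"class {data.class_names[code]!r} has {len(idx)} sample(s); SMOTE needs at least 2"
            )
        k = k_neighbors
        if k > len(idx) - 1:
            k = len(idx) - 1
            logger.warning(
                "class %r: k_neighbors capped at %d (class size %d)", data.class_names[code], k, len(idx)
            )
        Xc = data.X[idx]
        # pairwise squared Euclidean within the class (gram-matrix form);
        # self excluded via inf diagonal
        sq = np.einsum("ij,ij->i", Xc, Xc)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (Xc @ Xc.T)
        np.fill_diagonal(d2, np.inf)
        neighbors = np.argsort(d2, axis=1, kind="stable")[:, :k]
        for _ in range(deficit):
            i = int(rng.integers(len(idx)))
            z = int(neighbors[i, rng.integers(k)])
            delta = rng.uniform()
            new_X.append(Xc[i] + delta * (Xc[z] - Xc[i]))
            new_y.append(code)

    if not new_X:
        return FeatureMatrix(data.X.copy(), data.y.copy(), list(data.class_names), data.synthetic.copy())
    X = np.vstack([data.X, np.array(new_X)])
    y = np.concatenate([data.y, np.array(new_y, dtype=np.int64)])
    flags = np.concatenate([data.synthetic, np.ones(len(new_y), dtype=bool)])
    return FeatureMatrix(X, y, list(data.class_names), flags)


@dataclass
class Standardizer:
    """Train-fitted per-column z-score transform; constant columns map to 0."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        if len(X) == 0:
            raise ValueError("cannot fit a standardizer on an empty matrix")
        return cls(mean=X.mean(axis=0), std=X.std(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.mean):
            raise ValueError(f"expected {len(self.mean)} columns, got {X.shape[1]}")
        safe = np.where(self.std > 0, self.std, 1.0)
        out = (X - self.mean) / safe
        out[:, self.std == 0] = 0.0
        return out

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return Z * np.where(self.std > 0, self.std, 1.0) + self.mean


def standardize(
    train: FeatureMatrix, others: list[FeatureMatrix] | None = None
) -> tuple[FeatureMatrix, list[FeatureMatrix], Standardizer]:
    """Z-score using train statistics; the identical transform is applied
    to every held-out matrix."""
    scaler = Standardizer.fit(train.X)
    train_t = FeatureMatrix(scaler.transform(train.X), train.y, list(train.class_names), train.synthetic.copy())
    others_t = [
        FeatureMatrix(scaler.transform(m.X), m.y, list(m.class_names), m.synthetic.copy())
        for m in (others or [])
    ]
    return train_t, others_t, scaler
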
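"""Inter-class similarity from class mean feature vectors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balancing import FeatureMatrix


@dataclass
class SimilarityMatrix:
    """k x k cosine similarities of class means, rescaled to [0, 1]."""

    values: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        k = len(self.class_order)
        if self.values.shape != (k, k):
            raise ValueError(f"expected {(k, k)} matrix, got {self.values.shape}")


def class_mean_vectors(data: FeatureMatrix, include_synthetic: bool = False) -> dict[str, np.ndarray]:
    """Per-class arithmetic column means, ordered by label code.

    SMOTE rows are excluded by default: interpolated points pull means
    toward segment midpoints and would bias the similarity diagnostics.
    """
    means: dict[str, np.ndarray] = {}
    keep = np.ones(len(data.y), dtype=bool) if include_synthetic else ~data.synthetic
    for code, name in enumerate(data.class_names):
        rows = data.X[(data.y == code) & keep]
        if len(rows) == 0:
            raise ValueError(f"class {name!r} has no rows to average")
        means[name] = rows.mean(axis=0)
    return means


def interclass_similarity(means: dict[str, np.ndarray]) -> SimilarityMatrix:
    """Pairwise cosine of the class means, mapped (c + 1) / 2 into [0, 1]."""
    if len(means) < 2:
        raise ValueError("need at least 2 classes")
    order = list(means)
    dims = {len(v) for v in means.values()}
    if len(dims) != 1:
        raise ValueError(f"mean vectors have mismatched dimensions: {sorted(dims)}")
    M = np.stack([np.asarray(means[name], dtype=np.float64) for name in order])
    norms = np.linalg.norm(M, axis=1)
    for name, n in zip(order, norms):
        if n == 0:
            raise ValueError(f"class {name!r} has a zero-norm mean vector")
    unit = M / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    cos = (cos + cos.T) / 2.0
    np.fill_diagonal(cos, 1.0)
    return SimilarityMatrix(values=(cos + 1.0) / 2.0, class_order=order)


def top_confusable_pairs(
    S: SimilarityMatrix, threshold: float | None = None, top_n: int | None = None
) -> list[tuple[str, str, float]]:
    """Off-diagonal pairs ranked by similarity, descending.

    Ties break on class-name order; output is deterministic.  Either a
    similarity *threshold* or a *top_n* cutoff (or neither) applies.
    """
    pairs = []
    k = len(S.class_order)
    for p in range(k):
        for q in range(p + 1, k):
            a, b = sorted((S.class_order[p], S.class_order[q]))
            pairs.append((a, b, float(S.values[p, q])))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    if threshold is not None:
        pairs = [t for t in pairs if t[2] >= threshold]
    if top_n is not None:
        pairs = pairs[:top_n]
    return pairs
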
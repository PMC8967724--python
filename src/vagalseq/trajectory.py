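"""Trajectory scoring on a 2-D embedding.

Organ position scores summarise where a cluster's projection targets sit
along the body's rostral-caudal axis (weighted mean of normalised organ
positions).  Trajectory scores place single cells along a polyline drawn
through ordered cluster centroids on the embedding, normalised to [0, 1] by
total arc length.  Tissue-layer indices summarise where a population's
endings terminate across gut wall layers (count-weighted mean of layer
index scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .organs import LAYER_INDEX, ORGAN_POSITIONS

__all__ = [
    "EmbeddingPath",
    "organ_position_score",
    "fit_principal_path",
    "trajectory_score",
    "tissue_layer_index",
    "score_position_regression",
]


@dataclass(frozen=True)
class EmbeddingPath:
    """Ordered polyline in embedding space with cumulative arc length."""

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("path needs >= 2 two-dimensional vertices")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive path vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)

    @property
    def cumulative_length(self) -> np.ndarray:
        """Arc length at each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])


def organ_position_score(
    weights: Mapping[str, float],
    positions: Mapping[str, float] = ORGAN_POSITIONS,
) -> float:
    """Weighted-average organ position of a cluster.

    ``weights`` maps organ -> P_organ-cluster (the cluster's share of that
    organ's single-barcode cells); ``positions`` maps organ -> normalised
    rostro-caudal position.  Returns sum(P * position) / sum(P).
    """
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all organ weights are zero; score undefined")
    return sum(w * positions[o] for o, w in weights.items()) / total


def fit_principal_path(centroids: Sequence[Sequence[float]]) -> EmbeddingPath:
    """Polyline through cluster centroids in caller-declared order."""
    return EmbeddingPath(np.asarray(centroids, dtype=float))


def trajectory_score(point: Sequence[float], path: EmbeddingPath) -> float:
    """Normalised arc-length position of a point projected onto a path.

    The point is orthogonally projected onto every segment (clamped to the
    segment ends); the globally nearest projection wins, with ties resolved
    toward the smaller arc length.  Result in [0, 1].
    """
    p = np.asarray(point, dtype=float)
    v = path.vertices
    a, b = v[:-1], v[1:]
    d = b - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / seg_len2, 0.0, 1.0)
    proj = a + t[:, None] * d
    dist = np.linalg.norm(proj - p, axis=1)
    cum = path.cumulative_length
    # strict argmin keeps the first (smallest-arc-length) of tied segments
    best = int(np.argmin(dist))
    arc = cum[best] + t[best] * np.sqrt(seg_len2[best])
    return float(arc / path.total_length)


def tissue_layer_index(
    ending_counts: Mapping[str, float],
    index_map: Mapping[str, float] = LAYER_INDEX,
) -> float:
    """Count-weighted mean tissue-layer index of a set of endings.

    Layers score mucosa/inner epithelium 0, muscle 1, connective tissue 2
    by default; the result lies between the smallest and largest index
    present.
    """
    total = sum(ending_counts.values())
    if total <= 0:
        raise ValueError("zero total endings")
    return sum(n * index_map[layer] for layer, n in ending_counts.items()) / total


def score_position_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
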
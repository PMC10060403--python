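"""Assisted-annotation support: diversity ordering, classical
pre-annotation, and inspection metrics (Dice, optimal-assignment AJI).

The learned embedder is a pluggable extractor; the classical default
concatenates a 32-bin intensity histogram, distribution moments and
edge-density statistics.  Selection is farthest-point (max-min) greedy
ordering in a PCA-reduced feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from skimage.filters import sobel, threshold_otsu

__all__ = [
    "EmbeddingMatrix",
    "SelectionOrder",
    "embed_images",
    "reduce_pca",
    "heterogeneity_order",
    "preannotate",
    "dice",
    "aji_plus",
    "default_features",
]

HIST_BINS = 32


@dataclass
class EmbeddingMatrix:
    features: np.ndarray  # (n_images, d)
    ids: list

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.ids) != self.features.shape[0]:
            raise ValueError(
                f"id count {len(self.ids)} != row count {self.features.shape[0]}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix must be finite")


@dataclass
class SelectionOrder:
    ids: list  # permutation of image identifiers
    scores: list[float]  # per-step min distance to already-selected (inf for the start)


def default_features(image: np.ndarray) -> np.ndarray:
    """Classical per-image descriptor: histogram + moments + edge stats."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    hist, _ = np.histogram(norm, bins=HIST_BINS, range=(0.0, 1.0))
    hist = hist / img.size
    flat = img.ravel()
    moments = np.array([
        flat.mean(),
        flat.std(),
        float(stats.skew(flat)) if flat.std() > 0 else 0.0,
        float(stats.kurtosis(flat)) if flat.std() > 0 else 0.0,
    ])
    edges = sobel(norm)
    edge_stats = np.array([edges.mean(), edges.std(), float((edges > 0.1).mean())])
    return np.concatenate([hist, moments, edge_stats])


def embed_images(
    images: Sequence[np.ndarray],
    extractor: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
    ids: Sequence | None = None,
) -> EmbeddingMatrix:
    """One feature row per image.

    ``extractor`` may be a callable applied per image, a precomputed
    (n, d) matrix (accepted unchanged when the row count matches), or
    None for the classical default.
    """
    n = len(images)
    if n < 1:
        raise ValueError("need at least one image")
    ids = list(ids) if ids is not None else list(range(n))
    if isinstance(extractor, np.ndarray):
        if extractor.shape[0] != n:
            raise ValueError(f"external feature matrix has {extractor.shape[0]} rows for {n} images")
        return EmbeddingMatrix(features=extractor, ids=ids)
    fn = extractor or default_features
    rows = [np.asarray(fn(img), dtype=float).ravel() for img in images]
    d = len(rows[0])
    if any(len(r) != d for r in rows):
        raise ValueError("inconsistent feature length across images")
    return EmbeddingMatrix(features=np.vstack(rows), ids=ids)


def reduce_pca(m: EmbeddingMatrix, k: int = 10) -> EmbeddingMatrix:
    """Project centered rows onto the top-k principal axes.

    Sign convention: each axis is flipped so its largest-magnitude
    loading is positive, making the reduction deterministic.
    """
    X = m.features
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    if k > min(n - 1, d):
        raise ValueError(f"k={k} exceeds min(n-1, d) = {min(n - 1, d)}")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    V = evecs[:, order]
    for c in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, c])), c] < 0:
            V[:, c] = -V[:, c]
    return EmbeddingMatrix(features=Xc @ V, ids=list(m.ids))


def heterogeneity_order(m: EmbeddingMatrix, start=None) -> SelectionOrder:
    """Farthest-point (max-min) greedy ordering in Euclidean distance.

    The first pick is the medoid (minimum summed distance to all rows)
    unless ``start`` names an identifier; each subsequent pick maximizes
    the minimum distance to everything already selected.  Ties break by
    ascending identifier.
    """
    X, ids = m.features, m.ids
    n = len(ids)
    if n == 1:
        return SelectionOrder(ids=list(ids), scores=[float("inf")])
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    id_rank = np.argsort(np.argsort(np.array(ids, dtype=object), kind="stable"))
    if start is None:
        sums = d.sum(axis=1)
        first = min(range(n), key=lambda i: (sums[i], id_rank[i]))
    else:
        try:
            first = ids.index(start)
        except ValueError:
            raise ValueError(f"start identifier {start!r} not found") from None
    selected = [first]
    mind = d[first].copy()
    scores = [float("inf")]
    remaining = set(range(n)) - {first}
    while remaining:
        nxt = min(remaining, key=lambda i: (-mind[i], id_rank[i]))
        scores.append(float(mind[nxt]))
        selected.append(nxt)
        remaining.discard(nxt)
        np.minimum(mind, d[nxt], out=mind)
    return SelectionOrder(ids=[ids[i] for i in selected], scores=scores)


def preannotate(
    image: np.ndarray,
    method: str = "otsu",
    q: float = 95.0,
    external_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Classical pre-annotation mask: otsu, percentile, or external."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("pre-annotation expects a single-channel image")
    if method == "otsu":
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        return img > threshold_otsu(img)
    if method == "percentile":
        return img > np.percentile(img, q)
    if method == "external":
        if external_mask is None:
            raise ValueError("method 'external' requires external_mask")
        mask = np.asarray(external_mask)
        if mask.shape != img.shape:
            raise ValueError(f"external mask shape {mask.shape} != image shape {img.shape}")
        return mask.astype(bool)
    raise ValueError(f"unknown method {method!r}; known: otsu, percentile, external")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A&B| / (|A| + |B|); two empty masks score 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def aji_plus(truth: np.ndarray, pred: np.ndarray) -> float:
    """Aggregated Jaccard index with optimal one-to-one instance assignment.

    The assignment between truth and prediction instances maximizes the
    summed intersection-over-union; the score is the total matched
    intersection over the total matched union plus all unmatched areas.
    Two empty maps score 1.0.
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    t_ids = np.unique(truth[truth > 0])
    p_ids = np.unique(pred[pred > 0])
    if len(t_ids) == 0 and len(p_ids) == 0:
        return 1.0
    if len(t_ids) == 0 or len(p_ids) == 0:
        return 0.0
    t_index = {v: k for k, v in enumerate(t_ids)}
    p_index = {v: k for k, v in enumerate(p_ids)}
    t_areas = np.array([(truth == v).sum() for v in t_ids], dtype=float)
    p_areas = np.array([(pred == v).sum() for v in p_ids], dtype=float)
    inter = np.zeros((len(t_ids), len(p_ids)))
    both = (truth > 0) & (pred > 0)
    for tv, pv in zip(truth[both], pred[both]):
        inter[t_index[tv], p_index[pv]] += 1
    union = t_areas[:, None] + p_areas[None, :] - inter
    iou = inter / union
    rows, cols = linear_sum_assignment(-iou)
    num = 0.0
    den = 0.0
    matched_t, matched_p = set(), set()
    for r, c in zip(rows, cols):
        if inter[r, c] > 0:
            num += inter[r, c]
            den += union[r, c]
            matched_t.add(r)
            matched_p.add(c)
    den += sum(t_areas[r] for r in range(len(t_ids)) if r not in matched_t)
    den += sum(p_areas[c] for c in range(len(p_ids)) if c not in matched_p)
    return num / den if den > 0 else 0.0
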
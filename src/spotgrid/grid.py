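"""Macro-level grid detection: from a raw lattice image to a fitted GridModel.

Pipeline stages: percentile normalization, element segmentation (Otsu /
percentile / pluggable external scorer), morphological post-processing
with area filtering, rotation estimation from neighbourhood arrangement,
robust per-axis lattice fitting, and ROI extraction.  A semi-automated
path completes a partially known grid from a few clicked element centres.

The rotation and robust-fit procedures are deterministic reconstructions
of the described behaviour: rotation is the circular median (period 90
degrees) of nearest-neighbour displacement angles; fitting clusters
de-rotated centroids into lines per axis and takes medians.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening

from .models import GridModel, SpotROI, fold_angle_deg, rotation_matrix

__all__ = [
    "DetectedElementSet",
    "preprocess",
    "segment_elements",
    "postprocess_elements",
    "estimate_rotation",
    "fit_grid",
    "semi_automated_grid",
    "extract_rois",
    "detect_grid",
    "GridDetectionError",
]

LUMINANCE_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])


class GridDetectionError(RuntimeError):
    """Raised when automated grid detection cannot proceed; callers may
    fall back to the semi-automated path."""


@dataclass
class DetectedElementSet:
    """Candidate lattice elements: label raster plus per-element geometry."""

    labels: np.ndarray
    centroids: np.ndarray  # (n, 2) as (x, y)
    areas: np.ndarray  # (n,) pixel counts

    def __len__(self) -> int:
        return len(self.areas)


def preprocess(image: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Reduce to luminance and rescale percentiles [p_low, p_high] onto [0, 1].

    A constant image (equal percentiles) yields an all-zero raster with a
    warning rather than an exception.
    """
    if not 0 <= p_low < p_high <= 100:
        raise ValueError(f"percentiles must satisfy 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        # channel-first (3, h, w) or channel-last (h, w, 3)
        if img.shape[0] == 3 and img.shape[-1] != 3:
            img = np.tensordot(LUMINANCE_WEIGHTS, img, axes=(0, 0))
        elif img.shape[-1] == 3:
            img = img @ LUMINANCE_WEIGHTS
        else:
            raise ValueError(f"cannot interpret {img.shape} as a single- or 3-channel image")
    elif img.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got ndim={img.ndim}")
    lo, hi = np.percentile(img, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image: percentile window is empty, returning zeros")
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def segment_elements(
    image: np.ndarray,
    method: str = "otsu",
    q: float = 90.0,
    scores: np.ndarray | None = None,
    score_threshold: float = 0.5,
) -> np.ndarray:
    """Binary foreground mask of candidate elements.

    ``method`` is one of ``otsu``, ``percentile`` (threshold at the q-th
    intensity percentile) or ``external`` (caller-supplied per-pixel
    scores in [0, 1], thresholded at ``score_threshold``).
    """
    img = np.asarray(image, dtype=float)
    if method == "otsu":
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        return img > threshold_otsu(img)
    if method == "percentile":
        if np.ptp(img) == 0:
            return np.zeros(img.shape, dtype=bool)
        return img > np.percentile(img, q)
    if method == "external":
        if scores is None:
            raise ValueError("method 'external' requires a scores array")
        scores = np.asarray(scores, dtype=float)
        if scores.shape != img.shape:
            raise ValueError(
                f"external scores have wrong shape: expected {img.shape}, got {scores.shape}"
            )
        return scores > score_threshold
    raise ValueError(f"unknown segmentation method {method!r}; known: otsu, percentile, external")


def postprocess_elements(
    mask: np.ndarray,
    open_radius: int = 1,
    area_band: tuple[float, float] = (0.3, 3.0),
) -> DetectedElementSet:
    """Morphological opening, labeling and median-relative area filtering.

    Components with area outside ``[low, high] * median(areas)`` are
    dropped and the survivors relabeled consecutively.
    """
    low, high = area_band
    if not 0 < low < 1 < high:
        raise ValueError(f"area band must satisfy 0 < low < 1 < high, got {area_band}")
    m = np.asarray(mask, dtype=bool)
    if open_radius > 0:
        m = opening(m, disk(open_radius))
    lab = cc_label(m, connectivity=1)
    props = regionprops(lab)
    if not props:
        raise GridDetectionError("no candidate elements survive post-processing")
    areas = np.array([p.area for p in props], dtype=float)
    med = float(np.median(areas))
    keep = [p for p, a in zip(props, areas) if low * med <= a <= high * med]
    if not keep:
        raise GridDetectionError("all candidate elements rejected by the area filter")
    out = np.zeros_like(lab)
    cents = np.empty((len(keep), 2), dtype=float)
    out_areas = np.empty(len(keep), dtype=float)
    for new_id, p in enumerate(keep, start=1):
        out[lab == p.label] = new_id
        cy, cx = p.centroid
        cents[new_id - 1] = (cx, cy)
        out_areas[new_id - 1] = p.area
    return DetectedElementSet(labels=out, centroids=cents, areas=out_areas)


def _circular_median_deg(angles: np.ndarray, period: float = 90.0) -> float:
    """Median of angles on a circle of the given period.

    The circular mean locates a reference direction; angles are unwrapped
    into a half-period window around it and the ordinary median taken.
    """
    rad = np.asarray(angles, dtype=float) * (2.0 * math.pi / period)
    mean = math.atan2(np.sin(rad).mean(), np.cos(rad).mean()) * period / (2.0 * math.pi)
    shifted = (angles - mean + period / 2.0) % period - period / 2.0
    return float(mean + np.median(shifted))


def estimate_rotation(centroids: np.ndarray | Sequence[tuple[float, float]]) -> float:
    """Grid rotation in (-45, 45] from nearest-neighbour displacement angles.

    For each centroid the displacement to its nearest neighbour is taken,
    its angle folded modulo 90 degrees, and the circular median returned.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise GridDetectionError("rotation estimation needs at least 2 centroids")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=2)
    disp = pts[idx[:, 1]] - pts
    raw = np.degrees(np.arctan2(disp[:, 1], disp[:, 0]))
    folded = np.array([fold_angle_deg(a) for a in raw])
    return fold_angle_deg(_circular_median_deg(folded))


def _cluster_lines(coords: np.ndarray, gap: float) -> list[float]:
    """Single-linkage 1-D clustering: split sorted coords at gaps > ``gap``."""
    order = np.sort(coords)
    centers = []
    start = 0
    for k in range(1, len(order) + 1):
        if k == len(order) or order[k] - order[k - 1] > gap:
            centers.append(float(order[start:k].mean()))
            start = k
    return centers


def _fill_missing_lines(centers: list[float], pitch: float, tol: float = 0.1) -> list[float]:
    """Interpolate interior line centres where a gap is ~k pitches, k >= 2."""
    filled = [centers[0]]
    for a, b in zip(centers, centers[1:]):
        g = b - a
        k = int(round(g / pitch))
        if k >= 2 and abs(g / k - pitch) <= tol * pitch:
            filled.extend(a + g * m / k for m in range(1, k))
        filled.append(b)
    return filled


def fit_grid(
    elements: DetectedElementSet,
    rotation_deg: float,
    expected_shape: tuple[int, int] | None = None,
) -> GridModel:
    """Robust lattice fit from detected element centroids.

    Centroids are de-rotated; each axis is clustered into lines (gap
    threshold: half the median nearest-neighbour spacing); pitch is the
    median line spacing and the origin the first line centre, re-rotated
    back into the image frame.  When ``expected_shape`` is given, missing
    interior lines are interpolated if the pitch divides the gap within
    10%, and the resulting shape is validated against it.
    """
    pts = elements.centroids
    if len(pts) < 4:
        raise GridDetectionError(f"need at least 4 elements to fit a grid, got {len(pts)}")
    R = rotation_matrix(-rotation_deg)
    de = pts @ R.T
    tree = cKDTree(de)
    nn_dist, _ = tree.query(de, k=2)
    gap = float(np.median(nn_dist[:, 1])) / 2.0

    axes = []
    for axis in (0, 1):
        centers = _cluster_lines(de[:, axis], gap)
        if len(centers) < 2:
            raise GridDetectionError(
                f"detected elements span fewer than 2 distinct {'columns' if axis == 0 else 'rows'}"
            )
        pitch = float(np.median(np.diff(centers)))
        if expected_shape is not None:
            centers = _fill_missing_lines(centers, pitch)
        axes.append((centers, pitch))

    (xc, pitch_x), (yc, pitch_y) = axes
    cols, rows = len(xc), len(yc)
    if expected_shape is not None and (rows, cols) != tuple(expected_shape):
        raise GridDetectionError(
            f"detected grid shape ({rows}, {cols}) is irreconcilable with "
            f"expected shape {tuple(expected_shape)}"
        )
    Rb = rotation_matrix(rotation_deg)
    origin = Rb @ np.array([xc[0], yc[0]])
    radius = float(np.median(np.sqrt(elements.areas / math.pi)))
    return GridModel(
        rows=rows,
        cols=cols,
        origin_x=float(origin[0]),
        origin_y=float(origin[1]),
        pitch_x=pitch_x,
        pitch_y=pitch_y,
        rotation_deg=float(rotation_deg),
        spot_radius=radius,
    )


def semi_automated_grid(
    known: dict | None = None,
    clicked_points: Sequence[tuple[float, float]] | None = None,
) -> GridModel:
    """Complete a GridModel from known fields plus clicked element centres.

    Deterministic derivation rules, tried in order:

    * all eight fields known -> returned unchanged;
    * ``rows, cols, spot_radius`` + 3 clicks at element centres (0, 0),
      (0, cols-1) and (rows-1, 0) -> rotation from the first row
      direction, pitches from the edge lengths, origin = first click;
    * ``rows, cols, spot_radius`` + 2 clicks at opposite corner centres
      (0, 0) and (rows-1, cols-1), rotation known (default 0) -> pitches
      from the de-rotated diagonal, origin = first click.
    """
    known = dict(known or {})
    fields = ("rows", "cols", "origin_x", "origin_y", "pitch_x", "pitch_y",
              "rotation_deg", "spot_radius")
    if all(f in known for f in fields):
        return GridModel(**{f: known[f] for f in fields})

    missing = [f for f in ("rows", "cols", "spot_radius") if f not in known]
    pts = [np.asarray(p, dtype=float) for p in (clicked_points or [])]
    if missing or len(pts) < 2:
        need = missing + ([] if len(pts) >= 2 else ["clicked_points (>= 2 element centres)"])
        raise ValueError(f"underdetermined grid: missing {', '.join(need)}")
    rows, cols = int(known["rows"]), int(known["cols"])

    if len(pts) >= 3:
        p00, p0c, pr0 = pts[0], pts[1], pts[2]
        ex = p0c - p00
        rot = fold_angle_deg(math.degrees(math.atan2(ex[1], ex[0])))
        pitch_x = float(np.linalg.norm(ex)) / (cols - 1)
        pitch_y = float(np.linalg.norm(pr0 - p00)) / (rows - 1)
    else:
        rot = float(known.get("rotation_deg", 0.0))
        d = rotation_matrix(-rot) @ (pts[1] - pts[0])
        pitch_x = float(d[0]) / (cols - 1)
        pitch_y = float(d[1]) / (rows - 1)
    return GridModel(
        rows=rows,
        cols=cols,
        origin_x=float(pts[0][0]),
        origin_y=float(pts[0][1]),
        pitch_x=pitch_x,
        pitch_y=pitch_y,
        rotation_deg=float(known.get("rotation_deg", rot)),
        spot_radius=float(known["spot_radius"]),
    )


def extract_rois(image: np.ndarray, grid: GridModel) -> list[SpotROI]:
    """Row-major list of per-spot ROIs (disc masks, boxes clipped to bounds)."""
    h, w = np.asarray(image).shape[:2]
    grid.check_bounds((h, w))
    r = grid.spot_radius
    rois = []
    for k, (cx, cy) in enumerate(grid.centers()):
        i, j = divmod(k, grid.cols)
        x0 = max(0, int(math.floor(cx - r)))
        y0 = max(0, int(math.floor(cy - r)))
        x1 = min(w, int(math.ceil(cx + r)) + 1)
        y1 = min(h, int(math.ceil(cy + r)) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        rois.append(SpotROI(grid_index=(i, j), bbox=(x0, y0, x1, y1), mask=mask, center=(cx, cy)))
    return rois


def detect_grid(
    image: np.ndarray,
    expected_shape: tuple[int, int] | None = None,
    p_low: float = 1.0,
    p_high: float = 99.0,
    method: str = "otsu",
    open_radius: int = 1,
    area_band: tuple[float, float] = (0.3, 3.0),
    **segment_kwargs,
) -> GridModel:
    """Full automated pipeline: preprocess, segment, post-process, fit."""
    norm = preprocess(image, p_low, p_high)
    mask = segment_elements(norm, method=method, **segment_kwargs)
    elements = postprocess_elements(mask, open_radius=open_radius, area_band=area_band)
    rot = estimate_rotation(elements.centroids)
    return fit_grid(elements, rot, expected_shape=expected_shape)
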
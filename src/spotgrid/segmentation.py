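"""Micro-level instance segmentation and feature extraction.

The learned distance-map predictor is replaced by a classical default
(Otsu foreground + exact Euclidean distance transform); an external
predictor can be plugged in as long as it satisfies the distance-map
contract.  Instances are carved out of the distance map with a seeded
watershed and summarized into per-region feature records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

__all__ = [
    "RegionFeatures",
    "predict_distance_map",
    "watershed_instances",
    "semantic_argmax",
    "extract_features",
    "eccentricity_from_axes",
    "segment_instances",
    "FEATURE_COLUMNS",
]

#: column order of exported feature tables
FEATURE_COLUMNS = ["ID", "Area", "Eccentricity", "Mean intensity", "Major axis", "Minor axis"]


@dataclass
class RegionFeatures:
    """Per-instance shape and intensity record."""

    id: int
    area: float
    centroid: tuple[float, float]  # (x, y)
    eccentricity: float
    mean_intensity: float
    major_axis: float
    minor_axis: float


def eccentricity_from_axes(major: float, minor: float) -> float:
    """Eccentricity of the moment-equivalent ellipse: sqrt(1 - (minor/major)^2)."""
    if not 0 < minor <= major:
        raise ValueError(f"axes must satisfy 0 < minor <= major, got major={major}, minor={minor}")
    return math.sqrt(1.0 - (minor / major) ** 2)


def predict_distance_map(
    image: np.ndarray,
    predictor: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Per-pixel distance to the nearest background pixel.

    The classical default thresholds the image with Otsu and applies the
    exact Euclidean distance transform.  An external ``predictor`` is
    called with the image and must return a nonnegative raster of the
    same shape.
    """
    img = np.asarray(image, dtype=float)
    if predictor is not None:
        dmap = np.asarray(predictor(img), dtype=float)
        if dmap.shape != img.shape:
            raise ValueError(f"predictor output shape {dmap.shape} != image shape {img.shape}")
        if (dmap < 0).any():
            raise ValueError("predictor output must be nonnegative everywhere")
        return dmap
    if np.ptp(img) == 0:
        return np.zeros_like(img)
    fg = img > threshold_otsu(img)
    return ndi.distance_transform_edt(fg)


def _select_seeds(dmap: np.ndarray, h: float, min_seed_distance: float) -> list[tuple[int, int]]:
    """Deterministic seed points: h-maxima peaks, distance-suppressed.

    Each h-maxima plateau contributes its highest pixel (raster-order tie
    break); peaks are then accepted in descending height, skipping any
    closer than ``min_seed_distance`` to an accepted one.
    """
    peaks_mask = h_maxima(dmap, h)
    lab, n = ndi.label(peaks_mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return []
    cands = []
    for lb in range(1, n + 1):
        ys, xs = np.nonzero(lab == lb)
        k = int(np.argmax(dmap[ys, xs]))
        cands.append((float(dmap[ys[k], xs[k]]), int(ys[k]), int(xs[k])))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: list[tuple[int, int]] = []
    min_sq = min_seed_distance**2
    for _, y, x in cands:
        if all((y - ay) ** 2 + (x - ax) ** 2 >= min_sq for ay, ax in accepted):
            accepted.append((y, x))
    return accepted


def watershed_instances(
    dmap: np.ndarray,
    h: float = 1.0,
    min_seed_distance: float = 3.0,
) -> np.ndarray:
    """Seeded watershed on the inverted distance map, restricted to dmap > 0.

    Returns an instance map with labels 1..N (0 = background); zero seeds
    yield an all-zero map.
    """
    if h <= 0:
        raise ValueError("seed prominence h must be positive")
    dmap = np.asarray(dmap, dtype=float)
    seeds = _select_seeds(dmap, h, min_seed_distance)
    out = np.zeros(dmap.shape, dtype=np.int32)
    if not seeds:
        return out
    markers = np.zeros(dmap.shape, dtype=np.int32)
    for lb, (y, x) in enumerate(seeds, start=1):
        markers[y, x] = lb
    return watershed(-dmap, markers=markers, mask=dmap > 0, connectivity=1).astype(np.int32)


def semantic_argmax(score_stack: np.ndarray) -> np.ndarray:
    """Per-pixel class of maximal score; ties go to the lowest class index."""
    stack = np.asarray(score_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"expected a (n_classes >= 2, h, w) stack, got shape {stack.shape}")
    return np.argmax(stack, axis=0)


def extract_features(instances: np.ndarray, intensity: np.ndarray) -> list[RegionFeatures]:
    """One RegionFeatures record per instance label (Table-style schema)."""
    instances = np.asarray(instances)
    intensity = np.asarray(intensity, dtype=float)
    if instances.shape != intensity.shape:
        raise ValueError(
            f"instance map shape {instances.shape} != intensity shape {intensity.shape}"
        )
    feats = []
    for p in regionprops(instances, intensity_image=intensity):
        major, minor = p.axis_major_length, p.axis_minor_length
        ecc = eccentricity_from_axes(major, minor) if minor > 0 else 0.0
        cy, cx = p.centroid
        feats.append(
            RegionFeatures(
                id=int(p.label),
                area=float(p.area),
                centroid=(float(cx), float(cy)),
                eccentricity=float(ecc),
                mean_intensity=float(p.intensity_mean),
                major_axis=float(major),
                minor_axis=float(minor),
            )
        )
    return feats


def segment_instances(
    image: np.ndarray,
    predictor: Callable[[np.ndarray], np.ndarray] | None = None,
    h: float = 1.0,
    min_seed_distance: float = 3.0,
) -> tuple[np.ndarray, list[RegionFeatures]]:
    """Convenience chain: distance map -> watershed -> features."""
    dmap = predict_distance_map(image, predictor=predictor)
    inst = watershed_instances(dmap, h=h, min_seed_distance=min_seed_distance)
    return inst, extract_features(inst, np.asarray(image, dtype=float))


def features_to_frame(feats: list[RegionFeatures]):
    """Feature table in the exported CSV column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ID": f.id,
                "Area": f.area,
                "Eccentricity": f.eccentricity,
                "Mean intensity": f.mean_intensity,
                "Major axis": f.major_axis,
                "Minor axis": f.minor_axis,
            }
            for f in feats
        ],
        columns=FEATURE_COLUMNS,
    )
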
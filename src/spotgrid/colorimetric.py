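"""Colorimetric quantification: RGB scanner image -> per-spot scalar.

A registered colour transform scalarizes each pixel; per-spot values are
aggregated over the ROI disc mask; an optional calibration step fits a
monotone piecewise-linear map against known truth values and reports the
Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.color import rgb2hsv
from sklearn.isotonic import IsotonicRegression

from .models import SpotROI

__all__ = [
    "ColorTransform",
    "SpotQuantification",
    "CalibrationResult",
    "apply_transform",
    "quantify_spots",
    "calibrate",
    "TRANSFORMS",
]

LUMINANCE_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])
TRANSFORMS = ("luminance", "channel", "linear", "hue")
_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass
class ColorTransform:
    """Named RGB -> scalar transform.

    ``channel`` needs ``channel`` in {R, G, B}; ``linear`` needs finite
    ``weights`` (w_r, w_g, w_b).
    """

    name: str
    channel: str = "R"
    weights: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.name not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.name!r}; registry: {TRANSFORMS}")
        if self.name == "channel" and self.channel not in _CHANNEL_INDEX:
            raise ValueError(f"channel must be one of R, G, B, got {self.channel!r}")
        if self.name == "linear" and not np.all(np.isfinite(self.weights)):
            raise ValueError("linear weights must be finite")


@dataclass
class SpotQuantification:
    """Per-spot scalar metric; NaN marks missing spots."""

    values: np.ndarray  # (rows, cols), NaN = missing
    aggregator: str
    transform: str

    def long_form(self):
        import pandas as pd

        rows, cols = self.values.shape
        ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return pd.DataFrame(
            {"i": ii.ravel(), "j": jj.ravel(), "y_hat": self.values.ravel()}
        )


@dataclass
class CalibrationResult:
    pearson_r: float
    knots_x: np.ndarray  # quantification values (ascending)
    knots_y: np.ndarray  # calibrated values (monotone)
    n: int

    def apply(self, y_hat: np.ndarray) -> np.ndarray:
        """Evaluate the fitted monotone map (linear between knots, clamped)."""
        return np.interp(np.asarray(y_hat, dtype=float), self.knots_x, self.knots_y)


def apply_transform(rgb: np.ndarray, t: ColorTransform | str) -> np.ndarray:
    """Scalarize a 3-plane RGB raster with the named transform."""
    if isinstance(t, str):
        t = ColorTransform(name=t)
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[0] != 3:
        raise ValueError(f"expected a (3, h, w) RGB raster, got shape {rgb.shape}")
    if t.name == "luminance":
        return np.tensordot(LUMINANCE_WEIGHTS, rgb, axes=(0, 0))
    if t.name == "channel":
        return rgb[_CHANNEL_INDEX[t.channel]].copy()
    if t.name == "linear":
        return np.tensordot(np.asarray(t.weights, dtype=float), rgb, axes=(0, 0))
    # hue in degrees [0, 360)
    hsv = rgb2hsv(np.moveaxis(np.clip(rgb, 0.0, 1.0), 0, -1))
    return hsv[..., 0] * 360.0


def quantify_spots(
    scalar: np.ndarray,
    rois: list[SpotROI],
    aggregator: str = "median",
) -> SpotQuantification:
    """Aggregate the scalar raster over each ROI disc; empty masks -> NaN."""
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    agg = np.mean if aggregator == "mean" else np.median
    rows = 1 + max(r.grid_index[0] for r in rois)
    cols = 1 + max(r.grid_index[1] for r in rois)
    values = np.full((rows, cols), np.nan)
    for roi in rois:
        vals = roi.masked_values(np.asarray(scalar, dtype=float))
        if vals.size:
            values[roi.grid_index] = agg(vals)
    return SpotQuantification(values=values, aggregator=aggregator, transform="")


def calibrate(q: SpotQuantification | np.ndarray, truth: np.ndarray) -> CalibrationResult:
    """Pearson correlation plus monotone piecewise-linear calibration map.

    Fitted by isotonic regression of truth on quantification, direction
    chosen by the sign of the correlation.  Missing (NaN) pairs are
    excluded; fewer than 3 surviving pairs or zero truth variance is an
    error.
    """
    y_hat = (q.values if isinstance(q, SpotQuantification) else np.asarray(q, dtype=float)).ravel()
    y_true = np.asarray(truth, dtype=float).ravel()
    if y_hat.shape != y_true.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y_true.shape}")
    ok = np.isfinite(y_hat) & np.isfinite(y_true)
    y_hat, y_true = y_hat[ok], y_true[ok]
    if len(y_hat) < 3:
        raise ValueError(f"need at least 3 paired points, got {len(y_hat)}")
    if np.ptp(y_true) == 0 or np.ptp(y_hat) == 0:
        raise ValueError("zero variance in quantification or truth values")
    r = float(stats.pearsonr(y_hat, y_true).statistic)
    iso = IsotonicRegression(increasing=r >= 0, out_of_bounds="clip")
    iso.fit(y_hat, y_true)
    order = np.argsort(iso.X_thresholds_)
    return CalibrationResult(
        pearson_r=r,
        knots_x=np.asarray(iso.X_thresholds_)[order],
        knots_y=np.asarray(iso.y_thresholds_)[order],
        n=len(y_hat),
    )
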
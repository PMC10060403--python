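"""Shared geometric and tabular data types.

Coordinate convention used throughout the package: ``x`` is the column
index and ``y`` the row index, both 0-based with the origin at the centre
of the top-left pixel.  Rotations are expressed in degrees, counter-
clockwise positive in the (x, y) frame, and restricted to (-45, 45]
because a rectangular lattice is indistinguishable under 90-degree turns.
Bounding boxes are half-open pixel ranges.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

__all__ = [
    "GridModel",
    "SpotROI",
    "rotation_matrix",
    "fold_angle_deg",
]


def rotation_matrix(angle_deg: float) -> np.ndarray:
    """2x2 rotation matrix, counter-clockwise positive in the (x, y) frame."""
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[c, -s], [s, c]], dtype=float)


def fold_angle_deg(angle_deg: float) -> float:
    """Fold an angle modulo 90 degrees into the interval (-45, 45]."""
    a = (angle_deg + 45.0) % 90.0 - 45.0
    if a <= -45.0:
        a += 90.0
    return a


@dataclass
class GridModel:
    """Full parameterization of a rotated rectangular spot lattice.

    ``origin_x, origin_y`` is the centre of the element at grid index
    (row 0, col 0); ``pitch_x``/``pitch_y`` are the centre-to-centre
    distances along the grid axes; ``rotation_deg`` rotates the grid axes
    against the image axes.
    """

    rows: int
    cols: int
    origin_x: float
    origin_y: float
    pitch_x: float
    pitch_y: float
    rotation_deg: float
    spot_radius: float

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be positive")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("pitch_x and pitch_y must be positive")
        if self.spot_radius <= 0:
            raise ValueError("spot_radius must be positive")

    def center(self, i: int, j: int) -> tuple[float, float]:
        """Centre (x, y) of the element at grid index (row i, col j)."""
        R = rotation_matrix(self.rotation_deg)
        v = R @ np.array([j * self.pitch_x, i * self.pitch_y])
        return (self.origin_x + v[0], self.origin_y + v[1])

    def centers(self) -> np.ndarray:
        """All element centres as an (rows*cols, 2) array, row-major order."""
        jj, ii = np.meshgrid(np.arange(self.cols), np.arange(self.rows))
        offs = np.stack([jj.ravel() * self.pitch_x, ii.ravel() * self.pitch_y])
        R = rotation_matrix(self.rotation_deg)
        pts = (R @ offs).T + np.array([self.origin_x, self.origin_y])
        return pts

    def grid_index_of(self, x: float, y: float) -> tuple[int, int]:
        """Nearest grid index (i, j) for an image-frame point."""
        R = rotation_matrix(-self.rotation_deg)
        u = R @ np.array([x - self.origin_x, y - self.origin_y])
        j = int(round(u[0] / self.pitch_x))
        i = int(round(u[1] / self.pitch_y))
        return i, j

    def contains_point(self, x: float, y: float) -> bool:
        """True if (x, y) lies inside some spot disc of the lattice."""
        i, j = self.grid_index_of(x, y)
        if not (0 <= i < self.rows and 0 <= j < self.cols):
            return False
        cx, cy = self.center(i, j)
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.spot_radius**2

    def check_bounds(self, shape: tuple[int, int]) -> None:
        """Raise if any element centre falls outside an image of ``shape`` (h, w)."""
        h, w = shape
        pts = self.centers()
        bad = (pts[:, 0] < 0) | (pts[:, 0] > w - 1) | (pts[:, 1] < 0) | (pts[:, 1] > h - 1)
        if bad.any():
            k = int(np.flatnonzero(bad)[0])
            i, j = divmod(k, self.cols)
            raise ValueError(
                f"grid element ({i}, {j}) centre {tuple(pts[k])} lies outside "
                f"image of shape {shape}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridModel":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GridModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SpotROI:
    """One lattice element's region of interest.

    ``bbox`` is (x_min, y_min, x_max, y_max), half-open; ``mask`` is the
    boolean disc of the spot within the box.
    """

    grid_index: tuple[int, int]
    bbox: tuple[int, int, int, int]
    mask: np.ndarray = field(repr=False)
    center: tuple[float, float] = (0.0, 0.0)

    def extract(self, image: np.ndarray) -> np.ndarray:
        """Pixels of ``image`` within the box (2-D crop, not masked)."""
        x0, y0, x1, y1 = self.bbox
        return image[y0:y1, x0:x1]

    def masked_values(self, image: np.ndarray) -> np.ndarray:
        """1-D array of image values under the disc mask."""
        return self.extract(image)[self.mask]
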
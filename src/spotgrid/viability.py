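"""Live/dead fusion of per-channel instances into per-cell status.

Cells are anchored on the hoechst channel (total count).  Matching
between channels is mutual-nearest-neighbour on instance centroids with
a distance cap, resolved greedily in ascending distance.  A cell is
alive iff it is calcein-positive and pi-negative; cells positive for
both calcein and pi (faintly staining dying cells) count as dead, as do
hoechst-only cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import GridModel
from .segmentation import RegionFeatures

__all__ = [
    "ViabilityResult",
    "match_instances",
    "classify_cells",
    "compute_viability",
]

STATUS_COLUMNS = [
    "cell_id", "x", "y",
    "hoechst_positive", "calcein_positive", "pi_positive", "alive",
    "calcein_instance", "pi_instance",
]


@dataclass
class ViabilityResult:
    n_total: int
    n_alive: int
    viability: float | None  # None when n_total == 0 (undefined, not 0)
    per_spot: pd.DataFrame | None = None
    n_discarded: int = 0


def _centroids(feats: list[RegionFeatures]) -> np.ndarray:
    return np.array([f.centroid for f in feats], dtype=float).reshape(len(feats), 2)


def match_instances(
    anchor: list[RegionFeatures],
    other: list[RegionFeatures],
    max_match_distance: float,
) -> dict[int, int]:
    """One-to-one partial matching anchor index -> other index.

    Candidate pairs are mutual nearest neighbours by centroid distance;
    pairs farther apart than ``max_match_distance`` are discarded, the
    rest accepted greedily in ascending distance with each instance used
    at most once.  Deterministic under input order.
    """
    if max_match_distance <= 0:
        raise ValueError("max_match_distance must be positive")
    if not anchor or not other:
        return {}
    pa, pb = _centroids(anchor), _centroids(other)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    nn_a = np.argmin(d, axis=1)  # anchor -> nearest other
    nn_b = np.argmin(d, axis=0)  # other -> nearest anchor
    pairs = [
        (d[i, j], i, j)
        for i, j in enumerate(nn_a)
        if nn_b[j] == i and d[i, j] <= max_match_distance
    ]
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matching: dict[int, int] = {}
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        matching[i] = j
        used_a.add(i)
        used_b.add(j)
    return matching


def _default_cap(hoechst: list[RegionFeatures]) -> float:
    """Median hoechst equivalent diameter (fallback 10 px for empty input)."""
    if not hoechst:
        return 10.0
    return float(np.median([2.0 * math.sqrt(f.area / math.pi) for f in hoechst]))


def classify_cells(
    hoechst: list[RegionFeatures],
    calcein: list[RegionFeatures],
    pi: list[RegionFeatures],
    max_match_distance: float | None = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Per-cell staining status anchored on hoechst instances.

    Returns the cell status table plus a side list of calcein instance
    ids with no hoechst match (anomalies — reported, never counted).
    """
    cap = _default_cap(hoechst) if max_match_distance is None else max_match_distance
    m_cal = match_instances(hoechst, calcein, cap)
    m_pi = match_instances(hoechst, pi, cap)
    rows = []
    for i, f in enumerate(hoechst):
        cal = m_cal.get(i)
        pim = m_pi.get(i)
        calcein_pos = cal is not None
        pi_pos = pim is not None
        rows.append(
            {
                "cell_id": f.id,
                "x": f.centroid[0],
                "y": f.centroid[1],
                "hoechst_positive": True,
                "calcein_positive": calcein_pos,
                "pi_positive": pi_pos,
                "alive": calcein_pos and not pi_pos,
                "calcein_instance": calcein[cal].id if calcein_pos else pd.NA,
                "pi_instance": pi[pim].id if pi_pos else pd.NA,
            }
        )
    table = pd.DataFrame(rows, columns=STATUS_COLUMNS)
    matched_cal = set(m_cal.values())
    anomalies = [f.id for j, f in enumerate(calcein) if j not in matched_cal]
    return table, anomalies


def compute_viability(table: pd.DataFrame, grid: GridModel | None = None) -> ViabilityResult:
    """Counts and alive fraction; per-spot breakdown when a grid is given.

    Viability is ``n_alive / n_total``; with an empty table it is
    reported as undefined (None), never as 0.  With a grid, each cell is
    assigned to the spot disc containing its centroid; cells outside
    every spot go to a discard bucket.
    """
    n_total = len(table)
    n_alive = int(table["alive"].sum()) if n_total else 0
    viability = n_alive / n_total if n_total > 0 else None
    per_spot = None
    n_disc = 0
    if grid is not None and n_total:
        buckets: dict[tuple[int, int], list[bool]] = {}
        for _, row in table.iterrows():
            x, y = float(row["x"]), float(row["y"])
            if grid.contains_point(x, y):
                buckets.setdefault(grid.grid_index_of(x, y), []).append(bool(row["alive"]))
            else:
                n_disc += 1
        per_spot = pd.DataFrame(
            [
                {
                    "row": i,
                    "col": j,
                    "n_total": len(v),
                    "n_alive": int(sum(v)),
                    "viability": sum(v) / len(v),
                }
                for (i, j), v in sorted(buckets.items())
            ],
            columns=["row", "col", "n_total", "n_alive", "viability"],
        )
    return ViabilityResult(
        n_total=n_total,
        n_alive=n_alive,
        viability=viability,
        per_spot=per_spot,
        n_discarded=n_disc,
    )
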
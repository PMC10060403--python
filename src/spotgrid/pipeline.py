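"""Top-level pipeline binding grid detection to the per-spot stages.

``run_pipeline`` consumes a resolved configuration plus named inputs and
writes a result bundle: grid JSON, feature / status / quantification
CSVs and a run log with the resolved configuration.  Stage failures on
individual spots are recorded and do not abort the run.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colorimetric import ColorTransform, apply_transform, calibrate, quantify_spots
from .config import dump_config
from .grid import detect_grid, extract_rois
from .io import read_image, write_labels
from .models import GridModel
from .segmentation import features_to_frame, segment_instances
from .viability import classify_cells, compute_viability

__all__ = ["run_pipeline"]


def _load_grid(config: dict, inputs: dict, reference_image: np.ndarray) -> GridModel:
    if "grid_json" in inputs:
        return GridModel.from_json(inputs["grid_json"])
    if "grid_image" in inputs:
        g = config["grid"]
        img = read_image(inputs["grid_image"]).data
        expected = g["expected_shape"]
        return detect_grid(
            img,
            expected_shape=tuple(expected) if expected else None,
            p_low=g["p_low"],
            p_high=g["p_high"],
            method=g["method"],
            q=g["percentile_q"],
            open_radius=g["open_radius"],
            area_band=tuple(g["area_band"]),
        )
    raise ValueError("inputs must provide either 'grid_json' or 'grid_image'")


def _as_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def run_pipeline(config: dict, inputs: dict) -> dict:
    """Execute the configured stages; returns a manifest of written files.

    ``inputs`` maps names to paths or in-memory arrays:
    ``grid_image`` or ``grid_json`` (geometry), ``hoechst``/``calcein``/
    ``pi`` (viability stage), ``rgb`` (+ optional ``truth_csv``,
    colorimetric stage).
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": [], "failures": []}

    def _input_array(key: str) -> np.ndarray:
        val = inputs[key]
        if isinstance(val, (str, Path)):
            return _as_float(read_image(val).data)
        return _as_float(val)

    reference = None
    for key in ("hoechst", "rgb", "grid_image"):
        if key in inputs:
            arr = _input_array(key)
            reference = arr[0] if (key == "rgb" and arr.ndim == 3) else arr
            break
    if reference is None:
        raise ValueError("no image inputs given")

    grid = _load_grid(config, inputs, reference)
    grid_path = out_dir / "grid.json"
    grid.to_json(grid_path)
    manifest["outputs"].append(str(grid_path))

    if all(k in inputs for k in ("hoechst", "calcein", "pi")):
        seg = config["segmentation"]
        feats = {}
        for name in ("hoechst", "calcein", "pi"):
            img = _input_array(name)
            try:
                inst, f = segment_instances(
                    img, h=seg["h"], min_seed_distance=seg["min_seed_distance"]
                )
            except Exception as exc:  # pragma: no cover - defensive
                manifest["failures"].append({"stage": f"segment:{name}", "error": str(exc)})
                continue
            feats[name] = f
            write_labels(out_dir / f"instances_{name}.tif", inst)
            features_to_frame(f).to_csv(out_dir / f"features_{name}.csv", index=False)
            manifest["outputs"] += [
                str(out_dir / f"instances_{name}.tif"),
                str(out_dir / f"features_{name}.csv"),
            ]
        if len(feats) == 3:
            table, anomalies = classify_cells(
                feats["hoechst"], feats["calcein"], feats["pi"],
                max_match_distance=config["viability"]["max_match_distance"],
            )
            result = compute_viability(table, grid=grid)
            table.to_csv(out_dir / "cell_status.csv", index=False)
            summary = {
                "n_total": result.n_total,
                "n_alive": result.n_alive,
                "viability": result.viability,
                "n_discarded": result.n_discarded,
                "calcein_anomalies": anomalies,
            }
            with open(out_dir / "viability.json", "w") as fh:
                json.dump(summary, fh, indent=2)
            manifest["outputs"] += [str(out_dir / "cell_status.csv"), str(out_dir / "viability.json")]
            if result.per_spot is not None:
                result.per_spot.to_csv(out_dir / "viability_per_spot.csv", index=False)
                manifest["outputs"].append(str(out_dir / "viability_per_spot.csv"))

    if "rgb" in inputs:
        c = config["colorimetric"]
        rgb = _input_array("rgb")
        transform = ColorTransform(
            name=c["transform"], channel=c["channel"], weights=tuple(c["weights"])
        )
        scalar = apply_transform(rgb, transform)
        rois = extract_rois(scalar, grid)
        q = quantify_spots(scalar, rois, aggregator=c["aggregator"])
        q.transform = c["transform"]
        pd.DataFrame(q.values).to_csv(out_dir / "quantification_matrix.csv", index=False)
        q.long_form().to_csv(out_dir / "quantification.csv", index=False)
        manifest["outputs"] += [
            str(out_dir / "quantification_matrix.csv"),
            str(out_dir / "quantification.csv"),
        ]
        if "truth_csv" in inputs:
            truth = np.loadtxt(inputs["truth_csv"], delimiter=",", ndmin=2)
            cal = calibrate(q, truth)
            with open(out_dir / "calibration.json", "w") as fh:
                json.dump(
                    {
                        "pearson_r": cal.pearson_r,
                        "knots_x": cal.knots_x.tolist(),
                        "knots_y": cal.knots_y.tolist(),
                        "n": cal.n,
                    },
                    fh,
                    indent=2,
                )
            manifest["outputs"].append(str(out_dir / "calibration.json"))

    dump_config(config, out_dir / "resolved_config.yaml")
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(
            {
                "version": __version__,
                "python": sys.version.split()[0],
                "seed": config["seed"],
                "manifest": manifest,
            },
            fh,
            indent=2,
        )
    manifest["outputs"] += [str(out_dir / "resolved_config.yaml"), str(out_dir / "run_log.json")]
    return manifest
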
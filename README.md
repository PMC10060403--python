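# spotgrid

Image analysis for grid-structured high-throughput screens (droplet
microarrays, well plates): automated grid geometry estimation, spot-wise
instance segmentation with feature extraction, three-channel live/dead
viability fusion (hoechst / calcein / pi), colorimetric quantification of
RGB scanner images, and assisted-annotation support — all exercisable on
a built-in synthetic scene generator with exact ground truth.

## Layout

| Module | Purpose |
| --- | --- |
| `spotgrid.synthetic` | Grid, cell and colorimetric scene generators with planted truth |
| `spotgrid.grid` | Preprocess → segment → post-process → rotation → robust lattice fit; semi-automated completion; ROI extraction |
| `spotgrid.segmentation` | Distance-map prediction (classical default or pluggable), seeded watershed, semantic argmax, per-region features |
| `spotgrid.viability` | Mutual-NN channel matching, per-cell status fusion, viability fractions |
| `spotgrid.colorimetric` | RGB → scalar transforms, per-spot aggregation, isotonic calibration |
| `spotgrid.annotation` | Embedding + PCA + farthest-point selection ordering, classical pre-annotation, Dice and assignment-based AJI metrics |
| `spotgrid.io` / `spotgrid.config` / `spotgrid.pipeline` / `spotgrid.cli` | TIFF/PNG I/O, YAML config, full pipeline, CLI |

Learned predictors (segmentation scorers, distance-map networks, image
embedders) are *pluggable contracts* with classical defaults (Otsu,
Euclidean distance transform, histogram/moment/edge descriptors); no
network weights are shipped.

## CLI

```bash
spotgrid simulate grid --seed 1 --out sim/            # synthetic scene + truth
spotgrid detect-grid sim/grid.tif --expected-shape 4x6 --out det/
spotgrid segment image.tif --out seg/
spotgrid viability --hoechst h.tif --calcein c.tif --pi p.tif --grid grid.json --out via/
spotgrid colorimetric scan.png --grid grid.json --transform channel --truth truth.csv --out col/
spotgrid select --images imgs/ --out order.csv
spotgrid preannotate image.tif --method otsu --out mask.png
spotgrid score --truth t.tif --pred p.tif --metric ajiplus
spotgrid run --config cfg.yaml --grid-json grid.json --hoechst h.tif --calcein c.tif --pi p.tif --out out/
```

Conventions: `x` = column, `y` = row, 0-based, origin at the top-left
pixel centre; rotations counter-clockwise positive in the (x, y) frame,
restricted to (−45°, 45°]; bounding boxes half-open. Grid models are
JSON; feature/status tables are CSV; label maps are 16-bit TIFF.

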
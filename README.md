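# artefactscan

Image-based condition analysis for large-format paintings, in two parts:

1. **Deterioration pattern matching** — normalized correlation-coefficient
   template matching locates copies of a small reference pattern (e.g. a
   suspected microbial colonization mark cut from a UV-fluorescence
   photograph) inside a much larger scene image. Includes threshold sweeps
   with knee selection (the last stable threshold before the detection count
   jumps drastically), grouping of above-threshold pixels into detected
   areas, grid/subcell naming of hit locations (labels like `63C3`), box
   overlays, and a sampling-efficiency score
   (`100 · positives / detected areas`).
2. **Pigment-crystal arrangement** — colour-class segmentation (HSV gates)
   of pigment crystals on tiled cross-section micrographs, overlap-aware
   deduplication across stage-stepped tiles, and same-/cross-colour
   inter-crystal distance statistics (nearest-neighbour or all-pairs, with
   histograms and per-colour densities).

A light companion module summarizes environmental station logs (means,
diurnal extrema clock hours) and converts volumetric spore-trap counts to
spores/m³. Seeded synthetic generators (`artefactscan.synth`) produce every
input with machine-readable ground truth, so the whole toolkit is testable
offline.

## CLI

```bash
# generate a synthetic scene with planted patterns
artefactscan synth scene --recipe scene.json --out demo/

# locate the pattern, write a CSV report and an annotated overlay
artefactscan detect --scene demo/scene.png --template demo/tpl0.png \
    --threshold 0.675 --grid 10x10 --out report.csv --overlay overlay.png

# threshold sweep with knee selection
artefactscan sweep --scene demo/scene.png --template demo/tpl0.png \
    --lo 0.40 --hi 0.95 --step 0.01 --jump-factor 6

# crystal mosaic: generate, then analyze
artefactscan synth mosaic --recipe mosaic.json --out tiles/
artefactscan crystals --mosaic-dir tiles/ --mode nearest \
    --out stats.json --crystals-csv crystals.csv --hist hist.csv

# station logs and spore counts
artefactscan synth log --recipe log.json --out logdir/
artefactscan env summarize --log logdir/log.csv
artefactscan env spores --count 150 --flow 10 --duration 15
```

Recipe JSON schemas (all fields optional unless noted):

- scene: `{"seed": int (required), "size": [M, N], "templates":
  [{"id": str, "seed": int, "shape": [m, n]} | {"id": str, "path": "t.png"}],
  "k_plants": [int, ...], "noise_sd": float, "brightness_jitter": [lo, hi],
  "contrast_jitter": [lo, hi], "background": "flat"|"blotch"}`
- mosaic: `{"seed": int (required), "layout": [rows, cols], "tile_px":
  [h, w], "scale": px_per_um, "overlap_frac": [fy, fx], "class_intensity":
  {"blue": per_um2, ...}, "min_sep_um": float, "radius_um": [lo, hi]}`
- log: `{"seed": int (required), "days": int, "means": {...},
  "amplitudes": {...}, "peak_hours": {...}, "noise_sd": float}`

Each `synth` command writes a `truth.json` next to its outputs (plant
anchors; global crystal centroids, colours and observing tiles; configured
means and peak hours), sufficient to score recall and distance recovery
without re-reading the images.

## Conventions

- Pixel coordinates are 0-based `(row, col)` from the top-left; boxes are
  half-open. Grayscale conversion uses BT.601 luma weights.
- Correlation scores lie in [-1, +1]; windows with zero variance carry a
  sentinel score of 0 and a flag. Matching is same-size, same-orientation
  only.
- Tile-local points map to global micrometres via
  `tile origin (µm) + local_px / scale`, with
  `step = extent · (1 − overlap)` per axis.

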
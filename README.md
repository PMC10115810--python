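# histoquant

A quantification toolkit for whole-section immunofluorescence imaging of
kidney (and similar) tissue. It covers the classic, non-deep-learning half
of a section-analysis pipeline and treats deep-learning segmentations as
plain mask files from any external segmenter:

* **Calibrated I/O** — single-channel TIFF rasters with a μm/pixel scale,
  binary masks (0/255 TIFF), region outlines (GeoJSON polygons in μm),
  point sets (CSV `x_um,y_um[,area_um2]`), QC montages.
* **Preprocessing** — rolling-ball background subtraction (grayscale
  opening with a ball-shaped structuring element, default radius 50 px;
  exact for small radii, shrink-and-enlarge approximation for large ones)
  and block-mean downsampling.
* **Classic segmentation** — five histogram auto-threshold methods
  (`default_isodata`, `otsu`, `triangle`, `mean`, `li`) computed on a
  256-bin histogram, whole-section or per-ROI, plus a random-forest pixel
  classifier over a multi-scale filter bank (Gaussian, LoG, gradient
  magnitude, structure-tensor eigenvalues at σ ∈ {0.7, 1.0, 1.6, 3.5, 5.0}).
* **Nucleus detection** — fill holes → distance-transform watershed →
  particle filtering at a minimum area of 9 μm² (inclusive), emitting
  centroids in μm.
* **Validation** — seeded validation-ROI sampling with inclusion rules
  (membrane: positive area fraction in [0.1, 0.9]; nuclear: ≥ 5 reference
  nuclei), pixel confusion metrics (sensitivity, specificity, Dice =
  2·TP/((TP+FP)+(TP+FN))), one-to-one point matching within 5 μm
  (globally nearest pair first), detection Dice, and observer-comparison
  tables with median/IQR summaries. Degenerate 0/0 metrics are reported
  as missing, never as 0.
* **Quantification** — region-restricted area fraction, detections per
  mm², mask intersection-over-union, structure counting.
* **Spatial analysis** — circular-mean density heatmaps (default 200 μm
  radius), hexagonal close-packed circle tiling of a region outline,
  per-tile paired density tables, and Pearson correlation.
* **Synthetic scenes** — a seeded generator producing section-shaped
  regions with tubule/nucleus objects, membrane/nuclear/structure stain
  patterns, additive smooth background and noise, and paired channels
  whose tile-level densities correlate at a controllable ρ — so the whole
  pipeline is testable without any real slide.

## Tests

```sh
pytest tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (oracle agreements, detection recovery, tiling geometry,
correlation recovery, resolution robustness, determinism). Brute-force
oracles live in `tests/oracles.py` and are independent of the library code
paths they check.

## CLI

```sh
histoquant preprocess --radius-px 50 --scale 0.5 section.tif subtracted.tif
histoquant threshold --method triangle --scale 0.5 subtracted.tif mask.tif
histoquant detect --min-area-um2 9 --scale 0.5 mask.tif points.csv
histoquant validate --stain-class nuclear --radius-um 5 ref.csv comp.csv report.csv
histoquant quantify --region cortex_osom.geojson --metric area_fraction --scale 0.5 mask.tif summary.csv
histoquant heatmap --radius-um 200 --region cortex_osom.geojson --scale 0.5 mask.tif heat.tif
histoquant tiles --radius-um 200 cortex_osom.geojson tiles.csv
histoquant correlate tile_table.csv correlation.csv
histoquant synth --spec scene.yaml --seed 1 --out scene_dir/
histoquant batch config.yaml
```

`batch` runs preprocess → threshold → region metrics over a directory of
section TIFFs, writes one summary row per section, a QC montage, and a
reproducibility manifest (config + input checksums); per-section failures
are logged without aborting the batch and reflected in the exit status.

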
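# cytomorph

Laminar morphometry of Nissl-stained cerebral cortex: segmentation of
neuron somata from calibrated section images by local space-varying
thresholding, per-cell morphometric descriptors, and layer × hemisphere
statistics for cytoarchitectonic asymmetry studies.

## What it does

Quantitative cytoarchitecture asks whether the cellular make-up of a
cortical area — soma size, shape and packing — differs between cortical
layers and between hemispheres. `cytomorph` implements that analysis as a
reproducible pipeline:

1. **Segmentation.** Nissl staining renders somata dark on a light
   background, but illumination gradients and regional stain density defeat
   a global threshold. A smooth local background is estimated by Gaussian
   smoothing at a scale σ well above the soma diameter; a pixel is
   foreground when its intensity I satisfies `I < B(x, y) − t` for local
   background B and offset t. Connected components are extracted per
   cortical layer (an expert-provided layer map assigns pixels to L1–L6,
   background, or excluded vessels) and gated to the soma size range
   **[25, 400] μm²**, removing glial specks below and staining artifacts
   above.
2. **Morphometry.** Per cell: area (μm²), perimeter (μm, Crofton
   multi-direction estimate), major/minor axis lengths of the
   moments-equivalent ellipse (μm), aspect ratio `AR = major / minor ≥ 1`,
   and surface density — the number of neighbouring somata within a 50 μm
   radius of the cell's centroid.
3. **Statistics.** For each response Y ∈ {area, perimeter, AR, density}:
   group summaries (n, mean, SEM, Q1, Q3) per layer, per side and per
   layer × side, one-way F tests per factor, and the two-factor model

   `Y_ijk = μ + τ_i + β_j + (τβ)_ij + ε_ijk,  ε ~ N(0, σ²)`

   with τ the layer (6 levels), β the hemisphere side (2 levels) and (τβ)
   the 12 layer–side interactions (Type II sums of squares by default).
4. **Synthetic histology.** A seeded generator renders Nissl-like sections
   — six laminar bands of non-overlapping dark ellipses with per-layer,
   per-side lognormal area laws, plus specks, artifacts, vessels, an
   illumination gradient and noise — with exact ground truth, so every
   stage is verifiable without proprietary slide data. Its defaults
   reproduce published layer-by-side group means for chimpanzee area 44
   (e.g. L2 soma area 77.5 μm² left vs 93.8 μm² right).

## Worked example

```python
import cytomorph as cm

cfg = cm.default_config(seed=1)                      # published group means
image, layer_map, truth = cm.generate_section(cfg, "left")
cells = cm.segment_cells(image, layer_map, cm.SegmentationParams())
table = cm.build_morphometry_table(cells)
rep = cm.match_detections(truth, table, tol=5.0)
print(f"{len(table)} cells, precision {rep.precision:.3f}, "
      f"recall {rep.recall:.3f}, median area error "
      f"{100 * rep.median_abs_area_error:.2f}%")

bundle = cm.run_full_analysis(table)                 # one section => layer tests
print(f"area layer effect: F = {bundle.one_way['area']['layer'].f:.1f}, "
      f"p = {bundle.one_way['area']['layer'].p:.3g}")
```

prints (exact cell counts vary with the seed):

```
1611 cells, precision 1.000, recall 0.982, median area error 0.41%
area layer effect: F = 16.3, p = 1.05e-15
```

1611 of 1640 generated somata are recovered with no false detections and
sub-percent area error; the one-way layer effect on soma area is strongly
significant, reflecting the configured contrast between the large-celled
pyramidal layers (L3, L5, L6) and the smaller granular layers.

With both hemispheres pooled into one table, `run_full_analysis` adds the
side main effect and the layer × side interaction for all four responses;
`cytomorph.plots.render_figures` writes the per-layer boxplots, main-effect
and interaction plots, with the plotted values emitted as CSV beside each
image.

## Command line

```
cytomorph synth   --config pipeline.yaml          # render a cohort + truth
cytomorph segment --config pipeline.yaml          # component label rasters
cytomorph measure --config pipeline.yaml          # per-section + cohort CSVs
cytomorph analyze --config pipeline.yaml          # summaries + ANOVA JSON
cytomorph report  --config pipeline.yaml          # figures + value CSVs
cytomorph all     --config pipeline.yaml          # everything above
```

Stages compose: running them separately is byte-identical to `all`. Every
output carries the configuration hash and master seed.

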
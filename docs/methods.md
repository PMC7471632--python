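# Methods

## Problem and model

The package quantifies laminar cytoarchitecture from calibrated grayscale
images of Nissl-stained cortex. Somata take up the basic stain and appear
dark on a light background; a per-pixel layer map (produced upstream by
expert delineation, or by the synthetic generator) assigns each pixel to
one of the six cortical layers, to background, or to an excluded region
such as a blood vessel. The analysis chain is: per-layer soma segmentation
→ per-cell descriptors → two-factor statistics (layer × hemisphere side).

### Segmentation

A single global threshold fails on stained sections because illumination
and stain density vary smoothly across the field. The segmenter estimates a
local background B by Gaussian smoothing of the intensity image at a
physical scale `background_scale` (default 25 μm, converted to pixels
through the calibration; reflective boundaries; kernel truncated at 3σ so
affine intensity fields are preserved exactly away from borders). A pixel
is foreground iff `I < B − threshold_offset` (strict inequality; default
offset 0.2 on the [0, 1] intensity scale, roughly half the soma/background
contrast and ≈ 7 noise standard deviations, so both miss and
false-positive rates are negligible). The same procedure runs
independently inside each layer's pixel region — the background of a layer
is estimated from that layer's own pixels by normalized convolution — so
dense and sparse layers each get a locally adapted background, and
excluded pixels can never become foreground. A median-filter background
estimator is available as an alternative.

Connected components (8-connectivity by default; labels assigned in
row-major order of each component's first pixel, so labeling is fully
deterministic) are gated by physical area to the inclusive range
**[25, 400] μm²**: smaller particles are glial nuclei or debris, larger
ones staining artifacts or fused clumps. Components touching the image
border are retained but flagged `on_border`.

### Descriptors

* **Area** = pixel count × mpp².
* **Perimeter**: Crofton 4-direction boundary estimate × mpp (less biased
  than edge counting on rasterized shapes).
* **Axes**: the ellipse with the same normalized second central moments as
  the pixel region (standard region-properties convention). The
  minimum-area enclosing ellipse (Khachiyan's algorithm) is exposed via
  `ellipse="enclosing"` as the stricter geometric reading of an ellipse
  "fitting" the cell; the moments convention is the default because it is
  robust to single-pixel boundary noise. Degenerate regions (zero minor
  axis) are floored at one pixel-equivalent and flagged.
* **AR** = major/minor ≥ 1.
* **Density**: number of other somata whose centroid lies within 50 μm
  (boundary inclusive) of the cell's centroid, counted over all retained
  cells of the section regardless of layer (`density_within_layer=True`
  restricts it). No edge correction is applied; cells within 50 μm of the
  field border are flagged `edge_flag`.

Area and perimeter scale exactly as mpp² and mpp under calibration change;
AR is invariant.

### Statistics

For each response Y ∈ {area, perimeter, AR, density} on the pooled cell
table: per-layer, per-side and per-layer-and-side summaries (n, mean,
SEM = s/√n with ddof = 1, Q1/Q3 by linear interpolation between order
statistics); one-way F tests for layer and for side (textbook
between/within decomposition; zero within-group variance is reported as a
degenerate result, not an exception); and the full factorial model
`Y_ijk = μ + τ_i + β_j + (τβ)_ij + ε_ijk` fitted by OLS with F tests per
effect. Because segmentation yields unequal cell counts per design cell,
**Type II** sums of squares are the default (order-invariant, no contrast
dependence); Type III with sum-to-zero contrasts is available. The
observational unit is the individual cell; the specimen id is carried on
every record, and cell-level inference pseudoreplicates specimens — a
caveat inherited from the study design this pipeline reproduces, reported
rather than silently corrected. Single-side tables skip the side and
interaction tests with an explicit notice; empty design cells raise a
named error.

## Synthetic sections

The generator's purpose is verifiability: every stage of the pipeline can
be tested against exact ground truth.

* **Cell law.** Soma area is lognormal (positive support, right skew, as
  observed in segmented soma populations), parameterized by the
  natural-scale mean and CV. Elongation is `AR = 1 + Gamma(shape 4)` with
  mean `ar_mean`. An ellipse with the sampled area, AR and a uniform
  orientation is rasterized as a hard mask (no anti-aliasing), so the true
  pixel area is countable.
* **Placement.** Non-overlapping by rejection sampling against an
  occupancy raster with a minimum boundary gap (default 1.5 μm), so
  rendered somata never merge into one component; an `allow_overlap` mode
  exists to exercise clumped tissue. Cells are placed wholly inside their
  layer band — a stronger condition than the centroid rule, chosen because
  per-layer segmentation would split a straddling cell. Per-layer counts
  are Poisson at the configured areal density over the band.
* **Nuisance structure.** Glial specks (6–20 μm²), large artifacts
  (500–1500 μm²) and vessels (2000–6000 μm², labeled excluded) are
  rendered dark like somata, so only the particle gate (or the exclusion
  mask) removes them; a diagonal linear illumination gradient (default
  amplitude 0.1) defeats any global threshold; additive Gaussian noise
  (default SD 0.03) is clipped to [0, 1].
* **Defaults as study conditions.** The 12 layer × side soma-area means,
  the neighbour-count densities (converted to areal density by
  λ = d / (π · 50²)) and the mean ARs are the published group values for
  chimpanzee area 44. Area CVs are not published; they were fixed once at
  0.55 (granular layers) / 0.65 (pyramidal layers), the values that
  reproduce the published interquartile ratios of gated soma areas.
  Calibration is 0.5 μm/px (a 20× slide scan); band thicknesses
  (220/180/620/150/420/500 μm) give a realistic ~2.1 mm cortical depth.
* **Seeds.** One master seed; the per-section generator state is
  `SeedSequence([seed, side])`, and cohorts derive per-specimen,
  per-replicate seeds as `SeedSequence([master, specimen, replicate])` —
  identical configuration and seed give bit-identical images and tables.
  Sections-per-hemisphere replication is a free parameter.

What the generator does **not** emulate: overlapping/clumped somata under
the default settings, within-layer density gradients, non-elliptical soma
shapes, staining variation between sections, and scanner optics. Passing
tests therefore demonstrate correctness of the measurement and inference
machinery under a faithful statistical model of laminar tissue, not
photorealistic robustness; on real slides the segmentation parameters
(scale, offset, gate) remain the operator's responsibility.

`simulate_table` samples descriptor tables directly from the generative
laws (no rendering) for statistical calibration and power work; its
`family="normal"` option draws Gaussian rather than lognormal areas so
that type-I calibration of the F tests is performed under the model's own
normal-error assumption, where p-values are exactly uniform. Perimeters in
simulated tables are Ramanujan ellipse perimeters with 2% multiplicative
jitter; densities are Poisson at the configured neighbour mean.

## Validation harness

`match_detections` matches detected to true cells by greedy
nearest-centroid one-to-one assignment within a tolerance (5 μm in all
shipped checks), reporting precision, recall, per-cell area error, and the
unmatched lists; precision is flagged undefined when nothing was detected.
Independent oracles used in the test suite: a brute-force O(n²) distance
matrix for neighbour counts, BFS flood fill for connected components, the
closed-form balanced two-way ANOVA for the statsmodels-based fit, and
`scipy.stats.f_oneway` for the one-way implementation.

## Problem sizes and numerical choices

The shipped checks run at desk scale by design: segmentation fidelity is
measured on full default sections (~1600–1700 cells each, ≈ 15 s each);
type-I calibration uses 1000 simulated tables of 240 cells (20 per design
cell); the asymmetry-recovery study simulates 100 cohorts of 20,000 cells
per side — the scale of the original tables, whose reported SEMs (~0.5 μm²)
imply thousands of cells per design cell. At exactly 2,000 cells per side
the interaction test has only a few percent power at p < 0.001 under the
realistic area dispersion, which is itself an informative property of the
design. Tolerances: geometric recovery of rendered 20 × 10 μm ellipse axes
is within 5% (rasterization at 0.5 μm/px); rendered-circle AR ≤ 1.05;
closed-form ANOVA agreement to 1e-8 relative; the sum-of-squares identity
to 1e-8 relative on balanced designs.

## Known limitations

* Touching somata are not split (no watershed); the default generator's
  non-overlap gap makes this moot synthetically, but clumped real tissue
  will fuse cells into components that the upper gate then discards.
* Density counts are truncated near section borders (flagged, not
  corrected).
* Cell-level ANOVA pseudoreplicates specimens; a specimen-stratified
  resampling analysis would be the conservative alternative.
* The 8-bit image writer quantizes intensities; analyses in memory use
  float pixels throughout.
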
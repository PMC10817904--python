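# Methods

## Problem and model

The package measures epidermal thickness (ET) in cross-sectional skin OCT
images (B-scans: rows = axial depth, columns = lateral position) by
delineating two boundaries: the stratum corneum (SC), i.e. the bright
air/skin interface, and the lower-contrast dermal–epidermal junction (DEJ).
ET is the per-column row distance DEJ − SC, converted to micrometres by the
axial pixel pitch.

Segmentation is a two-stage hybrid:

1. **Patch classification.** Every pixel of a cropped target region owns a
   centered square patch (default 55×55 px, reflect-padded at borders). A
   compact CNN classifies the patch by its *center pixel* into
   {0: non-boundary, 1: SC, 2: DEJ}; the softmax outputs, scattered back
   onto the grid, form per-class probability maps. Training patches are
   labeled by the same center-pixel rule from reference traces and
   class-balanced by seeded subsampling to the minority-class count
   (three-way; the immediate neighbours of a boundary are non-boundary
   patches, so the negatives include hard examples by construction).
2. **Graph search.** Each probability map becomes an 8-connected pixel
   graph; the edge joining pixels with probabilities `P_c`, `P_n` has weight
   `w = 2 − (P_c + P_n) + w_min` with `w_min = 1e-5` keeping all weights
   strictly positive. An all-probability-1 column is appended on each side
   (automatic endpoint initialization): the minimum-cost corner-to-corner
   path slides along these columns at cost `w_min` per step, crosses the
   interior along the boundary ridge, and the added columns are stripped
   afterwards. The search is deliberately unconstrained — no monotone-column
   restriction and no band restriction between boundaries; SC and DEJ are
   searched independently on their own maps.

## Architecture family and exact parameter counting

The classifier family is fixed: three convolution (stride 1) + pooling
blocks, then two fully connected layers with ReLU, dropout (0.1) after FC1,
and a 4-unit softmax output (class 3 is reserved and never positive; it
exists because the output layer is 4 wide in both shipped presets, and
keeping it makes the parameter accounting exact). Everything else is
configuration. `count_parameters` is closed-form:

```
Σ_conv (k² · c_in + 1) · c_out  +  (flat + 1) · fc1  +  (fc1 + 1) · n_out
```

with `flat` obtained by propagating spatial sizes. Pooling output size on
unpadded input is `round((n − k)/s) + 1` where `round` is **floor or ceil
per layer**: the lean `cnn-gs-skin` preset (3×3 valid convs, filters
8/16/16, 2×2 stride-2 floor pooling) propagates 55→53→26→24→12→10→5
(flatten 400, FC1 32; 16,532 parameters), while `cnn-gs-baseline` (5×5
convs, filters 32/32/64, pooling 2×2/3×3/3×3 stride 2 with ceil rounding)
propagates 55→51→26→22→11→7→3 (flatten 576, FC1 64; 114,916 parameters).
Ceil-rounded windows are clipped at the border and averages divide by the
number of real elements. The two presets genuinely use different rounding
conventions; both are per-layer config fields rather than globals for this
reason.

## Training

Categorical cross-entropy with one-hot 4-class targets, RMSprop
(lr 1e-3, ρ 0.9, ε 1e-7), batch size 512, early stopping on validation loss
(patience 5, best-validation weights restored). A KL-divergence loss option
exists; for one-hot targets its value and gradient coincide with
cross-entropy, so it is an interface alternative rather than a numerical
one. The CNN engine (im2col convolutions, pooling with the rounding
conventions above, inverted dropout) is written in numpy with explicit
backward passes; all randomness (weight init, shuffling, dropout,
subsampling) flows through seeded `numpy.random.Generator` instances, so
identical seeds and data reproduce training bit-for-bit in single-threaded
arithmetic.

## Preprocessing

Min–max normalization to [0, 1] (rejecting constant images), non-local
means despeckling (patch 7, search window 21, strength 0.8·σ̂ with σ̂
estimated from the image), then air/SC detection: per column, the first row
whose downward intensity gradient exceeds `median + 3σ` of that column's
gradient, median-filtered over columns (window 9). The threshold is
adaptive per column, making detection invariant to affine intensity
rescaling. The target region spans `min(trace) − margin_above` to
`max(trace) + depth_below` (defaults 10 and 300 rows; 300 rows ≈ 980 µm at
3.26 µm/px covers the epidermis at all body sites). Normalization happens
before air-region removal; coordinates are 0-based with half-open row bands,
and `TargetRegion` records the offset so region↔parent row mapping is exact.

## Pixel skipping and infill

The inference patchset takes every s-th pixel of the *flattened* region in
row-major raster order — so the patchset size is exactly ⌈N/s⌉ (half at
step 2, a quarter at step 4), not the 1/s² a 2-D grid stride would give —
and the evaluated pixels interleave diagonally across rows. After
classification, each unevaluated pixel receives, per class, the mean of its
*evaluated* 4-neighbors (plus-shaped kernel); pixels with no evaluated
4-neighbor keep probability 0 (impossible at steps ≤ 4). The pass is single
and non-iterative — filled values never feed later fills — so the result is
order-independent, and no additional patches are ever classified. An
optional refinement pass (classify real patches where a neighbor's boundary
probability exceeds a threshold) exists in concept but is not enabled: the
quarter-size patchset is exactly ⌈N/4⌉ without it.

## Graph search details

The adjacency structure is a scipy CSR matrix — an adjacency list in sparse
form (a dense matrix over a 460×1500-pixel graph would need ~2×10¹¹
entries). The distance field is computed with `scipy.sparse.csgraph.dijkstra`;
the path is reconstructed backward from the end node, at each step keeping
the neighbors `u` with `dist[u] + w(u,v) = dist[v]` (within a 1e-9 relative
tolerance) and choosing the lexicographically smallest (row, column). This
tie-break makes traces deterministic on flat probability fields. Note that
ties between *structurally different* optimal paths are rare by
construction: every edge carries the additive `w_min`, so among
equal-probability routes the one with fewer edges is strictly cheaper
(e.g. on a uniform map the maximal-diagonal path wins, not a top-row path).
Correctness is tested against exhaustive enumeration of simple paths
(branch-and-bound DFS) on random maps up to 5×5.

A path may visit one column at several rows; the per-column representative
is the first-visited row (config-switchable to the rounded mean). Both
boundaries are searched over the full region; the DEJ search is not
restricted below the found SC.

## Parallel inference

The patchset is split into `n_workers` contiguous chunks; each worker
process loads the serialized checkpoint (`.npz` weights + embedded YAML
config) once and runs the same forward pass. Output equals single-process
inference up to float32 summation order (tested to ≤1e-6; in practice
bit-identical). Workers are capped at the number of available patches, with
a warning.

## Evaluation metrics

- **Position accuracy**: fraction of columns with |pred − ref| ≤ 2 px
  (≈6.5 µm axially — the tolerance within which trained human annotators
  judge a boundary placement satisfactory); computed over the full trace
  width, symmetric in its arguments, monotone in the tolerance.
- **Position error**: mean and SD of the per-column absolute difference.
- **ET accuracy**: fraction of images whose predicted mean ET lies within
  the reference trace's own per-image SD of the reference mean ET. The SD
  could alternatively be read as an across-annotator or across-image spread;
  the per-image reading is the default because it needs only one reference
  trace pair per image, and a global-SD alternative is a config switch.
- **Classification report**: per-class PPV, sensitivity and F1 at argmax
  decisions, plus one-vs-rest AUC from the class's probability column
  (rank statistic); classes absent from the labels are flagged undefined.
- Metric reporting converts px → µm at 3.25 µm/px by default while the
  acquisition default pitch is 3.26 µm/px; both are explicit config fields,
  never hard-coded, because instrument calibration and reporting conventions
  can legitimately differ at the third digit.

## Phantoms: what they emulate, and what they do not

A phantom stacks four layers per column — air (reflectance 0.05), a 2-row
bright SC line (0.95), an epidermis band (0.40), dermis (0.65) — along
boundary traces built from a low-frequency sinusoid plus a smoothed seeded
random walk (so traces are curved but 8-connected after rounding).
Multiplicative gamma speckle (unit mean, shape 8 ≈ 35 % contrast;
`shape = inf` means noise-free) and a σ = 1 px Gaussian blur provide
OCT-like texture; the default frame is 460×1500 px at 3.26×4 µm. Cohorts
draw per-image parameters uniformly from configured ranges with per-image
seeds derived from one master seed, and emit a 70/15/15 train/val/test
split (sizes round half-down for train and val, remainder to test).

Phantoms deliberately omit depth-dependent attenuation, the confocal gate,
shadowing artifacts, pathology, and annotator disagreement. Passing the
end-to-end tests therefore shows that the pipeline machinery — labeling,
training, probability-map assembly, skipping/infill, graph search, metric
accounting — is correct and self-consistent; it does not certify accuracy
on clinical images, where boundary contrast is weaker and the DEJ is
genuinely ambiguous.

## Problem sizes used in tests and the acceptance script

The end-to-end experiment trains the `cnn-gs-skin` preset on a 34-phantom
cohort (24/5/5 split) of 220×256-px frames with SC depth ~ U(70, 95) px,
ET ~ U(45, 75) px and curvature amplitude ~ U(4, 10) px, giving 6,144
balanced training patches per class; training runs at most 10 epochs. The
five held-out phantoms are segmented at skip steps 4 and 1 and scored
against generator truth. These sizes are the package's chosen desk-scale
study conditions; the phantom generator's own defaults remain the full
460×1500 reference frame.

## Known limitations

- The CNN engine is CPU/numpy; there is no GPU path, and training beyond
  tens of thousands of patches is slow by deep-learning-framework standards.
- Only the two-boundary problem is addressed; no multi-layer simultaneous
  search, no region-restricted second search.
- Pruning/quantization of the network and learned infill schemes are out of
  scope; the `first`-row trace rule can bias a vertically wandering path's
  trace by a pixel (the `mean` rule is available).
- The air/SC detector assumes the air region is darker than the SC line and
  that every column contains skin; columns without a detectable edge raise
  an error rather than guessing.
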
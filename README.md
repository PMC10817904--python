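# octskin

Fast two-boundary segmentation of skin OCT B-scans, for measuring
**epidermal thickness (ET)** — a quantity that changes in psoriasis, atopic
dermatitis, vitiligo, skin cancers and other conditions. The package
delineates the **stratum corneum (SC)** — the bright air/skin interface —
and the **dermal–epidermal junction (DEJ)** on cross-sectional OCT images,
and reports ET as the per-column axial distance between the two, in pixels
and micrometres.

## Method

The segmenter is a two-stage patch-CNN + graph-search pipeline:

1. **Patch classification.** The B-scan is min–max normalized to [0, 1],
   despeckled with non-local means, and cropped to a target region around
   the gradient-detected air/SC interface. Each pixel of the region is the
   center of a 55×55 patch; a small CNN (3 conv+pool blocks, 2 fully
   connected layers, softmax) classifies the patch as
   {non-boundary, SC, DEJ} by its *center pixel*, yielding per-class
   probability maps.
2. **Graph search.** Each probability map becomes an 8-connected pixel
   graph with edge weights

   ```
   w(u, v) = 2 − (P_u + P_v) + w_min ,     w_min = 1e-5
   ```

   so edges between high-probability pixels are nearly free. An
   all-probability-1 column appended on each side (automatic endpoint
   initialization) lets Dijkstra's algorithm run corner-to-corner without
   manual endpoint selection; stripping those columns leaves the boundary
   trace across the full width.

Two accelerations make the classification stage fast on a plain CPU:

- **Pixel skipping**: only every *s*-th pixel (raster order) is classified —
  the patchset shrinks to ⌈N/s⌉ (half at step 2, a quarter at step 4) — and
  skipped pixels are infilled with the mean of their evaluated 4-neighbors
  (plus-shaped kernel `[[0,1,0],[1,0,1],[0,1,0]]`).
- **Multi-process inference**: the patchset is split into contiguous chunks,
  each worker process loads the trained model once; results are identical to
  single-process inference.

Two model presets ship with the package: `cnn-gs-skin` (3×3 convs, filters
8/16/16, 2×2 pooling, FC1 32 — 16,532 parameters) and the heavier
`cnn-gs-baseline` (5×5 convs, filters 32/32/64 — 114,916 parameters). The
CNN engine (im2col convolutions, max/average pooling with per-layer
floor/ceil output rounding, dropout, RMSprop, early stopping) is
implemented in numpy inside the package.

Because clinical OCT datasets are rarely shareable, the package includes a
first-class **phantom generator**: layered synthetic B-scans (dark air,
bright SC line, darker epidermis band, brighter dermis) with smooth
sinusoid + random-walk boundary curvature, multiplicative gamma speckle and
Gaussian blur — with exact ground-truth traces, so the whole pipeline is
trainable and testable end to end.

## Worked example

```bash
# 12 phantoms at a reduced frame, train the lean preset, segment one image
octskin phantom --n 12 --seed 1 --height 220 --width 256 --out phantoms
octskin train --cohort phantoms --preset cnn-gs-skin --seed 1 \
              --max-epochs 10 --out model.npz
octskin segment --image phantoms/phantom-0009.png --model model.npz --step 4 \
                --out segmented
octskin evaluate --pred segmented/phantom-0009-traces.csv \
                 --manual phantoms/phantom-0009-traces.csv --out eval.json
octskin count-params --preset cnn-gs-skin
```

A run of this recipe printed:

```
wrote 12 phantoms to phantoms
model 'cnn-gs-skin': 16,532 parameters (count_parameters=16,532)
stopped at epoch 9 (best 9, val acc 0.9707); saved model.npz
ET 28.5 px (92.6 um); outputs in segmented
[all] overall position accuracy 0.9961, ET accuracy 1.0000
16,532
```

meaning: the built network's introspected parameter total matches the
closed-form count; training early-stopped with the best-validation weights
at 97.1 % patch accuracy; the segmented phantom has a mean epidermal
thickness of 28.5 px (≈93 µm at 3.25 µm/px — the 220-row phantom scales its
anatomy down from the 460-row reference frame); and 99.6 % of boundary
columns lie within 2 px of the ground-truth traces.

The same API is available from Python (`octskin.generate_cohort`,
`octskin.build_model`, `octskin.train`, `octskin.segment_scan`,
`octskin.position_accuracy`, ...); see `docs/methods.md` for the model and
its assumptions.

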
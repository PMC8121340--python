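# Methods

## Problem

A spectral-domain OCT B-scan is a depth × lateral-position cross-section of
the retina (rows = depth, y increasing downward; columns = A-scans).  Three
boundaries matter for staging age-related macular degeneration: the internal
limiting membrane (ILM, the retina's upper edge), the inner edge of the
retinal pigment epithelium (RPE), and the outer edge of Bruch's membrane
(BM).  Drusen — extracellular deposits between RPE and BM — lift the RPE
away from a BM that stays smooth, so the RPE–BM gap carries the clinical
signal.  The package segments all three boundaries fully automatically and
reports per-A-scan mean absolute error (MAE) in pixels.

## Pipeline

1. **Denoising** (`preprocess`).  OCT speckle is multiplicative; an
   edge-preserving bilateral filter (window diameter d = 15 px, photometric
   and geometric stds 100) attenuates it without blurring the layer steps.
   Weights follow the standard product-of-Gaussians form
   w = exp(−Δx²/2σs²)·exp(−ΔI²/2σc²), normalized per pixel, with reflect
   padding at the borders (avoids dark halos).  Intensities are treated on
   the 8-bit scale, consistent with σc = 100 gray levels.

2. **Region of interest** (`roi`).  Otsu's threshold on the denoised scan,
   morphological opening (5×5 square element, 2 iterations), dilation (5×5,
   7 iterations), then removal of 8-connected components smaller than
   1000 px.  The mask's tight bounding box — not a pixel mask — is the ROI,
   so later stages see rectangular crops.  "Opening before dilation"
   requires a spatially coherent foreground; this is why the ROI stage runs
   after denoising: raw speckle shreds the Otsu mask and the opening erases
   it entirely.

3. **Coarse band proposal** (`coarse_seg`).  A canonical 4-level U-Net
   (average-pool downsampling, transposed-conv upsampling, batch norm,
   dropout 0.2, 1×1-conv softmax head) labels each pixel of the ROI crop
   resized to 128×128 with one of four classes: background ("bottom"), ILM
   band, RPE band, BM band.  Ground-truth traces are rasterized as 1-px
   polylines and dilated (3×3 element, 2 iterations) into bands so they
   survive four downsamplings.  Training minimizes soft multi-class Dice
   loss, 1 − 2·VP/(2·VP + FP + FN) with probability-weighted counts,
   averaged over the three foreground classes.  The stage is judged only as
   a region proposer: its bands become per-edge crops, and what matters is
   that the true boundary falls inside them (band recall).

4. **Fine edge detection** (`edge_net`).  One model per boundary, each a
   dense-inception multi-scale edge detector: six main blocks of paired 3×3
   conv + BN + ReLU, 3×3/stride-2 max pooling between blocks, and from
   block 3 on the sub-block output averaged with a 1×1-projected border
   connection of the block input.  Each block feeds a non-weight-shared
   upsampling head (1×1 channel collapse, then stride-2 transposed-conv
   chain) producing a side edge map at input resolution; a learned 1×1
   fusion over the six side maps gives the fused map.  Spatial sizes must be
   multiples of 16 (five poolings).  Targets are un-dilated 1-px polylines —
   the detector is built for thin edges.  The loss is class-balanced
   cross-entropy: with β the non-edge fraction (typically 0.85–0.90), edge
   pixels weigh β and background pixels 1 − β, summed over the six side
   outputs plus the fused output with uniform per-output weights.  Samples
   with no edge pixels degenerate the weighting (β = 1 zeroes the loss) and
   are skipped with a warning.

5. **Trace extraction** (`boundary`).  Per fused-map column: columns whose
   maximum falls below `threshold_frac` (default 0.3) of the global maximum
   are missing; elsewhere the trace row is the probability-weighted centroid
   of rows with p ≥ 0.5 × column max (sub-pixel, preferred over argmax).
   Missing interior columns are filled by linear interpolation, ends by
   nearest-neighbor extension, because MAE needs a value in every column.
   Traces are mapped back to original coordinates through the composed crop
   geometry (row' = row/row_scale + row_offset; columns resampled at
   integers).  No topological ordering between edges is enforced — the
   ordering ILM < RPE ≤ BM is measured, not imposed.

6. **Evaluation** (`evaluate`).  Per scan, MAE is the mean over common
   columns of |x_i − y_i| in pixels at original resolution; dataset figures
   are the mean and the population standard deviation (divisor T) of
   per-scan MAEs, reported per group (drusen-bearing / control / all) and
   per edge.  A `variance=True` flag reports the mean squared deviation
   without the square root.  Missing columns are excluded pairwise and
   logged; a missing edge excludes the scan with a warning.

## Synthetic phantoms

`phantom` generates B-scans with known traces: a smooth ILM curve with an
inverted-Gaussian foveal dip; a smooth BM (low-order polynomial); RPE =
BM − offset − Σ Gaussian drusen (drusen lift RPE upward, BM undisturbed,
count ~ Poisson, amplitude and lateral width uniform in configurable
ranges); five constant intensity bands (vitreous, 3-px bright ILM band,
inner retina, bright RPE band, sub-BM); multiplicative Gamma speckle with
mean 1 and std `speckle_level` applied last.  Traces are kept at float
precision; the painted image rounds to the nearest row.  Everything is
deterministic in (spec, seed).

What the phantom does **not** emulate: real texture inside the retina
(layers between ILM and RPE), vessel shadows, geographic atrophy, wet-AMD
fluid, scanner PSFs, intensity calibration of any particular device (no
published intensity statistics exist for the source hardware, so band gray
levels are free parameters).  Passing the recovery study therefore shows
that the cascade's mechanics — ROI, band proposal, edge localization,
coordinate bookkeeping — recover known geometry under speckle; it does not
certify accuracy on clinical scans.

## Training protocols

*Full-scale recipe* (config defaults): 300 epochs, batch 4, Adadelta with
initial learning rate 1e-4 and per-iteration decay 0.095 (Keras-legacy
lr_t = lr₀/(1 + decay·t)); coarse input 128×128; edge input 128×992
(aspect-distorting resize of a 512×1000 band; width kept maximal because
narrow widths misrepresent drusen curvature).

*Desk-scale protocol* (`PipelineConfig.desk_scale`), used by the test suite
and `scripts/acceptance.py`: phantoms 128×256; coarse U-Net base width 4;
edge nets at 1/8 of the published widths with input 32×256; batch 4; Adam
(lr 5e-3) for 45 coarse epochs and 25 edge epochs.  Adam replaces Adadelta
here because the Adadelta recipe is tuned for a 300-epoch schedule and
barely moves in the few hundred optimization steps a desk run affords.  The
coarse schedule is longer than the edge one: the thin ILM band separates
from the inner retina only after ~40 epochs of soft Dice, while RPE/BM
bands and all three edge nets converge in ~20.  Problem sizes for the
recovery study: 48 training phantoms (drusen-bearing), 16 held-out (10
drusen-bearing + 6 control); these sizes give stable sub-pixel MAE
estimates while keeping a full retrain in the minutes range on one CPU
core.

Edge models are trained on band crops proposed by the *trained* coarse
stage (as at deployment): the ILM model sees the ILM-band crop, the RPE and
BM models the joint RPE/BM-band crop.

## Numerical choices

- The layer engine is plain numpy (float32, NCHW): windowed-einsum
  convolutions, explicit backprop, He initialization, seeded
  `numpy.random.Generator` everywhere (dropout masks and shuffling derive
  from the model seed), so runs are bit-reproducible on a single CPU
  thread.
- Max pooling uses 3×3/stride-2 with 1-px padding (output = ceil(n/2));
  upsampling heads crop any overshoot back to the target size, which keeps
  any multiple-of-16 input exact.
- Dice denominators of absent classes are treated as 0/0 → 0; edge-loss
  probabilities are clipped to [1e-7, 1 − 1e-7].
- Otsu on a constant image returns the constant with a warning; an empty
  ROI mask raises an error naming the scan.
- Resizes: bilinear for images, nearest for label maps.
- Interpolation fill, centroid reduction and `threshold_frac` are explicit,
  configurable choices where the procedure is otherwise under-specified.

## Known limitations

- The phantom's five-band intensity model is far simpler than clinical OCT;
  desk-scale results quantify mechanism, not clinical accuracy.
- The coarse stage can propose over-thick bands early in training; band
  recall (not band Dice) is the acceptance-relevant quantity.
- No ordering constraint between the three traces; rare crossings are
  possible and are measured by the ordering statistic.
- Full-width DexiNed and 300-epoch schedules are configurable but not
  validated here (CPU-scale runs only).
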
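# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of `echonac`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Segmentation network

The segmenter is a U-Net over a single grayscale channel. Each level holds
two 3×3 convolutions, each followed by batch normalization, dropout
(default rate 0.1) and ReLU; downsampling is 2×2 max pooling, upsampling is
factor-2 bilinear interpolation (implemented as zero-stuffing plus a fixed
smoothing kernel) with skip concatenation; the head is a 1×1 convolution
with a sigmoid, so lesion-free images can legitimately map to an empty
probability mass. Default clinical-scale shape: depth 4, 32 base channels
doubling per level, input 448×384. The published parameter count of the
clinical model is not targeted — too many hyperparameters of that network
are unreported for a faithful reconstruction, so the canonical U-Net shape
is used.

Two strictly additive modules define the ablation family:

* **SCSE attention** after every encoder, bottleneck and decoder block:
  a channel gate (global average pool → bottleneck MLP with reduction 8 →
  sigmoid) plus a spatial gate (1×1 convolution → sigmoid), summed.
* **ASPP** at the bottleneck: parallel 3×3 convolutions at dilation rates
  {1, 6, 12, 18} (rate 1 as a 1×1 convolution) plus a global-pooling
  branch, fused by a 1×1 projection with batch norm.

Because the modules only add parameters, removing ASPP from the full model
reproduces the attention-only variant exactly, and so on; the test suite
asserts this compositionality on parameter budgets.

The network runs on `echonac.nn`, a small numpy reverse-mode autodiff
engine written for this package (convolution as im2col + GEMM, gradients
verified against central finite differences in the test suite). Weights are
float32; weight initialization is He-normal, seeded.

## Hybrid loss

Four terms, each reduced by the mean over pixels so values are comparable
across resolutions:

* **BCE** — mean binary cross-entropy, probabilities clipped to
  [1e−7, 1 − 1e−7].
* **Dice** — 1 − (2Σpt + s)/(Σp + Σt + s), smoothing s = 1.
* **Active contour** — Chan–Vese-style decomposition: mean
  forward-difference gradient magnitude of the probability map (a length /
  perimeter penalty) plus a region-fit term with fixed region constants
  c₁ = 1, c₂ = 0 (binary truth), weight λ = 1. Note the length term is a
  perimeter *penalty*, not an error: it is nonzero even at a perfect sharp
  prediction. Consequently "loss at prob == truth" is exactly
  w_ac × length(truth); the other three terms vanish there.
* **Hausdorff surrogate** — mean of (p − t)² · (d_t^α + d_p^α) with α = 2,
  where d_t, d_p are unsigned Euclidean distance transforms to the
  boundaries of the truth and of the thresholded prediction (computed per
  batch sample, treated as constants for the gradient). A mask with no
  boundary (empty or full-frame foreground) contributes a zero distance
  map. The surrogate's ordering agrees with the exact symmetric Hausdorff
  distance for displaced copies of the same lesion; across lesions of
  different sizes it is area-weighted and not order-comparable, which is
  how the ordering test suite is constructed.

**Default weights (1, 1, 0.5, 0.05).** The distance-squared weights of the
Hausdorff term scale with the image diagonal and otherwise dominate the
region terms by one to two orders of magnitude early in training, which
destabilizes optimization at small scale (validation IoU oscillates or
collapses with w_hd = 0.5). With w_hd = 0.05 the region terms lead early
training and the boundary terms refine, which is the intended division of
labor. All weights are configurable.

## Training

Adam with β₁ = 0.5, β₂ = 0.999 (the standard reading of "betas from 0.5 to
0.999"), learning rate 0.002, batch size 4, up to 100 epochs at clinical
scale; no learning-rate schedule. Augmentation co-applies geometric
transforms to image and mask (right-angle rotations — restricted to
half-turns plus axis flips for non-square grids so the shape is preserved —
and random crop-with-resize, nearest-neighbour for masks) and applies
photometric brightness/contrast jitter to the image only. Images are
rescaled to the fixed network resolution with bilinear interpolation
(aspect ratio not preserved), masks with nearest-neighbour. The checkpoint
returned is the epoch with the best validation metric — pooled-count lesion
IoU by default — not the last epoch. Training aborts on NaN loss. With a
fixed seed the recorded history is bitwise reproducible.

**Problem sizes.** All experiments in this repository run on one CPU, so
the suite uses a scaled-down regime chosen once: smoke training uses the
full variant at depth 3, 8 base channels, ASPP rates (1, 2, 4), 200
phantoms at 128×96, 14 epochs; the ablation experiment uses 80 phantoms at
64×48 for 12 epochs, four variants × three seeds. At this scale the
directional claim (full ≥ plain baseline on seed-averaged macro IoU) is the
meaningful statement; per-variant margins of the clinical-scale experiment
are not expected to reproduce.

## Synthetic phantoms

`echonac.phantom` emulates the statistical structure of breast B-mode
images, not ultrasound physics:

* **Lesion geometry** — ellipse with a low-order radial Fourier
  perturbation (harmonics 2–5, amplitude = `boundary_irregularity`, 0 gives
  the exact ellipse); footprints leaving the frame are rejected.
* **Appearance** — lesions are hypoechoic: the background (level 0.6 with
  smooth multiplicative gain variation) is attenuated by `contrast` inside
  the lesion, edge-softened by a Gaussian of `blur_sigma`; optional
  posterior acoustic shadowing darkens a band below the lesion; distractor
  blobs of weaker contrast are placed outside the lesion; unit-mean
  gamma-distributed multiplicative speckle (shape = `speckle_looks`,
  default 16) is applied last. The scale bar is metadata (`px_per_cm`), not
  a burned-in graphic.
* **NAC cohort** — defaults are the study conditions: 57 patients, 29 pCR
  (assigned by count, shuffled by seed), log-normal baseline areas
  (median 4 cm², σ = 0.5), 6 cycles. Per-cycle area retention is a
  persistent patient-level chemosensitivity trait (pCR mean 0.60, non-pCR
  mean 0.85, between-patient sd 0.15) plus per-cycle jitter (sd 0.05).
  Measurements per model (LAM = 2a, DAM = 4ab, MSM = DLM = πab) carry
  fractional Gaussian noise (sd 0.10) plus an absolute precision floor
  (0.10 cm for axes, 0.15 cm² for areas — caliper/tracing precision), which
  dominates once residual tumors are small. Setting
  `measurement_noise_sd=0` disables all measurement noise (exact noise-free
  limit).

The trait-plus-jitter structure is what keeps the per-cycle pCR AUC roughly
cycle-stable, as observed clinically; with independent per-cycle retention
draws the AUC would rise toward 1 as cycles accumulate signal. A mild
first-cycle attenuation remains (one cycle of shrinkage signal against the
full measurement noise), so cross-cycle DeLong comparisons involving cycle
1 are non-significant in only ~70–85% of replicates, while comparisons
among cycles ≥ 2 are non-significant in ≥ 90%; the property test asserts
the latter. What passing phantom tests shows about real data is limited:
phantom parameters are generator conventions, not estimates fitted to
clinical images, and segmentation difficulty at clinical scale (posterior
shadowing severity, heterogeneous echotexture, operator variation) is not
calibrated.

## Geometry

Components are 8-connected (4-connectivity splits thin diagonal necks),
filtered at `min_area_px` = 10 to suppress speckle specks. The longest axis
is the maximum center-to-center distance between pixel centers (computed on
convex-hull vertices, which is exact; verified against the brute-force
pairwise oracle). The perpendicular width is the projection extent of the
pixel centers onto the normal of the longest-axis direction, clamped to a
minimum of 1 px so one-pixel-thin components keep a physical width; no
other +1 px end-correction is applied anywhere, keeping implementation and
oracles consistent. Conventions the clinical literature leaves open, chosen
here: "diameter" = equivalent diameter 2√(area/π); "area ratio" = lesion
pixels / image pixels; multifocal sizes sum per model (longest axes for
LAM, per-component axis products for DAM, areas for MSM/DLM), with the
largest component's axis also reported separately.

## Response statistics

Ratio N = size after N cycles / pre-NAC size; the pCR predictor is the
reduction 1 − Ratio N, oriented so that AUC ≥ 0.5 means reduction predicts
pCR. AUC is the Mann–Whitney probability with midrank ties; the 95% CI is
the DeLong asymptotic-normal interval truncated to [0, 1]. Paired DeLong
comparisons (same patients under two measurement models or two cycles) use
the covariance of the structural components; cross-cycle comparisons are
paired on the common patient subset; mixed 6/8-cycle cohorts restrict each
cycle's ROC to patients measured at that cycle. Cycles with a single
outcome class are flagged (NaN), not computed. Undefined metric ratios
(0/0) anywhere in the package are reported as NaN rather than coerced.

## Known limitations

* No physical wave simulation, no 3-D volumes, no axillary node modelling,
  no DICOM ingestion.
* The numpy network is CPU-bound; clinical-scale (448×384, depth 4) training
  is out of reach of this engine and is specified by configuration only.
* DeLong comparisons across cycles assume the same patients at both cycles;
  the unpaired path treats curves as fully independent and is conservative
  for overlapping cohorts.
* Phantom realism is qualitative; none of its parameters were estimated
  from clinical images.
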
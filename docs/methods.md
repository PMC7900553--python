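# Methods

## The pipeline

`histomut` treats mutation prediction from H&E slides as a weakly supervised
patch-classification problem. A slide contributes a set of fixed-size tumor
tiles, each tile inherits the slide's binary label vector over eight
biomarker genes, a compact residual CNN scores tiles, and the slide-level
score per gene is the unweighted mean of its tile probabilities. Evaluation
is the per-gene ROC/AUC over slides under twofold slide-level
cross-validation.

## Tiling and quality filters

Tiles are laid on the non-overlapping grid of multiples of the tile size
(512 px at full scale, 64 px in the desk profile); partial edge windows are
dropped rather than padded, which keeps window statistics comparable. A
window is kept iff

* its background fraction ≤ `bg_max` (default 0.75), and
* its tumor-mask fraction ≥ `tumor_min` (default 0.5).

Histopathology has no canonical definition of "background", so the package
uses an explicit HSV rule: a pixel is background when saturation < 0.15 and
value > 0.82. This captures white glass while keeping pale eosin tissue
(e.g. RGB (200, 120, 160) has S ≈ 0.40 and survives). Both thresholds are
configurable; every property test and oracle comparison uses the same rule,
so the kept-tile set is exactly reproducible by an independent recount.

Slide-level quality control uses a noise ratio: (blank + blurred area) /
total area, with blank given by the background rule and blur measured as
the variance of a 3×3 Laplacian over fixed blocks (64 px default) falling
below a threshold. Slides above a configurable cutoff (default 0.75) are
rejected. Blur filtering is off by default — the synthetic generator
produces no out-of-focus regions, and a universal variance threshold is
scanner-dependent; the parameter exists for real material.

## The stain color model

Pixel colors (RGB in [0, 1]; optical density available by configuration)
are modeled as a mixture of N = 3 trivariate Gaussians — nucleus,
cytoplasm, background — with weights Wₙ ∈ [0, 1], ΣWₙ = 1, means Vₙ and
full covariances Cₙ. Fitting maximizes the data log-likelihood
Σₖ ln Σₙ Wₙ N(xₖ | Vₙ, Cₙ) by EM:

* E-step: posterior responsibilities computed in log space
  (log-sum-exp); pixels whose density underflows everywhere are
  hard-assigned to the nearest mean and logged.
* M-step: standard weighted moments (weights = mean responsibility, means
  and covariances = responsibility-weighted first and second moments).
* Safeguards: every covariance update is eigenvalue-floored at ε = 1e-6,
  which keeps components SPD under collapse. Convergence is a relative
  log-likelihood change below 1e-6 (cap 200 iterations).

Initialization is luminance-quantile seeding — pixels sorted by luma
(0.299R + 0.587G + 0.114B) and split into tertiles, which in H&E material
lands near the nucleus/cytoplasm/background partition — plus three seeded
random restarts; the best final log-likelihood wins. Full covariances are
the default; a diagonal option exists because the three channels are nearly
uncorrelated within the background class but distinctly correlated within
stained tissue, and some applications prefer the cheaper model.

### Color transfer

Components of the source and reference mixtures are paired by ascending
luminance of their means (ties: green channel, then index) — luminance
orders nucleus < cytoplasm < background robustly for H&E. Each pixel is
hard-assigned to its argmax-responsibility source component (matching the
idea that every pixel belongs to one tissue color class; soft blending is
available) and mapped by the whitening–coloring transform

x′ = V_ref + C_ref^{1/2} C_src^{−1/2} (x − V_src),

with symmetric square roots from eigendecompositions, then clipped to the
valid range. With source = reference this is the identity up to clipping
and 8-bit rounding (≤ 2/255 per channel), and it is idempotent thereafter.
Normalization is fitted per slide (one source model per slide) by default;
per-tile fitting is a configuration choice. The background component is
transferred like any other, with an optional pass-through flag.

## The tile classifier

Architecture (all counts configurable): a 3×3 stride-1 stem convolution
with `n_filters` kernels, then `n_residual_blocks` residual blocks — each
conv–BN–ReLU–conv–BN plus an identity shortcut, ReLU after the addition,
followed by 2×2 max-pooling — then global average pooling and a dense layer
with 8 independent sigmoid outputs. Spatial dimensions are preserved inside
a block, so the shortcut needs no projection. The network, including
im2col-based convolution, batch-norm statistics and the full backward pass,
is implemented in NumPy; backprop is verified against central finite
differences in the test suite.

Training: seeded SGD with momentum 0.9, L2 on conv/dense weights, batches
shuffled per epoch from a deterministic generator. The loss is multi-label
binary cross-entropy over the 8 outputs (class-weighted and focal variants
available); biomarkers with a single class in the training tiles are masked
out of the loss and logged. One network serves all 8 biomarkers;
per-biomarker one-vs-rest training is a configuration choice. No optimizer
beyond momentum SGD is offered — the learning rate and L2 coefficient are
the tuned quantities.

Inference runs in float64, so predicted probabilities are independent of
batch composition to well below 1e-6.

Cross-validation is twofold at the slide level: slides are shuffled with a
seeded generator and split 1:1 (odd counts favor fold 1); all tiles of a
slide share its fold, so no slide leaks between training and validation.
The hyperparameter grid spans exactly four dimensions — filter count,
residual-block count, batch size, loss function — each point scored by
twofold CV, best point = highest mean validation AUC over biomarkers.

## The synthetic cohort generator

Each synthetic slide is built from the pipeline's own generative
assumptions, with every truth emitted for oracle tests:

* colors: a known 3-component mixture (nucleus mean (0.30, 0.20, 0.50),
  cytoplasm (0.85, 0.55, 0.70), background (0.97, 0.96, 0.97); diagonal
  covariances 2e-3, 2e-3, 4e-4). The background covariance is tight enough
  that the HSV background rule recognizes ≥ 99% of true glass pixels.
* geometry: tissue = union of random disks grown to a target cover
  fraction (default 0.7); nuclei = Poisson-count ellipses (radius 2–4 px at
  desk scale, random orientation and axis ratio, overlap allowed) placed
  uniformly over tissue; the tumor mask is the tissue region.
* label effect: slides mutated in the signal biomarker have nucleus
  density multiplied by (1 + δ). The effect is purely morphological —
  nuclear density, not color — so stain normalization cannot erase it and
  the normalization and classification tests stay independent. δ applies
  to density only; radius is held fixed so the null/alternative comparison
  has a single moving part.
* labels: the signal biomarker is exactly balanced across the cohort; the
  other seven genes get independent fair-coin labels with no morphological
  correlate, serving as built-in negative controls.

All randomness descends from one master seed through named seed sequences,
so any artifact is reproducible from (params, seed).

What the generator does **not** emulate: texture within cytoplasm,
chromatin structure, nucleoli, stain gradients, pen marks, folds, blur, or
any real biology of the eight genes. Passing the end-to-end tests therefore
shows that the pipeline can recover a morphological signal through tiling,
normalization, weak supervision and aggregation — not that AUCs on real
clinical cohorts are reproduced, which requires real slides and full-scale
training.

## Study conditions (desk profile)

The experiments and the reproduction script run a deliberately small
profile chosen once for CPU-scale work: 256×256 slides tiled at 64×64
(≈ 12 kept tiles per slide), nucleus density 800 per 512² tissue area
(≈ 12.5 expected nuclei per tile, doubled at δ = 1), 20 slides per cohort,
and a compact network (8 filters, 2 residual blocks, kernel 3, batch 16,
learning rate 0.05, L2 1e-4, 10 epochs). At these sizes one twofold-CV run
takes well under a minute on one CPU. The full-scale profile (512×512
tiles, 32 filters) uses the same code paths and is exercised structurally
but not trained in the test suite. With δ = 1 the expected per-tile nucleus
counts (≈ 12.5 vs 25) give a tile-level Bayes AUC near 0.98, so a
median slide-level AUC ≥ 0.9 is an achievable but non-trivial bar; with
δ = 0 the AUC concentrates around 0.5 with the substantial variance
expected from 10-slide validation folds.

## Numerical choices

* Gaussian densities via Cholesky factorization; non-SPD covariances raise
  an error naming the smallest eigenvalue.
* Log-likelihoods and responsibilities are log-sum-exp stabilized;
  responsibilities sum to 1 within 1e-12.
* The EM trace is monitored per iteration; monotonicity holds to a 1e-9
  relative tolerance (the covariance floor can in principle perturb it).
* ROC curves sweep grouped unique scores so tied scores step diagonally;
  the trapezoidal area then equals the Mann–Whitney concordance with ties
  counted ½, and is checked exactly against a brute-force pairwise count.
* Heat maps accumulate window scores and coverage per pixel; uncovered
  pixels are NaN in the matrix and transparent in the rendered overlay.
  The colormap is a continuous blue–white–red ramp (presentation only,
  configurable).
* Max-pooling routes gradients through argmax indices (exact subgradient
  even under ties); batch-norm inference uses running statistics.

## Known limitations

* The color model is fitted on raw pixel colors; no stain-deconvolution
  (hematoxylin/eosin absorbance) variant is provided.
* Weak supervision assigns every tumor tile its slide's labels; tiles
  without discriminative morphology add label noise, which real cohorts
  will exhibit far more strongly than the generator.
* The noise-ratio blur term is a block-variance heuristic with a
  scanner-dependent threshold, not a calibrated focus measure.
* Pyramidal WSI formats are out of scope; slides enter as plain rasters.
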
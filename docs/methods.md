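# Methods

## Problem and model

The package segments geographic-atrophy-like lesions in multi-channel 2-D
en face images and attaches a per-pixel epistemic-uncertainty estimate to
every prediction.  The segmentation network is an encoder/decoder U-Net:

* **Contractive path** — five convolutional blocks (two 3×3 convolutions,
  each followed by a rectified linear unit) alternating with four 2×2
  stride-2 max-pools; output channels start at `base_channels` (32 at full
  scale) and double after each pool.
* **Expansive path** — four steps of 2× bilinear upsampling, concatenation
  with the skip tensor, and a convolutional block.  The skip tensor is not
  the raw encoder feature map but its *downsampling remainder*
  `rem(x) = x − upsample(downsample(x))`: the high-frequency content that
  the pooling path destroys, which is exactly what the decoder cannot
  recover on its own.
* **Head** — dropout (p = 0.2), a 3×3 convolution to 8 channels with
  rectified linear activation, and a 3×3 convolution to 1 channel through
  the bounded algebraic activation `final(x) = (x/√(x²+1) + 1)/2`, whose
  range is the open interval (0, 1); outputs are read as GA probabilities.

The **drop variant** adds dropout with p = 0.5 after the last three
contractive blocks and the first two expansive blocks and keeps every
dropout layer active at inference; the **standard variant** uses dropout
only during training.

### Bilinear convention

Both the remainder and the decoder upsampling use the convention where
output pixel *i* samples the source at `(i + 0.5)/2 − 0.5`, edge-clamped.
Under this convention the 2× upsampling of a 1×1 block is constant, so
`rem(constant) ≡ 0` exactly — pinned by a loop-oracle test.  Upsampling is
implemented as a per-axis linear operator, which makes its adjoint (needed
for backpropagation) the plain matrix transpose.

### Other fixed conventions

* Concatenation order: upsampled features first, remainder second.  Only a
  permutation of learned channels; fixed for reproducibility.
* Weight initialisation: He-normal on convolution kernels, zero biases,
  from a per-model seeded generator.  Ensembles need *different*
  initialisations, which distinct seeds provide.
* No normalisation layers anywhere.
* Encoder dropout (drop variant) is applied to the block output before it
  feeds both the pooling path and the remainder skip, matching a purely
  sequential placement of the layer.
* Max-pool gradient routes to the first maximum under ties.

## Training

Loss per step: `dice_loss + 0.001 · Σ_k HoyerSquare(W_k)` over convolution
kernels `W_k` (biases excluded, per the usual usage of this sparsity
measure).  Dice loss uses additive smoothing ε = 1 (configurable) so empty
masks are well-behaved.  Hoyer-Square `(Σ|w|)²/Σw²` is scale-invariant and
ranges from 1 (one-hot) to n (uniform); an all-zero array is defined as 0.
The implementation normalises by max|w| before squaring, which leaves the
value unchanged but avoids underflow for pathologically tiny weights.

Optimiser: Adam (β₁ = 0.9, β₂ = 0.999), learning rate
`initial_lr · 0.999^epoch`.  Ensembles use k-fold cross-validation with a
seeded shuffle and round-robin fold assignment; member *j* trains on all
folds except *j* with its own seed.  Augmentation applies one shared
geometric draw per sample (flips, 90° rotations, integer translations up to
4 px) to image and masks, and photometric gain/offset jitter to the image
only.  Model selection is "last epoch"; per-epoch logs record lr, Dice
loss, Hoyer term, their sum, and validation Dice.

### Scale presets

The `full` preset is the full-scale configuration: width 32,
5-member ensemble, 5000 epochs, initial lr 1e-4, MC dropout up to T = 64,
128×128 images.  The `desk` preset is the configuration the tests and the
acceptance script actually exercise: 40 synthetic 64×64 samples (30
training / 10 held-out test), width 8, a 3-member ensemble plus one drop
model, 30 epochs, T ∈ {4, 16}.  With ~170× fewer epochs the full-scale
learning rate is far too small to train, so the desk preset uses batch size 2 with initial
lr 1e-3 — chosen once during pipeline bring-up as the setting where
training converges (validation Dice ≈ 0.9) while larger rates (≥ 5e-3)
collapse to empty masks under the Hoyer gradient.  All other loss and
schedule constants are identical across presets.

The drop variant's dropout-off validation Dice is essentially meaningless
(five stacked p = 0.5 layers create a large train/inference mismatch); the
model is only ever scored through its MC-dropout average, which is also how
it is meant to be deployed.

## Bayesian inference and uncertainty

`ensemble_predict` averages the deterministic outputs of K members;
`mc_dropout_predict` averages T dropout-active passes with per-run seeds
derived from one master seed.  Per-pixel entropy is computed **from the
averaged probability** (the predictive distribution), not by averaging
per-run entropies.  Probabilities are clamped to `[1e-12, 1 − 1e-12]`
before logs; exact 0/1 inputs use the `0·log 0 ≡ 0` convention.  The
entropy kernel canonicalises on `min(p, 1−p)` so `H(p)` and `H(1−p)` share
identical floats, and map averaging sorts the per-pixel stack before the
reduction, making the result bit-identical under any permutation of runs
or members.

## Evaluation

Entropy thresholds are fractions of the 1-bit maximum on the grid
{0.01, 0.10, 0.20, …, 1.00} ("below 1 %", then 10 % steps).  At each
threshold, pixels with entropy ≤ threshold are retained; the probability
map is binarised at 0.5 (configurable) and Dice is computed against each
grader over the retained pixels only, the two scores averaged per image,
then averaged over images — *not* pooled over pixels, so every image
carries equal weight.  Conventions: Dice = 1 when prediction and grader
are both empty on the retained set; a record with empty retention is
undefined, excluded from averages, and counted in `n_undefined`.  Percent
removed is `100 · #(entropy > threshold)/#pixels`, which is exactly
non-increasing in the threshold.

95 % confidence intervals use a seeded percentile bootstrap over samples
(2000 resamples at full scale, 500 in the desk preset).

Paired model comparisons use the two-sided Wilcoxon signed-rank test with
zero differences dropped and midranks for ties; for up to 16 nonzero pairs
the p-value is exact, by enumeration of all sign patterns of the rank sums
(`p = P₀(min rank sum ≤ observed)`); for tie-free data up to 25 pairs the
exact signed-rank null distribution is used, and beyond that a normal
approximation with continuity correction.  Significance is assessed at α/m for m pairwise
comparisons (Bonferroni).  The trade-off statistic is the Pearson
correlation between mean Dice and mean percent removed across the
threshold grid (per model); computing it across images instead is available
via the per-sample sweep table.

## Synthetic cohort

The generator emulates only the statistical structure the analysis needs:

* **Lesions** — 1–3 ellipses with random centre, size, aspect and
  orientation, radius modulated by a smooth random Fourier series
  (harmonics 2–5, rms 1) scaled by `boundary_roughness`; rasterised as
  polygons.  Merging is allowed; lesions are bright (0.75) on a darker
  background (0.25) with iid Gaussian channel noise (sd 0.05), clipped to
  [0, 1].
* **Graders** — the truth boundary is warped by a smoothed random
  displacement field (Gaussian-filtered white noise, per-component sd
  `grader_boundary_sd`, vector magnitude capped below 2 sd); pixels at
  least 2 sd inside the boundary are preserved by construction.  Small
  components (< 25 % of the largest) are each deleted with probability
  `grader_satellite_flip_prob`, and with the same probability a spurious
  small satellite is added.  Two independent grader seeds per sample yield
  annotations that agree in cores and differ at boundaries/satellites
  (mean pairwise Dice ≈ 0.9 at defaults).
* **Seeding** — per-sample seeds derive from
  `SeedSequence([cohort_seed, index, role])`, so extending a cohort never
  changes earlier samples, and every artefact is a pure function of
  (config, seed).

What the generator does **not** model: OCT physics, slab extraction,
pseudo-color channel semantics, realistic GA morphology statistics, or
spatially correlated grader bias.  Passing tests therefore demonstrate the
correctness and internal behaviour of the method — training dynamics,
uncertainty ordering between Bayesian and baseline models, selective
prediction gains — not clinical performance on real SS-OCT data.

## Known limitations

* The pure-numpy network is single-threaded-BLAS fast but far from GPU
  scale; the `full` preset is provided for completeness and has not been
  run here.
* At very low entropy thresholds (1 %) the retained set can exclude nearly
  all lesion pixels for weakly confident models, making masked Dice
  degenerate (0 or 1 per image); the sweep table reports these honestly
  rather than filtering them.
* Bootstrap confidence intervals treat samples as exchangeable; with eyes
  contributing multiple images a clustered bootstrap would be needed.
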
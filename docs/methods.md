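# Methods

## Model

`histobridge` trains a single conditional denoising-diffusion model
`f_θ(x_t; t, c, G, T)` over RGB image patches and uses it for unpaired
translation and counterfactual editing between condition "domains".  The
three condition channels are

* a categorical label `c` from a finite registered set (tissue preparation,
  stain, tumor type, ...),
* a genomic profile `G = {(g_i, m_i)}`: one boolean (non-synonymous)
  mutation bit per gene of a registered panel,
* a transcriptomic profile `T = {(g_i, t_i)}`: one quantile-normalized
  expression value per gene of a (possibly different) registered panel.

### Forward process and training

A linear variance schedule `β_1..β_T` (defaults 1e-4..2e-2 at `T = 1000`,
rescaled by `1000/T` otherwise so the terminal signal level is
T-independent) defines the usual forward marginal
`x_t = sqrt(ᾱ_t) x_0 + sqrt(1−ᾱ_t) ε` with `ᾱ_t = Π_s (1−β_s)`.
Training is plain conditional ε-prediction: per item, draw `t` uniformly
and `ε ~ N(0, I)` from an item-specific seed, and minimize the MSE between
injected and predicted noise.  There is no auxiliary classifier and no
guidance weight; the deterministic sampler below uses the conditional
network exactly as trained.  Schedules are 0-based internally:
`alpha_bars[t]` is the `ᾱ_{t+1}` of 1-based presentations, and the clean
image sits "before" index 0 at `ᾱ = 1`.

### Conditioning

Each gene carries a wild-type embedding `e_g` and a mutant embedding
`ẽ_g`.  The genomic condition is `Σ_i MLP_gen(e_{g_i}` or `ẽ_{g_i})` with
the mutation bit selecting the row.  The transcriptomic condition is
`Σ_i MLP_txn(e_{g_i}) ⊙ MLP_exp([e_{g_i}, t_i])` — the `⊙` is an
element-wise product of two width-`d` vectors, and `MLP_exp` receives the
gene embedding concatenated with the scalar expression value, keeping gene
identity and quantity separable.  The combined vector
`e_cat + e_genomic + e_transcriptomic` is added to the timestep embedding
and injected into every residual block through a per-block learned linear
projection (block widths differ across levels, so a projection is forced).
Absent omics channels contribute exact zero vectors, making
categorical-only models a strict special case.  Embedding tables are
initialized at unit scale — the class-embedding convention of conditional
diffusion models — so the condition signal is visible against the O(1)
timestep embedding from the first optimizer step; with small-scale
initialization the conditioning pathway trains far too slowly to steer
sampling at desk scale.

Quantile normalization maps each gene's values to `rank/(n+1)` across
samples with average ranks for ties; an all-tied column maps to 0.5.

### Network

The ε-predictor is a DDPM-style U-Net: `GroupNorm → SiLU → 3×3 conv`
residual blocks, average-pool downsampling, nearest-neighbor upsampling,
skip concatenation, and single-head self-attention where configured.  The
desk-scale reference configuration is 32×32 resolution, base width 16,
channel multipliers (1, 2, 4), one block per level, embedding width 64,
attention at the 8×8 bottleneck (~0.66 M parameters); 128×128 and wider
variants are reachable by config.  The output convolution is
zero-initialized, so an untrained model predicts exactly zero noise.

The whole stack (reverse-mode autodiff, conv/attention layers, Adam) is
implemented in numpy inside `histobridge.nn`; convolution runs as k²
shifted batched matmuls, which keeps every temporary at activation size —
on memory-bandwidth-limited single-CPU machines this is substantially
faster than an im2col buffer.  Gradients are verified against central
finite differences in the unit tests.

## Translation bridges

Translation composes two deterministic DDIM solves of the probability-flow
ODE with one network: encode under the source condition (clean → latent),
decode under the target condition (latent → clean).  Both directions
iterate

    x_next = sqrt(ᾱ_next) x̂_0 + sqrt(1−ᾱ_next) ε̂

where `x̂_0` and `ε̂` come from a single network call at the *current*
level of `x` (they are algebraically linked through the forward marginal,
`x_t = sqrt(ᾱ_t) x̂_0 + sqrt(1−ᾱ_t) ε̂`).  Evaluating at the current level
and recombining at the next is essential: recombining at the evaluation
level is an exact algebraic identity and moves nothing.  Encode and decode
visit the same (level, label) pairs in opposite orders, which is what makes
the bridge approximately invertible; the residual one-step lag is the
standard DDIM-inversion discretization error and vanishes as the plan
densifies (measured on the synthetic study at seed 1: mean abs pixel error
≈ 0.030 / 0.016 / 0.008 at 50 / 100 / 200 steps on [−1, 1] data).  Latents are not
re-noised or clamped between the solves, and `x̂_0` is not clipped during
sampling (clipping exists as an off-by-default option).

### Reduced-step calibration

`calibrate_timesteps` picks a step budget: (1) translate sample images with
the full `T`-step plan; (2) for each candidate count, translate with a
balanced evenly-spaced plan and record mean SSIM to the reference; (3) the
chosen budget `N*` is the *smallest* candidate within `elbow_tolerance`
(default 0.01) of the best SSIM achieved — a reproducible, monotone-robust
reading of the elbow heuristic; (4) `N*` is re-allocated between the two
schedule halves over first-half fractions {0.5, 0.6, 0.7, 0.8, 0.9} and
the best-SSIM allocation wins.  Weighting the first (low-noise) half
harder tends to preserve structure, which is why the search is biased that
way.

## Evaluation suite

* **FID**: `‖μ−μ₀‖² + Tr(Σ+Σ₀−2(ΣΣ₀)^{1/2})` over feature Gaussians with
  unbiased covariances.  The matrix square root goes through the symmetric
  product `Σ^{1/2} Σ₀ Σ^{1/2}`, so the computation stays in real symmetric
  eigendecompositions (negative eigenvalues are clipped at 0; a result
  below −1e-6 raises).
* **ΔFID** = FID(before, ref) − FID(after, ref), positive when translation
  moved the set toward the reference.
* **Inverted normalized FID** = FID(real_a, real_b) / FID(synth, real_b),
  ≈ 1 when synthetic images match a real split.  Note both terms sit at the
  estimator noise floor when all sets coincide, so single ratios are
  heavy-tailed; compare medians over replicates.
* **SSIM / structural distance**: uniform (unweighted) 7×7 sliding window,
  sample-covariance normalization, constants `c1=(0.01·L)²`, `c2=(0.03·L)²`
  at data range `L = 1`; the per-window map is returned alongside the mean.
  Structural distance is `(1−SSIM)/2`, clipped into [0, 1].  RGB images are
  scored per channel and the maps averaged.
* **Cosine distance**, **Isolation-Forest inlier scores** (decision scores
  rescaled ×2 and clipped into [−1, 1]; higher = more in-distribution),
  **mMV@k** majority-vote retrieval accuracy (vote ties break toward the
  label with the nearest supporting item), and **editing effectiveness**
  (percentage reduction of the mean cosine distance to the top-K retrieved
  items, K = 5 by default).

Feature extraction is a pluggable contract.  The default extractor block-
averages the image to 16×16, applies a fixed-seed Gaussian projection with
a tanh nonlinearity, and appends channel moment statistics (128
dimensions).  It is deterministic, carries no downloaded weights, and
preserves the ordinal contrasts (hue, brightness, texture) the relative
metrics need; absolute FID magnitudes from pretrained deep networks are
deliberately out of scope, so conclusions rest on signs, orderings and
ratios, which are extractor-robust.

## Preprocessing front end

Tissue detection: Otsu threshold on the Gaussian-blurred (σ = 5 px by
default) HSV saturation channel; above-threshold pixels are tissue; a
constant-saturation slide yields an empty mask with a warning.  Tiling:
0-based half-open sliding windows fully inside the image, row-major, kept
when the window's tissue fraction ≥ 0.5 (default).  Triage labels a patch
positive iff its best cosine similarity to positive anchor features
strictly exceeds that to negative anchors (ties negative).  DAB positivity:
optical-density transform, unmixing with the Ruifrok–Johnston
hematoxylin–DAB matrix (scikit-image's `hdx_from_rgb`), mean of the DAB
channel floored at zero.

## Synthetic study

The generator renders 32×32 histology-like patches whose generative
factors are recoverable by simple estimators, mirroring the qualitative
read-outs of real experiments (hue ↔ stain/preparation identity,
nucleus-like blob density ↔ cellularity, background brightness ↔ a
continuous expression effect):

* two domains differing only in background hue (0.08 vs 0.55 — deliberately
  non-antipodal on the hue circle so signed circular differences are
  unambiguous), saturation 0.55, value 0.85, Gaussian grain σ = 0.02;
* one mutation gene `GENE_BLOBS` bound to blob count (wild type 3, mutant
  9); blobs are dark (V = 0.25) non-overlapping soft-edged disks of radius
  ≈ 2.2 px placed by rejection sampling;
* one expression gene `GENE_BRIGHT` bound to background brightness with
  slope 0.15 per unit of normalized expression.

`measure_attributes` is the independent closure oracle: Otsu on luminance
(trusted only when the luminance range exceeds 0.25, so blank fields count
zero blobs), connected components with a 4 px minimum area, circular mean
hue over background pixels, mean V as background brightness.  Slide
fixtures are bright near-white backgrounds with saturated elliptical
tissue regions and their ground-truth masks.

What passing on this study does *not* show: the generator has none of the
spatial heterogeneity, stain variability, compression artifacts or
semantic structure of real whole-slide images, so results here validate
the algorithmic machinery (invertibility, conditioning, metrics), not
histopathological performance.

### Study sizes and defaults

Training: 64 images per domain, 2 000–2 500 Adam steps (lr 2e-3, batch 8,
β = (0.9, 0.999)), `T = 1000`.  These sizes are the package's chosen
desk-scale conditions: the loss plateaus around 0.005–0.02 well before
2 000 steps and the conditional structure (hue by label, blob count by
gene bit) is recoverable from translations at that point.  Translation and
editing use a 200-step plan (100 + 100) unless calibrated otherwise.
Numerical tie-breaks and degenerate-input rules are documented on the
relevant functions (empty gene registries embed to zero; single-candidate
calibration returns the full plan; Otsu on constant channels warns and
returns empty masks).

## Known limitations

* Single-process CPU execution; identical seeds give bit-identical results,
  but large resolutions are slow by design of the numpy backend.
* DDIM inversion is approximate (one-step lag); perfect reconstruction is
  approached, not reached, as plans densify.
* The default feature extractor is intentionally shallow; plug in a deep
  extractor for semantically meaningful absolute FIDs.
* Pyramidal WSI containers (SVS/NDPI) are not parsed; slides enter as
  plain raster images.
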
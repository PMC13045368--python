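# histobridge

Unpaired translation and counterfactual editing of histopathology image
patches with an omics-conditioned diffusion model, plus the quantitative
evaluation suite that goes with it.

## The problem

Histology archives mix tissue preparations (cryosection vs FFPE), stains
(H&E vs IHC markers), tumor types and molecular backgrounds.  Many
questions — "what would this cryosection look like as an FFPE slide?",
"how would this tissue look if *TP53* were mutated?" — are image
*translation* problems with no paired ground truth.  `histobridge`
implements a diffusion-bridge answer: train **one** conditional denoising
diffusion model `f_θ(x_t; t, c, G, T)` over patches, where

* `c` is a categorical domain label from a finite set `C`,
* `G = {(g_i, m_i)}` holds boolean mutation bits over a registered gene panel,
* `T = {(g_i, t_i)}` holds quantile-normalized expression values.

With `ᾱ_t` the cumulative signal level of the variance schedule, a
deterministic DDIM solve of the probability-flow ODE under the *source*
condition encodes a patch into a Gaussian-like latent, and the reverse
solve under the *target* condition decodes it:

    x_lat = ODESolve(x_src ; f_θ(·; c_src, G_src, T_src), 0 → T)
    x_trg = ODESolve(x_lat ; f_θ(·; c_trg, G_trg, T_trg), T → 0)

with each step updating
`x_next = √ᾱ_next · x̂₀ + √(1−ᾱ_next) · ε̂`, both predictions coming from a
single network call.  Editing an omics profile means running the bridge
with the modified profile on the decode side only.  Evaluation uses the
Fréchet distance between feature Gaussians (FID) and its before/after
difference ΔFID, SSIM and the structural distance (1−SSIM)/2,
cosine-distance retrieval (mMV@k), Isolation-Forest inlier scores, and a
top-K editing-effectiveness statistic.  A slide front end (Otsu tissue
masking on blurred saturation, sliding-window tiling, anchor triage) and
H-DAB stain quantification round out the pipeline.

Everything runs on a plain CPU: the U-Net, its reverse-mode autodiff and
the Adam loop are implemented in numpy inside the package, and a synthetic
data module generates histology-like fixtures with recoverable ground
truth so the whole method is testable end to end without downloads.

## Worked example

Train on the synthetic two-domain study and translate held-out patches
(domain_a has an orange-pink background hue, domain_b a blue one; a
synthetic gene controls the count of nucleus-like blobs):

```bash
histobridge train --out runs/toy
histobridge synth --n-per-domain 4 --out runs/inputs
histobridge translate \
    --checkpoint runs/toy/checkpoint.npz \
    --src-label domain_a --trg-label domain_b \
    --steps 200 --in runs/inputs --out runs/translated
histobridge evaluate --in runs/translated \
    --reference runs/inputs --before runs/inputs --out runs/eval
```

On this study the library-level run (see the reproduction section below,
seed 1) prints, among others:

```
"roundtrip_mae_200_steps":   {"value": 0.0082, "n": 8},
"translation_delta_fid":     {"value": 95.8,   "n": 20},
"translation_hue_shift_pct": {"value": 100.0,  "n": 20},
"edit_blob_increase_pct":    {"value": 100.0,  "n": 9}
```

Reading: encode→decode under the *same* condition reconstructs patches to
~0.008 mean absolute pixel error on [−1, 1] data (the bridge is close to
invertible at a 200-step plan); translating domain_a → domain_b moves the
set's feature Gaussian toward the real domain_b set (ΔFID > 0) and shifts
the measured background hue toward the target domain in every held-out
patch; flipping the synthetic mutation bit on the decode side raises the
measured blob count in every edited patch — the counterfactual edit does
what the gene's ground-truth binding says it should.

## Layout

| Path | Contents |
| --- | --- |
| `src/histobridge/schedule.py` | variance schedule, forward marginal, ε↔x₀ algebra |
| `src/histobridge/conditioning.py` | label/gene embeddings, profile I/O, quantile normalization |
| `src/histobridge/denoiser.py` | conditional U-Net ε-predictor |
| `src/histobridge/translate.py` | DDIM bridges, timestep plans, elbow calibration |
| `src/histobridge/metrics.py` | FID family, SSIM, retrieval, inlier, editing metrics |
| `src/histobridge/preprocessing.py` | tissue masking, tiling, triage, DAB quantification |
| `src/histobridge/synthetic.py` | ground-truth fixture generator (images + slides) |
| `src/histobridge/nn/` | numpy autodiff, layers, Adam |
| `src/histobridge/cli.py` | `histobridge` command-line interface |
| `docs/methods.md` | model, conventions, parameter choices, limitations |
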
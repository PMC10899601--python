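# Methods

## Problem and model

`wsimil` infers slide-level biology — tumor status, a panel of continuous
protein abundances (RPPA-style), prognostic risk and drug-response
likelihood — from H&E whole-slide images using only slide-level labels.
The pipeline has four stages:

1. **Preprocessing.** Foreground tissue is separated from the glass
   background by Otsu thresholding, applied to the HSV *saturation* channel
   of a downsampled copy of the slide (the background of an H&E scan is
   near-white and hence near-zero saturation, making saturation a more
   stable channel than luminance). Small objects and holes below 64 px are
   removed by morphology. The tissue area is tessellated into
   non-overlapping `tile_px`² tiles (half-open grid `[x0, x0+tile_px)`,
   stride = `tile_px`, 0-based row-major order, edge tiles dropped); a tile
   is retained when its mask-derived tissue fraction is at least
   `min_tissue_frac` (default 0.5). Optional Reinhard color normalization
   matches per-channel LAB means and standard deviations to a reference
   tile or preset; Macenko-style stain unmixing is deliberately not
   implemented (moment matching is sufficient for the synthetic cohorts and
   is the cheaper, reference-based default).

2. **Contrastive pretraining.** A convolutional encoder *f* maps a tile *x*
   to an embedding *h = f(x)*; a two-layer projection head *g* maps *h* to
   *z = g(h)*, L2-normalized. Two stochastic augmentations of one tile form
   a positive pair; negatives are K keys cached in a FIFO memory queue and
   produced by a momentum (EMA) copy of the encoder. With
   sim(z_i, z_j) = z_iᵀz_j / (τ|z_i||z_j|), the loss of an anchor is the
   InfoNCE softmax  −log [ exp(sim(z, z′)) / (exp(sim(z, z′)) +
   Σ_k exp(sim(z, z_k))) ].  The denominator includes the positive term —
   the bounded, standard momentum-contrast convention; the variant that
   sums only the K negatives is available via `include_positive=False`.
   Defaults: τ = 0.07, K = 256 at desk scale (4096 is the documented
   value for full-size cohorts), EMA m = 0.999, SGD with lr 0.03, weight decay 1e-4,
   momentum 0.9. Augmentations are crop-resize (area scale 0.5–1.0), both
   flips, mild color jitter (±0.15), random grayscale (p 0.2) and Gaussian
   blur (p 0.5). After pretraining the projection head is discarded and
   *h* is the tile feature.

3. **Gated-attention aggregation.** Tile embeddings are pooled by
   e_i = wᵀ(tanh(V h_i) ⊙ σ(U h_i)), a = softmax(e) (max-subtracted),
   S = Σ a_i h_i. Attention hidden width L defaults to 128 (64 at desk
   scale). The pooled feature is permutation-invariant and lies in the
   convex hull of the tile embeddings; ranking ties are broken by row-major
   tile order so outputs are reproducible.

4. **Heads.** Diagnosis and response use a linear layer + 2-way softmax and
   cross-entropy; protein regression uses one hidden layer and an output
   node per protein with MSE averaged over the panel. Heads and attention
   are trained jointly (Adam, default lr 1e-4; 1e-3 at desk scale where
   runs are short), early-stopped on validation loss. The encoder is frozen
   by default and can be fine-tuned end-to-end (`fine_tune_encoder`).
   Patients with several slides inherit the patient label during training;
   evaluation averages predictions per patient.

**HER2-proxy drug response.** The response model never sees response
labels: the protein head is fine-tuned on the HER2-like protein level
alone, and its predicted HER2 level is used directly as the response
score. In the synthetic cohorts responders are defined by *low* HER2-like
levels, so the ROC uses the negated score; an audit counter
(`responder_labels_read`) proves label isolation, and a poisoning test
asserts the trained weights are bit-identical under label flips.

**Survival.** Prognostic risk is a Cox proportional-hazards model
h(t|x) = h0(t) exp(θᵀx) fitted by minimizing the negative log partial
likelihood with Breslow tie handling (full risk set for tied events,
R(t_i) = {j : T_j ≥ t_i}; tied censored subjects stay in the risk set).
The optimizer is deterministic full-batch L-BFGS on the exact analytic
gradient (validated against central finite differences); the Breslow
baseline is h0(t_i) = d_i / Σ_{j∈R(t_i)} exp(θᵀx_j). Risk groups come from
a median split of training-set risk scores, ties to the low group.
Univariate hazard ratios carry Wald 95% CIs from the observed information.

## Neural-network substrate

All models run on a compact reverse-mode automatic-differentiation core
(`wsimil.autodiff`) over numpy arrays: broadcasting arithmetic, matmul,
im2col 2-D convolution, the usual activations and stabilized
log-sum-exp/softmax. Every operation's gradient is tested against central
finite differences. The tile encoder is a configurable small CNN (strided
3×3 conv blocks, global average pooling, linear embedding; desk default
2 blocks, 16/32 channels, d = 32, input 32²) sized so pretraining and
fine-tuning complete in minutes on one CPU core; depth, width and embedding
dimension are configuration, not architecture changes.

## Synthetic cohorts

The generator (`wsimil.synthetic`) emulates the structure the pipeline
assumes, not H&E appearance. A slide is a pale background with one smooth
tissue blob (thresholded smoothed Gaussian field); tumor subregions are
carved from a second, higher-frequency field inside the blob and rendered
with a hue shift toward hematoxylin purple plus dense dark nuclei-like
speckle (16% of pixels vs 2% in normal tissue). One knob
(`texture_strength` ∈ [0,1]) interpolates tumor texture between
indistinguishable and fully distinct. Labels are coupled to morphology:

- signal protein j: p_j = α_j·tumor_fraction + ε, ε ~ N(0, noise_sd),
  with α_j fixed per protein (drawn once per cohort from U(0.8, 1.6), or
  forced with `signal_alpha`); non-signal proteins are pure noise;
- survival: exponential proportional hazards (constant baseline
  h0 = 0.1 — the simplest invertible model consistent with the Cox form)
  on the latent features (tumor_fraction, tissue darkness) with
  θ = (2.0, 1.0); censored subjects observe a uniform fraction of their
  event time, at rate `censoring_rate` (0.3);
- responder: HER2-like protein (the first signal protein) below its
  cohort median (single slides use the theoretical mixture median).

Cohorts are split 60/20/20 into train/val/test; too-small cohorts fill
train first, then val, then test, with a logged warning. Everything is a
pure function of `(params, seed)`; identical seeds reproduce slide bytes.

Desk-scale defaults (the conditions all end-to-end tests and the
acceptance script use): 60 slides of 512² px, 64² px tiles (an 8×8 grid,
64 tiles per slide), tumor prevalence 0.5 with tumor fractions in
[0.15, 0.5], 32 proteins of which 8 carry signal, noise_sd 0.1. The
256² px tile and 223-protein panel of clinical RPPA data remain the
documented configuration for real cohorts. What passing these tests shows
is that the machinery — weak supervision, attention localization, FDR
control, label isolation — behaves correctly when the signal is present by
construction; it does not certify performance on real H&E slides, where
staining variation, artifacts and far subtler morphology–molecule links
dominate.

## Numerical and design choices

- Softmax and log-sum-exp are always max-subtracted; the InfoNCE loss
  aborts with diagnostics on non-finite values.
- Otsu on a blank (zero-variance) slide returns an explicit no-tissue
  mask instead of raising.
- Reinhard matching guards zero-variance channels (constant tiles map to
  the reference mean color); outputs are clipped to the valid pixel range,
  so extreme reference statistics can shift moments slightly at the gamut
  boundary.
- Heatmaps min-max rescale attention per slide; constant-attention slides
  map to 0.5; uncovered pixels are NaN (missing), never 0, and overlays
  show the plain slide there regardless of alpha.
- Cross-validation folds are assigned at patient level so slides of one
  patient never straddle folds.
- BH correction reports adjusted p-values and applies the step-up
  rejection rule at α (the two decision rules coincide).
- Benjamini–Hochberg false-positive checks on the null proteins use a
  tolerance of 2.5 binomial standard errors of the observed fraction,
  reflecting the granularity of a 24-protein null panel.

## Known limitations

- No pyramidal SVS reader: slides are plain PNG/TIFF rasters (the
  synthetic cohorts' native format); magnification changes are
  area-average downsamples preserving the ×40/×20/×10/×5 ladder.
- The desk-scale CNN is far smaller than a 50-layer backbone; absolute
  embedding quality is not comparable to GPU-scale pretraining, only the
  training dynamics and interfaces are.
- Survival modelling is univariate/linear in the provided covariates; no
  time-dependent covariates or competing risks.
- The generator does not model stain physics, scanner variation, pen
  marks, blur or tissue folds.
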
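# wsimil

Weakly supervised contrastive multiple-instance learning for whole-slide
histopathology. `wsimil` infers slide-level biology — tumor status,
continuous protein abundances (RPPA-style panels), prognostic risk and
drug-response likelihood — from H&E slide images using **slide-level labels
only**: no pixel annotation is ever consumed.

It is aimed at computational-pathology researchers who want a tested,
CPU-friendly reference implementation of this weak-supervision recipe,
complete with a synthetic-cohort generator that makes every stage testable
against known ground truth.

## Method

1. **Tissue segmentation & tiling** — Otsu thresholding on the HSV
   saturation channel of a downsampled slide, morphology cleanup, then a
   non-overlapping grid of `tile_px`² tiles kept when tissue fraction ≥
   `min_tissue_frac`; optional Reinhard LAB color normalization.
2. **Momentum-contrast pretraining** — tile encoder *f* and projection
   head *g* trained with the InfoNCE loss
   `L = −log exp(sim(z,z′)) / (exp(sim(z,z′)) + Σₖ exp(sim(z,zₖ)))`,
   `sim(zᵢ,zⱼ) = zᵢᵀzⱼ/(τ|zᵢ||zⱼ|)`, against K negatives from a FIFO
   memory queue filled by an EMA momentum encoder (SGD lr 0.03, weight
   decay 1e-4, momentum 0.9; τ = 0.07). The projection head is discarded
   afterwards; *h = f(x)* is the tile feature.
3. **Gated-attention pooling** — `eᵢ = wᵀ(tanh(Vhᵢ) ⊙ σ(Uhᵢ))`,
   `a = softmax(e)`, slide feature `S = Σ aᵢhᵢ`; attention scores are
   deconvolved back onto slide coordinates as interpretable heatmaps.
4. **Heads** — 2-way softmax for tumor diagnosis and response; multi-task
   regression (one output per protein, panel-averaged MSE) for protein
   levels; a Cox proportional-hazards model `h(t|x) = h₀(t)exp(θᵀx)`
   (Breslow baseline, analytic-gradient fitting) for prognosis. Drug
   response follows the HER2-proxy protocol: the protein head is tuned on
   the HER2-like protein level only and its prediction is the response
   score — response labels are provably never read during training.

All neural components run on a small numpy autodiff core; no GPU or
deep-learning framework is required.

## Worked example

```python
from wsimil import pipeline

cfg = pipeline.parse_config(overrides={})
cfg.update(out_dir="demo_run", n_slides=60, seed=1,
           pretrain_epochs=6, head_epochs=100, patience=20, head_lr=1e-3)
report = pipeline.run("all", cfg)
print(report["diagnosis"])
print(round(report["protein"]["mean_r"], 3), report["protein"]["n_significant"])
print(report["response"])
```

On a seeded 60-slide synthetic cohort (8×8 tile grid per slide) this
prints, in about one minute on one CPU core:

```
{'accuracy': 1.0, 'confusion': [[6, 0], [0, 6]], 'auc': 1.0}
0.197 11
{'auc': 0.9714285714285715}
```

meaning: the held-out tumor/normal diagnosis is perfect on the 12-patient
test split; the mean held-out Pearson r across the 32-protein panel is
0.197 with 11 proteins BH-significant (the 8 planted signal proteins reach
r = 0.76–0.92, the 24 pure-noise proteins stay near zero); and scoring
responders by the predicted HER2-like protein level alone — without ever
training on response labels — yields ROC AUC 0.97. The same CLI flow is

```bash
wsimil all --set out_dir=demo_run --set n_slides=60 --set seed=1 \
           --set pretrain_epochs=6 --set head_epochs=100 --set head_lr=1e-3
```

Per-stage commands (`synthesize`, `tile`, `pretrain`, `train`, `predict`,
`heatmap`, `evaluate`) reuse each other's artifacts; every run freezes its
resolved configuration and logs artifact hashes to `run_log.jsonl`.

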
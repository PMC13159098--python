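# biscale

Bi-scale prediction of gene expression from whole-slide-image patch
embeddings — at the tissue (bulk RNA-seq) scale and the near-cellular
(Visium spot) scale — with a gated causal linear recurrence, two-stage
training, and a multi-scale evaluation and downstream-analysis suite.

## Who this is for

Computational pathology and spatial-transcriptomics researchers who want a
transparent, CPU-friendly, fully seeded implementation of
histology-to-transcriptome prediction: slide patches go in as an ordered
embedding sequence, per-spot and per-slide expression predictions come
out, and the surrounding protocol (normalization, gene-panel selection,
cross-validation, early stopping, similarity AUC, survival-score and
differential-expression rules) is reproducible end-to-end on synthetic
cohorts — no downloads, no GPU, no pretrained encoder weights.

## The model

A slide is a sequence of patch embeddings `x_1 … x_n` (`x_i ∈ R^d`).  Four
per-step coefficient vectors come from learned affine maps,
`a_i, b_i, c_i, g_i = Linear(x_i)`, and patch information fuses through a
first-order causal recurrence with elementwise products:

    h_i = a_i ⊙ h_{i−1} + b_i ⊙ x_i        (h_0 = 0)
    y_i = g_i ⊙ (c_i ⊙ h_i)

A learnable CLS token appended after the last patch accumulates the whole
slide; MLP heads map each local output `y_i` to a spot-scale prediction
`ẑ_i` and the CLS output to the slide-scale prediction `ẑ_global`.
Training is two-stage: scale-specific pretraining (bulk model on
`Loss_global`, spot model on `Loss_local + Loss_global` with pseudo-bulk
as the global target), then joint fine-tuning in which each optimization
step pairs one spatial and one bulk sample and the two models minimize the
mirrored convex combinations

    Loss_bulk = λ·Loss_local + (1−λ)·Loss_global
    Loss_spot = (1−λ)·Loss_local + λ·Loss_global

with λ the reciprocal of the spatial up-sampling factor.  See
`docs/methods.md` for the complete protocol, the initialization scheme,
and what the synthetic cohorts do and do not demonstrate.

## Worked example

Train the bulk-scale model on the built-in synthetic cohort (40 bulk
slides × 30 patches, 20 genes, a known linear embedding→expression map)
and evaluate on a held-out cross-validation fold:

```python
import numpy as np
from biscale import (SynthConfig, TrainConfig, FusionParams,
                     generate_cohort, pretrain, per_gene_metrics)
from biscale.training import predict_global, split_samples, make_cv_splits

cohort = generate_cohort(SynthConfig(seed=0))   # 40 bulk + 10 spatial slides
fold = make_cv_splits([s.patient_id for s in cohort.bulk], k=5, seed=0)[0]
train = split_samples(cohort.bulk, fold.train_patients)
val = split_samples(cohort.bulk, fold.val_patients)
test = split_samples(cohort.bulk, fold.test_patients)

model = FusionParams.for_training(d=16, G=20, level="bulk", seed=0)
best, records = pretrain(model, train, val, TrainConfig(seed=0))
print(f"trained {len(records)} epochs; "
      f"best validation mean r = {max(r.corr for r in records):.3f}")

report = per_gene_metrics(predict_global(best, test),
                          np.vstack([s.z_global for s in test]), level="bulk")
print(f"test median per-gene r = {report.median_r:.3f}; "
      f"{report.per_gene['well_predicted'].sum()}/20 genes well-predicted")
```

Output:

```
trained 200 epochs; best validation mean r = 0.992
test median per-gene r = 0.920; 20/20 genes well-predicted
```

The validation number is the early-stopping criterion (mean per-gene
Pearson r of the slide-level predictions); the test numbers show the
planted linear signal is recovered on unseen patients — a gene counts as
well-predicted at r > 0.4 with p < 0.05 at the bulk scale (r > 0.2 at the
spot scale).

## Command line

The same pipeline as shell commands (see `examples/config.yaml` for a
commented configuration):

```sh
biscale simulate --config examples/config.yaml --seed 7 --out cohort/
biscale pretrain --data cohort/ --stage bulk --seed 7 --out pre_bulk.npz
biscale pretrain --data cohort/ --stage spot --seed 7 --out pre_spot.npz
biscale finetune --data cohort/ --bulk-ckpt pre_bulk.npz \
                 --spot-ckpt pre_spot.npz --seed 7 --out-dir ft/
biscale predict  --data cohort/ --ckpt ft/finetuned_bulk.npz \
                 --level bulk --out pred_bulk.tsv
biscale evaluate --pred pred_bulk.tsv --truth cohort/bulk_targets.tsv \
                 --level bulk --out-prefix eval_bulk
```

Further subcommands: `prep-expr` (TPM/CPM + log), `prep-wsi` (tile,
tissue-filter and embed a slide image), `select-genes` (two-scale
mean-rank panel), `similarity-auc`, `risk-score`, `de`, `metaprogram`.
Every command writes a run manifest next to its outputs, and the whole
chain is byte-reproducible under a fixed seed.

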
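# Methods

## The prediction problem

`biscale` predicts gene expression from whole-slide-image (WSI) patch
embeddings at two resolutions simultaneously: the tissue (bulk) scale —
one expression profile per slide — and the near-cellular (spot) scale of
Visium-style spatial transcriptomics, where each capture spot has its own
profile and pixel coordinate.  A slide enters the model as an ordered
sequence of patch embeddings `x_1 … x_n` (d-dimensional vectors produced by
any deterministic patch encoder; the package ships a pluggable encoder
interface and a synthetic stand-in, not pretrained pathology weights).

## Expression preparation

Bulk RNA-seq counts are converted to TPM; spot counts to CPM.  Each spatial
slide additionally yields a pseudo-bulk profile: gene-wise sums of spot
counts, CPM-normalized — the slide's bulk-scale training target.  All
matrices are transformed with `v -> log2(v + 1)` so both scales share a
dynamic range under a single MSE objective, and predictions are restricted
to a user-supplied protein-coding id set.  Spots detecting fewer than 100
genes (inclusive threshold: exactly 100 is kept) are discarded before
pseudo-bulk construction — whether the published pipeline filters before or
after aggregation is not documented; filtering first is our choice and is
flagged in the QC report.

The target-gene panel is chosen by image association: per gene and per
scale, the score is the maximum absolute Pearson correlation between the
gene's log expression and any image-feature dimension (bulk-scale image
features are the mean of a slide's patch embeddings).  Scores are ranked
within each scale (rank 1 = best, average ranks on ties), the two ranks are
averaged, and the K = 1000 best genes by mean rank are kept, residual ties
breaking lexicographically so the panel is reproducible.  Collapsing a
feature *block* to one correlation per gene is underdetermined; max-|r| was
chosen as the strongest-linear-link summary and is switchable.

## WSI preparation

Slides are assumed pre-resampled to 20x (0.5 um/pixel).  Bulk slides are
tiled into non-overlapping 256 px patches ordered x-major by (x, y) origin
(0-based pixels, x = column; the recurrence is order-sensitive, so the
ordering is recorded in every checkpoint).  A pixel counts as tissue when
its darkest RGB channel is below 220/255 — a deliberate stand-in for any
segmentation method.  Patches with coverage strictly below 15% are
discarded (exactly 15% is kept) and a slide survives QC only with strictly
more than `min_tiles` tiles (1000 by default; synthetic tests lower it).
Spot patches are 256 px crops centered on the spot coordinate; near a
border the window is shifted inward rather than padded, and the shift is
flagged per spot.

## The fusion model

Patch fusion is a single gated causal linear recurrence (a Mamba-style
scan, one layer, unidirectional):

    a_i, b_i, c_i, g_i = Linear(x_i)            (four independent affine maps)
    h_i = a_i ⊙ h_{i-1} + b_i ⊙ x_i             h_0 = 0
    y_i = g_i ⊙ (c_i ⊙ h_i)

with a_i acting as memory decay, b_i as input injection, c_i as read-out
and g_i as output gating.  A learnable CLS embedding is appended as the
*last* sequence element so its hidden state has integrated every patch; its
output y_CLS carries the slide-global summary.  Two independent two-layer
MLP heads (hidden width d, GELU) map y_i to per-spot predictions and y_CLS
to the global prediction.  Each head applies a parameter-free layer
normalization to its input so the head operates on a scale-stable
representation of the recurrence output, as is conventional for this model
family.

Losses are MSE with squared errors averaged over genes (so local and global
terms share a scale regardless of G; a sum convention is available):

    Loss_local  = (1/n) Σ_i ||ẑ_i − z_i||²/G
    Loss_global = ||ẑ_global − z_global||²/G

By default the coefficient maps are taken literally as raw affine outputs.
Because an unbounded decay makes the n-step product `Π a_i` numerically
explosive under optimization, the model offers a sigmoid squashing of a_i
(bounded memory decay); the training pipeline always enables it, while the
raw form remains the contract checked against the hand-unrolled reference
implementation.

### Initialization

The training pipeline (`FusionParams.for_training`) uses a pass-through
gate initialization, the standard recipe for gated linear recurrences: the
b/c/g biases start at 1 and their weights at U(±0.25/√d), so at
initialization `y_i ≈ h_i ≈` a decayed sum of the inputs instead of a
random cubic of them; the decay bias is level-appropriate — +4 for the
bulk model (σ(4) ≈ 0.98: a long-memory integrator whose CLS state
approximates the slide-mean embedding) and −2 for the spot model
(σ(−2) ≈ 0.12: the current spot dominates its own prediction).  Head
output biases are set to the per-gene mean of the training targets (the
regression base rate).  Without these choices the prescribed learning rate
and epoch budget leave the model stuck at the mean predictor.  The generic
`FusionParams.init` keeps the plain symmetric-uniform/zero-bias scheme for
contract and gradient tests.

## Training protocol

Two stages, both optimized with Rectified Adam (variance-rectified
adaptive moments, decoupled weight decay 5e-3, betas 0.9/0.999), batch
size 1 — one patient-level sample per step.

*Pretraining* (lr 2e-4, up to 200 epochs) fits two separate models: the
bulk model on `Loss_global` over bulk samples, and the spot model on
`Loss_local + Loss_global` over spatial samples, the pseudo-bulk profile
supplying the global target.  The early-stopping controller watches the
internal validation set (10% of the training patients, patient-wise): a
checkpoint is saved whenever the validation loss reaches a new minimum;
after 20 consecutive epochs in which neither the loss nor the mean
per-gene Pearson correlation improves on its best-so-far, training stops.
The correlation is level-appropriate (global across samples for the bulk
model, concatenated spot predictions for the spot model).

*Fine-tuning* (lr 2e-5) trains both models jointly.  The spatial pool is
up-sampled to the bulk sample count (the factor is round(1/λ)) so every
step pairs one spatial sample with one bulk sample; per step the spatial
sample contributes the local term and half the global term, the bulk sample
the other half (the published protocol does not say how the two global
contributions combine; averaging keeps the term on a single-sample scale).
The bulk-focused model minimizes `λ·local + (1−λ)·global` and the
spot-focused model the mirrored combination; λ defaults to 0.1 (0.05 for
the COAD/KIRC configurations).  Checkpointing and stopping use the
validation correlation only, with the pretrained checkpoint's correlation
as the baseline — the saved fine-tuned model therefore can never be worse
than its pretrained parent on that criterion.

Evaluation follows patient-wise five-fold cross-validation (80/20 with the
10% inner split); per-gene Pearson r, its two-sided t-approximation p, and
MSE are computed on predictions concatenated across held-out
patients/spots.  A gene is *well-predicted* at r > 0.4 (bulk) or r > 0.2
(spot), strictly, with p < 0.05 and no multiple-testing correction.
Constant prediction or truth vectors are flagged degenerate, scored r = 0
and excluded from the median.

## Bulk–spot similarity AUC

Every predicted spot profile is Pearson-correlated with every predicted
bulk profile over the shared panel (n × m matrix); per-spot means are the
similarity scores.  The same procedure on ground truth yields reference
scores, binarized at their median (strictly above = high; ties at the
median are low).  The AUC of the predicted scores against these labels is
computed by the Mann–Whitney midrank formula.

## Downstream procedures

Applied to predicted expression; the heavyweight fitting lives in external
tools and this package applies their outputs:

- **Risk score** — `Σ C_i · Exp_i` over an externally fitted penalized
  proportional-hazards signature, followed by median stratification
  (score strictly above the median = high risk; all-equal scores are an
  error).
- **Stage binarization** — AJCC stages I–II map to low, III–IV to high;
  sub-stage letters and "Stage " prefixes are normalized first.
- **Differential expression** — Wilcoxon signed-rank (paired, bulk use) or
  rank-sum (unpaired, spot use) per gene, Benjamini–Hochberg FDR, fold
  change as the ratio of de-logged group means (scale switchable), with the
  DE call `FDR < 0.05` and fold change `> 1.25` (or `< 1/1.25`, since both
  directions are reported).
- **Meta-program spatial correlation** — per slide, pairwise Pearson
  correlations among meta-program genes over that slide's spot predictions;
  per-slide matrices averaged, then average-linkage hierarchical clustering
  on distance 1 − r.  The linkage is unstated in the protocol we follow;
  average linkage is our choice.
- The Scissor selection fractions (3% tumor/normal, 10% recurrence) ship as
  named constants for interoperability only.

## Synthetic cohorts

The generator emulates paired bulk + spatial cohorts with a *known*
embedding-to-expression mapping.  Per slide, an L-dimensional latent
morphology field varies smoothly in space (a three-component low-frequency
cosine mixture per dimension plus a slide-level Gaussian offset — cheap,
smooth and seedable, in place of Gaussian-process sampling).  Embeddings
are an orthonormal affine image of the latent plus optional Gaussian noise
(orthonormal so embedding entries keep the O(1) scale of real encoder
outputs); mean log2 expression is a second affine image.  With a count
depth set, spot counts are Poisson draws over the softmax-normalized
composition (Gamma-mixed for negative-binomial overdispersion if
requested), bulk counts sum patch-level draws, and the stored pseudo-bulk
target reproduces `make_pseudobulk` of the stored counts exactly.  Without
a depth, targets are the exact mean log expression — the noiseless linear
regime in which the cohort is provably predictable (a linear probe on the
embeddings attains per-gene r ≥ 0.99), used to test signal recovery.

The default conditions are the desk-scale study: 40 bulk slides × 30
patches, 10 spatial slides × 50 spots, d = 16, L = 4, G = 20, noiseless.
These sizes keep the complete two-stage study under a minute on one CPU.
What passing at this scale shows is that the architecture, losses,
optimizer and controller recover a planted linear signal end-to-end; it
does not show histological realism (no H&E texture, no batch effects, no
segmentation noise) or performance on real cohorts.

## Numerical choices and limitations

- Everything runs in float64 NumPy; gradients are analytic and verified
  against finite differences to 1e-4 relative.
- TPM/CPM columns must sum to 1e6 within 1e-3 relative; all-zero columns
  are preserved as zeros with a QC flag rather than NaN.
- All randomness flows from explicit integer seeds; the same seed
  reproduces checkpoints and pipeline artifacts byte-identically.
- One recurrence layer only; no positional encodings, no bidirectional
  scan, no hardware-aware kernels.  Whether the published architecture
  stacks multiple blocks is unknown; depth is not emulated.
- Coordinates are 0-based pixels, x = column, y = row, half-open
  intervals — stated in every sidecar file.
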
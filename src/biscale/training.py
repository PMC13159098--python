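"""Two-stage optimization: scale-specific pretraining, then joint fine-tuning.

Stage 1 pretrains two separate models — a bulk model on the global loss
only, and a spot model on local + global (pseudo-bulk supplying the global
target).  Stage 2 fine-tunes both jointly: every optimization step pairs
one spatial sample with one bulk sample (the spatial pool is up-sampled to
the bulk count), and the two models weight the local/global terms with the
mirrored convex combinations lam / (1 - lam).

Optimization is Rectified Adam with batch size 1, decoupled weight decay,
and the dual-criterion early-stopping controller: checkpoints are saved on
every new validation-loss minimum, and training stops after ``patience``
consecutive epochs without improvement unless the validation correlation
keeps setting new bests.  Fine-tuning saves and stops on correlation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fusion_model import FusionParams, forward, forward_backward

PRETRAIN_LR = 2e-4
FINETUNE_LR = 2e-5
WEIGHT_DECAY = 5e-3
DEFAULT_PATIENCE = 20
DEFAULT_MAX_EPOCHS = 200
#: fine-tuning mixing weight per cancer type; reciprocal of the spatial
#: up-sampling factor
LAMBDA_BY_CANCER = {"BRCA": 0.1, "COAD": 0.05, "KIRC": 0.05}


@dataclass
class TrainConfig:
    stage: str = "pretrain"  # 'pretrain' | 'finetune'
    max_epochs: int = DEFAULT_MAX_EPOCHS
    lr: float = PRETRAIN_LR
    weight_decay: float = WEIGHT_DECAY
    batch_size: int = 1
    patience: int = DEFAULT_PATIENCE
    lam: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ValueError("lam must lie in (0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size != 1:
            raise ValueError("only batch_size=1 is supported (one sample per step)")

    @property
    def upsample_factor(self) -> int:
        """Spatial up-sampling factor, the reciprocal of lam (rounded)."""
        return max(1, round(1.0 / self.lam))


@dataclass
class CVSplit:
    fold_id: int
    train_patients: list
    val_patients: list
    test_patients: list


@dataclass
class EpochRecord:
    epoch: int
    loss: float
    corr: float
    checkpointed: bool = False
    stopped: bool = False


def make_cv_splits(patient_ids, k: int = 5, inner_val_frac: float = 0.10,
                   seed: int = 0) -> list[CVSplit]:
    """Patient-wise k-fold splits with an inner validation hold-out.

    Each patient lands in exactly one test fold; within each fold,
    ``inner_val_frac`` of the training portion (at least one patient) is
    held out for validation/early stopping.  Deterministic under ``seed``.
    """
    ids = list(dict.fromkeys(patient_ids))  # unique, order-preserving
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} distinct patients")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds = np.array_split(np.arange(len(order)), k)
    splits = []
    for f, test_idx in enumerate(folds, start=1):
        test = [order[i] for i in test_idx]
        rest = [p for p in order if p not in set(test)]
        n_val = max(1, round(inner_val_frac * len(rest)))
        perm = np.random.default_rng(seed + f).permutation(len(rest))
        val = [rest[i] for i in perm[:n_val]]
        train = [rest[i] for i in perm[n_val:]]
        splits.append(CVSplit(f, train, val, test))
    return splits


def split_samples(samples, patients) -> list:
    wanted = set(patients)
    return [s for s in samples if s.patient_id in wanted]


def early_stop_update(history: list[EpochRecord], new: tuple[float, float],
                      patience: int = DEFAULT_PATIENCE) -> tuple[bool, bool]:
    """Dual-criterion controller decision for a new (loss, corr) epoch.

    Replays the history so the decision is a pure function of the record:
    a checkpoint is due whenever the loss sets a new minimum; after
    ``patience`` consecutive epochs in which neither the loss nor the
    correlation improved on its best-so-far, training stops.
    """
    best_loss, best_corr = math.inf, -math.inf
    counter = 0
    save = stop = False
    seq = [(r.loss, r.corr) for r in history] + [tuple(new)]
    for loss, corr in seq:
        save = loss < best_loss
        corr_improved = corr > best_corr
        if save:
            best_loss = loss
        if corr_improved:
            best_corr = corr
        counter = 0 if (save or corr_improved) else counter + 1
        stop = counter >= patience
    return save, stop


def mean_per_gene_r(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over genes of the per-gene Pearson r across samples; genes that
    are constant in either vector contribute 0."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    pc = pred - pred.mean(axis=0)
    tc = truth - truth.mean(axis=0)
    ps = np.sqrt((pc ** 2).sum(axis=0))
    ts = np.sqrt((tc ** 2).sum(axis=0))
    denom = ps * ts
    r = np.where(denom > 0, (pc * tc).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return float(r.mean())


# ---------------------------------------------------------------------------
# Rectified Adam
# ---------------------------------------------------------------------------

class RAdam:
    """Rectified Adam over a dict of parameter arrays, with decoupled
    weight decay.  The adaptive step is variance-rectified: while the
    approximated simple-moving-average length rho_t < 5 the update falls
    back to un-adapted momentum."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 weight_decay: float = 0.0, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        t = self.t
        b1t, b2t = self.b1 ** t, self.b2 ** t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho_t > 5.0:
            r_t = math.sqrt(
                ((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
            )
        else:
            r_t = None
        for k, p in params.items():
            g = grads[k]
            m = self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            v = self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            m_hat = m / (1.0 - b1t)
            if r_t is not None:
                v_hat = np.sqrt(v / (1.0 - b2t)) + self.eps
                p -= self.lr * r_t * m_hat / v_hat
            else:
                p -= self.lr * m_hat
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p


# ---------------------------------------------------------------------------
# Stage 1: scale-specific pretraining
# ---------------------------------------------------------------------------

def _is_spot_sample(sample) -> bool:
    return hasattr(sample, "z_local")


def _validate(params: FusionParams, val) -> tuple[float, float]:
    """Validation loss (the stage objective) and mean per-gene Pearson r.

    The correlation is level-appropriate: global predictions across samples
    for bulk cohorts, concatenated local (spot) predictions for spatial
    cohorts."""
    losses = []
    g_pred, g_true, l_pred, l_true = [], [], [], []
    any_spot = False
    for s in val:
        out = forward(s.embeddings, params)
        from .fusion_model import loss_global, loss_local  # local import avoids cycle noise
        lg = loss_global(out.global_prediction, s.z_global, params.loss_reduce)
        if _is_spot_sample(s):
            any_spot = True
            ll = loss_local(out.local_predictions, s.z_local, params.loss_reduce)
            losses.append(ll + lg)
            l_pred.append(out.local_predictions)
            l_true.append(s.z_local)
        else:
            losses.append(lg)
            g_pred.append(out.global_prediction)
            g_true.append(s.z_global)
    loss = float(np.mean(losses))
    if any_spot:
        corr = mean_per_gene_r(np.vstack(l_pred), np.vstack(l_true))
    else:
        corr = mean_per_gene_r(np.vstack(g_pred), np.vstack(g_true))
    return loss, corr


def _init_head_biases(params: FusionParams, train: list) -> None:
    """Initialize the output-layer biases to the per-gene mean of the
    training targets (the regression base rate), so optimization starts
    from the mean predictor instead of spending steps crawling to it."""
    g_targets = [s.z_global for s in train]
    if g_targets:
        params.params["gb2"][:] = np.mean(np.vstack(g_targets), axis=0)
    l_targets = [s.z_local for s in train if _is_spot_sample(s)]
    if l_targets:
        params.params["lb2"][:] = np.mean(np.vstack(l_targets), axis=0)


def pretrain(params: FusionParams, train: list, val: list,
             cfg: TrainConfig) -> tuple[FusionParams, list[EpochRecord]]:
    """Pretrain one model on a bulk-only or spot-only cohort.

    Bulk samples optimize the global loss only; spatial samples optimize
    local + global (the pseudo-bulk profile is the global target).  One
    sample per optimization step; the saved checkpoint is the best epoch
    under the dual-criterion controller.
    """
    if not train:
        raise ValueError("empty training data")
    if not val:
        raise ValueError("empty validation data")
    _init_head_biases(params, train)
    opt = RAdam(params.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    records: list[EpochRecord] = []
    best = params.copy()
    for epoch in range(1, cfg.max_epochs + 1):
        for idx in rng.permutation(len(train)):
            s = train[idx]
            if _is_spot_sample(s):
                _, _, grads = forward_backward(
                    s.embeddings, params, z_local=s.z_local, z_global=s.z_global)
            else:
                _, _, grads = forward_backward(
                    s.embeddings, params, z_global=s.z_global)
            opt.step(params.params, grads)
        loss, corr = _validate(params, val)
        save, stop = early_stop_update(records, (loss, corr), cfg.patience)
        records.append(EpochRecord(epoch, loss, corr, save, stop))
        if save:
            best = params.copy()
        if stop:
            break
    return best, records


# ---------------------------------------------------------------------------
# Stage 2: joint bi-scale fine-tuning
# ---------------------------------------------------------------------------

def _paired_epoch_order(n_bulk: int, n_spot: int, rng: np.random.Generator):
    """Per-epoch pairing: the spatial pool is tiled to the bulk count and
    both sides are shuffled, so each of the n_bulk steps pairs one spatial
    with one bulk sample."""
    bulk_order = rng.permutation(n_bulk)
    tiled = np.tile(np.arange(n_spot), int(np.ceil(n_bulk / n_spot)))[:n_bulk]
    spot_order = tiled[rng.permutation(n_bulk)]
    return bulk_order, spot_order


class _FinetuneState:
    def __init__(self, params: FusionParams, w_local: float, w_global: float,
                 cfg: TrainConfig, val: list):
        self.params = params
        self.w_local = w_local
        self.w_global = w_global
        self.opt = RAdam(params.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
        self.val = val
        # the pretrained checkpoint is the baseline: fine-tuning only saves
        # strict correlation improvements, so it can never degrade it
        _, self.best_corr = _validate(params, val)
        self.best = params.copy()
        self.counter = 0
        self.active = True
        self.records: list[EpochRecord] = []


def finetune(bulk_model: FusionParams, spot_model: FusionParams,
             bulk_train: list, spot_train: list,
             bulk_val: list, spot_val: list,
             cfg: TrainConfig) -> tuple[FusionParams, FusionParams,
                                        list[EpochRecord], list[EpochRecord]]:
    """Joint fine-tuning of the bulk- and spot-focused models.

    loss_bulk = lam*local + (1-lam)*global and loss_spot mirrors the
    weights; the global term averages the spatial pseudo-bulk and the bulk
    sample contributions.  Checkpointing and stopping use the validation
    correlation only (level-appropriate per model).  Returns the two best
    checkpoints plus both epoch logs.
    """
    if bulk_model.G != spot_model.G or bulk_model.d != spot_model.d:
        raise ValueError("pretrained models must share (d, G)")
    panel_b = bulk_model.meta.get("gene_panel")
    panel_s = spot_model.meta.get("gene_panel")
    if panel_b is not None and panel_s is not None and list(panel_b) != list(panel_s):
        raise ValueError("pretrained models must share the gene panel")
    if not bulk_train or not spot_train:
        raise ValueError("both bulk and spatial training data are required")

    lam = cfg.lam
    ft_cfg = cfg
    states = {
        "bulk": _FinetuneState(bulk_model, lam, 1.0 - lam, ft_cfg, bulk_val),
        "spot": _FinetuneState(spot_model, 1.0 - lam, lam, ft_cfg, spot_val),
    }
    rng = np.random.default_rng(cfg.seed)
    for epoch in range(1, cfg.max_epochs + 1):
        bulk_order, spot_order = _paired_epoch_order(
            len(bulk_train), len(spot_train), rng)
        for bi, si in zip(bulk_order, spot_order):
            b, s = bulk_train[bi], spot_train[si]
            for st in states.values():
                if not st.active:
                    continue
                # spatial sample: local term + half the global term
                _, _, g1 = forward_backward(
                    s.embeddings, st.params, z_local=s.z_local,
                    z_global=s.z_global, w_local=st.w_local,
                    w_global=0.5 * st.w_global)
                # bulk sample: the other half of the global term
                _, _, g2 = forward_backward(
                    b.embeddings, st.params, z_global=b.z_global,
                    w_global=0.5 * st.w_global)
                for k in g1:
                    g1[k] += g2[k]
                st.opt.step(st.params.params, g1)
        for st in states.values():
            if not st.active:
                continue
            loss, corr = _validate(st.params, st.val)
            save = corr > st.best_corr
            if save:
                st.best_corr = corr
                st.best = st.params.copy()
                st.counter = 0
            else:
                st.counter += 1
            stop = st.counter >= cfg.patience
            st.records.append(EpochRecord(epoch, loss, corr, save, stop))
            if stop:
                st.active = False
        if not any(st.active for st in states.values()):
            break
    return (states["bulk"].best, states["spot"].best,
            states["bulk"].records, states["spot"].records)


# ---------------------------------------------------------------------------
# Prediction helpers
# ---------------------------------------------------------------------------

def predict_global(params: FusionParams, samples: list) -> np.ndarray:
    """Stacked global predictions, one row per sample."""
    return np.vstack([forward(s.embeddings, params).global_prediction
                      for s in samples])


def predict_local(params: FusionParams, samples: list) -> list[np.ndarray]:
    """Per-slide spot-level prediction matrices (n_spots x G each)."""
    return [forward(s.embeddings, params).local_predictions for s in samples]
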
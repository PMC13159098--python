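"""Per-gene accuracy metrics and the bulk-spot similarity AUC.

Predictions are evaluated gene-by-gene on vectors concatenated across all
test patients (bulk) or spots (spatial): Pearson r with a two-sided p-value
from the t approximation, plus MSE.  A gene is called well-predicted when
r exceeds the scale-specific threshold (0.4 bulk, 0.2 spot, strict) with
p < 0.05.

The similarity AUC asks whether predicted expression preserves the
bulk-spot relationship: every spot profile is correlated with every bulk
profile, per-spot means of the true correlations are median-binarized into
high/low labels, and the AUC measures how well the predicted per-spot
means rank those labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

WELL_PREDICTED_R = {"bulk": 0.4, "spot": 0.2}
WELL_PREDICTED_P = 0.05


@dataclass
class EvalReport:
    level: str
    per_gene: pd.DataFrame  # pearson_r, p_value, mse, well_predicted, degenerate
    median_r: float
    fraction_well_predicted: float

    def summary(self) -> dict:
        return {
            "level": self.level,
            "n_genes": int(len(self.per_gene)),
            "median_r": self.median_r,
            "fraction_well_predicted": self.fraction_well_predicted,
            "n_well_predicted": int(self.per_gene["well_predicted"].sum()),
        }

    def to_tsv(self, path) -> None:
        self.per_gene.to_csv(path, sep="\t", index=True, index_label="gene_id")


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pearson r with the two-sided t-approximation p-value; constant
    vectors yield (0, 1, degenerate=True)."""
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc ** 2).sum()), np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0 or n < 3:
        return 0.0, 1.0, True
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0, False
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p), False


def per_gene_metrics(pred: np.ndarray, truth: np.ndarray, level: str,
                     gene_ids: list[str] | None = None) -> EvalReport:
    """Per-gene Pearson r, p, MSE and well-predicted calls on concatenated
    predictions.

    ``pred`` and ``truth`` are samples x G with aligned rows and genes.
    Degenerate genes (constant in either vector) get r = 0 and are excluded
    from the median.
    """
    if level not in WELL_PREDICTED_R:
        raise ValueError(f"level must be 'bulk' or 'spot', got {level!r}")
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    G = pred.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(G)]
    rows = []
    for j in range(G):
        r, p, degen = _pearson_with_p(pred[:, j], truth[:, j])
        mse = float(np.mean((pred[:, j] - truth[:, j]) ** 2))
        well = (not degen) and (r > WELL_PREDICTED_R[level]) and (p < WELL_PREDICTED_P)
        rows.append((r, p, mse, well, degen))
    per_gene = pd.DataFrame(
        rows, columns=["pearson_r", "p_value", "mse", "well_predicted", "degenerate"],
        index=pd.Index(gene_ids, name="gene_id"),
    )
    valid = per_gene.loc[~per_gene["degenerate"], "pearson_r"]
    median_r = float(valid.median()) if len(valid) else float("nan")
    frac = float(per_gene["well_predicted"].mean())
    return EvalReport(level, per_gene, median_r, frac)


@dataclass
class SimilarityResult:
    corr_matrix: np.ndarray   # n_spots x m_bulk, predicted profiles
    spot_scores: np.ndarray   # per-spot mean over bulk samples (predicted)
    true_scores: np.ndarray   # same from ground truth
    labels: np.ndarray        # 1 iff true score > median of true scores
    auc: float


def _profile_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlations over the shared gene axis; constant
    profiles contribute 0."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    As = np.sqrt((Ac ** 2).sum(axis=1))
    Bs = np.sqrt((Bc ** 2).sum(axis=1))
    out = (Ac / np.where(As == 0, 1.0, As)[:, None]) @ (
        Bc / np.where(Bs == 0, 1.0, Bs)[:, None]).T
    out[As == 0, :] = 0.0
    out[:, Bs == 0] = 0.0
    return np.clip(out, -1.0, 1.0)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formula with midranks for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be non-empty")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bulk_spot_similarity_auc(pred_spot: np.ndarray, pred_bulk: np.ndarray,
                             true_spot: np.ndarray, true_bulk: np.ndarray
                             ) -> SimilarityResult:
    """Bulk-spot expression-similarity AUC over a shared gene panel.

    All four matrices are profiles x genes.  Correlating each spot profile
    with each bulk profile gives an n x m matrix; per-spot means are the
    similarity scores.  Ground-truth scores are median-binarized (strictly
    above the median = high) and the AUC of the predicted scores against
    those labels is returned.
    """
    mats = [np.asarray(m, float) for m in (pred_spot, pred_bulk, true_spot, true_bulk)]
    pred_spot, pred_bulk, true_spot, true_bulk = mats
    n, m = pred_spot.shape[0], pred_bulk.shape[0]
    if n < 2 or m < 2:
        raise ValueError("need at least 2 spots and 2 bulk samples")
    if len({a.shape[1] for a in mats}) != 1:
        raise ValueError("all matrices must share the gene panel")
    corr = _profile_correlations(pred_spot, pred_bulk)
    spot_scores = corr.mean(axis=1)
    true_corr = _profile_correlations(true_spot, true_bulk)
    true_scores = true_corr.mean(axis=1)
    labels = true_scores > np.median(true_scores)
    auc = rank_auc(spot_scores, labels)
    return SimilarityResult(corr, spot_scores, true_scores,
                            labels.astype(int), auc)
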
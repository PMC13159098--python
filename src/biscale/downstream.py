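"""Downstream procedures applied to predicted expression.

Covers the recurrence-risk score (weighted sum of fitted proportional-
hazards coefficients over predicted expression) with median stratification,
tumor-stage binarization, rank-based differential expression with the
FDR < 0.05 & fold-change > 1.25 filter, and meta-program spatial
co-expression with hierarchical clustering.  Model *fitting* (penalized
Cox, Scissor, deconvolution, pathway scoring) happens in external tools;
this module applies their outputs to predictions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

#: DE filter thresholds
DE_FDR = 0.05
DE_FOLD_CHANGE = 1.25
#: selection fractions used by external Scissor analyses (interoperability
#: constants only; no selection is performed here)
SCISSOR_TUMOR_FRACTION = 0.03
SCISSOR_RECURRENCE_FRACTION = 0.10

META_PROGRAM_NAMES = ("cell cycle", "stress/hypoxia", "mesenchymal",
                      "protein regulation")


@dataclass
class RiskModel:
    """Externally fitted proportional-hazards signature: genes + coefficients."""

    gene_ids: list[str]
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.gene_ids) != len(self.coefficients):
            raise ValueError("one coefficient per gene is required")
        if not np.any(self.coefficients != 0):
            raise ValueError("risk model must have at least one nonzero coefficient")

    @classmethod
    def from_tsv(cls, path) -> "RiskModel":
        df = pd.read_csv(path, sep="\t")
        return cls(df["gene_id"].tolist(), df["coefficient"].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": self.gene_ids,
                      "coefficient": self.coefficients}).to_csv(
            path, sep="\t", index=False)


@dataclass
class MetaProgramSet:
    """One transcriptional meta-program of intratumor heterogeneity."""

    program_name: str
    gene_ids: list[str]


def risk_score(expr: np.ndarray, gene_ids: list[str], model: RiskModel) -> np.ndarray:
    """Per-sample risk score: sum_i C_i x Exp_i over the model genes.

    ``expr`` is samples x genes with columns named by ``gene_ids``.
    """
    expr = np.asarray(expr, float)
    idx = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in model.gene_ids if g not in idx]
    if missing:
        raise KeyError(f"model gene(s) absent from expression: {missing[:5]}")
    cols = [idx[g] for g in model.gene_ids]
    return expr[:, cols] @ model.coefficients


def stratify_by_median(scores: np.ndarray) -> np.ndarray:
    """Median split into 'high' / 'low'; ties at the median go to 'low'."""
    scores = np.asarray(scores, float)
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if np.all(scores == scores[0]):
        raise ValueError("all scores equal; median stratification undefined")
    med = np.median(scores)
    return np.where(scores > med, "high", "low")


_STAGE_MAP = {"I": "low", "II": "low", "III": "high", "IV": "high"}


def binarize_stage(stages) -> np.ndarray:
    """Collapse AJCC-style stages: I-II -> low, III-IV -> high.

    Accepts sub-stages ('IIA') and 'Stage ' prefixes; anything else raises
    with the offending values listed.
    """
    out, bad = [], []
    for s in stages:
        t = re.sub(r"^stage\s*", "", str(s).strip(), flags=re.IGNORECASE).upper()
        t = re.sub(r"[ABC]$", "", t)
        if t in _STAGE_MAP:
            out.append(_STAGE_MAP[t])
        else:
            bad.append(s)
    if bad:
        raise ValueError(f"unparseable stage value(s): {bad}")
    return np.array(out)


def de_genes(group_a: np.ndarray, group_b: np.ndarray,
             gene_ids: list[str] | None = None, paired: bool = False,
             values_are_log2p1: bool = True) -> pd.DataFrame:
    """Rank-based two-group differential expression with the FDR/FC filter.

    Uses the Wilcoxon signed-rank test when ``paired`` (bulk usage) and the
    rank-sum (Mann-Whitney) test otherwise (spot usage), Benjamini-Hochberg
    FDR, and fold change as the ratio of group means on the linear scale
    (inputs on log2(v+1) scale are de-logged first).  A gene is called DE
    iff fdr < 0.05 and fold change > 1.25 (up) or < 1/1.25 (down).
    """
    A, B = np.asarray(group_a, float), np.asarray(group_b, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be samples x G with matching genes")
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired test requires equal group sizes")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 samples (or pairs) per group")
    G = A.shape[1]
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(G)]
    lin_a = np.power(2.0, A) - 1.0 if values_are_log2p1 else A
    lin_b = np.power(2.0, B) - 1.0 if values_are_log2p1 else B
    stat = np.empty(G)
    pval = np.empty(G)
    for j in range(G):
        if paired:
            diff = A[:, j] - B[:, j]
            if np.all(diff == 0):
                stat[j], pval[j] = 0.0, 1.0
            else:
                res = stats.wilcoxon(A[:, j], B[:, j], zero_method="wilcox",
                                     alternative="two-sided")
                stat[j], pval[j] = res.statistic, res.pvalue
        else:
            res = stats.mannwhitneyu(A[:, j], B[:, j], alternative="two-sided")
            stat[j], pval[j] = res.statistic, res.pvalue
    fdr = multipletests(pval, method="fdr_bh")[1]
    eps = 1e-12
    fc = (lin_a.mean(axis=0) + eps) / (lin_b.mean(axis=0) + eps)
    direction = np.where(fc >= 1.0, "up", "down")
    is_de = (fdr < DE_FDR) & ((fc > DE_FOLD_CHANGE) | (fc < 1.0 / DE_FOLD_CHANGE))
    return pd.DataFrame(
        {"statistic": stat, "p": pval, "fdr": fdr, "fold_change": fc,
         "direction": direction, "de": is_de},
        index=pd.Index(gene_ids, name="gene_id"),
    )


def apply_de_filter(fdr: np.ndarray, fold_change: np.ndarray) -> np.ndarray:
    """The bare DE call on precomputed (fdr, fold-change) pairs."""
    fdr, fc = np.asarray(fdr, float), np.asarray(fold_change, float)
    return (fdr < DE_FDR) & ((fc > DE_FOLD_CHANGE) | (fc < 1.0 / DE_FOLD_CHANGE))


def metaprogram_spatial_correlation(
    slide_preds: list[np.ndarray],
    gene_ids: list[str],
    programs: list[MetaProgramSet],
    n_clusters: int = 2,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Cross-sample spatial co-expression of meta-program genes.

    Per slide (spots x G predictions), pairwise Pearson correlations among
    all program genes are computed over that slide's spots; the per-slide
    matrices are averaged into a cross-sample matrix.  Average-linkage
    hierarchical clustering on distance 1 - r groups genes with similar
    spatial patterns.  Returns (correlation matrix, cluster labels,
    program membership), all indexed by gene.
    """
    if not slide_preds:
        raise ValueError("at least one slide is required")
    panel = set(gene_ids)
    membership: dict[str, str] = {}
    for prog in programs:
        kept = [g for g in prog.gene_ids if g in panel]
        for g in kept:
            membership.setdefault(g, prog.program_name)
    prog_genes = [g for g in gene_ids if g in membership]
    if not prog_genes:
        raise ValueError("no program gene overlaps the prediction panel")
    col = {g: i for i, g in enumerate(gene_ids)}
    idx = [col[g] for g in prog_genes]
    k = len(prog_genes)
    acc = np.zeros((k, k))
    degenerate = np.ones(k, dtype=bool)
    for pred in slide_preds:
        sub = np.asarray(pred, float)[:, idx]
        c = sub - sub.mean(axis=0)
        s = np.sqrt((c ** 2).sum(axis=0))
        ok = s > 0
        degenerate &= ~ok
        z = c / np.where(ok, s, 1.0)
        r = z.T @ z
        r[~ok, :] = 0.0
        r[:, ~ok] = 0.0
        np.fill_diagonal(r, 1.0)
        acc += np.clip(r, -1.0, 1.0)
    mean_r = acc / len(slide_preds)
    mean_r[degenerate, :] = 0.0
    mean_r[:, degenerate] = 0.0
    mean_r = (mean_r + mean_r.T) / 2.0
    np.fill_diagonal(mean_r, 1.0)
    dist = np.clip(1.0 - mean_r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    corr_df = pd.DataFrame(mean_r, index=prog_genes, columns=prog_genes)
    return (corr_df,
            pd.Series(labels, index=prog_genes, name="cluster"),
            pd.Series({g: membership[g] for g in prog_genes}, name="program"))
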
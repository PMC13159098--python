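"""Expression normalization and target-gene selection at both scales.

Bulk RNA-seq counts are converted to TPM, Visium-style spot counts to CPM,
and per-slide pseudo-bulk profiles are built by summing spot counts and
CPM-normalizing the sum.  All matrices are then log2(v+1)-transformed so the
bulk and spot targets share a dynamic range.  The image-predictable gene
panel is selected by ranking gene-vs-image-feature correlations within each
scale and averaging the two ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MILLION = 1e6
#: column-sum relative tolerance for TPM/CPM matrices
NORM_RTOL = 1e-3
#: default minimum number of detected genes for a spot to be kept
DEFAULT_MIN_GENES = 100
#: default size of the image-predictable target-gene panel
DEFAULT_PANEL_SIZE = 1000

_VALID_STATES = ("raw_counts", "tpm", "cpm", "log2p1")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with a normalization-state tag.

    Parameters
    ----------
    values
        Non-negative matrix, genes as rows, samples (or spots) as columns.
    gene_ids, sample_ids
        Ordered unique identifiers for rows / columns.
    state
        One of ``raw_counts``, ``tpm``, ``cpm``, ``log2p1``.
    gene_lengths
        Optional per-gene lengths in bases; required for TPM conversion.
    zero_columns
        QC flags: columns that were all-zero in the raw counts and were kept
        as zeros through normalization.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    state: str = "raw_counts"
    gene_lengths: np.ndarray | None = None
    zero_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x sample matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.state not in _VALID_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if self.zero_columns is None:
            self.zero_columns = np.zeros(len(self.sample_ids), dtype=bool)
        if self.state in ("tpm", "cpm"):
            sums = self.values.sum(axis=0)
            ok = self.zero_columns | np.isclose(sums, MILLION, rtol=NORM_RTOL)
            if not ok.all():
                bad = [self.sample_ids[i] for i in np.flatnonzero(~ok)]
                raise ValueError(
                    f"{self.state} columns must sum to 1e6; offending: {bad[:5]}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.gene_ids),
            list(self.sample_ids),
            self.state,
            None if self.gene_lengths is None else self.gene_lengths.copy(),
            self.zero_columns.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSelection:
    """Result of the two-scale mean-rank target-gene selection."""

    gene_ids: list[str]  # the selected panel, ordered best-first
    table: pd.DataFrame  # all common genes: score/rank per level, mean_rank, selected
    K: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="gene_id")


def _require_state(m: ExpressionMatrix, *states: str) -> None:
    if m.state not in states:
        raise ValueError(f"expected state in {states}, got {m.state!r}")


def counts_to_tpm(m: ExpressionMatrix, lengths: np.ndarray | None = None) -> ExpressionMatrix:
    """Convert raw counts to transcripts-per-million.

    Counts are divided by gene length in kilobases to obtain per-gene rates,
    and each column of rates is rescaled to sum to 1e6.  All-zero columns are
    preserved as zeros and flagged in ``zero_columns``.
    """
    _require_state(m, "raw_counts")
    if lengths is None:
        lengths = m.gene_lengths
    if lengths is None:
        raise ValueError("gene lengths are required for TPM conversion")
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != (m.n_genes,):
        raise ValueError("one length per gene is required")
    bad = ~(lengths > 0)
    if bad.any():
        raise ValueError(
            f"non-positive gene length for {[m.gene_ids[i] for i in np.flatnonzero(bad)[:5]]}"
        )
    rate = m.values / (lengths[:, None] / 1e3)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    safe = np.where(zero, 1.0, colsum)
    tpm = rate / safe[None, :] * MILLION
    tpm[:, zero] = 0.0
    return ExpressionMatrix(
        tpm, list(m.gene_ids), list(m.sample_ids), "tpm", lengths.copy(), zero
    )


def counts_to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each raw-count column to sum to 1e6 (counts-per-million)."""
    _require_state(m, "raw_counts")
    colsum = m.values.sum(axis=0)
    zero = colsum == 0
    safe = np.where(zero, 1.0, colsum)
    cpm = m.values / safe[None, :] * MILLION
    cpm[:, zero] = 0.0
    return ExpressionMatrix(
        cpm, list(m.gene_ids), list(m.sample_ids), "cpm", None, zero
    )


def make_pseudobulk(spots: ExpressionMatrix) -> np.ndarray:
    """Sum spot counts gene-wise and CPM-normalize the summed vector.

    The result is the per-slide pseudo-bulk profile used as the bulk-scale
    training target for spatial samples.  Returns a per-gene CPM vector that
    sums to 1e6 (unless the slide has no counts at all, which is an error).
    """
    _require_state(spots, "raw_counts")
    if spots.n_samples == 0:
        raise ValueError("cannot build a pseudo-bulk profile from zero spots")
    total = spots.values.sum(axis=1)
    s = total.sum()
    if s == 0:
        raise ValueError("all spot counts are zero; pseudo-bulk undefined")
    return total / s * MILLION


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply v -> log2(v + 1) elementwise to a TPM or CPM matrix."""
    _require_state(m, "tpm", "cpm")
    out = np.log2(m.values + 1.0)
    return ExpressionMatrix(
        out, list(m.gene_ids), list(m.sample_ids), "log2p1", None, m.zero_columns.copy()
    )


def filter_spots(spots: ExpressionMatrix, min_genes: int = DEFAULT_MIN_GENES) -> ExpressionMatrix:
    """Keep spots with at least ``min_genes`` genes detected (value > 0).

    The threshold is inclusive and spot order is preserved.  May return a
    matrix with zero spots; the caller decides how to handle that.
    """
    n_detected = (spots.values > 0).sum(axis=0)
    keep = n_detected >= min_genes
    return ExpressionMatrix(
        spots.values[:, keep],
        list(spots.gene_ids),
        [s for s, k in zip(spots.sample_ids, keep) if k],
        spots.state,
        None if spots.gene_lengths is None else spots.gene_lengths.copy(),
        spots.zero_columns[keep],
    )


def restrict_to_protein_coding(m: ExpressionMatrix, coding_ids) -> ExpressionMatrix:
    """Filter the gene axis to a user-supplied protein-coding id set."""
    coding = set(coding_ids)
    keep = np.array([g in coding for g in m.gene_ids], dtype=bool)
    if not keep.any():
        raise ValueError("no genes left after protein-coding restriction")
    return ExpressionMatrix(
        m.values[keep],
        [g for g, k in zip(m.gene_ids, keep) if k],
        list(m.sample_ids),
        m.state,
        None if m.gene_lengths is None else m.gene_lengths[keep],
        m.zero_columns.copy(),
    )


def _max_abs_correlation(expr: np.ndarray, feats: np.ndarray) -> np.ndarray:
    """Per gene, the maximum |Pearson r| against any feature dimension.

    expr: samples x genes, feats: samples x d.  Constant gene or feature
    columns contribute correlation 0 (with a warning for constant genes).
    """
    n = expr.shape[0]
    if feats.shape[0] != n:
        raise ValueError("expression and features must share sample ordering")
    ec = expr - expr.mean(axis=0)
    fc = feats - feats.mean(axis=0)
    es = np.sqrt((ec ** 2).sum(axis=0))
    fs = np.sqrt((fc ** 2).sum(axis=0))
    const_genes = es == 0
    if const_genes.any():
        warnings.warn(
            f"{int(const_genes.sum())} constant gene column(s); correlation set to 0",
            stacklevel=3,
        )
    es_safe = np.where(const_genes, 1.0, es)
    fs_safe = np.where(fs == 0, 1.0, fs)
    r = (ec / es_safe).T @ (fc / fs_safe)  # genes x d
    r[const_genes, :] = 0.0
    r[:, fs == 0] = 0.0
    return np.abs(r).max(axis=1)


def select_target_genes(
    bulk: ExpressionMatrix,
    bulk_features: np.ndarray,
    spot: ExpressionMatrix,
    spot_features: np.ndarray,
    K: int = DEFAULT_PANEL_SIZE,
) -> GeneSelection:
    """Select the image-predictable gene panel by two-scale mean rank.

    Per gene and per scale the image-association score is the maximum
    absolute Pearson correlation between that gene's expression and any of
    the image-feature dimensions.  Scores are ranked within each scale
    (rank 1 = highest score, ties receive average ranks), the two ranks are
    averaged, and the ``K`` genes with the best (smallest) mean rank are
    selected; residual ties break lexicographically on gene id.
    """
    common = sorted(set(bulk.gene_ids) & set(spot.gene_ids))
    if K > len(common):
        raise ValueError(f"K={K} exceeds the {len(common)} genes common to both scales")
    b_idx = {g: i for i, g in enumerate(bulk.gene_ids)}
    s_idx = {g: i for i, g in enumerate(spot.gene_ids)}
    b_expr = bulk.values[[b_idx[g] for g in common]].T  # samples x genes
    s_expr = spot.values[[s_idx[g] for g in common]].T
    score_bulk = _max_abs_correlation(b_expr, np.asarray(bulk_features, dtype=float))
    score_spot = _max_abs_correlation(s_expr, np.asarray(spot_features, dtype=float))
    # rank 1 = highest score; average ranks on ties
    rank_bulk = rankdata(-score_bulk, method="average")
    rank_spot = rankdata(-score_spot, method="average")
    mean_rank = (rank_bulk + rank_spot) / 2.0
    order = sorted(range(len(common)), key=lambda i: (mean_rank[i], common[i]))
    selected_idx = order[:K]
    selected = [common[i] for i in selected_idx]
    sel_mask = np.zeros(len(common), dtype=bool)
    sel_mask[selected_idx] = True
    table = pd.DataFrame(
        {
            "score_bulk": score_bulk,
            "score_spot": score_spot,
            "rank_bulk": rank_bulk,
            "rank_spot": rank_spot,
            "mean_rank": mean_rank,
            "selected": sel_mask,
        },
        index=pd.Index(common, name="gene_id"),
    )
    return GeneSelection(gene_ids=selected, table=table, K=K)
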
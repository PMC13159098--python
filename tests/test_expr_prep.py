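"""Normalization, pseudo-bulk, spot filtering and gene-panel selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from biscale import (ExpressionMatrix, counts_to_cpm, counts_to_tpm,
                     filter_spots, log_transform, make_pseudobulk,
                     restrict_to_protein_coding, select_target_genes)

MILLION = 1e6


def em(values, state="raw_counts", lengths=None):
    values = np.atleast_2d(np.asarray(values, float))
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(values.shape[0])],
                            [f"s{i}" for i in range(values.shape[1])],
                            state, lengths)


class TestTPM:
    def test_single_gene_forced_to_million(self):
        out = counts_to_tpm(em([[7.0]]), np.array([1234.0]))
        assert out.values[0, 0] == pytest.approx(MILLION)

    def test_equal_counts_equal_lengths_split_evenly(self):
        out = counts_to_tpm(em([[10.0], [10.0]]), np.array([1000.0, 1000.0]))
        np.testing.assert_allclose(out.values[:, 0], [5e5, 5e5])

    def test_length_correction(self):
        # rates 10/1 and 20/4 = 5 -> 2/3 vs 1/3 of a million
        out = counts_to_tpm(em([[10.0], [20.0]]), np.array([1000.0, 4000.0]))
        np.testing.assert_allclose(out.values[:, 0], [666666.67, 333333.33],
                                   rtol=1e-6)

    def test_matches_spreadsheet_oracle_on_random_counts(self, random_counts):
        m = random_counts(15, 6)
        lengths = np.random.default_rng(1).uniform(500, 5000, 15)
        out = counts_to_tpm(m, lengths)
        # independent elementwise oracle
        expected = np.empty_like(m.values)
        for j in range(6):
            rates = [m.values[i, j] / (lengths[i] / 1e3) for i in range(15)]
            for i in range(15):
                expected[i, j] = rates[i] / sum(rates) * MILLION
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_zero_length_error_names_gene(self):
        with pytest.raises(ValueError, match="g1"):
            counts_to_tpm(em([[1.0], [1.0]]), np.array([100.0, 0.0]))

    def test_wrong_state_rejected(self):
        with pytest.raises(ValueError, match="state"):
            counts_to_tpm(em([[1e6]], state="cpm"), np.array([100.0]))


class TestCPM:
    def test_proportional_scaling(self):
        out = counts_to_cpm(em([[1.0], [1.0], [2.0]]))
        np.testing.assert_allclose(out.values[:, 0], [250000, 250000, 500000])

    def test_zero_column_kept_and_flagged(self):
        out = counts_to_cpm(em([[1.0, 0.0], [3.0, 0.0]]))
        assert out.zero_columns.tolist() == [False, True]
        np.testing.assert_array_equal(out.values[:, 1], 0.0)

    def test_matches_per_column_oracle(self, random_counts):
        m = random_counts(20, 5)
        out = counts_to_cpm(m)
        for j in range(5):
            tot = m.values[:, j].sum()
            np.testing.assert_allclose(out.values[:, j],
                                       m.values[:, j] / tot * MILLION)

    def test_column_sums_are_a_million(self, random_counts):
        out = counts_to_cpm(random_counts(30, 8))
        np.testing.assert_allclose(out.values.sum(axis=0), MILLION, rtol=1e-3)


class TestPseudobulk:
    def test_single_spot_equals_its_cpm(self):
        m = em([[3.0], [1.0]])
        np.testing.assert_allclose(make_pseudobulk(m),
                                   counts_to_cpm(m).values[:, 0])

    def test_identical_spots_equal_either_cpm(self):
        m = em([[3.0, 3.0], [1.0, 1.0]])
        np.testing.assert_allclose(make_pseudobulk(m),
                                   counts_to_cpm(m).values[:, 0])

    def test_matches_column_sum_oracle(self, random_counts):
        m = random_counts(30, 8)
        total = m.values.sum(axis=1)
        np.testing.assert_allclose(make_pseudobulk(m),
                                   total / total.sum() * MILLION)

    def test_invariant_to_spot_order(self, random_counts):
        m = random_counts(12, 9)
        perm = np.random.default_rng(0).permutation(9)
        m2 = ExpressionMatrix(m.values[:, perm], list(m.gene_ids),
                              [m.sample_ids[i] for i in perm], "raw_counts")
        np.testing.assert_allclose(make_pseudobulk(m), make_pseudobulk(m2))

    def test_empty_matrix_rejected(self):
        m = ExpressionMatrix(np.zeros((3, 0)), ["a", "b", "c"], [], "raw_counts")
        with pytest.raises(ValueError):
            make_pseudobulk(m)


class TestLogTransform:
    @pytest.mark.parametrize("v,expected", [(0.0, 0.0), (1.0, 1.0), (3.0, 2.0)])
    def test_reference_points(self, v, expected):
        m = ExpressionMatrix(np.array([[v]]), ["g"], ["s"], "cpm",
                             zero_columns=np.array([True]))
        assert log_transform(m).values[0, 0] == pytest.approx(expected)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(np.float64, (4, 3),
                      elements=st.floats(0, 60, allow_nan=False)))
    def test_inverts_exp2_minus_one(self, logvals):
        m = ExpressionMatrix(np.exp2(logvals) - 1.0,
                             [f"g{i}" for i in range(4)],
                             [f"s{i}" for i in range(3)], "cpm",
                             zero_columns=np.ones(3, bool))
        np.testing.assert_allclose(log_transform(m).values, logvals, atol=1e-9)

    def test_raw_counts_rejected(self):
        with pytest.raises(ValueError, match="state"):
            log_transform(em([[1.0]]))


class TestFilterSpots:
    def test_boundary_inclusive(self):
        values = np.zeros((120, 2))
        values[:100, 0] = 1.0   # exactly 100 detected genes: retained
        values[:99, 1] = 1.0    # 99: dropped
        out = filter_spots(em(values), min_genes=100)
        assert out.sample_ids == ["s0"]

    def test_all_below_threshold_gives_empty(self):
        out = filter_spots(em(np.ones((5, 3))), min_genes=100)
        assert out.n_samples == 0

    def test_order_preserved(self):
        values = np.ones((3, 4))
        values[:, 2] = 0.0
        out = filter_spots(em(values), min_genes=2)
        assert out.sample_ids == ["s0", "s1", "s3"]


class TestRestrictProteinCoding:
    def test_identity_when_all_coding(self):
        m = em(np.arange(6.0).reshape(3, 2))
        out = restrict_to_protein_coding(m, set(m.gene_ids))
        np.testing.assert_array_equal(out.values, m.values)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            restrict_to_protein_coding(em(np.ones((3, 2))), set())

    def test_subset_keeps_original_order(self):
        m = em(np.arange(20.0).reshape(10, 2))
        out = restrict_to_protein_coding(m, {"g7", "g2", "g9", "g0"})
        assert out.gene_ids == ["g0", "g2", "g7", "g9"]
        np.testing.assert_array_equal(out.values, m.values[[0, 2, 7, 9]])


def _panel_fixture(seed, n_samples, genes_planted, genes_noise, d=3, noise=0.05):
    """Expression where 'planted' genes track a feature dimension."""
    rng = np.random.default_rng(seed)
    feats = rng.normal(size=(n_samples, d))
    gene_ids, rows = [], []
    for i in range(genes_planted):
        gene_ids.append(f"planted{i:02d}")
        rows.append(5.0 + feats[:, i % d] + noise * rng.normal(size=n_samples))
    for i in range(genes_noise):
        gene_ids.append(f"noise{i:02d}")
        rows.append(5.0 + rng.normal(size=n_samples))
    values = np.clip(np.array(rows), 0, None)
    m = ExpressionMatrix(values, gene_ids,
                         [f"s{i}" for i in range(n_samples)], "log2p1")
    return m, feats


class TestSelectTargetGenes:
    def test_planted_genes_recovered(self):
        bulk, bfeats = _panel_fixture(1, 40, 10, 40)
        spot, sfeats = _panel_fixture(2, 60, 10, 40)
        sel = select_target_genes(bulk, bfeats, spot, sfeats, K=10)
        assert sorted(sel.gene_ids) == sorted(g for g in bulk.gene_ids
                                              if g.startswith("planted"))

    def test_perfect_correlation_gene_ranks_first(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(30, 2))
        values = np.vstack([feats[:, 0], rng.normal(size=30), rng.normal(size=30)])
        m = ExpressionMatrix(values - values.min() + 0.1, ["hit", "n1", "n2"],
                             [f"s{i}" for i in range(30)], "log2p1")
        sel = select_target_genes(m, feats, m, feats, K=1)
        assert sel.gene_ids == ["hit"]
        assert sel.table.loc["hit", "rank_bulk"] == 1.0

    def test_tied_scores_break_lexicographically(self):
        rng = np.random.default_rng(4)
        feats = rng.normal(size=(20, 1))
        sig = feats[:, 0]
        values = np.vstack([sig, sig, rng.normal(size=20)])  # two identical genes
        m = ExpressionMatrix(values - values.min() + 0.1, ["zz", "aa", "nn"],
                             [f"s{i}" for i in range(20)], "log2p1")
        sel = select_target_genes(m, feats, m, feats, K=1)
        assert sel.gene_ids == ["aa"]

    def test_gene_order_invariance_up_to_tiebreak(self):
        bulk, bfeats = _panel_fixture(5, 25, 5, 20)
        spot, sfeats = _panel_fixture(6, 35, 5, 20)
        sel1 = select_target_genes(bulk, bfeats, spot, sfeats, K=8)
        perm = np.random.default_rng(0).permutation(bulk.n_genes)
        bulk2 = ExpressionMatrix(bulk.values[perm],
                                 [bulk.gene_ids[i] for i in perm],
                                 list(bulk.sample_ids), "log2p1")
        spot2 = ExpressionMatrix(spot.values[perm],
                                 [spot.gene_ids[i] for i in perm],
                                 list(spot.sample_ids), "log2p1")
        sel2 = select_target_genes(bulk2, bfeats, spot2, sfeats, K=8)
        assert sel1.gene_ids == sel2.gene_ids

    def test_constant_gene_scores_zero_with_warning(self):
        rng = np.random.default_rng(7)
        feats = rng.normal(size=(15, 2))
        values = np.vstack([np.full(15, 2.0), rng.normal(size=15) + 5])
        m = ExpressionMatrix(values, ["flat", "var"],
                             [f"s{i}" for i in range(15)], "log2p1")
        with pytest.warns(UserWarning, match="constant"):
            sel = select_target_genes(m, feats, m, feats, K=1)
        assert sel.table.loc["flat", "score_bulk"] == 0.0
        assert sel.gene_ids == ["var"]

    def test_oversized_panel_rejected(self):
        bulk, bfeats = _panel_fixture(8, 20, 2, 3)
        with pytest.raises(ValueError, match="K"):
            select_target_genes(bulk, bfeats, bulk, bfeats, K=10)
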
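"""Length weighting, RPKM, TMM factors and the two redundancy filters."""

import numpy as np
import pandas as pd
import pytest

from conftest import EDGER_TMM_FACTORS, EDGER_TMM_REFERENCE, make_tmm_matrix
from transcriptage.expression import ExpressionMatrix
from transcriptage.preprocess import (
    filter_correlated_duplicates,
    filter_sequence_redundant,
    length_weight,
    rpkm,
    tmm_factors,
    tmm_normalize,
    tmm_reference_stage,
)


def matrix(values, genes=None, stages=None, kind="raw_counts"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    stages = stages or [f"S{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=stages), kind)


def gene_table(lengths, genes=None):
    genes = genes or [f"g{i + 1}" for i in range(len(lengths))]
    return pd.DataFrame({"gene_id": genes, "cds_length": lengths})


class TestLengthWeight:
    def test_division_and_zero(self):
        out = length_weight(matrix([[100.0, 0.0]]), gene_table([1000]))
        assert out.values[0, 0] == pytest.approx(0.1)
        assert out.values[0, 1] == 0.0
        assert out.kind == "length_weighted"

    def test_length_ratio(self):
        out = length_weight(matrix([[100.0], [100.0]]), gene_table([500, 2000]))
        assert out.values[0, 0] == pytest.approx(0.2)
        assert out.values[1, 0] == pytest.approx(0.05)
        assert out.values[0, 0] / out.values[1, 0] == pytest.approx(4.0)

    def test_missing_length_names_gene(self):
        with pytest.raises(KeyError, match="g2"):
            length_weight(matrix([[1.0], [1.0]]), gene_table([100], genes=["g1"]))


class TestRpkm:
    def test_definitional(self):
        counts = matrix([[10.0], [999990.0]], genes=["g1", "filler"])
        out = rpkm(counts, gene_table([1000, 1_000_000], genes=["g1", "filler"]))
        assert out.values[0, 0] == pytest.approx(10.0)

    def test_hand_value(self):
        counts = matrix([[5.0], [2e6 - 5.0]], genes=["g1", "filler"])
        out = rpkm(counts, gene_table([500, 10_000], genes=["g1", "filler"]))
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_doubling_all_counts_leaves_rpkm_unchanged(self):
        counts = matrix([[10.0, 20.0], [90.0, 80.0]])
        genes = gene_table([1000, 2000])
        doubled = matrix(counts.values * 2)
        np.testing.assert_allclose(rpkm(counts, genes).values, rpkm(doubled, genes).values)

    def test_column_normalized_length_weight_proportional_to_rpkm(self):
        rng = np.random.default_rng(5)
        counts = matrix(rng.poisson(50.0, (30, 4)) + 1.0)
        genes = gene_table(rng.integers(300, 3000, 30).tolist())
        lw = length_weight(counts, genes)
        lw_norm = lw.values / lw.values.sum(axis=0)
        rp = rpkm(counts, genes).values
        for j in range(4):  # proportional per stage
            ratio = rp[:, j] / lw_norm[:, j]
            np.testing.assert_allclose(ratio, ratio[0])


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        col = np.arange(1.0, 51.0)
        m = matrix(np.column_stack([col, col]))
        assert tmm_factors(m).tolist() == [1.0, 1.0]

    def test_proportional_libraries_give_unit_factors(self):
        col = np.arange(1.0, 51.0)
        m = matrix(np.column_stack([col, 2 * col]))
        assert tmm_factors(m).tolist() == [1.0, 1.0]

    def test_matches_edger_oracle(self):
        factors = tmm_factors(make_tmm_matrix(), reference=EDGER_TMM_REFERENCE)
        for stage, expected in EDGER_TMM_FACTORS.items():
            assert factors[stage] == pytest.approx(expected, abs=1e-6)

    def test_reference_selection_matches_upper_quartile_rule(self):
        assert tmm_reference_stage(make_tmm_matrix()) == EDGER_TMM_REFERENCE

    def test_library_size_invariance(self):
        # M-values and the double trim see only proportions, so unweighted
        # factors are exactly scale-invariant; the precision-weighted default
        # depends mildly on absolute counts
        rng = np.random.default_rng(41)
        cont = matrix(rng.lognormal(3.0, 1.0, (200, 4)))  # tie-free values
        factors = np.array([3.0, 0.5, 7.0, 1.9])
        cont_scaled = cont.with_values(cont.values * factors, cont.kind)
        np.testing.assert_allclose(
            tmm_factors(cont, reference="S4", weighted=False).to_numpy(),
            tmm_factors(cont_scaled, reference="S4", weighted=False).to_numpy(),
            rtol=1e-9)
        # discrete counts tie in M, and precision weights see absolute
        # counts: the default is invariant only approximately
        m = make_tmm_matrix()
        scaled = m.with_values(m.values * factors, m.kind)
        np.testing.assert_allclose(tmm_factors(m, reference="L4").to_numpy(),
                                   tmm_factors(scaled, reference="L4").to_numpy(),
                                   rtol=0.10)

    def test_all_zero_stage_rejected(self):
        m = matrix([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(m)

    def test_normalize_restores_composition(self):
        # noise-free composition shift: library B equals A except 10 genes
        # inflated 8-fold; after TMM scaling the unaffected genes take
        # identical values in both libraries
        rng = np.random.default_rng(99)
        base = rng.lognormal(4.0, 1.0, 200).round() + 1.0
        b = base.copy()
        b[:10] *= 8
        m = matrix(np.column_stack([base, b]))
        scaled = tmm_normalize(m, reference="S1")
        assert scaled.kind == "tmm_scaled"
        np.testing.assert_allclose(scaled.values[10:, 0], scaled.values[10:, 1], rtol=1e-10)


class TestCorrelationFilter:
    def make_inputs(self):
        # one 3-gene component (identical short, hot genes), one 2-gene
        # component, one independent gene
        base = np.array([1000.0, 30000.0, 2000.0, 15000.0, 500.0])
        rows = [base, base * 2.0, base * 3.0,
                base[::-1], base[::-1] * 1.5,
                np.array([5.0, 300.0, 20000.0, 80.0, 60.0])]
        m = matrix(rows)
        genes = gene_table([300, 250, 400, 200, 350, 450])
        return m, genes

    def test_toy_components_collapse(self):
        m, genes = self.make_inputs()
        filtered, report = filter_correlated_duplicates(m, genes, max_length_bp=500,
                                                        min_peak_expression=10_000)
        assert len(report.removed) == 3
        assert filtered.n_genes == 3
        # representatives are the longest CDS of each component: g3 (400), g5 (350)
        assert set(filtered.gene_ids) >= {"g3", "g5", "g6"}

    def test_perfect_pair_collapses(self):
        m = matrix([np.array([1.0, 2.0, 3.0]) * 20000, np.array([2.0, 4.0, 6.0]) * 20000])
        _, report = filter_correlated_duplicates(m, gene_table([100, 200]),
                                                 max_length_bp=500, min_peak_expression=1)
        assert report.removed_genes == ["g1"]  # g2 kept: longer CDS

    def test_no_pair_above_threshold(self):
        m = matrix([[1e5, 1.0, 1e5], [1.0, 1e5, 1.0]])
        filtered, report = filter_correlated_duplicates(m, gene_table([100, 100]),
                                                        max_length_bp=500, min_peak_expression=1)
        assert report.removed.empty and filtered.n_genes == 2

    def test_candidacy_excludes_long_or_cold_genes(self):
        m, genes = self.make_inputs()
        _, report = filter_correlated_duplicates(m, genes, max_length_bp=500,
                                                 min_peak_expression=100_000)
        assert report.removed.empty  # nothing hot enough

    def test_constant_gene_not_a_candidate(self):
        m = matrix([[2e4, 2e4, 2e4], [2e4, 2e4, 2e4], [1e4, 2e4, 3e4]])
        filtered, report = filter_correlated_duplicates(m, gene_table([100, 100, 100]),
                                                        max_length_bp=500, min_peak_expression=1)
        assert report.removed.empty  # zero-variance genes cannot cluster

    def test_needs_three_stages(self):
        with pytest.raises(ValueError):
            filter_correlated_duplicates(matrix([[1.0, 2.0]]), gene_table([100]))


class TestSequenceFilter:
    def align_rows(self, rows):
        return pd.DataFrame(rows, columns=["query_gene", "subject_id",
                                           "pct_identity_protein", "pct_identity_dna",
                                           "aligned_gaps_protein"])

    def test_passing_pair_clusters(self):
        aligns = self.align_rows([("g1", "g2", 98.0, 96.0, 0)])
        kept, report = filter_sequence_redundant(aligns, gene_table([100, 200]))
        assert kept == {"g2"} and report.removed_genes == ["g1"]

    def test_gap_blocks_clustering(self):
        aligns = self.align_rows([("g1", "g2", 98.0, 96.0, 1)])
        kept, report = filter_sequence_redundant(aligns, gene_table([100, 200]))
        assert kept == {"g1", "g2"} and report.removed.empty

    def test_identity_thresholds(self):
        aligns = self.align_rows([("g1", "g2", 96.9, 99.0, 0), ("g1", "g3", 99.0, 94.9, 0)])
        kept, _ = filter_sequence_redundant(aligns, gene_table([100, 200, 300]))
        assert kept == {"g1", "g2", "g3"}

    def test_transitive_chain_single_component(self):
        aligns = self.align_rows([("A", "B", 98.0, 96.0, 0), ("B", "C", 97.5, 95.5, 0),
                                  ("A", "C", 80.0, 70.0, 0)])
        kept, report = filter_sequence_redundant(
            aligns, gene_table([100, 300, 200], genes=["A", "B", "C"]))
        assert kept == {"B"}  # longest CDS representative
        assert len(report.removed) == 2

    def test_unknown_gene_rejected(self):
        aligns = self.align_rows([("g1", "ghost", 98.0, 96.0, 0)])
        with pytest.raises(KeyError, match="ghost"):
            filter_sequence_redundant(aligns, gene_table([100]))


def test_filters_commute_on_independent_criteria():
    """Sequence and correlation filters remove disjoint gene sets here, so
    applying them in either order yields the same final gene set."""
    base = np.array([1000.0, 30000.0, 2000.0])
    m = matrix([base, base * 2, np.array([50.0, 60.0, 20000.0]),
                np.array([20000.0, 70.0, 50.0])])
    genes = gene_table([300, 250, 400, 500])
    aligns = pd.DataFrame([("g3", "g4", 99.0, 98.0, 0)],
                          columns=["query_gene", "subject_id", "pct_identity_protein",
                                   "pct_identity_dna", "aligned_gaps_protein"])

    corr_first, _ = filter_correlated_duplicates(m, genes, max_length_bp=500,
                                                 min_peak_expression=10_000)
    kept_a, _ = filter_sequence_redundant(aligns, genes)
    final_a = set(corr_first.gene_ids) & kept_a

    kept_b, _ = filter_sequence_redundant(aligns, genes)
    sub = m.subset_genes([g for g in m.gene_ids if g in kept_b])
    corr_second, _ = filter_correlated_duplicates(sub, genes, max_length_bp=500,
                                                  min_peak_expression=10_000)
    final_b = set(corr_second.gene_ids)
    assert final_a == final_b
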
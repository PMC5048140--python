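"""Bootstrap CIs, permutation null, gamma moment fit, combined p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from transcriptage.expression import ExpressionMatrix
from transcriptage.indices import tai
from transcriptage.inference import (
    GammaFit,
    bootstrap_ci,
    combine_p,
    gamma_moment_fit,
    permutation_null,
    permutation_surrogates,
    stage_p_value,
)


def matrix(values, genes=None, stages=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    stages = stages or [f"S{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=stages))


def genes_for(ranks, genes=None):
    return pd.DataFrame({
        "gene_id": genes or [f"g{i + 1}" for i in range(len(ranks))],
        "cds_length": [1000] * len(ranks),
        "phylostratum": ranks,
    })


class TestBootstrap:
    def test_identical_genes_zero_width(self):
        m = matrix([[2.0, 3.0]] * 5)
        low, high = bootstrap_ci(m, genes_for([4] * 5), n_boot=200, seed=0)
        np.testing.assert_allclose(low, high)

    def test_interval_brackets_point_estimate(self, fixture_genes, weighted):
        low, high = bootstrap_ci(weighted, fixture_genes, "TAI", n_boot=400, seed=1)
        point = tai(weighted, fixture_genes).values
        assert (low <= point + 1e-9).all() and (point <= high + 1e-9).all()

    def test_seed_determinism(self, fixture_genes, weighted):
        a = bootstrap_ci(weighted, fixture_genes, "TAI", n_boot=150, seed=9)
        b = bootstrap_ci(weighted, fixture_genes, "TAI", n_boot=150, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_minimum_replicates_enforced(self, fixture_genes, weighted):
        with pytest.raises(ValueError):
            bootstrap_ci(weighted, fixture_genes, n_boot=50)


class TestPermutationSurrogates:
    def test_matches_exhaustive_enumeration_on_four_genes(self):
        """Sampled surrogate mean/variance agree with brute force over all
        covariate x expression permutation pairs of a 4-gene toy."""
        cov = np.array([1.0, 2.0, 5.0, 11.0])
        e = np.array([0.4, 0.3, 0.2, 0.1])
        total = e.sum()
        exact = np.array([
            sum(cp * eq for cp, eq in zip(cov_perm, e_perm)) / total
            for cov_perm in itertools.permutations(cov)
            for e_perm in itertools.permutations(e)
        ])
        n_perm = 4000
        rng = np.random.default_rng(42)
        sampled = permutation_surrogates(e[:, None], cov, n_perm, rng)[0]
        se_mean = exact.std() / np.sqrt(n_perm)
        assert abs(sampled.mean() - exact.mean()) < 4 * se_mean
        assert abs(sampled.var(ddof=1) - exact.var()) < 5 * exact.var() * np.sqrt(2 / n_perm)

    def test_shared_and_fresh_have_same_marginals(self):
        rng_values = np.random.default_rng(8)
        values = rng_values.uniform(0.1, 5.0, (30, 3))
        cov = rng_values.integers(1, 12, 30).astype(float)
        shared = permutation_surrogates(values, cov, 3000, np.random.default_rng(0), True)
        fresh = permutation_surrogates(values, cov, 3000, np.random.default_rng(1), False)
        for s in range(3):
            ks = stats.ks_2samp(shared[s], fresh[s])
            assert ks.pvalue > 0.001

    def test_constant_covariate_yields_constant_surrogates(self):
        values = np.random.default_rng(2).uniform(1, 4, (10, 2))
        sur = permutation_surrogates(values, np.full(10, 7.0), 200, np.random.default_rng(0))
        np.testing.assert_allclose(sur, 7.0)


class TestGammaFit:
    def test_closed_form_moment_inversion(self):
        # mean 2, sample variance 1 -> shape 4, scale 0.5
        fit = gamma_moment_fit(np.array([1.0, 2.0, 3.0]))
        assert fit.shape == pytest.approx(4.0)
        assert fit.scale == pytest.approx(0.5)

    def test_recovery_from_samples(self):
        rng = np.random.default_rng(10)
        fit = gamma_moment_fit(rng.gamma(shape=4.0, scale=0.5, size=100_000))
        assert fit.shape == pytest.approx(4.0, rel=0.05)
        assert fit.scale == pytest.approx(0.5, rel=0.05)

    def test_degenerate_surrogates_rejected(self):
        with pytest.raises(ValueError):
            gamma_moment_fit(np.full(100, 3.0))
        with pytest.raises(ValueError):
            gamma_moment_fit(np.array([0.0, 1.0, 2.0]))


class TestStagePValue:
    def test_median_gives_one(self):
        fit = GammaFit(shape=4.0, scale=0.5)
        median = stats.gamma.ppf(0.5, a=4.0, scale=0.5)
        assert stage_p_value(median, fit) == pytest.approx(1.0)

    def test_far_tail_vanishes(self):
        fit = GammaFit(shape=4.0, scale=0.5)
        assert stage_p_value(1e3, fit) < 1e-12

    def test_nonpositive_observed_scored_at_boundary(self):
        fit = GammaFit(shape=4.0, scale=0.5)
        assert stage_p_value(0.0, fit) == pytest.approx(np.finfo(float).tiny)

    def test_agrees_with_empirical_tail_within_factor_two(self):
        rng = np.random.default_rng(11)
        draws = rng.gamma(shape=4.0, scale=0.5, size=1_000_000)
        fit = GammaFit(shape=4.0, scale=0.5)
        for observed in (0.40, 0.75, 1.2, 4.0, 5.5):
            empirical = 2 * min((draws <= observed).mean(), (draws >= observed).mean())
            if empirical < 1e-3:
                continue
            assert 0.5 < stage_p_value(observed, fit) / empirical < 2.0


class TestCombineP:
    def test_all_ones_boundary(self):
        assert combine_p([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form_even_df(self):
        # X = -4 ln 0.05, df = 4: survival = exp(-X/2) (1 + X/2)
        x = -2 * (2 * np.log(0.05))
        expected = np.exp(-x / 2) * (1 + x / 2)
        assert combine_p([0.05, 0.05]) == pytest.approx(expected)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.001, 1.0, 7)
        expected = stats.combine_pvalues(p, method="fisher").pvalue
        assert combine_p(p) == pytest.approx(expected)
        expected_st = stats.combine_pvalues(p, method="stouffer").pvalue
        assert combine_p(p, method="stouffer") == pytest.approx(expected_st)

    def test_zero_input_clamped(self):
        assert 0.0 < combine_p([0.0, 0.5]) < 1e-200

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10),
           st.floats(min_value=0.1, max_value=1.0))
    def test_componentwise_smaller_never_larger_combined(self, p_values, shrink):
        smaller = [p * shrink for p in p_values]
        assert combine_p(smaller) <= combine_p(p_values) + 1e-12


class TestPermutationNull:
    def test_constant_covariate_p_one(self):
        m = matrix(np.random.default_rng(1).uniform(1, 5, (8, 3)))
        null = permutation_null(m, genes_for([6] * 8), n_perm=150, seed=0)
        np.testing.assert_allclose(null.p_per_stage, 1.0)
        assert null.p_combined == pytest.approx(1.0)

    def test_seed_determinism(self, fixture_genes, weighted):
        a = permutation_null(weighted, fixture_genes, n_perm=150, seed=21)
        b = permutation_null(weighted, fixture_genes, n_perm=150, seed=21)
        np.testing.assert_array_equal(a.surrogates, b.surrogates)
        assert a.p_combined == b.p_combined
        assert a.p_fisher == b.p_fisher

    def test_report_shape_and_fisher_always_present(self, fixture_genes, weighted):
        null = permutation_null(weighted, fixture_genes, n_perm=120, seed=2)
        report = null.report()
        assert list(report["stage"]) == weighted.stage_ids
        assert 0 < null.p_fisher <= 1
        assert 0 < null.p_combined <= 1

    def test_empirical_combiner_needs_shared_permutations(self, fixture_genes, weighted):
        with pytest.raises(ValueError):
            permutation_null(weighted, fixture_genes, n_perm=120, seed=0,
                             combine_method="empirical", share_across_stages=False)

    def test_gamma_fit_p_tracks_empirical_p_on_matched_null(self):
        """On a transcriptome-scale null (500 genes), the gamma moment fit
        reproduces the empirical permutation p within a factor of 2 down to
        p ~ 1e-3 (the approximation degrades for very small gene sets)."""
        rng = np.random.default_rng(33)
        values = rng.lognormal(0.0, 1.0, (500, 1))
        cov = rng.integers(1, 12, 500).astype(float)
        sur = permutation_surrogates(values, cov, 200_000, rng)[0]
        fit = gamma_moment_fit(sur)
        for quantile in (0.002, 0.01, 0.05, 0.25, 0.75, 0.95, 0.99, 0.998):
            observed = float(np.quantile(sur, quantile))
            empirical = 2 * min((sur <= observed).mean(), (sur >= observed).mean())
            empirical = min(1.0, empirical)
            if empirical < 1e-3:
                continue
            assert 0.5 < stage_p_value(observed, fit) / empirical < 2.0
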
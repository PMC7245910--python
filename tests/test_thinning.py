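import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from countthin import (
    CountMatrix,
    DesignBlock,
    Permutation,
    ThinLogMatrix,
    binomial_thin,
    build_thin_log,
    point_mass_sampler,
    thin_2group,
    thin_all,
    thin_diff,
    thin_gene,
    thin_lib,
)

from conftest import poisson_counts


class TestBuildThinLog:
    def test_zero_coefficients_give_zero_q(self):
        g, n = 4, 6
        fixed = DesignBlock.empty(g, n)
        permuted = DesignBlock(np.ones((n, 1)), np.zeros((g, 1)))
        tl = build_thin_log(fixed, permuted, Permutation.identity(n))
        assert np.array_equal(tl.q, np.zeros((g, n)))
        assert np.array_equal(tl.e, np.zeros(g))

    def test_hand_case_single_gene(self):
        # un-offset row is (0, 1); row max 1 is subtracted
        fixed = DesignBlock.empty(1, 2)
        permuted = DesignBlock(np.array([[0.0], [1.0]]), np.array([[1.0]]))
        tl = build_thin_log(fixed, permuted, Permutation.identity(2))
        assert tl.e == pytest.approx([1.0])
        assert tl.q[0] == pytest.approx([-1.0, 0.0])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        g, n, p2, p3 = 20, 8, 2, 2
        fixed = DesignBlock(rng.normal(size=(n, p2)), rng.normal(size=(g, p2)))
        permuted = DesignBlock(rng.normal(size=(n, p3)),
                               rng.normal(size=(g, p3)))
        pi = rng.permutation(n)
        tl = build_thin_log(fixed, permuted, Permutation(pi))

        # independent elementwise evaluation with explicit loops
        for i in range(g):
            row = []
            for j in range(n):
                val = 0.0
                for a in range(p2):
                    val += fixed.coef[i, a] * fixed.design[j, a]
                for a in range(p3):
                    val += permuted.coef[i, a] * permuted.design[pi[j], a]
                row.append(val)
            e_i = max(row)
            assert tl.e[i] == pytest.approx(e_i)
            for j in range(n):
                assert tl.q[i, j] == pytest.approx(min(row[j] - e_i, 0.0))

    def test_every_row_attains_zero(self):
        rng = np.random.default_rng(11)
        g, n = 15, 9
        fixed = DesignBlock(rng.normal(size=(n, 3)), rng.normal(size=(g, 3)))
        tl = build_thin_log(fixed, DesignBlock.empty(g, n),
                            Permutation.identity(n))
        assert np.all(tl.q <= 0)
        assert tl.q.max(axis=1) == pytest.approx(np.zeros(g))

    def test_shape_mismatch_raises(self):
        fixed = DesignBlock.empty(3, 4)
        permuted = DesignBlock.empty(3, 5)
        with pytest.raises(ValueError, match="disagree"):
            build_thin_log(fixed, permuted, Permutation.identity(4))

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            DesignBlock(np.ones((4, 1)), np.array([[np.nan]] * 3))


class TestBinomialThin:
    def test_q_zero_is_identity(self, small_counts):
        tl = ThinLogMatrix(np.zeros(small_counts.shape))
        out = binomial_thin(small_counts, tl, seed=3)
        assert np.array_equal(out.values, small_counts.values)

    def test_zero_counts_stay_zero(self):
        y = CountMatrix(np.zeros((4, 5), dtype=int))
        tl = ThinLogMatrix(-np.abs(np.random.default_rng(0).normal(size=(4, 5))))
        out = binomial_thin(y, tl, seed=9)
        assert np.array_equal(out.values, np.zeros((4, 5), dtype=int))

    def test_mean_matches_binomial_closed_form(self):
        g, n = 10, 100
        y = CountMatrix(np.full((g, n), 10000))
        tl = ThinLogMatrix(np.full((g, n), np.log2(0.5)))
        out = binomial_thin(y, tl, seed=100)
        grand_mean = out.values.mean()
        se = np.sqrt(10000 * 0.5 * 0.5 / (g * n))
        assert abs(grand_mean - 5000.0) < 3 * se

    def test_positive_q_rejected(self, small_counts):
        q = np.zeros(small_counts.shape)
        q[0, 0] = 0.1
        with pytest.raises(ValueError, match="non-positive"):
            ThinLogMatrix(q)

    def test_neg_inf_rejected(self):
        with pytest.raises(ValueError, match="-inf"):
            ThinLogMatrix(np.full((2, 2), -np.inf))

    def test_shape_mismatch(self, small_counts):
        tl = ThinLogMatrix(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="shape"):
            binomial_thin(small_counts, tl, seed=0)


class TestThinDiff:
    def test_null_signal_returns_input(self, small_counts):
        g, n = small_counts.shape
        fixed = DesignBlock(np.ones((n, 1)), np.zeros((g, 1)))
        permuted = DesignBlock(np.ones((n, 1)), np.zeros((g, 1)))
        res = thin_diff(small_counts, fixed, permuted, seed=7)
        assert np.array_equal(res.counts.values, small_counts.values)

    def test_custom_q_matches_binomial_thin(self, small_counts):
        rng = np.random.default_rng(21)
        q = -np.abs(rng.normal(size=small_counts.shape))
        res = thin_diff(small_counts, custom_q=q, seed=123)
        direct = binomial_thin(small_counts, ThinLogMatrix(q), seed=123)
        assert np.array_equal(res.counts.values, direct.values)

    def test_custom_q_excludes_blocks(self, small_counts):
        g, n = small_counts.shape
        with pytest.raises(ValueError, match="custom_q"):
            thin_diff(small_counts, DesignBlock.empty(g, n),
                      custom_q=np.zeros((g, n)), seed=0)

    def test_two_group_log2_ratio_recovers_effect(self):
        # point-mass -1 effect on every gene halves group-1 counts
        g, n = 500, 100
        y = poisson_counts(g, n, seed=17, mean=400.0)
        x = np.zeros((n, 1))
        x[: n // 2, 0] = 1.0
        permuted = DesignBlock(x, np.full((g, 1), -1.0))
        res = thin_diff(y, permuted=permuted, seed=99)
        grp = res.design_perm_applied[:, 0]
        m1 = res.counts.values[:, grp == 1].mean(axis=1)
        m0 = res.counts.values[:, grp == 0].mean(axis=1)
        log_ratio = np.log2(m1 / m0)
        assert abs(log_ratio.mean() + 1.0) < 0.05

    def test_fixed_permutation_commutes_with_prepermuted_design(self, small_counts):
        g, n = small_counts.shape
        rng = np.random.default_rng(4)
        x3 = rng.normal(size=(n, 2))
        b3 = rng.normal(scale=0.3, size=(g, 2))
        pi = Permutation(rng.permutation(n))
        res1 = thin_diff(small_counts,
                         permuted=DesignBlock(x3, b3),
                         permutation=pi, seed=55)
        res2 = thin_diff(small_counts,
                         permuted=DesignBlock(x3[pi.pi], b3),
                         permutation=Permutation.identity(n), seed=55)
        assert np.array_equal(res1.counts.values, res2.counts.values)
        assert np.array_equal(res1.thin_log.q, res2.thin_log.q)

    def test_provenance_recorded(self, small_counts):
        g, n = small_counts.shape
        rng = np.random.default_rng(2)
        block = DesignBlock(rng.normal(size=(n, 1)),
                            rng.normal(scale=0.2, size=(g, 1)))
        res = thin_diff(small_counts, permuted=block, seed=13)
        assert res.seed == 13
        assert np.array_equal(res.design_perm_applied,
                              block.design[res.permutation.pi])
        assert np.array_equal(res.coef_perm, block.coef)


class TestThin2Group:
    def test_prop_null_one_is_identity(self, small_counts):
        res = thin_2group(small_counts, prop_null=1.0, seed=8)
        assert np.array_equal(res.counts.values, small_counts.values)
        assert np.array_equal(res.coef_perm, np.zeros((small_counts.n_genes, 1)))

    def test_alpha_zero_point_mass(self, small_counts):
        res = thin_2group(small_counts, prop_null=0.4,
                          coef_sampler=point_mass_sampler(-0.7),
                          alpha=0.0, seed=5)
        b = res.coef_perm[:, 0]
        nonnull = b != 0
        assert nonnull.sum() == int(np.ceil(0.6 * small_counts.n_genes))
        assert np.allclose(b[nonnull], -0.7)

    def test_alpha_one_scales_with_row_sd(self, small_counts):
        res = thin_2group(small_counts, prop_null=0.0,
                          coef_sampler=point_mass_sampler(1.0),
                          alpha=1.0, seed=5)
        b = res.coef_perm[:, 0]
        logs = np.log2(small_counts.values + 0.5)
        # independent sd computation with plain python arithmetic
        for g in range(small_counts.n_genes):
            row = logs[g].tolist()
            m = sum(row) / len(row)
            s = (sum((v - m) ** 2 for v in row) / (len(row) - 1)) ** 0.5
            assert b[g] == pytest.approx(s, rel=1e-12)

    def test_group_sizes_exact(self, medium_counts):
        res = thin_2group(medium_counts, prop_null=1.0, group_prop=0.3,
                          seed=3)
        x = res.design_perm_applied[:, 0]
        assert set(np.unique(x)) <= {0.0, 1.0}
        assert x.sum() == int(np.floor(0.3 * medium_counts.n_samples))

    def test_invalid_fractions(self, small_counts):
        with pytest.raises(ValueError):
            thin_2group(small_counts, prop_null=1.5, seed=0)
        with pytest.raises(ValueError):
            thin_2group(small_counts, prop_null=0.5, group_prop=0.0, seed=0)


class TestUniformThinning:
    def test_lib_identity(self, small_counts):
        out = thin_lib(small_counts, np.zeros(small_counts.n_samples), seed=1)
        assert np.array_equal(out.values, small_counts.values)

    def test_lib_column_total(self):
        y = CountMatrix(np.full((1000, 3), 1000))
        factors = np.array([-1.0, 0.0, 0.0])
        out = thin_lib(y, factors, seed=77)
        total = out.values[:, 0].sum()
        se = np.sqrt(1000 * 1000 * 0.5 * 0.5)
        assert abs(total - 5e5) < 3 * se
        assert np.array_equal(out.values[:, 1:], y.values[:, 1:])

    def test_lib_large_negative_factor_nearly_empties_column(self, small_counts):
        factors = np.zeros(small_counts.n_samples)
        factors[0] = -30.0
        out = thin_lib(small_counts, factors, seed=2)
        assert out.values[:, 0].sum() == 0

    def test_lib_rejects_positive(self, small_counts):
        with pytest.raises(ValueError):
            thin_lib(small_counts, np.full(small_counts.n_samples, 0.1), seed=0)

    def test_gene_identity_and_closed_form(self):
        y = CountMatrix(np.full((2, 1000), 4))
        factors = np.array([np.log2(0.25), 0.0])
        out = thin_gene(y, factors, seed=10)
        assert np.array_equal(out.values[1], y.values[1])
        total = out.values[0].sum()
        se = np.sqrt(4000 * 0.25 * 0.75)
        assert abs(total - 1000) < 3 * se

    def test_gene_zero_counts_unchanged(self):
        y = CountMatrix(np.vstack([np.zeros((1, 4), dtype=int),
                                   np.full((1, 4), 7)]))
        out = thin_gene(y, np.array([-3.0, 0.0]), seed=4)
        assert np.array_equal(out.values[0], np.zeros(4, dtype=int))

    def test_all_identity(self, small_counts):
        out = thin_all(small_counts, 0.0, seed=6)
        assert np.array_equal(out.values, small_counts.values)

    def test_all_equals_lib_with_constant_vector(self, medium_counts):
        f = np.log2(0.3)
        a = thin_all(medium_counts, f, seed=31)
        b = thin_lib(medium_counts, np.full(medium_counts.n_samples, f),
                     seed=31)
        assert np.array_equal(a.values, b.values)

    def test_all_grand_total(self):
        y = CountMatrix(np.full((100, 100), 1000))
        out = thin_all(y, np.log2(0.1), seed=8)
        total = out.values.sum()
        se = np.sqrt(1e7 * 0.1 * 0.9)
        assert abs(total - 1e6) < 3 * se


count_matrices = hnp.arrays(
    dtype=np.int64,
    shape=st.tuples(st.integers(1, 6), st.integers(2, 6)),
    elements=st.integers(0, 500),
)


class TestProperties:
    @given(vals=count_matrices, data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_thinned_leq_input(self, vals, data):
        y = CountMatrix(vals)
        q = data.draw(hnp.arrays(np.float64, vals.shape,
                                 elements=st.floats(-5, 0)))
        out = binomial_thin(y, ThinLogMatrix(q), seed=0)
        assert np.all(out.values <= y.values)
        assert np.all(out.values >= 0)

    @given(vals=count_matrices)
    @settings(max_examples=20, deadline=None)
    def test_q_zero_identity(self, vals):
        y = CountMatrix(vals)
        out = binomial_thin(y, ThinLogMatrix(np.zeros(vals.shape)), seed=1)
        assert np.array_equal(out.values, y.values)

    @given(vals=count_matrices, seed=st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_seed_determinism(self, vals, seed):
        y = CountMatrix(vals)
        q = np.full(vals.shape, -0.5)
        a = binomial_thin(y, ThinLogMatrix(q), seed=seed)
        b = binomial_thin(y, ThinLogMatrix(q), seed=seed)
        assert np.array_equal(a.values, b.values)
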
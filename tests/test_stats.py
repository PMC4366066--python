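import math

import numpy as np
import pytest

import oracles
from fasterx import stats as st


class TestMannWhitney:
    def test_separated_samples_exact_enumeration(self):
        res = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_no_separation(self):
        res = st.mann_whitney_u([1.0, 2.0, 3.0], [1.5, 2.5, 0.5])
        assert res.p_value > 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.mann_whitney_u([], [1.0])

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for n1 in range(2, 7):
            for n2 in range(2, 7):
                vals = rng.permutation(100)[: n1 + n2].astype(float)
                a, b = vals[:n1], vals[n1:]
                u_or, p_or = oracles.mann_whitney_exact(a, b)
                res = st.mann_whitney_u(a, b)
                assert res.method == "exact"
                assert res.statistic == pytest.approx(u_or)
                assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_tied_samples_match_permutation_oracle(self, rng):
        a = rng.integers(0, 6, size=40).astype(float)
        b = rng.integers(1, 7, size=55).astype(float)
        res = st.mann_whitney_u(a, b)
        assert res.method == "asymptotic"
        p_perm = oracles.mann_whitney_permutation_p(a, b, n_perm=20000, seed=1)
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestWilcoxonSignedRank:
    def test_all_positive_differences_exact(self):
        res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.25)
        assert res.method == "exact"

    def test_one_sided_variant(self):
        res = st.wilcoxon_signed_rank([1.0, 2.0, 3.0], sidedness="one")
        assert res.p_value == pytest.approx(0.125)

    def test_perfect_antisymmetry_is_nonsignificant(self):
        res = st.wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0])
        assert res.p_value > 0.8

    def test_zeros_dropped(self):
        res = st.wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n == 3

    def test_all_zero_differences_undefined(self):
        res = st.wilcoxon_signed_rank([0.0, 0.0])
        assert math.isnan(res.statistic) and math.isnan(res.p_value)
        assert "zero" in res.note

    def test_exact_branch_matches_signflip_oracle(self, rng):
        for n in range(3, 9):
            d = rng.permutation(50)[:n].astype(float) + 0.5
            signs = rng.choice([-1.0, 1.0], size=n)
            d = d * signs
            t_or, p_or = oracles.wilcoxon_exact(d)
            res = st.wilcoxon_signed_rank(d)
            assert res.method == "exact"
            assert res.statistic == pytest.approx(t_or)
            assert res.p_value == pytest.approx(p_or, abs=1e-12)

    def test_tied_differences_match_signflip_permutation(self, rng):
        d = rng.integers(-4, 5, size=60).astype(float)
        d = d[d != 0]
        res = st.wilcoxon_signed_rank(d)
        assert res.method == "asymptotic"
        p_perm = oracles.signflip_permutation_p(d, n_perm=20000, seed=2)
        assert res.p_value == pytest.approx(p_perm, abs=0.02)


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert st.spearman_rho(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert st.spearman_rho(x, -(x**3)).statistic == pytest.approx(-1.0)

    def test_ties_equal_pearson_of_midranks(self, rng):
        from scipy.stats import pearsonr, rankdata

        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float) + 0.3 * x
        res = st.spearman_rho(x, y)
        expected = pearsonr(rankdata(x), rankdata(y)).statistic
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        res = st.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.statistic)


class TestStandardizedOls:
    def test_exact_linear_response(self, rng):
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        y = 2.0 * x1 - 1.0 * x2 + 3.0
        fit = st.fit_standardized_ols(y, {"a": x1, "b": x2})
        assert fit.r_multiple == pytest.approx(1.0, abs=1e-8)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_toy_matches_normal_equations_oracle(self):
        # 8-point toy: solve the standardized normal equations directly
        y = np.array([2.1, 3.0, 1.2, 5.5, 4.4, 3.3, 2.2, 6.1])
        c1 = np.array([1.0, 2.0, 0.5, 4.0, 3.5, 2.5, 1.5, 5.0])
        c2 = np.array([7.0, 5.0, 8.0, 2.0, 3.0, 6.0, 6.5, 1.0])
        fit = st.fit_standardized_ols(y, {"c1": c1, "c2": c2})

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        X = np.column_stack([np.ones(8), z(c1), z(c2)])
        beta = np.linalg.solve(X.T @ X, X.T @ z(y))
        assert fit.coefficients["c1"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.coefficients["c2"] == pytest.approx(beta[2], abs=1e-10)
        resid = z(y) - X @ beta
        assert np.allclose(fit.residuals, resid, atol=1e-10)

    def test_residuals_orthogonal_to_covariates_and_sum_zero(self, rng):
        y = rng.normal(size=200)
        cov = {k: rng.normal(size=200) for k in ("a", "b", "c")}
        fit = st.fit_standardized_ols(y, cov)
        assert abs(fit.residuals.sum()) < 1e-9
        for k, v in cov.items():
            zc = (v - v.mean()) / v.std(ddof=1)
            assert abs(float(fit.residuals @ zc)) < 1e-8

    def test_null_response_gives_small_coefficients(self, rng):
        y = rng.normal(size=4000)
        cov = {k: rng.normal(size=4000) for k in ("a", "b")}
        fit = st.fit_standardized_ols(y, cov)
        assert fit.r_multiple < 0.1
        assert all(abs(b) < 0.1 for b in fit.coefficients.values())

    def test_collinear_covariates_error_names_pair(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="'a' and 'b'"):
            st.fit_standardized_ols(
                rng.normal(size=30), {"a": x, "b": 2.0 * x, "c": rng.normal(size=30)}
            )


class TestResidualGroupTest:
    def test_composition_equals_direct_mann_whitney(self, rng):
        y = rng.normal(size=100)
        cov = {"a": rng.normal(size=100)}
        labels = np.array(["X"] * 30 + ["A"] * 70)
        fit = st.fit_standardized_ols(y, cov)
        res = st.residual_group_test(fit, labels)
        direct = st.mann_whitney_u(fit.residuals[labels == "X"], fit.residuals[labels == "A"])
        assert res.statistic == direct.statistic
        assert res.p_value == direct.p_value

    def test_empty_group_rejected(self, rng):
        fit = st.fit_standardized_ols(
            rng.normal(size=20), {"a": rng.normal(size=20)}
        )
        with pytest.raises(ValueError, match="zero members"):
            st.residual_group_test(fit, np.array(["A"] * 20))

    def test_shifted_group_detected(self, rng):
        # X residual distribution shifted by +1 SD: overwhelming power
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = r.normal(size=1000)
            labels = np.array(["X"] * 200 + ["A"] * 800)
            y[:200] += 1.0
            cov = {"a": r.normal(size=1000)}
            fit = st.fit_standardized_ols(y, cov)
            if st.residual_group_test(fit, labels).p_value < 0.01:
                rejections += 1
        assert rejections >= 19


class TestEqualSizeBins:
    def test_exact_equal_sizes(self, rng):
        v = rng.normal(size=100)
        bins = st.equal_size_bins(v, 10)
        counts = np.bincount(bins, minlength=10)
        assert list(counts) == [10] * 10

    def test_remainder_goes_to_lower_bins(self):
        bins = st.equal_size_bins(np.arange(23.0), 10)
        counts = list(np.bincount(bins, minlength=10))
        assert sum(counts) == 23
        assert counts == sorted(counts, reverse=True)
        assert max(counts) - min(counts) <= 1

    def test_ties_broken_deterministically_by_input_order(self):
        v = np.zeros(6)
        bins = st.equal_size_bins(v, 3)
        assert list(bins) == [0, 0, 1, 1, 2, 2]


class TestStratifiedComparison:
    @staticmethod
    def _random_inputs(rng, n=600, px=0.25):
        response = rng.normal(size=n)
        cov = {
            "level": rng.normal(size=n),
            "tau": rng.uniform(size=n),
            "degree": rng.poisson(8, size=n).astype(float),
        }
        chrom = np.where(rng.uniform(size=n) < px, "X", "A")
        return response, cov, chrom

    def test_category_without_both_classes_contributes_no_pair(self):
        response = np.array([1.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0, 13.0])
        cov = {"c": np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 3.0, 3.0])}
        chrom = np.array(["X", "A", "X", "A", "A", "A", "X", "X"])
        res = st.stratified_xa_comparison(response, cov, chrom, n_bins=4)
        # bins 2 (A only) and 3 (X only) are dropped
        assert res.n_categories_retained == 2

    def test_monotone_transform_invariance(self, rng):
        response, cov, chrom = self._random_inputs(rng)
        r1 = st.stratified_xa_comparison(response, cov, chrom, n_bins=5)
        cov2 = {
            "level": np.exp(cov["level"]),
            "tau": cov["tau"] ** 3,
            "degree": 2.0 * cov["degree"] + 1.0,
        }
        r2 = st.stratified_xa_comparison(response, cov2, chrom, n_bins=5)
        assert r1.n_categories_retained == r2.n_categories_retained
        assert np.allclose(r1.differences, r2.differences)
        assert r1.test.p_value == pytest.approx(r2.test.p_value)

    def test_insufficient_overlap_rejected(self):
        response = np.arange(8.0)
        cov = {"c": np.arange(8.0)}
        chrom = np.array(["X"] * 4 + ["A"] * 4)
        with pytest.raises(ValueError, match="insufficient overlap"):
            st.stratified_xa_comparison(response, cov, chrom, n_bins=4)

    def test_each_gene_in_exactly_one_category(self, rng):
        response, cov, chrom = self._random_inputs(rng, n=200)
        res = st.stratified_xa_comparison(response, cov, chrom, n_bins=4)
        assert len(res.bin_index) == 200
        assert res.bin_index.notna().all().all()
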
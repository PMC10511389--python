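import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from histostrain.stats import (
    DEFAULT_REGION_PAIRS,
    compare_groups_sdi,
    compute_sdi,
    fit_mean_strain_vs_proportion,
    pairwise_region_tests,
)


class TestComputeSdi:
    def test_constant_sample(self):
        s = compute_sdi([1.0, 1.0, 1.0])
        assert (s.mean, s.maximum, s.coefficient_of_variation, s.skewness) == (1, 1, 0, 0)

    def test_hand_computed_example(self):
        # direct evaluation of the sample formulas for {0, 0, 0, 1}
        s = compute_sdi([0.0, 0.0, 0.0, 1.0])
        assert s.mean == 0.25
        assert s.maximum == 1.0
        assert s.coefficient_of_variation == pytest.approx(2.0, abs=1e-12)
        assert s.skewness == pytest.approx(2.0, abs=1e-12)

    def test_lognormal_sample_right_skewed(self):
        rng = np.random.default_rng(0)
        s = compute_sdi(rng.lognormal(0.0, 0.6, 10000))
        assert s.skewness > 0

    def test_zero_mean_cv_undefined(self):
        s = compute_sdi([-1.0, 0.0, 1.0])
        assert np.isnan(s.coefficient_of_variation)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            compute_sdi([0.1, 0.2])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        data=st.lists(
            st.floats(min_value=0.001, max_value=0.5), min_size=4, max_size=40
        ),
        scale=st.floats(min_value=0.1, max_value=10.0),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_permutation_and_scaling_invariances(self, data, scale, seed):
        x = np.array(data)
        perm = np.random.default_rng(seed).permutation(x)
        a, b = compute_sdi(x), compute_sdi(perm)
        assert a.mean == pytest.approx(b.mean) and a.maximum == b.maximum
        c = compute_sdi(scale * x)
        assert c.mean == pytest.approx(scale * a.mean, rel=1e-12)
        assert c.maximum == pytest.approx(scale * a.maximum, rel=1e-12)
        if np.ptp(x) > 1e-9:
            assert c.coefficient_of_variation == pytest.approx(
                a.coefficient_of_variation, rel=1e-9
            )
            assert c.skewness == pytest.approx(a.skewness, rel=1e-6, abs=1e-9)


class TestCompareGroupsSdi:
    def test_identical_groups_not_rejected(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        res = compare_groups_sdi(g, g.copy())
        assert res.p_value > 0.9

    def test_separated_gaussian_groups_rejected(self):
        rng = np.random.default_rng(4)
        a = 0.10 + 0.005 * rng.standard_normal(5)
        b = 0.12 + 0.005 * rng.standard_normal(3)
        res = compare_groups_sdi(a, b)
        assert res.branch == "t"
        # closed-form two-sample pooled t oracle
        na, nb = len(a), len(b)
        sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value < 0.05

    def test_heavy_tailed_groups_use_rank_branch(self):
        rng = np.random.default_rng(1)
        a = rng.standard_cauchy(20)
        b = rng.standard_cauchy(20) + 10.0
        res = compare_groups_sdi(a, b)
        assert res.branch == "ranksum"

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_sdi([1.0], [1.0, 2.0])


class TestPairwiseRegionTests:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(-3.0, 0.5, 200)
        samples = {l: base.copy() for l in ("A1", "A2", "A3", "A4", "A5")}
        results = pairwise_region_tests(samples)
        assert not any(r.significant for r in results)

    def test_shifted_region_significant_after_correction(self):
        rng = np.random.default_rng(3)
        a3 = rng.normal(0.05, 0.01, 200)
        samples = {
            "A1": a3 + 0.05,
            "A2": rng.normal(0.05, 0.01, 200),
            "A3": a3,
            "A4": rng.normal(0.05, 0.01, 200),
            "A5": rng.normal(0.05, 0.01, 200),
        }
        by_pair = {r.pair: r for r in pairwise_region_tests(samples)}
        assert by_pair[("A1", "A3")].significant
        assert by_pair[("A1", "A3")].corrected_alpha == pytest.approx(0.05 / 6)

    def test_u_statistic_complete_separation(self):
        samples = {"A1": np.array([1.0, 2.0]), "A2": np.array([3.0, 4.0])}
        res = pairwise_region_tests(samples, pairs=(("A1", "A2"),))
        assert res[0].statistic == 0.0

    def test_u_statistic_matches_exhaustive_rank_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.5, 1.0, 20)
        res = pairwise_region_tests({"A1": a, "A4": b}, pairs=(("A1", "A4"),))[0]
        u_oracle = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert res.statistic == pytest.approx(u_oracle, abs=1e-12)

    def test_missing_region_skipped_and_divisor_adjusted(self):
        rng = np.random.default_rng(6)
        samples = {
            "A1": rng.normal(0.1, 0.01, 50),
            "A2": rng.normal(0.1, 0.01, 50),
            "A3": rng.normal(0.1, 0.01, 50),
            "A5": rng.normal(0.1, 0.01, 50),
        }
        results = pairwise_region_tests(samples)
        skipped = [r for r in results if r.skipped]
        tested = [r for r in results if not r.skipped]
        assert {r.pair for r in skipped} == {("A4", "A5"), ("A1", "A4")}
        assert all(r.corrected_alpha == pytest.approx(0.05 / 4) for r in tested)

    def test_bonferroni_monotone_in_pair_count(self):
        rng = np.random.default_rng(7)
        samples = {
            "A1": rng.normal(0.10, 0.01, 100),
            "A3": rng.normal(0.05, 0.01, 100),
            "A4": rng.normal(0.10, 0.01, 100),
            "A5": rng.normal(0.05, 0.01, 100),
        }
        many = {
            r.pair: r
            for r in pairwise_region_tests(
                samples, pairs=(("A1", "A3"), ("A4", "A5"), ("A3", "A5"))
            )
        }
        few = {r.pair: r for r in pairwise_region_tests(samples, pairs=(("A1", "A3"),))}
        assert many[("A1", "A3")].significant
        assert few[("A1", "A3")].significant

    def test_default_pair_list_is_the_six_study_comparisons(self):
        assert len(DEFAULT_REGION_PAIRS) == 6


class TestLinearFit:
    def test_collinear_points_give_r2_one(self):
        x = np.array([0.0, 0.1, 0.2, 0.3])
        res = fit_mean_strain_vs_proportion(x, 0.1 - 0.2 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.2)

    def test_independent_noise_gives_tiny_r2(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 1000)
        y = rng.normal(0.1, 0.01, 1000)
        assert fit_mean_strain_vs_proportion(x, y).r_squared < 0.01

    def test_matches_normal_equations_oracle(self):
        x = np.array([0.05, 0.12, 0.31, 0.47, 0.60])
        y = np.array([0.13, 0.115, 0.09, 0.06, 0.05])
        res = fit_mean_strain_vs_proportion(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert res.intercept == pytest.approx(beta[0], abs=1e-12)
        assert res.slope == pytest.approx(beta[1], abs=1e-12)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_mean_strain_vs_proportion([0.1, 0.1, 0.1], [1.0, 2.0, 3.0])
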
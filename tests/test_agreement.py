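import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from graftcalib import (
    InputError,
    NumericalError,
    bland_altman,
    compare_dependent_correlations,
    corrected_error_summary,
    difference,
    error_ratio,
    icc_two_way,
    ols_fit,
    pearson_ci,
    summarize,
)

pct_vectors = st.lists(st.floats(min_value=-80.0, max_value=200.0,
                                 allow_nan=False), min_size=2, max_size=30)


class TestPerDonorStatistics:
    def test_difference(self):
        np.testing.assert_allclose(difference([900.0], [800.0]), [100.0])
        np.testing.assert_allclose(difference([770.117], [783.7]), [-13.583])
        x = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(difference(x, x), np.zeros(3))

    def test_error_ratio(self):
        np.testing.assert_allclose(error_ratio([900.0], [800.0]), [12.5])
        x = np.array([700.0, 800.0])
        np.testing.assert_allclose(error_ratio(x, x), [0.0, 0.0])
        with pytest.raises(InputError):
            error_ratio([900.0], [0.0])

    def test_summarize(self):
        s = summarize([-10.0, 10.0])
        assert s.mean == pytest.approx(0.0)
        assert s.sd == pytest.approx(14.1421, abs=1e-4)
        assert summarize([0.0, 0.0, 0.0]).sd == 0.0
        with pytest.raises(NumericalError):
            summarize([1.0])


@settings(derandomize=True, max_examples=50, deadline=None)
@given(ratios=pct_vectors, c=st.floats(min_value=0.1, max_value=1.5))
def test_error_ratio_transform_identity(ratios, c):
    """Applying factor c maps each ratio through
    (c*(1 + ratio/100) - 1)*100; the mean follows the same identity and the
    SD scales by c, to machine precision."""
    agw = np.full(len(ratios), 500.0)
    est = agw * (1.0 + np.asarray(ratios) / 100.0)
    pre = summarize(error_ratio(est, agw))
    post = summarize(error_ratio(c * est, agw))
    expected = (c * (1.0 + np.asarray(ratios) / 100.0) - 1.0) * 100.0
    np.testing.assert_allclose(post.per_donor, expected, rtol=1e-9, atol=1e-9)
    mean_t, sd_t = corrected_error_summary(c, pre.mean, pre.sd)
    assert post.mean == pytest.approx(mean_t, abs=1e-9)
    assert post.sd == pytest.approx(sd_t, abs=1e-9)


class TestPearsonCI:
    def test_perfect_correlation_clamped(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == res.ci_high == res.r

    def test_zero_correlation_interval_width(self):
        # symmetric x against x^2 has exactly r = 0; CI = tanh(z_.975/sqrt(100))
        x = np.linspace(-1, 1, 103)
        res = pearson_ci(x, x**2)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.ci_high == pytest.approx(0.1935, abs=1e-3)
        assert res.ci_low == pytest.approx(-res.ci_high, abs=1e-12)

    def test_scale_invariance(self, paired_data):
        egv, agw = paired_data
        base = pearson_ci(egv, agw)
        scaled = pearson_ci(7.3 * egv, agw)
        assert scaled.r == pytest.approx(base.r, abs=1e-14)
        assert scaled.ci_low == pytest.approx(base.ci_low, abs=1e-14)

    def test_constant_input_rejected(self):
        with pytest.raises(NumericalError):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestOlsFit:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.se_resid == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fit(self):
        fit = ols_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-2.0 / 3.0)
        assert fit.r_squared == pytest.approx(0.9643, abs=1e-4)
        assert fit.se_resid == pytest.approx(0.4082, abs=1e-4)

    def test_r_squared_equals_pearson_squared(self, paired_data):
        egv, agw = paired_data
        fit = ols_fit(egv, agw)
        r = pearson_ci(egv, agw).r
        assert fit.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(NumericalError):
            ols_fit(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([700.0, 800.0, 900.0])
        res = bland_altman(x, x)
        assert res.mean_diff == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_symmetric_differences(self):
        res = bland_altman([790.0, 810.0], [800.0, 800.0])
        assert res.mean_diff == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(27.719, abs=1e-3)
        assert res.loa_low == pytest.approx(-27.719, abs=1e-3)

    def test_loa_bracket_mean(self, paired_data):
        egv, agw = paired_data
        res = bland_altman(0.85 * egv, agw)
        assert res.loa_low <= res.mean_diff <= res.loa_high
        assert res.loa_high - res.mean_diff == pytest.approx(1.96 * res.sd_diff)


def icc_a1_anova(matrix: np.ndarray) -> float:
    """Brute-force two-way ANOVA ICC(A,1) oracle (independent of the package)."""
    n, k = matrix.shape
    gm = matrix.mean()
    ss_rows = k * ((matrix.mean(axis=1) - gm) ** 2).sum()
    ss_cols = n * ((matrix.mean(axis=0) - gm) ** 2).sum()
    ss_tot = ((matrix - gm) ** 2).sum()
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err
                                 + k / n * (ms_cols - ms_err))


class TestIcc:
    def test_identical_series_gives_one(self):
        x = np.array([700.0, 750.0, 800.0, 850.0, 900.0])
        res = icc_two_way(x, x)
        assert res.icc == pytest.approx(1.0)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_constant_shift_lowers_absolute_agreement(self):
        x = np.array([700.0, 750.0, 800.0, 850.0, 900.0])
        res = icc_two_way(x + 60.0, x)
        assert res.icc < 1.0
        assert pearson_ci(x + 60.0, x).r == pytest.approx(1.0)
        # the consistency variant ignores the shift
        assert icc_two_way(x + 60.0, x, variant="C-1").icc == pytest.approx(1.0)

    def test_matches_brute_force_anova(self, paired_data):
        toy = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 6.0]])
        res = icc_two_way(toy[:, 0], toy[:, 1])
        assert res.icc == pytest.approx(icc_a1_anova(toy), rel=1e-10)
        egv, agw = paired_data
        res = icc_two_way(0.85 * egv, agw)
        assert res.icc == pytest.approx(
            icc_a1_anova(np.column_stack([0.85 * egv, agw])), rel=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(NumericalError):
            icc_two_way(np.full(5, 3.0), np.full(5, 3.0))


class TestSteiger:
    def test_equal_correlations_give_null(self):
        z, p = compare_dependent_correlations(0.8, 0.8, 0.5, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = compare_dependent_correlations(0.8, 0.7, 0.6, 100)
        z2, p2 = compare_dependent_correlations(0.7, 0.8, 0.6, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_domain_errors(self):
        with pytest.raises(InputError):
            compare_dependent_correlations(1.0, 0.5, 0.5, 100)
        with pytest.raises(InputError):
            compare_dependent_correlations(0.5, 0.4, 0.3, 5)

    def test_p_value_agrees_with_null_simulation(self):
        """The two-sided p for (0.80, 0.70, 0.60, n=100) matches the
        frequency of as-extreme statistics simulated under H0 within 0.02."""
        n, reps = 100, 100_000
        z_obs, p_impl = compare_dependent_correlations(0.80, 0.70, 0.60, n)
        r_common = 0.75  # pooled correlation under H0: rho12 = rho13
        cov = np.array([[1.0, r_common, r_common],
                        [r_common, 1.0, 0.60],
                        [r_common, 0.60, 1.0]])
        chol = np.linalg.cholesky(cov)
        rng = np.random.default_rng(2024)
        exceed = 0
        for _ in range(10):
            x = rng.standard_normal((reps // 10, n, 3)) @ chol.T
            xc = x - x.mean(axis=1, keepdims=True)
            xc /= np.linalg.norm(xc, axis=1, keepdims=True)
            r12 = np.einsum("bi,bi->b", xc[:, :, 0], xc[:, :, 1])
            r13 = np.einsum("bi,bi->b", xc[:, :, 0], xc[:, :, 2])
            r23 = np.einsum("bi,bi->b", xc[:, :, 1], xc[:, :, 2])
            rm2 = (r12**2 + r13**2) / 2.0
            f = np.minimum((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0)
            h = (1.0 - f * rm2) / (1.0 - rm2)
            z_null = (np.arctanh(r12) - np.arctanh(r13)) * np.sqrt(
                (n - 3) / (2.0 * (1.0 - r23) * h))
            exceed += int((np.abs(z_null) >= abs(z_obs)).sum())
        p_sim = exceed / reps
        assert p_impl == pytest.approx(p_sim, abs=0.02)
        # sanity: statistic is standard normal under the null
        assert 2 * stats.norm.sf(abs(z_obs)) == pytest.approx(p_impl)
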
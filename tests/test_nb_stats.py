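import numpy as np
import pytest
from scipy import stats

from diffloopkit import nb_stats
from diffloopkit.nb_stats import (
    NormFactors,
    estimate_dispersion,
    exact_test,
    glm_fit,
    glm_lrt,
    glm_qlf,
    logcpm,
    norm_factors,
    run_test,
    wald_test,
)
from conftest import make_count_matrix


def unit_nf(s, libsize=1e6):
    return NormFactors(effective_libsize=np.full(s, libsize), method="libsize")


def nb_counts(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    lam = rng.gamma(shape=r, scale=mu / r, size=size)
    return rng.poisson(lam)


class TestNormFactors:
    @pytest.mark.parametrize("method", ["median_of_ratios", "tmm", "libsize"])
    def test_identical_samples_unit_factors(self, method):
        rng = np.random.default_rng(0)
        col = rng.poisson(20, size=200) + 1
        cm = make_count_matrix(np.stack([col, col], axis=1))
        nf = norm_factors(cm, method)
        ratio = nf.effective_libsize[1] / nf.effective_libsize[0]
        assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_doubled_sample_median_of_ratios(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(50, size=500) + 1
        cm = make_count_matrix(np.stack([a, 2 * a], axis=1))
        nf = norm_factors(cm, "median_of_ratios")
        ratio = nf.effective_libsize[1] / nf.effective_libsize[0]
        assert ratio == pytest.approx(2.0, rel=1e-6)

    def test_single_sample_factor_one(self):
        cm = make_count_matrix(np.array([[3], [5]]), conditions=["A"])
        nf = norm_factors(cm, "median_of_ratios")
        assert nf.effective_libsize[0] == 8

    def test_mor_fallback_when_no_common_row(self, caplog):
        cm = make_count_matrix(np.array([[3, 0], [0, 5]]))
        with caplog.at_level("WARNING"):
            nf = norm_factors(cm, "median_of_ratios")
        assert nf.method == "libsize"

    def test_tmm_factors_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(30, size=(400, 4)) + 1
        counts[:, 2] *= 3
        cm = make_count_matrix(counts)
        nf = norm_factors(cm, "tmm")
        factors = nf.effective_libsize / counts.sum(axis=0)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, rel=1e-9)


class TestDispersion:
    def test_poisson_data_near_zero_dispersion(self):
        rng = np.random.default_rng(42)
        mu = rng.uniform(20, 200, size=2000)
        counts = rng.poisson(mu[:, None], size=(2000, 4))
        cm = make_count_matrix(counts)
        est = estimate_dispersion(cm, unit_nf(4, counts.sum(axis=0).mean()))
        assert est.common < 0.01

    def test_nb_dispersion_recovery(self):
        rng = np.random.default_rng(43)
        mu = rng.uniform(100, 1000, size=2000)
        counts = nb_counts(rng, np.broadcast_to(mu[:, None], (2000, 4)), 0.2,
                           (2000, 4))
        cm = make_count_matrix(counts)
        est = estimate_dispersion(cm, unit_nf(4, counts.sum(axis=0).mean()))
        assert 0.1 <= est.common <= 0.3

    def test_infinite_prior_df_collapses_tagwise_to_common(self):
        rng = np.random.default_rng(44)
        counts = rng.poisson(50, size=(200, 4))
        cm = make_count_matrix(counts)
        est = estimate_dispersion(cm, unit_nf(4), prior_df=np.inf)
        assert (est.tagwise == est.common).all()

    def test_one_rep_per_condition_rejected(self):
        cm = make_count_matrix(np.array([[3, 5]]), conditions=["A", "B"])
        with pytest.raises(ValueError, match="fixed dispersion"):
            estimate_dispersion(cm, unit_nf(2))


def enumerate_exact_p(a_sum, b_sum, na, nb, phi):
    """Independent oracle: conditional two-group law via scipy group-sum pmfs."""
    T = a_sum + b_sum
    mu_group = T / 2.0  # equal group sizes assumed by callers below
    ks = np.arange(0, T + 1)
    if phi == 0:
        pa = stats.poisson.pmf(ks, mu_group)
        pb = stats.poisson.pmf(T - ks, mu_group)
    else:
        r = na / phi  # sum of na NB(mu, phi) = NB(na*mu, phi/na)
        p = r / (r + mu_group)
        pa = stats.nbinom.pmf(ks, r, p)
        pb = stats.nbinom.pmf(T - ks, nb / phi, (nb / phi) / (nb / phi + mu_group))
    probs = pa * pb
    probs = probs / probs.sum()
    obs = probs[a_sum]
    return probs[probs <= obs * (1 + 1e-12)].sum()


class TestExactTest:
    def test_symmetric_counts_p_one(self):
        cm = make_count_matrix([[2, 2, 2, 2]])
        res = exact_test(cm, unit_nf(4), 0.0)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_binomial_case_zero_vs_ten(self):
        cm = make_count_matrix([[0, 0, 5, 5]])
        res = exact_test(cm, unit_nf(4), 0.0)
        # conditional law is Binomial(10, 1/2); two-sided p = P(0) + P(10)
        assert res["pvalue"].iloc[0] == pytest.approx(2 / 1024, rel=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle_spot(self, phi):
        rng = np.random.default_rng(7)
        for _ in range(25):
            T = int(rng.integers(1, 51))
            a = int(rng.integers(0, T + 1))
            counts = np.array([[a, 0, T - a, 0]])
            cm = make_count_matrix(counts)
            res = exact_test(cm, unit_nf(4), phi)
            expected = enumerate_exact_p(a, T - a, 2, 2, phi)
            assert res["pvalue"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_condition_swap_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson([20, 20, 45, 45], size=(50, 4))
        cm = make_count_matrix(counts, conditions=["A", "A", "B", "B"])
        cm_sw = make_count_matrix(counts[:, [2, 3, 0, 1]],
                                  conditions=["A", "A", "B", "B"])
        r1 = exact_test(cm, unit_nf(4), 0.1)
        r2 = exact_test(cm_sw, unit_nf(4), 0.1)
        np.testing.assert_allclose(r1["pvalue"], r2["pvalue"], atol=1e-8)
        np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-8)

    @pytest.mark.parametrize("test", ["exact", "glm_lrt", "glm_qlf", "wald"])
    def test_global_libsize_rescaling_leaves_p(self, test):
        # a common rescaling of every effective library size carries no
        # information about the contrast, so p-values must not move
        rng = np.random.default_rng(9)
        counts = rng.poisson([30, 25, 60, 50], size=(40, 4))
        cm = make_count_matrix(counts)
        lib = np.array([0.9e6, 1.1e6, 1.0e6, 1.2e6])
        r1 = run_test(cm, NormFactors(lib, "libsize"), 0.1, test)
        r2 = run_test(cm, NormFactors(lib * 7.0, "libsize"), 0.1, test)
        np.testing.assert_allclose(r1["pvalue"], r2["pvalue"], atol=1e-6)


class TestGLM:
    def test_flat_counts_zero_stat(self):
        cm = make_count_matrix([[10, 10, 10, 10]])
        nf = unit_nf(4)
        full = glm_fit(cm, nf, 0.1, "full")
        red = glm_fit(cm, nf, 0.1, "null")
        assert full.coef[0] == pytest.approx(0.0, abs=1e-8)
        assert red.deviance[0] - full.deviance[0] == pytest.approx(0.0, abs=1e-8)
        res = glm_lrt(full, red, cm, nf)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_four_fold_change_recovered(self):
        cm = make_count_matrix([[10, 10, 40, 40]])
        full = glm_fit(cm, unit_nf(4), 0.0, "full")
        assert full.coef[0] / np.log(2) == pytest.approx(2.0, abs=1e-6)

    def test_poisson_limit_matches_analytic_deviance(self):
        # at phi=0 the NB GLM is Poisson regression: D = 2*sum[y log(y/mu) - (y-mu)]
        y = np.array([[3, 7, 12, 2]])
        cm = make_count_matrix(y)
        full = glm_fit(cm, unit_nf(4), 0.0, "full")
        muA, muB = y[0, :2].mean(), y[0, 2:].mean()
        mu = np.array([muA, muA, muB, muB])
        expected = 2 * np.sum(y[0] * np.log(y[0] / mu) - (y[0] - mu))
        assert full.deviance[0] == pytest.approx(expected, abs=1e-8)

    def test_lrt_chi2_reference_value(self):
        # a statistic of 3.841459 sits at the 5% tail of chi-square df 1
        assert stats.chi2.sf(3.841459, 1) == pytest.approx(0.05, rel=1e-4)
        cm = make_count_matrix([[10, 10, 10, 10], [5, 15, 30, 22]])
        nf = unit_nf(4)
        full = glm_fit(cm, nf, 0.05, "full")
        red = glm_fit(cm, nf, 0.05, "null")
        res = glm_lrt(full, red, cm, nf)
        stat = red.deviance - full.deviance
        np.testing.assert_allclose(res["pvalue"], stats.chi2.sf(stat, 1), atol=1e-12)

    def test_qlf_raw_quasi_dispersion_definition(self):
        # residual deviance 4 on 2 df gives raw s^2 = 2
        from diffloopkit.nb_stats import _squeeze_var
        s2 = np.array([4.0 / 2.0])
        assert s2[0] == 2.0
        d0, s0, post = _squeeze_var(np.full(100, 2.0), df=2)
        # all equal s2: no spread beyond chi-square noise -> full shrinkage
        assert np.isinf(d0)
        np.testing.assert_allclose(post, post[0])

    def test_qlf_needs_residual_df(self):
        cm = make_count_matrix([[3, 5]], conditions=["A", "B"])
        nf = unit_nf(2)
        full = glm_fit(cm, nf, 0.1, "full")
        red = glm_fit(cm, nf, 0.1, "null")
        with pytest.raises(ValueError, match="exact test"):
            glm_qlf(full, red, cm, nf)

    def test_condition_swap_symmetry_glm_tests(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson([20, 20, 45, 45], size=(60, 4))
        cm = make_count_matrix(counts)
        cm_sw = make_count_matrix(counts[:, [2, 3, 0, 1]])
        for test in ("glm_lrt", "glm_qlf", "wald"):
            r1 = run_test(cm, unit_nf(4), 0.1, test)
            r2 = run_test(cm_sw, unit_nf(4), 0.1, test)
            np.testing.assert_allclose(r1["pvalue"], r2["pvalue"], atol=1e-8)
            np.testing.assert_allclose(r1["log2fc"], -r2["log2fc"], atol=1e-8)


class TestWald:
    def test_equal_means_p_near_one(self):
        cm = make_count_matrix([[12, 12, 12, 12]])
        res = wald_test(cm, unit_nf(4), 0.1)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_normal_reference_quantile(self):
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.05, rel=1e-4)

    def test_base_mean_with_unit_factors(self):
        cm = make_count_matrix([[4, 6, 8, 6]])
        res = wald_test(cm, unit_nf(4), 0.1)
        assert res["covariate"].iloc[0] == pytest.approx(6.0)


class TestLogCPM:
    def test_zero_count_reference_value(self):
        cm = make_count_matrix([[0]], conditions=["A"])
        v = logcpm(cm, unit_nf(1, 1e6))
        assert v[0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6), rel=1e-9)
        assert v[0] == pytest.approx(-1.0, abs=0.01)

    def test_scale_invariance(self):
        cm1 = make_count_matrix([[100, 200]])
        cm2 = make_count_matrix([[200, 400]])
        v1 = logcpm(cm1, NormFactors([1e6, 1e6], "libsize"))
        v2 = logcpm(cm2, NormFactors([2e6, 2e6], "libsize"))
        # invariance is exact only without the +0.5/+1 stabilizing priors
        np.testing.assert_allclose(v1, v2, atol=0.01)

    def test_thousand_cpm_reference(self):
        cm = make_count_matrix([[1000]], conditions=["A"])
        v = logcpm(cm, unit_nf(1, 1e6))
        assert v[0] == pytest.approx(np.log2(1000), abs=0.01)


class TestParameterRecovery:
    def test_planted_log2fc_recovered_within_bias_bound(self):
        rng = np.random.default_rng(55)
        n = 400
        mu_a = rng.uniform(50, 300, size=n)
        counts = np.column_stack([
            nb_counts(rng, mu_a, 0.1, n), nb_counts(rng, mu_a, 0.1, n),
            nb_counts(rng, 4 * mu_a, 0.1, n), nb_counts(rng, 4 * mu_a, 0.1, n),
        ])
        cm = make_count_matrix(counts)
        res = run_test(cm, unit_nf(4), 0.1, "glm_lrt")
        assert abs(res["log2fc"].mean() - 2.0) < 0.2
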
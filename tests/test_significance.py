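import numpy as np
import pytest

from diffloopkit import nb_stats
from diffloopkit.significance import (
    EqualOccupancyBins,
    IHWConfig,
    StratificationConfig,
    bh_adjust,
    equal_occupancy_bins,
    ihw_adjust,
    stratified_test,
)
from conftest import make_count_matrix


class TestBH:
    def test_hand_computed_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04], atol=1e-15)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == 0.3

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(5)), np.ones(5))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_adjust(np.array([0.1, np.nan]))

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 500))
            ours = bh_adjust(p)
            oracle = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestIHW:
    def test_constant_covariate_identical_to_bh(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=400)
        padj, w = ihw_adjust(p, np.zeros(400), IHWConfig(alpha=0.05))
        np.testing.assert_array_equal(padj, bh_adjust(p))
        assert (w == 1).all()

    def test_small_n_falls_back_to_bh(self, caplog):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=30)
        cov = rng.normal(size=30)
        with caplog.at_level("WARNING"):
            padj, w = ihw_adjust(p, cov, IHWConfig())
        np.testing.assert_array_equal(padj, bh_adjust(p))
        assert (w == 1).all()

    def test_weight_budget_constraint(self):
        # learned weights satisfy sum_g w_g n_g = n on every training split
        from diffloopkit.significance import _learn_weights

        rng = np.random.default_rng(4)
        n = 2000
        p = rng.uniform(size=n)
        p[:200] = rng.uniform(size=200) * 1e-4
        groups = np.repeat(np.arange(5), n // 5)
        w = _learn_weights(p, groups, 5, alpha=0.05)
        n_g = np.bincount(groups, minlength=5)
        assert np.dot(w, n_g) == pytest.approx(n, rel=1e-9)

    def test_informative_covariate_beats_bh(self):
        # all signal in the high-covariate half: weighting must not lose power
        rng = np.random.default_rng(5)
        n = 5000
        cov = rng.uniform(size=n)
        p = rng.uniform(size=n)
        signal = cov > 0.5
        idx = np.flatnonzero(signal)[:600]
        p[idx] = rng.beta(0.08, 1.0, size=600)
        padj_ihw, _ = ihw_adjust(p, cov, IHWConfig(alpha=0.05, seed=0))
        padj_bh = bh_adjust(p)
        assert (padj_ihw <= 0.05).sum() >= (padj_bh <= 0.05).sum()

    def test_null_fdp_controlled(self):
        # full-null p with a covariate that looks informative: realized
        # rejection rate (= FDP) stays near alpha across MC repeats
        rng = np.random.default_rng(6)
        any_rejection = []
        for _ in range(40):
            p = rng.uniform(size=2000)
            cov = rng.normal(size=2000)
            padj, _ = ihw_adjust(p, cov, IHWConfig(alpha=0.05, seed=7))
            any_rejection.append((padj <= 0.05).any())
        rate = np.mean(any_rejection)
        sd = np.std(any_rejection, ddof=1) / np.sqrt(len(any_rejection))
        assert rate <= 0.05 + 2 * max(sd, 0.03)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=1000)
        cov = rng.normal(size=1000)
        a1, w1 = ihw_adjust(p, cov, IHWConfig(seed=3))
        a2, w2 = ihw_adjust(p, cov, IHWConfig(seed=3))
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(w1, w2)


class TestEqualOccupancy:
    def test_single_distance_single_bin(self):
        d = np.full(10, 50_000)
        c = np.full(10, 3)
        bins = equal_occupancy_bins(d, c, StratificationConfig(M=5))
        assert bins.n_bins == 1
        assert (bins.membership == 0).all()

    def test_greedy_quota_closure_last_under_quota(self):
        # four occupied 10 kb lattice intervals with counts 30/30/30/10,
        # quota C/M = 25: each interval closes its own stratum
        d = np.array([10_000, 20_000, 30_000, 40_000])
        c = np.array([30, 30, 30, 10])
        bins = equal_occupancy_bins(d, c, StratificationConfig(M=4))
        assert bins.n_bins == 4
        assert bins.bin_totals.tolist() == [30, 30, 30, 10]

    def test_greedy_accumulation_across_intervals(self):
        d = np.array([10_000, 20_000, 30_000, 40_000])
        c = np.array([10, 10, 10, 70])
        bins = equal_occupancy_bins(d, c, StratificationConfig(M=4))
        assert bins.n_bins == 2
        assert bins.bin_totals.tolist() == [30, 70]
        assert bins.membership.tolist() == [0, 0, 0, 1]

    def test_zero_total_count_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            equal_occupancy_bins(np.array([20_000]), np.array([0]),
                                 StratificationConfig())

    def test_invariants_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(50, 500))
            d = rng.integers(10_000, 3_000_001, size=n)
            c = rng.poisson(5, size=n) + 1
            M = int(rng.integers(2, 40))
            bins = equal_occupancy_bins(d, c, StratificationConfig(M=M))
            quota = bins.C / M
            # every non-final stratum meets the quota
            assert (bins.bin_totals[:-1] >= quota - 1e-9).all()
            # membership covers all in-range loops exactly once
            assert (bins.membership >= 0).sum() == bins.N
            # strata are contiguous in distance
            for b in range(bins.n_bins - 1):
                assert bins.boundaries[b][1] <= bins.boundaries[b + 1][0]
            order = bins.membership[np.argsort(d, kind="mergesort")]
            order = order[order >= 0]
            assert (np.diff(order) >= 0).all()


class TestStratifiedTest:
    def make_cm(self, rng, n=60):
        # the short-distance half carries clearly more than half the mass,
        # so M=2 closes one stratum per distance cluster
        mu = np.where(np.arange(n) < n // 2, 60, 20)[:, None]
        counts = rng.poisson(mu, size=(n, 4))
        counts[counts.sum(axis=1) == 0, 0] = 1
        d1 = np.full(n // 2, 50_000)
        d2 = np.full(n - n // 2, 2_000_000)
        start1 = np.arange(n) * 5000
        start2 = start1 + np.concatenate([d1, d2])
        return make_count_matrix(counts, start1=start1, start2=start2)

    def test_single_bin_equals_unstratified_bh(self):
        rng = np.random.default_rng(10)
        cm = self.make_cm(rng)
        bins = equal_occupancy_bins(cm.distance, cm.counts.sum(axis=1),
                                    StratificationConfig(M=1))
        assert bins.n_bins == 1
        res = stratified_test(cm, bins, test="exact", fixed_dispersion=0.1)
        nf = nb_stats.norm_factors(cm, "median_of_ratios")
        direct = nb_stats.exact_test(cm, nf, 0.1)
        np.testing.assert_allclose(res["pvalue"], direct["pvalue"], atol=1e-12)
        np.testing.assert_allclose(res["padj"], bh_adjust(direct["pvalue"].to_numpy()),
                                   atol=1e-12)

    def test_two_bins_compose_with_pooled_bh(self):
        rng = np.random.default_rng(11)
        cm = self.make_cm(rng)
        bins = equal_occupancy_bins(cm.distance, cm.counts.sum(axis=1),
                                    StratificationConfig(M=2))
        assert bins.n_bins == 2
        res = stratified_test(cm, bins, test="exact", fixed_dispersion=0.1)
        # per-stratum p equals a run restricted to that stratum
        pooled = []
        for b in (0, 1):
            rows = np.flatnonzero(bins.membership == b)
            sub = cm.subset(rows)
            nf = nb_stats.norm_factors(sub, "median_of_ratios")
            direct = nb_stats.exact_test(sub, nf, 0.1)
            got = res[res["stratum"] == b]["pvalue"].to_numpy()
            np.testing.assert_allclose(got, direct["pvalue"], atol=1e-12)
            pooled.append(direct["pvalue"].to_numpy())
        expected_padj = bh_adjust(np.concatenate(pooled))
        order = np.concatenate([np.flatnonzero(bins.membership == b) for b in (0, 1)])
        got_padj = res.sort_values("stratum", kind="mergesort")["padj"].to_numpy()
        np.testing.assert_allclose(got_padj, expected_padj, atol=1e-12)

    def test_tiny_stratum_falls_back_to_exact(self, caplog):
        rng = np.random.default_rng(12)
        cm = self.make_cm(rng, n=24)
        bins = equal_occupancy_bins(cm.distance, cm.counts.sum(axis=1),
                                    StratificationConfig(M=2))
        with caplog.at_level("INFO"):
            res = stratified_test(cm, bins, test="glm_qlf", min_bin_loops=100)
        assert (res["test"] == "exact").all()


class TestBHProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bh_bounds_dominance_and_oracle(self, p):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        adj = bh_adjust(p)
        assert ((adj >= p - 1e-15) & (adj <= 1.0)).all()
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)
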
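import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conjfdr.cfdr import (CfdrConfig, assign_strata, build_lookup_grid,
                          cfdr_values, conditional_cdf, conjunction_fdr,
                          joint_exceedance_counts, run_conjunction)

from conftest import panel_from_p
from oracles import oracle_cfdr, oracle_conditional_cdf


class TestConditionalCdf:
    def test_counting_example(self):
        p1 = [0.01, 0.2, 0.5, 0.9]
        p2 = [0.04, 0.03, 0.6, 0.8]
        assert conditional_cdf(p1, p2, 0.25, 0.05) == 1.0
        assert conditional_cdf(p1, p2, 0.25, 0.05) == \
            oracle_conditional_cdf(p1, p2, 0.25, 0.05)

    def test_total_mass(self, rng):
        p1, p2 = rng.uniform(size=50), rng.uniform(size=50)
        assert conditional_cdf(p1, p2, 1.0, 0.5) == 1.0

    def test_reduces_to_marginal_when_unconditioned(self, rng):
        p1, p2 = rng.uniform(size=200), rng.uniform(size=200)
        assert conditional_cdf(p1, p2, 0.3, 1.0) == np.mean(p1 <= 0.3)

    def test_empty_stratum_sentinel(self):
        assert np.isnan(conditional_cdf([0.5], [0.5], 0.5, 0.01))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        p1, p2 = r.uniform(size=30), r.uniform(size=30)
        t1, t2 = r.uniform(0.01, 1), r.uniform(0.05, 1)
        got = conditional_cdf(p1, p2, t1, t2)
        exp = oracle_conditional_cdf(p1, p2, t1, t2)
        assert got == pytest.approx(exp, abs=1e-15)


class TestCfdrValues:
    def test_p1_of_one_gives_one(self):
        p1 = np.concatenate([[1.0], np.linspace(0.01, 0.99, 150)])
        p2 = np.linspace(0.01, 1.0, 151)
        c = cfdr_values(p1, p2, CfdrConfig(min_stratum_size=10))
        assert c[0] == 1.0

    def test_independent_null_cfdr_is_conservative(self, rng):
        """Under independence F(t1|t2) -> t1, so the ratio p1/F -> 1: with
        everything null the estimated FDR is ~1 at moderate p1, and the
        raw (pre-monotonicity) ratio at p1 = 0.05 is within Monte-Carlo
        error of its analytic value."""
        n = 100_000
        p1, p2 = rng.uniform(size=n), rng.uniform(size=n)
        c = cfdr_values(p1, p2)
        near = np.abs(p1 - 0.05) < 0.002
        # raw ratio before the running-min: p1 / ecdf(p1) ~ 1
        raw = p1[near] / (np.searchsorted(np.sort(p1), p1[near], side="right") / n)
        assert np.mean(raw) == pytest.approx(1.0, abs=0.01)
        # after stratification + monotonicity nothing looks discoverable
        assert np.mean(c[near]) > 0.9

    def test_pleiotropic_toy_counting(self):
        """Every p2 <= 0.01 SNP also has p1 <= 0.001: cfdr = 0.001 / 1.0."""
        n = 400
        p1 = np.full(n, 0.5)
        p2 = np.full(n, 0.9)
        p1[:120], p2[:120] = 0.001, 0.01  # jointly extreme SNPs
        c = cfdr_values(p1, p2, CfdrConfig(min_stratum_size=100))
        assert c[0] == pytest.approx(0.001 / 1.0, abs=1e-15)

    def test_monotone_in_p1_within_stratum(self, rng):
        n = 2000
        p1, p2 = rng.uniform(size=n), rng.uniform(size=n)
        cfg = CfdrConfig()
        c = cfdr_values(p1, p2, cfg)
        idx = assign_strata(p2, cfg.sorted_strata(), cfg.min_stratum_size)
        for s in np.unique(idx):
            m = idx == s
            order = np.argsort(p1[m])
            assert np.all(np.diff(c[m][order]) >= -1e-15)

    def test_order_invariance(self, rng):
        n = 3000
        p1, p2 = rng.uniform(size=n), rng.uniform(size=n)
        perm = rng.permutation(n)
        c = cfdr_values(p1, p2)
        cp = cfdr_values(p1[perm], p2[perm])
        np.testing.assert_allclose(cp, c[perm], atol=1e-15)

    def test_small_stratum_falls_back(self, rng, caplog):
        p1 = rng.uniform(size=500)
        p2 = rng.uniform(0.5, 1.0, size=500)  # nothing reaches p2 <= 0.1
        c = cfdr_values(p1, p2, CfdrConfig(min_stratum_size=100))
        assert np.all((0 <= c) & (c <= 1))

    def test_base_stratum_too_small_errors(self):
        with pytest.raises(ValueError, match="base stratum"):
            cfdr_values([0.5] * 10, [0.5] * 10, CfdrConfig(min_stratum_size=100))


class TestConjunction:
    @pytest.mark.parametrize("a,b,expected", [(0.2, 0.05, 0.2), (0.03, 0.03, 0.03),
                                              (0.0, 1.0, 1.0)])
    def test_max_rule(self, a, b, expected):
        assert conjunction_fdr(a, b) == expected

    def test_exact_max_identity_on_panel(self, small_sim):
        panel, _ = small_sim
        res = run_conjunction(panel, "trait1", "trait2")
        np.testing.assert_array_equal(
            res["conjfdr"], np.maximum(res["cfdr_1g2"], res["cfdr_2g1"]))
        assert ((res["conjfdr"] >= res["cfdr_1g2"]) & (res["conjfdr"] >= res["cfdr_2g1"])).all()
        assert (res["significant"] == (res["conjfdr"] < 0.05)).all()

    def test_duplicated_trait_is_symmetric(self, rng):
        p = np.clip(rng.uniform(size=2000) ** 3, 1e-12, 1)
        panel = panel_from_p(p, p)
        res = run_conjunction(panel, "trait1", "trait2")
        np.testing.assert_allclose(res["cfdr_1g2"], res["cfdr_2g1"], atol=1e-15)
        if res["significant"].any():
            worst_sig_p = p[res["significant"]].max()
            assert worst_sig_p <= p[~res["significant"].to_numpy()].min()


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed,n", [(0, 500), (1, 2000)])
    def test_cfdr_matches_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        p1 = np.clip(r.uniform(size=n) ** 2, 1e-10, 1)
        p2 = np.clip(r.uniform(size=n) ** 2, 1e-10, 1)
        got = cfdr_values(p1, p2)
        exp = oracle_cfdr(p1, p2)
        np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_counting_kernel_matches_loops(self, rng):
        p1, p2 = rng.uniform(size=300), rng.uniform(size=300)
        t1s = [0.5, 0.1, 0.01]
        t2s = [1.0, 0.2]
        counts = joint_exceedance_counts(p1, p2, t1s, t2s)
        for s, t2 in enumerate(t2s):
            for g, t1 in enumerate(t1s):
                assert counts[s, g] == np.sum((p1 <= t1) & (p2 <= t2))


class TestLookupGrid:
    def test_counts_non_increasing_and_cfdr_bounded(self, rng):
        p1, p2 = rng.uniform(size=5000), rng.uniform(size=5000)
        grid = build_lookup_grid(p1, p2)
        assert np.all(np.diff(grid.counts, axis=1) <= 0)   # p1 grid decreasing
        assert np.all(np.diff(grid.counts, axis=0) <= 0)   # strata tighten
        assert np.all((grid.cfdr_table >= 0) & (grid.cfdr_table <= 1))
        # non-decreasing in p1 within a stratum (grid is stored decreasing in p1)
        assert np.all(np.diff(grid.cfdr_table, axis=1) <= 1e-15)


class TestPruning:
    def test_ld_averaged_counts_stay_calibrated(self, rng):
        from conjfdr.loci import assign_blocks
        from conjfdr.simulate import SimConfig, simulate_panel
        from conjfdr.sumstats import harmonize

        tables, _ = simulate_panel(SimConfig(n_snps=5000, ld_block_size=5,
                                             rho=0.7, seed=5))
        panel = harmonize(tables)
        blocks = assign_blocks(panel.snp_ids, panel.chrom, panel.pos,
                               method="window", window_bp=20_000)
        cfg = CfdrConfig(pruning_r=20, pruning_seed=1, min_stratum_size=50)
        res = run_conjunction(panel, "trait1", "trait2", cfg, blocks=blocks)
        assert ((res["conjfdr"] >= 0) & (res["conjfdr"] <= 1)).all()
        res0 = run_conjunction(panel, "trait1", "trait2",
                               CfdrConfig(min_stratum_size=50))
        # averaged-ecdf estimates should stay close to the all-SNP estimates
        assert np.median(np.abs(res["conjfdr"] - res0["conjfdr"])) < 0.05

    def test_pruning_requires_blocks(self, rng):
        panel = panel_from_p(rng.uniform(size=300), rng.uniform(size=300))
        with pytest.raises(ValueError, match="block"):
            run_conjunction(panel, "trait1", "trait2",
                            CfdrConfig(pruning_r=5, min_stratum_size=50))
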
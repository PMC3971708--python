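import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermotrace as tt
from thermotrace.core_io import Alignment, RootedTree
from thermotrace.inference import (
    FitOptions,
    PruningEngine,
    _Objective,
    partition_sites,
    site_rates,
)
from thermotrace.substitution_model import GGParams

from conftest import random_gg_params
from oracles import (
    all_rooted_topologies,
    enum_site_logliks,
    homogeneous_loglik,
    topology_to_newick,
)


class TestLoglikelihood:
    def test_zero_branch_star_collapses_to_root_frequency(self):
        """Two identical 'G' tips on zero branches: likelihood = pi_G."""
        tree = RootedTree.from_newick("(a:0,b:0);")
        aln = Alignment(("a", "b"), ("G", "G"))
        params = GGParams.homogeneous(tree, 0.6, 1.0, 1.0, n_categories=1)
        params = GGParams(0.6, params.theta_branch, 1.0, 1.0, 1)
        res = tt.loglikelihood(aln, tree, params)
        assert res.loglik == pytest.approx(np.log(0.3), abs=1e-12)

    def test_stationary_reduction_matches_independent_homogeneous_path(
            self, quartet_tree):
        """With all thetas equal the model is stationary T92+gamma and must
        agree with a separate expm-based pruning implementation."""
        params = GGParams.homogeneous(quartet_tree, 0.62, 2.5, 0.7,
                                      n_categories=4)
        aln = tt.simulate_gg(quartet_tree, params, 60, seed=3)
        res = tt.loglikelihood(aln, quartet_tree, params)
        oracle = homogeneous_loglik(aln, quartet_tree, 0.62, 2.5, 0.7, 4)
        assert res.loglik == pytest.approx(oracle, abs=1e-10)

    def test_matches_enumeration_oracle_on_quartet(self, quartet_tree):
        rng = np.random.default_rng(11)
        params = random_gg_params(quartet_tree, rng)
        aln = tt.simulate_gg(quartet_tree, params, 30, seed=4)
        res = tt.loglikelihood(aln, quartet_tree, params)
        oracle = enum_site_logliks(aln, quartet_tree, params)
        assert np.abs(res.per_site_logliks - oracle).max() < 1e-10
        rel = abs(res.loglik - oracle.sum()) / abs(oracle.sum())
        assert rel < 1e-10

    def test_missing_data_columns_are_uninformative(self, quartet_tree):
        rng = np.random.default_rng(5)
        params = random_gg_params(quartet_tree, rng, n_categories=2)
        aln = tt.simulate_gg(quartet_tree, params, 20, seed=6)
        all_missing = Alignment(
            aln.taxa, tuple(s + "N-" for s in aln.sequences)
        )
        res1 = tt.loglikelihood(aln, quartet_tree, params)
        res2 = tt.loglikelihood(all_missing, quartet_tree, params)
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-9)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=10, deadline=None)
    def test_invariant_to_leaf_order_and_child_rotation(self, seed):
        rng = np.random.default_rng(seed)
        t1 = RootedTree.from_newick("((a:0.1,b:0.3):0.2,(c:0.15,d:0.05):0.4);")
        t2 = RootedTree.from_newick("((d:0.05,c:0.15):0.4,(b:0.3,a:0.1):0.2);")
        p1 = random_gg_params(t1, rng, n_categories=4)
        # map t1 branch params to the same branches in t2 via leaf sets
        def clade_key(tree, v):
            return frozenset(tree.labels[u] for u in tree.clade_leaves(v))
        lookup = {clade_key(t1, v): th for v, th in p1.theta_branch.items()}
        p2 = GGParams(
            p1.theta_root,
            {v: lookup[clade_key(t2, v)] for v in range(t2.n_nodes)
             if v != t2.root},
            p1.kappa, p1.alpha, p1.n_categories,
        )
        aln = tt.simulate_gg(t1, p1, 25, seed=seed)
        shuffled = Alignment(aln.taxa[::-1], aln.sequences[::-1])
        l1 = tt.loglikelihood(aln, t1, p1).loglik
        l2 = tt.loglikelihood(shuffled, t2, p2).loglik
        assert l2 == pytest.approx(l1, abs=1e-9)

    def test_enumeration_agreement_over_random_topologies(self):
        """Pruning equals brute-force enumeration on random 5-leaf trees."""
        rng = np.random.default_rng(2024)
        topologies = all_rooted_topologies(list("abcde"))
        picks = rng.choice(len(topologies), size=5, replace=False)
        for idx in picks:
            tree = RootedTree.from_newick(
                topology_to_newick(topologies[idx], rng)
            )
            params = random_gg_params(tree, rng, n_categories=2)
            aln = tt.simulate_gg(tree, params, 10, seed=int(idx))
            res = tt.loglikelihood(aln, tree, params)
            oracle = enum_site_logliks(aln, tree, params)
            assert np.abs(res.per_site_logliks - oracle).max() < 1e-10


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, quartet_tree):
        rng = np.random.default_rng(8)
        params = random_gg_params(quartet_tree, rng, n_categories=4)
        aln = tt.simulate_gg(quartet_tree, params, 100, seed=9)
        engine = PruningEngine(aln, quartet_tree, 4)
        obj = _Objective(engine, 4, homogeneous=False, optimize_bl=True)
        x = obj.pack(params)
        _, g = obj(x)
        h = 1e-5
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (obj(xp)[0] - obj(xm)[0]) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFitting:
    def test_auto_initialization_is_observed_gc(self, small_study):
        from thermotrace.inference import _auto_init

        aln = small_study.alignment
        init = _auto_init(aln, small_study.tree, 8)
        assert init.theta_root == pytest.approx(
            float(aln.gc_content().mean()), abs=1e-12
        )
        assert init.kappa == 2.0 and init.alpha == 0.5

    def test_refit_from_optimum_is_fixed_point(self, small_study):
        opts = FitOptions(n_starts=1, seed=0)
        fit1 = tt.fit_gg(small_study.alignment, small_study.tree, options=opts)
        fit2 = tt.fit_gg(small_study.alignment, small_study.tree,
                         init=fit1.params, options=opts)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-4)
        assert fit2.loglik >= fit1.loglik - 1e-6

    def test_parameter_recovery_on_simulated_data(self):
        cfg = tt.StudyConfig(n_taxa=16, n_sites=2000)
        study = tt.make_synthetic_study(cfg, seed=42)
        res = tt.fit_gg(study.alignment, study.tree,
                        options=FitOptions(n_starts=1, seed=0))
        assert res.converged
        assert res.params.theta_root == pytest.approx(0.45, abs=0.05)

    def test_homogeneous_nested_in_gg(self, small_study):
        opts = FitOptions(n_starts=1, seed=0)
        hom = tt.fit_homogeneous(small_study.alignment, small_study.tree,
                                 options=opts)
        assert hom.n_free_params == 3
        gg = tt.fit_gg(small_study.alignment, small_study.tree,
                       init=hom.params, options=opts)
        assert gg.loglik >= hom.loglik - 1e-6
        constrained = tt.loglikelihood(
            small_study.alignment, small_study.tree, hom.params
        )
        assert constrained.loglik == pytest.approx(hom.loglik, abs=1e-9)

    def test_nonconvergence_is_flagged_not_silent(self, small_study):
        res = tt.fit_gg(small_study.alignment, small_study.tree,
                        options=FitOptions(n_starts=1, max_iter=2))
        assert res.converged is False


class TestModelSelection:
    """AIC should pick the branch-wise model exactly when the data carry
    branch heterogeneity in composition."""

    @staticmethod
    def _balanced_tree():
        from thermotrace.simulation import make_balanced_tree

        return make_balanced_tree(8)

    def test_aic_prefers_gg_under_strong_branch_heterogeneity(self):
        tree = self._balanced_tree()
        anc_a, anc_b = tree.children[tree.root]
        opts = FitOptions(n_starts=1, seed=0)
        wins = 0
        for seed in range(20):
            thetas = {}
            for v in range(tree.n_nodes):
                if v == tree.root:
                    continue
                in_a = v <= anc_a  # post-order: clade A occupies lower IDs
                thetas[v] = 0.70 if in_a else 0.45
            params = GGParams(0.45, thetas, 2.0, 0.5, 4)
            aln = tt.simulate_gg(tree, params, 2000, seed=seed)
            gg = tt.fit_gg(aln, tree, options=opts, n_categories=4)
            hom = tt.fit_homogeneous(aln, tree, options=opts, n_categories=4)
            wins += gg.aic < hom.aic
        assert wins >= 18

    def test_aic_prefers_homogeneous_on_homogeneous_data(self):
        tree = self._balanced_tree()
        opts = FitOptions(n_starts=1, seed=0)
        wins = 0
        for seed in range(20):
            params = GGParams.homogeneous(tree, 0.55, 2.0, 0.5, 4)
            aln = tt.simulate_gg(tree, params, 2000, seed=seed)
            gg = tt.fit_gg(aln, tree, options=opts, n_categories=4)
            hom = tt.fit_homogeneous(aln, tree, options=opts, n_categories=4)
            wins += hom.aic <= gg.aic
        assert wins > 10

    def test_free_parameter_counts_differ_by_branch_count(self, small_study):
        opts = FitOptions(n_starts=1, seed=0, max_iter=50)
        gg = tt.fit_gg(small_study.alignment, small_study.tree, options=opts)
        hom = tt.fit_homogeneous(small_study.alignment, small_study.tree,
                                 options=opts)
        n_branches = small_study.tree.n_nodes - 1
        assert gg.n_free_params - hom.n_free_params == n_branches


class TestSiteRates:
    def test_single_category_gives_unit_rates(self, small_study):
        params = GGParams.homogeneous(small_study.tree, 0.5, 2.0, 0.5,
                                      n_categories=1)
        profile = site_rates(small_study.alignment, small_study.tree, params)
        assert np.allclose(profile.mean_rate, 1.0)

    def test_invariant_columns_are_slower_than_variable_ones(self, quartet_tree):
        aln = Alignment(("a", "b", "c", "d"), ("AC", "AG", "AT", "AA"))
        params = GGParams.homogeneous(quartet_tree, 0.5, 2.0, 0.5,
                                      n_categories=8)
        profile = site_rates(aln, quartet_tree, params)
        assert profile.mean_rate[0] < profile.mean_rate[1]

    def test_category_posteriors_match_brute_force_bayes(self, quartet_tree):
        rng = np.random.default_rng(13)
        params = random_gg_params(quartet_tree, rng, n_categories=4)
        aln = tt.simulate_gg(quartet_tree, params, 20, seed=14)
        profile = site_rates(aln, quartet_tree, params)
        # oracle: per-category site likelihoods by enumeration
        from thermotrace.substitution_model import discretize_gamma
        K = 4
        per_cat = np.empty((aln.sites, K))
        for k in range(K):
            rates = discretize_gamma(params.alpha, K).rates
            scaled = quartet_tree.with_lengths(
                quartet_tree.lengths * rates[k]
            )
            single = GGParams(params.theta_root, params.theta_branch,
                              params.kappa, 1.0, 1)
            per_cat[:, k] = enum_site_logliks(aln, scaled, single)
        from scipy.special import softmax
        oracle = softmax(per_cat, axis=1)
        assert np.abs(profile.category_posterior - oracle).max() < 1e-10


class TestPartitionSites:
    def test_median_split_of_four_rates(self):
        profile = tt.SiteRateProfile(
            category_posterior=np.eye(4),
            mean_rate=np.array([0.1, 0.2, 1.0, 2.7]),
            rates=np.array([0.1, 0.2, 1.0, 2.7]),
        )
        part = partition_sites(profile, 0.5)
        assert list(part.slow.indices) == [0, 1]
        assert list(part.fast.indices) == [2, 3]

    def test_quarter_quantile_on_eight_distinct_rates(self):
        rates = np.array([0.3, 0.1, 2.0, 0.5, 1.4, 0.8, 3.0, 0.2])
        profile = tt.SiteRateProfile(np.zeros((8, 2)), rates, np.array([1., 1.]))
        part = partition_sites(profile, 0.25)
        assert len(part.slow) == 2
        assert set(part.slow.indices) == {1, 7}

    def test_tied_rates_split_deterministically_by_index(self):
        rates = np.ones(6)
        profile = tt.SiteRateProfile(np.zeros((6, 2)), rates, np.array([1., 1.]))
        part = partition_sites(profile, 0.5)
        assert list(part.slow.indices) == [0, 1, 2]
        assert list(part.fast.indices) == [3, 4, 5]

    def test_partition_is_exhaustive_and_disjoint(self, small_study):
        opts = FitOptions(n_starts=1, seed=0)
        fit = tt.fit_gg(small_study.alignment, small_study.tree, options=opts)
        profile = site_rates(small_study.alignment, small_study.tree,
                             fit.params)
        part = partition_sites(profile, 0.5)
        merged = np.sort(np.concatenate([part.slow.indices, part.fast.indices]))
        assert np.array_equal(merged, np.arange(small_study.alignment.sites))

    def test_slow_sites_show_fewer_pairwise_differences(self, small_study):
        opts = FitOptions(n_starts=1, seed=0)
        fit = tt.fit_gg(small_study.alignment, small_study.tree, options=opts)
        profile = site_rates(small_study.alignment, small_study.tree,
                             fit.params)
        part = partition_sites(profile, 0.5)
        codes = small_study.alignment.to_codes()

        def mean_pairwise_diff(cols):
            sub = codes[:, cols]
            n = sub.shape[0]
            diffs = [
                (sub[i] != sub[j]).mean()
                for i in range(n) for j in range(i + 1, n)
            ]
            return np.mean(diffs)

        assert (mean_pairwise_diff(part.slow.indices)
                < mean_pairwise_diff(part.fast.indices))
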
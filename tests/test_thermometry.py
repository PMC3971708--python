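import numpy as np
import pandas as pd
import pytest
from scipy import stats

import thermotrace as tt
from thermotrace.ancestral import CompositionSummary
from thermotrace.core_io import RootedTree
from thermotrace.thermometry import (
    build_thermometer,
    compare_nodes,
    correspondence_axes,
    estimate_ancestral_ogt,
    pic_contrasts,
    pic_correlation,
)

from oracles import (
    brownian_tip_covariance,
    contrast_weight_matrix,
    permutation_ranksum_pvalue,
)


class TestBuildThermometer:
    def test_exact_linear_data_recovered(self):
        gc = pd.Series({f"t{i}": 0.3 + 0.05 * i for i in range(8)})
        ogt = 10.0 + 100.0 * gc
        th = build_thermometer(gc, ogt)
        assert th.slope == pytest.approx(100.0, abs=1e-9)
        assert th.intercept == pytest.approx(10.0, abs=1e-9)
        assert th.residual_sd == pytest.approx(0.0, abs=1e-9)
        assert th.spearman_rho == pytest.approx(1.0)

    def test_constant_composition_rejected(self):
        gc = pd.Series({"a": 0.5, "b": 0.5, "c": 0.5})
        ogt = pd.Series({"a": 30.0, "b": 50.0, "c": 70.0})
        with pytest.raises(ValueError, match="variance"):
            build_thermometer(gc, ogt)

    def test_too_few_matched_taxa_rejected(self):
        gc = pd.Series({"a": 0.4, "b": 0.5, "c": 0.6})
        ogt = pd.Series({"a": 30.0, "b": 50.0, "x": 70.0})
        with pytest.raises(ValueError, match=">= 3"):
            build_thermometer(gc, ogt)

    def test_unmatched_taxa_excluded_not_fatal(self, small_study):
        gc = small_study.alignment.gc_content()
        ogt = small_study.ogt_table.drop(gc.index[0])
        th = build_thermometer(gc, ogt)
        assert th.n == len(ogt)

    def test_spearman_matches_brute_force_rank_correlation(self, small_study):
        gc = small_study.alignment.gc_content()
        ogt = small_study.ogt_table
        th = build_thermometer(gc, ogt)
        x = gc.loc[ogt.index].to_numpy()
        rx = stats.rankdata(x)
        ry = stats.rankdata(ogt.to_numpy())
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert th.spearman_rho == pytest.approx(oracle, abs=1e-12)

    def test_prediction_at_mean_gc_is_mean_ogt(self, small_study):
        gc = small_study.alignment.gc_content()
        ogt = small_study.ogt_table
        th = build_thermometer(gc, ogt)
        assert th.predict(gc.loc[ogt.index].mean()) == pytest.approx(
            ogt.mean(), abs=1e-9
        )


class TestIndependentContrasts:
    def test_two_leaf_contrast_formula(self):
        tree = RootedTree.from_newick("(a:1,b:1);")
        cs = pic_contrasts(tree, {"a": 0.0, "b": 2.0})
        assert cs.contrasts[0] == pytest.approx(-np.sqrt(2.0), abs=1e-12)
        assert abs(cs.contrasts[0]) == pytest.approx(2.0 / np.sqrt(2.0))

    def test_perfect_linear_traits_give_unit_correlation(self, small_study):
        tree = small_study.tree
        x = {tree.labels[v]: float(i)
             for i, v in enumerate(tree.leaves())}
        y = {k: 3.0 + 2.0 * v for k, v in x.items()}
        rho, p = pic_correlation(tree, x, y)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_affine_invariance(self, small_study):
        tree = small_study.tree
        rng = np.random.default_rng(3)
        x = {lab: float(rng.normal()) for lab in tree.leaf_labels()}
        y = {lab: float(rng.normal()) for lab in tree.leaf_labels()}
        rho1, p1 = pic_correlation(tree, x, y)
        x2 = {k: 100.0 - 7.0 * v for k, v in x.items()}
        rho2, p2 = pic_correlation(tree, x2, y)
        assert abs(rho2) == pytest.approx(abs(rho1), abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_contrasts_whiten_brownian_covariance(self):
        """GLS oracle: the contrast map W must satisfy W C W' = I for the
        Brownian tip covariance C (contrasts are decorrelated, variance 1)."""
        tree = RootedTree.from_newick(
            "(((a:0.3,b:0.5):0.2,c:0.7):0.4,(d:0.6,e:0.2):0.3);"
        )
        W = contrast_weight_matrix(tree)
        C = brownian_tip_covariance(tree)
        assert np.abs(W @ C @ W.T - np.eye(W.shape[0])).max() < 1e-8

    def test_missing_leaf_value_reported(self, quartet_tree):
        with pytest.raises(ValueError, match="'d'"):
            pic_contrasts(quartet_tree, {"a": 1.0, "b": 2.0, "c": 3.0})


class TestAncestralOGT:
    def test_deterministic_mapping_without_residual_noise(self):
        th = tt.Thermometer(100.0, 10.0, 0.0, 10, 1.0, 0.0, 1.0)
        comp = CompositionSummary({0: np.full(50, 0.60)})
        est = estimate_ancestral_ogt(comp, th, convolve_residual=False)
        assert np.allclose(est.samples[0], 70.0)
        assert est.lower[0] == est.upper[0] == est.mean[0] == 70.0

    def test_monotone_in_composition(self):
        th = tt.Thermometer(100.0, 10.0, 0.0, 10, 1.0, 0.0, 1.0)
        rng = np.random.default_rng(0)
        gcs = rng.uniform(0.3, 0.7, size=200)
        est1 = estimate_ancestral_ogt(
            CompositionSummary({0: gcs}), th, convolve_residual=False)
        est2 = estimate_ancestral_ogt(
            CompositionSummary({0: gcs + 0.05}), th, convolve_residual=False)
        assert np.all(est2.samples[0] > est1.samples[0])

    def test_interval_narrows_with_posterior_certainty(self):
        th = tt.Thermometer(150.0, -20.0, 0.0, 10, 1.0, 0.0, 1.0)
        rng = np.random.default_rng(1)
        wide = CompositionSummary({0: 0.5 + rng.normal(0, 0.05, 400)})
        narrow = CompositionSummary({0: 0.5 + rng.normal(0, 0.005, 400)})
        ew = estimate_ancestral_ogt(wide, th, convolve_residual=False)
        en = estimate_ancestral_ogt(narrow, th, convolve_residual=False)
        assert (en.upper[0] - en.lower[0]) < (ew.upper[0] - ew.lower[0])

    def test_residual_convolution_widens_interval(self):
        th = tt.Thermometer(150.0, -20.0, 5.0, 10, 1.0, 0.0, 1.0)
        comp = CompositionSummary({0: np.full(500, 0.5)})
        off = estimate_ancestral_ogt(comp, th, convolve_residual=False)
        on = estimate_ancestral_ogt(comp, th, convolve_residual=True, seed=2)
        assert (on.upper[0] - on.lower[0]) > (off.upper[0] - off.lower[0])


class TestCompareNodes:
    def test_identical_samples_are_null(self):
        x = np.arange(50, dtype=float)
        stat, p, direction = compare_nodes(x, x.copy())
        assert p > 0.9
        assert stat == pytest.approx(50 * 50 / 2)
        assert direction == "tied"

    def test_fully_separated_samples(self):
        a = np.arange(1, 101, dtype=float)
        b = np.arange(201, 301, dtype=float)
        stat, p, direction = compare_nodes(a, b)
        assert p < 1e-10
        assert direction == "b_hotter"

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.8, 1.0, 15)
        _, p, _ = compare_nodes(a, b)
        p_perm = permutation_ranksum_pvalue(a, b, n_perm=10000, seed=10)
        mc_err = 3 * np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / 10000)
        assert abs(p - p_perm) < max(mc_err, 0.02)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_nodes(np.ones(5), np.ones(20))


class TestCorrespondenceAnalysis:
    def test_independence_table_has_zero_scores(self):
        r = np.array([[2.0], [3.0], [5.0]])
        c = np.array([[1.0, 4.0, 2.0]])
        table = r @ c
        scores, inertia = correspondence_axes(table)
        assert np.abs(scores).max() < 1e-10
        assert np.abs(inertia).max() < 1e-20

    def test_row_scores_match_eigendecomposition_oracle(self):
        table = np.array([
            [30.0, 10.0, 5.0],
            [10.0, 40.0, 10.0],
            [5.0, 10.0, 30.0],
        ])
        scores, inertia = correspondence_axes(table)
        # oracle: eigendecomposition of S S^T
        P = table / table.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        evals, evecs = np.linalg.eigh(S @ S.T)
        order = np.argsort(evals)[::-1][:2]
        lam = evals[order]
        F = evecs[:, order] * np.sqrt(lam) / np.sqrt(r)[:, None]
        for axis in range(2):
            diff = min(
                np.abs(scores[:, axis] - F[:, axis]).max(),
                np.abs(scores[:, axis] + F[:, axis]).max(),
            )
            assert diff < 1e-8
        assert np.abs(np.sort(inertia)[::-1] - lam).max() < 1e-10

    def test_total_inertia_equals_chi_square_over_total(self):
        rng = np.random.default_rng(4)
        table = rng.integers(1, 50, size=(6, 4)).astype(float)
        _, inertia = correspondence_axes(table)
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert inertia.sum() == pytest.approx(chi2 / table.sum(), rel=1e-10)

    def test_zero_row_rejected(self):
        table = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            correspondence_axes(table)
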
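"""Mixed Yule-coalescent likelihood, threshold fits and the LR test."""

import itertools
import math

import numpy as np
import pytest

from barcodescope.distances import DistMatrix
from barcodescope.gmyc import (
    GMYCParams,
    TreeError,
    TreeNode,
    UltraTree,
    _IntervalData,
    _fit_params,
    delimit_units,
    fit_gmyc_multiple,
    fit_gmyc_single,
    fit_null,
    gmyc_loglik,
    gmyc_lr_test,
    upgma_ultrametric,
)
from barcodescope.synthetic_data import _coalescent_subtree, simulate_species_tree


def pair(l1, l2, age):
    return TreeNode(age, [TreeNode(0, label=l1), TreeNode(0, label=l2)])


@pytest.fixture
def three_tip_tree():
    ab = pair("a", "b", 0.1)
    return UltraTree(TreeNode(0.4, [ab, TreeNode(0, label="c")]))


class TestUltraTree:
    def test_rejects_non_ultrametric_newick(self):
        with pytest.raises(TreeError, match="ultrametric"):
            UltraTree.from_newick("((a:1,b:2):1,c:2);")

    def test_newick_roundtrip_preserves_ages(self, three_tip_tree):
        back = UltraTree.from_newick(three_tip_tree.to_newick())
        assert back.tip_labels() == three_tip_tree.tip_labels()
        assert sorted(n.age for n in back.internal) == pytest.approx(
            sorted(n.age for n in three_tip_tree.internal)
        )

    def test_rejects_increasing_ages(self):
        bad = TreeNode(0.1, [pair("a", "b", 0.5), TreeNode(0, label="c")])
        with pytest.raises(TreeError, match="ages"):
            UltraTree(bad)


class TestUPGMA:
    def test_hand_example(self):
        dm = DistMatrix(
            ids=("A", "B", "C"),
            values=np.array([[0, 0.02, 0.10], [0.02, 0, 0.10], [0.10, 0.10, 0]]),
        )
        tree = upgma_ultrametric(dm)
        assert sorted(round(n.age, 6) for n in tree.internal) == [0.01, 0.05]
        # (A,B) cherry below the root
        cherry = min(tree.internal, key=lambda n: n.age)
        assert {c.label for c in cherry.children} == {"A", "B"}

    def test_two_taxa(self):
        dm = DistMatrix(ids=("A", "B"), values=np.array([[0, 0.3], [0.3, 0]]))
        tree = upgma_ultrametric(dm)
        assert tree.root.age == pytest.approx(0.15)

    def test_output_is_ultrametric(self, rng):
        n = 8
        x = rng.random((n, 4))
        vals = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        np.fill_diagonal(vals, 0.0)
        tree = upgma_ultrametric(DistMatrix(ids=tuple(f"t{i}" for i in range(n)), values=vals))
        assert all(tip.age == 0 for tip in tree.tips)
        for node in tree.internal:
            assert all(c.age <= node.age for c in node.children)


class TestLoglik:
    def test_three_tip_coalescent_hand_sum(self, three_tip_tree):
        params = GMYCParams(1.0, 1.0, 1.0, 1.0)
        expected = (math.log(6) - 6 * 0.1) + (math.log(2) - 2 * 0.3)
        assert gmyc_loglik(three_tip_tree, [], params) == pytest.approx(expected)

    def test_all_coalescent_labeling_equals_null(self, rng):
        root = _coalescent_subtree([f"t{i}" for i in range(8)], 0.5, rng)
        tree = UltraTree(root)
        params = GMYCParams(5.0, 1.0, 2.0, 1.2)
        # with zero speciation nodes only the coalescent process acts
        data = _IntervalData(tree, frozenset())
        expected = float(
            np.sum(np.log(2.0 * (data.C @ data.v ** 1.2)))
            - np.sum(2.0 * (data.C @ data.v ** 1.2) * data.x)
        )
        assert gmyc_loglik(tree, [], params) == pytest.approx(expected)

    def test_null_rate_mle_matches_closed_form(self, rng):
        """At a fixed exponent the rate MLE is (#events) / sum(w_i x_i)."""
        root = _coalescent_subtree([f"t{i}" for i in range(10)], 0.5, rng)
        tree = UltraTree(root)
        data = _IntervalData(tree, frozenset())
        params, lnL = _fit_params(data, seed=0)
        w = data.C @ data.v ** params.p_coal
        lam_hat = len(data.x) / float(np.sum(w * data.x))
        assert params.lambda_coal == pytest.approx(lam_hat, rel=1e-4)

    def test_component_event_rate_variant(self, three_tip_tree):
        params = GMYCParams(1.0, 1.0, 1.0, 1.0)
        # all events coalescent: pooled and component event terms coincide
        total = gmyc_loglik(three_tip_tree, [], params)
        comp = gmyc_loglik(three_tip_tree, [], params, event_rate="component")
        assert comp == pytest.approx(total)
        # with a speciation node the component term is strictly smaller
        # (each event's own rate is below the pooled rate)
        root = three_tip_tree.root
        total = gmyc_loglik(three_tip_tree, [root], params)
        comp = gmyc_loglik(three_tip_tree, [root], params, event_rate="component")
        assert comp < total

    def test_inconsistent_labeling_rejected(self, three_tip_tree):
        cherry = min(three_tip_tree.internal, key=lambda n: n.age)
        with pytest.raises(ValueError, match="ancestor"):
            gmyc_loglik(three_tip_tree, [cherry], GMYCParams(1, 1, 1, 1))


class TestSingleThreshold:
    def test_three_clear_pairs_delimited(self):
        subs = [pair(f"{s}1", f"{s}2", 0.001) for s in "abc"]
        inner = TreeNode(0.5, subs[:2])
        tree = UltraTree(TreeNode(0.8, [inner, subs[2]]))
        fit = fit_gmyc_single(tree, seed=1)
        assert fit.n_entities == 3
        assert 0.001 < fit.threshold < 0.5
        blocks = sorted(sorted(m) for m in fit.entities.units.values())
        assert blocks == [["a1", "a2"], ["b1", "b2"], ["c1", "c2"]]

    def test_entity_count_equals_branches_crossing_threshold(self):
        tree, _ = simulate_species_tree(4, theta=0.01, seed=3)
        fit = fit_gmyc_single(tree, seed=3)
        T = fit.threshold
        crossing = sum(
            1
            for n in tree.nodes
            if n.parent is not None and n.age < T < n.parent.age
        )
        assert fit.n_entities == crossing

    def test_nesting_against_null_on_random_trees(self, rng):
        for _ in range(10):
            root = _coalescent_subtree(
                [f"t{i}" for i in range(10)], float(rng.uniform(0.2, 2.0)), rng
            )
            tree = UltraTree(root)
            fit = fit_gmyc_single(tree, seed=0)
            assert fit.lnL_gmyc >= fit.lnL_null - 1e-6

    def test_clusters_exclude_singletons(self):
        tree, _ = simulate_species_tree(5, theta=0.001, n_per_species=3, seed=2)
        fit = fit_gmyc_single(tree, seed=2)
        assert all(len(m) >= 2 for m in fit.clusters.units.values())


class TestMultipleThreshold:
    def _deep_shallow_tree(self):
        # species A coalescences 10x older than species B's
        A = TreeNode(0.10, [pair("a1", "a2", 0.08), pair("a3", "a4", 0.09)])
        B = TreeNode(0.010, [pair("b1", "b2", 0.008), pair("b3", "b4", 0.009)])
        return UltraTree(TreeNode(2.0, [A, B]))

    def test_never_below_single_threshold_likelihood(self):
        tree, _ = simulate_species_tree(4, theta=0.01, seed=5)
        fs = fit_gmyc_single(tree, seed=5)
        fm = fit_gmyc_multiple(tree, single_fit=fs, seed=5)
        assert fm.lnL_gmyc >= fs.lnL_gmyc - 1e-9

    def test_splits_deep_species_single_does_not(self):
        """Exhaustive enumeration over all consistent labelings of the 7
        internal nodes confirms the hill-climb finds the global optimum."""
        tree = self._deep_shallow_tree()
        fs = fit_gmyc_single(tree, seed=1)
        fm = fit_gmyc_multiple(tree, single_fit=fs, seed=1)
        # single keeps the deep species whole; multiple splits it
        single_blocks = sorted(sorted(m) for m in fs.entities.units.values())
        assert ["a1", "a2", "a3", "a4"] in single_blocks
        multi_blocks = sorted(sorted(m) for m in fm.entities.units.values())
        assert ["a1", "a2"] in multi_blocks and ["a3", "a4"] in multi_blocks

        best = -np.inf
        for mask in itertools.product([0, 1], repeat=len(tree.internal)):
            spec = frozenset(n for n, m in zip(tree.internal, mask) if m)
            if not all(n.parent is None or n.parent in spec for n in spec):
                continue
            _, lnL = _fit_params(_IntervalData(tree, spec), seed=1)
            best = max(best, lnL)
        assert fm.lnL_gmyc == pytest.approx(best, abs=1e-4)


class TestLRTest:
    def test_zero_lr_gives_p_one(self):
        lr, p = gmyc_lr_test(10.0, 10.0)
        assert lr == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        _, p = gmyc_lr_test(0.0, 7.815 / 2.0, df=3)
        assert p == pytest.approx(0.050, abs=5e-4)

    def test_monotone_in_alternative_likelihood(self):
        _, p1 = gmyc_lr_test(0.0, 1.0)
        _, p2 = gmyc_lr_test(0.0, 2.0)
        assert p2 < p1

    def test_negative_lr_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            gmyc_lr_test(5.0, 4.0)

    def test_null_simulations_rarely_rejected(self, rng):
        """Single-population coalescent trees: LR p > .05 in >= 90%."""
        nonrej = 0
        n_reps = 40
        for seed in range(1, n_reps + 1):
            local = np.random.default_rng(seed)
            root = _coalescent_subtree([f"t{i}" for i in range(12)], 1.0, local)
            fit = fit_gmyc_single(UltraTree(root), seed=seed)
            nonrej += fit.p_value > 0.05
        assert nonrej >= 0.9 * n_reps
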
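"""Descriptor-selection cascade: merit arithmetic, GA search, tree, OLS."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polysorb.cluster import fit_em
from polysorb.core import InvalidInputError, ModelingDataset
from polysorb.selection import (
    CorrelationCache,
    GASettings,
    SelectionConfig,
    SingularDesignError,
    TreeSettings,
    build_tree,
    cfs_merit,
    entropy,
    genetic_search,
    regression_top_descriptor,
    select_descriptors,
    tree_descriptor_ranking,
)


def _merit_by_hand(X, y, idx):
    """Direct evaluation of Hall's merit from scratch correlations."""
    k = len(idx)
    r_cf = np.mean([abs(np.corrcoef(X[:, j], y)[0, 1]) for j in idx])
    if k == 1:
        return r_cf
    r_ff = np.mean([
        abs(np.corrcoef(X[:, a], X[:, b])[0, 1])
        for a, b in combinations(idx, 2)
    ])
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


class TestCfsMerit:
    @pytest.fixture()
    def data(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(40) * 0.3
        names = ["a", "b", "c", "d", "e"]
        return X, y, names

    def test_singleton_equals_abs_correlation(self, data):
        X, y, names = data
        r = abs(np.corrcoef(X[:, 0], y)[0, 1])
        assert cfs_merit(["a"], X, y, names) == pytest.approx(r, abs=1e-12)

    def test_exact_duplicate_pair_identity(self, data):
        X, y, names = data
        X2 = np.column_stack([X, X[:, 0]])
        merit = cfs_merit(["a", "f"], X2, y, names + ["f"])
        r = abs(np.corrcoef(X[:, 0], y)[0, 1])
        assert merit == pytest.approx(r, abs=1e-12)

    def test_matches_hand_computation(self, data):
        X, y, names = data
        for idx in ([0, 1], [0, 1, 2], [1, 3, 4], list(range(5))):
            expected = _merit_by_hand(X, y, idx)
            got = cfs_merit([names[j] for j in idx], X, y, names)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_unknown_name_rejected(self, data):
        X, y, names = data
        with pytest.raises(InvalidInputError):
            cfs_merit(["zz"], X, y, names)

    def test_constant_column_contributes_zero(self, data):
        X, y, names = data
        X2 = X.copy()
        X2[:, 4] = 7.0
        assert cfs_merit(["e"], X2, y, names) == 0.0

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=25, deadline=None)
    def test_affine_rescaling_invariance(self, a, b):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.standard_normal(30) * 0.1
        names = ["x", "y", "z"]
        base = cfs_merit(names, X, y, names)
        X2 = X.copy()
        X2[:, 1] = a * X2[:, 1] + b
        assert cfs_merit(names, X2, a * y + b, names) == pytest.approx(base, rel=1e-9)


class TestGeneticSearch:
    def test_matches_exhaustive_on_small_problem(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((30, 8))
        y = X[:, :2] @ [1.0, 0.8] + rng.standard_normal(30) * 0.4
        names = [f"d{j}" for j in range(8)]
        cache = CorrelationCache(X, y, names)
        brute = max(
            cache.merit_idx(np.array(c))
            for k in range(1, 9)
            for c in combinations(range(8), k)
        )
        res = genetic_search(X, y, GASettings(seed=3), names=names)
        assert res.merit == pytest.approx(brute, abs=1e-12)

    def test_best_ever_merit_is_nondecreasing(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 12))
        y = X[:, 0] + rng.standard_normal(25)
        progress: list = []
        genetic_search(X, y, GASettings(seed=1, generations=40),
                       names=[f"d{j}" for j in range(12)], progress=progress)
        merits = [m for _, m in progress]
        assert all(b >= a for a, b in zip(merits, merits[1:]))

    def test_frozen_ga_cannot_move(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 6))
        y = X[:, 2] + rng.standard_normal(20) * 0.2
        names = sorted(f"d{j}" for j in range(6))
        ga = GASettings(seed=0, population=8, generations=15,
                        crossover_prob=0.0, mutation_prob=0.0)
        ind = np.zeros(6, dtype=bool)
        ind[[1, 4]] = True
        pop = np.tile(ind, (8, 1))
        res = genetic_search(X, y, ga, names=names, initial_population=pop)
        assert res.descriptor_names == frozenset({names[1], names[4]})

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 15))
        y = X[:, 3] + rng.standard_normal(20) * 0.3
        names = [f"d{j}" for j in range(15)]
        a = genetic_search(X, y, GASettings(seed=5), names=names)
        b = genetic_search(X, y, GASettings(seed=5), names=names)
        assert a == b

    def test_all_constant_table_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(InvalidInputError):
            genetic_search(X, np.arange(10.0), GASettings(seed=0), names=["a", "b", "c"])

    def test_subset_recovery_on_planted_library(self, small_library):
        table, _, eqs, truth = small_library
        y = np.array([e.wu_eq for e in eqs])
        res = genetic_search(table.values, y, GASettings(seed=1),
                             names=table.descriptor_names)
        assert len(res.descriptor_names & truth.signal_names) >= 2


class TestDecisionTree:
    def test_entropy_identities(self):
        assert entropy([5, 0]) == 0.0
        assert entropy([4, 4]) == pytest.approx(1.0)

    def test_perfect_separator_splits_at_midpoint(self):
        X = np.array([[1.0], [2.0], [4.0], [8.0], [9.0], [10.0]])
        labels = ["lo", "lo", "lo", "hi", "hi", "hi"]
        tree = build_tree(X, labels, names=["f"], settings=TreeSettings(min_leaf=2))
        root = tree.root
        assert root.descriptor == "f"
        assert root.threshold == pytest.approx((4.0 + 8.0) / 2)
        assert root.left.is_leaf and root.right.is_leaf
        assert root.left.label == "lo" and root.right.label == "hi"

    def test_root_matches_exhaustive_gain_ratio_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((8, 2))
        labels = np.array(["a", "a", "b", "b", "a", "b", "a", "b"])
        settings = TreeSettings(min_leaf=1, prune=False)
        tree = build_tree(X, labels, names=["f0", "f1"], settings=settings)

        def gain_ratio(col, thr):
            left = labels[X[:, col] <= thr]
            right = labels[X[:, col] > thr]
            def h(ls):
                _, c = np.unique(ls, return_counts=True)
                return entropy(c)
            gain = h(labels) - (len(left) * h(left) + len(right) * h(right)) / 8
            split_info = entropy([len(left), len(right)])
            return gain / split_info if split_info > 0 else -1.0

        best = max(
            (
                (gain_ratio(c, 0.5 * (v1 + v2)), c, 0.5 * (v1 + v2))
                for c in (0, 1)
                for v1, v2 in zip(sorted(X[:, c])[:-1], sorted(X[:, c])[1:])
                if v1 != v2
            ),
        )
        assert tree.root.descriptor == f"f{best[1]}"
        assert gain_ratio(int(tree.root.descriptor[1]), tree.root.threshold) == pytest.approx(best[0])

    def test_single_class_yields_single_leaf(self):
        X = np.arange(6.0)[:, None]
        tree = build_tree(X, ["same"] * 6, names=["f"])
        assert tree.root.is_leaf
        assert tree_descriptor_ranking(tree) == []

    def test_training_accuracy_at_least_majority_rate(self, small_library):
        table, _, eqs, _ = small_library
        y = np.array([e.wu_eq for e in eqs])
        cl = fit_em(y, K=3, seed=0)
        from polysorb.cluster import assign_class

        labels = [assign_class(cl, [v])[0] for v in y]
        X = table.values[:, :10]
        tree = build_tree(X, labels, names=list(table.descriptor_names[:10]))
        majority = max(labels.count(c) for c in set(labels)) / len(labels)
        assert tree.training_accuracy(X, labels) >= majority

    def test_breadth_first_ranking_order(self):
        # hand-built three-level tree: root 'main'; level two 'aux' (n=8)
        # and 'main' again (n=4, duplicate, must not repeat); level three
        # 'tail' under the larger branch
        from polysorb.selection import TreeModel, TreeNode

        leaf = lambda n, lab: TreeNode(n=n, counts={lab: n}, label=lab)
        lvl3 = TreeNode(n=4, counts={"b": 2, "c": 2}, label="b",
                        descriptor="tail", threshold=0.5,
                        left=leaf(2, "b"), right=leaf(2, "c"))
        lvl2_big = TreeNode(n=8, counts={"b": 4, "c": 4}, label="b",
                            descriptor="aux", threshold=1.0,
                            left=lvl3, right=leaf(4, "c"))
        lvl2_small = TreeNode(n=4, counts={"a": 2, "d": 2}, label="a",
                              descriptor="main", threshold=9.0,
                              left=leaf(2, "a"), right=leaf(2, "d"))
        root = TreeNode(n=12, counts={"a": 2, "b": 4, "c": 4, "d": 2},
                        label="b", descriptor="main", threshold=3.5,
                        left=lvl2_big, right=lvl2_small)
        tree = TreeModel(root, ("main", "aux", "tail"), TreeSettings())
        # level order; within level two, the larger node (n=8, 'aux') first;
        # 'main' already ranked at the root is not repeated
        assert tree_descriptor_ranking(tree) == ["main", "aux", "tail"]

    def test_leaf_only_tree_ranks_nothing(self):
        from polysorb.selection import TreeModel, TreeNode

        stump = TreeNode(n=5, counts={"a": 5}, label="a")
        assert tree_descriptor_ranking(TreeModel(stump, ("f",), TreeSettings())) == []


class TestRegressionTopDescriptor:
    def test_exact_column_wins(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        z = (X - X.mean(0)) / X.std(0)
        y = z[:, 2].copy()
        name, coefs = regression_top_descriptor(
            X, y, names=["a", "b", "c", "d"], return_coefs=True
        )
        assert name == "c"
        assert coefs["c"] == pytest.approx(1.0, abs=1e-8)
        for other in ("a", "b", "d"):
            assert abs(coefs[other]) < 1e-8

    def test_recovers_dominant_coefficient(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((100, 2))
        Z = (Z - Z.mean(0)) / Z.std(0)
        y = 3.0 * Z[:, 0] + 1.0 * Z[:, 1] + rng.normal(0, 0.01, 100)
        name, coefs = regression_top_descriptor(
            Z, y, names=["z1", "z2"], return_coefs=True
        )
        assert name == "z1"
        assert coefs["z1"] == pytest.approx(3.0, abs=0.01)
        assert coefs["z2"] == pytest.approx(1.0, abs=0.01)

    def test_collinear_columns_error_without_fallback(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(SingularDesignError):
            regression_top_descriptor(X, x, names=["a", "b"])
        # deterministic winner with the ridge fallback on
        name = regression_top_descriptor(X, x, names=["a", "b"], ridge_fallback=True)
        assert name in ("a", "b")

    def test_exclusion_list_is_respected(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 3))
        y = 2 * X[:, 0] + X[:, 1]
        name = regression_top_descriptor(X, y, names=["a", "b", "c"], exclude=["a"])
        assert name == "b"


class TestSelectDescriptors:
    @pytest.fixture(scope="class")
    def fitted_cluster(self, small_library):
        _, _, eqs, _ = small_library
        return fit_em(np.array([e.wu_eq for e in eqs]), K=3, seed=0)

    def test_n_final_one_returns_regression_descriptor(self, small_dataset, fitted_cluster):
        cfg = SelectionConfig(n_final=1, ga=GASettings(seed=2, generations=20))
        sel = select_descriptors(small_dataset, fitted_cluster, cfg)
        assert sel.final_descriptors == (sel.regression_descriptor,)

    def test_final_list_within_candidates(self, small_dataset, fitted_cluster):
        cfg = SelectionConfig(ga=GASettings(seed=2, generations=20))
        sel = select_descriptors(small_dataset, fitted_cluster, cfg)
        assert len(sel.final_descriptors) == 3
        assert len(set(sel.final_descriptors)) == 3
        assert set(sel.final_descriptors) <= sel.cfs_subset | {"time"}

    def test_all_points_target_includes_time(self, small_library):
        table, series, eqs, _ = small_library
        ds = ModelingDataset.from_series(table, series)
        pts = np.column_stack([ds.point_times, ds.point_wu])
        cl = fit_em(pts, K=3, seed=0)
        cfg = SelectionConfig(ga=GASettings(seed=3, generations=10))
        sel = select_descriptors(ds, cl, cfg)
        assert sel.included_time
        assert "time" in sel.final_descriptors

    def test_cascade_deterministic(self, small_dataset, fitted_cluster):
        cfg = SelectionConfig(ga=GASettings(seed=7, generations=15))
        a = select_descriptors(small_dataset, fitted_cluster, cfg)
        b = select_descriptors(small_dataset, fitted_cluster, cfg)
        assert a == b
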
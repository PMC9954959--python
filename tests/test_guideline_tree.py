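"""Gini splitting, best-first growth, prepruning, ranking, export."""

import numpy as np
import pytest

from thyrocad.guideline_tree import (
    GuidelineTree,
    Leaf,
    Node,
    best_split,
    classification_loss,
    export_dot,
    export_guideline,
    gini,
    grow_tree,
    predict_tree,
    rank_signs,
    top_signs,
)


@pytest.mark.parametrize(
    "counts, expected",
    [((10, 0), 0.0), ((5, 5), 0.5), ((3, 1), 0.375)],
)
def test_gini_closed_form(counts, expected):
    assert gini(counts) == pytest.approx(expected, abs=1e-12)


def test_gini_rejects_empty_node():
    with pytest.raises(ValueError):
        gini((0, 0))


def test_best_split_finds_the_pure_binary_cut():
    rng = np.random.default_rng(0)
    X = rng.integers(1, 4, size=(60, 5)).astype(float)
    X[:, 2] = rng.integers(1, 3, size=60)          # the "P4"-like sign
    y = (X[:, 2] == 2).astype(int)
    rec = best_split(X, y, range(5))
    assert rec.sign_index == 2
    assert rec.threshold == 1.5
    assert rec.impurity_decrease == pytest.approx(gini(np.bincount(y, minlength=2)))


def test_best_split_single_class_returns_none():
    X = np.arange(10, dtype=float).reshape(-1, 1)
    assert best_split(X, np.ones(10, dtype=int), [0]) is None


def test_best_split_tie_goes_to_lower_sign_index():
    rng = np.random.default_rng(1)
    col = rng.integers(1, 3, size=40).astype(float)
    X = np.column_stack([col, col])                # identical candidates
    y = (col == 2).astype(int)
    rec = best_split(X, y, [0, 1])
    assert rec.sign_index == 0


def brute_force_split(X, y, signs):
    """Independent exhaustive search over every sign and midpoint."""
    n = len(y)
    parent = gini([np.sum(y == 0), np.sum(y == 1)])
    best = None
    for j in signs:
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left, right = y[X[:, j] < thr], y[X[:, j] >= thr]
            child = (
                len(left) * gini([np.sum(left == 0), np.sum(left == 1)])
                + len(right) * gini([np.sum(right == 0), np.sum(right == 1)])
            ) / n
            dec = parent - child
            if dec > 1e-12 and (
                best is None
                or dec > best[2] + 1e-12
                or (abs(dec - best[2]) <= 1e-12 and (j, thr) < best[:2])
            ):
                best = (j, thr, dec)
    return best


def test_best_split_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(5, 31))
        d = int(rng.integers(1, 6))
        X = rng.integers(1, 6, size=(n, d)).astype(float)
        y = rng.integers(0, 2, size=n)
        expected = brute_force_split(X, y, range(d))
        got = best_split(X, y, range(d))
        if expected is None:
            assert got is None
        else:
            assert (got.sign_index, got.threshold) == expected[:2]
            assert got.impurity_decrease == pytest.approx(expected[2], abs=1e-12)


def test_root_split_agrees_with_reference_cart():
    """Depth-1 cross-check against scikit-learn's CART on tie-free data."""
    sklearn_tree = pytest.importorskip("sklearn.tree")
    rng = np.random.default_rng(3)
    X = rng.normal(size=(80, 4))                    # continuous: no ties
    y = (X[:, 1] + 0.3 * rng.normal(size=80) > 0).astype(int)
    ref = sklearn_tree.DecisionTreeClassifier(criterion="gini", max_depth=1,
                                              random_state=0).fit(X, y)
    rec = best_split(X, y, range(4))
    assert rec.sign_index == ref.tree_.feature[0]
    # sklearn stores thresholds in float32
    assert rec.threshold == pytest.approx(ref.tree_.threshold[0], rel=1e-6)


def test_pure_dataset_is_a_single_leaf():
    X = np.arange(12, dtype=float).reshape(-1, 2)
    tree = grow_tree(X, np.ones(6, dtype=int))
    assert isinstance(tree.root, Leaf)
    assert tree.n_splits == 0
    assert classification_loss(tree, X, np.ones(6, dtype=int)) == 0.0


def test_split_budget_is_respected(default_table):
    tree = grow_tree(default_table.X, default_table.labels, max_splits=7)
    assert tree.pruned and tree.n_splits <= 7


def test_unpruned_tree_terminates_only_at_unsplittable_leaves(default_table):
    tree = grow_tree(default_table.X, default_table.labels)
    X, y = default_table.X, default_table.labels

    def check(node, idx):
        if isinstance(node, Leaf):
            assert best_split(X[idx], y[idx], range(X.shape[1])) is None
            return
        go_left = X[idx, node.split.sign_index] < node.split.threshold
        check(node.left, idx[go_left])
        check(node.right, idx[~go_left])

    check(tree.root, np.arange(X.shape[0]))


def test_two_sign_interaction_is_recovered():
    """label = (sign0 high) AND (sign1 high): depth-2 tree on those signs."""
    rng = np.random.default_rng(11)
    X = rng.integers(1, 4, size=(200, 3)).astype(float)
    y = ((X[:, 0] >= 2) & (X[:, 1] >= 3)).astype(int)
    tree = grow_tree(X, y)
    used = set()

    def walk(node):
        if isinstance(node, Node):
            used.add(node.split.sign_index)
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    assert used == {0, 1}
    assert classification_loss(tree, X, y) == 0.0


def test_majority_leaf_loss_from_study_class_sizes(default_table):
    majority = GuidelineTree(root=Leaf(label=1, purity=284 / 398, n_samples=398),
                             n_splits=0, pruned=False)
    loss = classification_loss(majority, default_table.X, default_table.labels)
    assert loss == pytest.approx(114 / 398)


def test_pruning_never_lowers_resubstitution_loss(default_table):
    X, y = default_table.X, default_table.labels
    full = grow_tree(X, y)
    pruned = grow_tree(X, y, max_splits=7)
    assert classification_loss(full, X, y) <= classification_loss(pruned, X, y)


def test_deeper_budgets_never_lose_accuracy(default_table):
    X, y = default_table.X, default_table.labels
    losses = [classification_loss(grow_tree(X, y, max_splits=k), X, y)
              for k in (1, 3, 7, 15)]
    assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))


def test_single_informative_sign_dominates_ranking():
    rng = np.random.default_rng(5)
    X = rng.integers(1, 3, size=(100, 4)).astype(float)
    y = (X[:, 3] == 2).astype(int)
    ranking = rank_signs(X, y)
    assert ranking.entries[0][0] == 3
    assert ranking.entries[0][1] > 0
    assert all(imp == 0.0 for j, imp in ranking.entries if j != 3)


def test_random_labels_rank_far_below_informative_ones():
    rng = np.random.default_rng(6)
    X = rng.integers(1, 5, size=(150, 10)).astype(float)
    y_informative = (X[:, 0] >= 3).astype(int)
    y_random = rng.integers(0, 2, size=150)
    top_informative = rank_signs(X, y_informative).entries[0][1]
    top_random = rank_signs(X, y_random).entries[0][1]
    assert top_random < 0.25 * top_informative


def test_importances_conserve_total_weighted_decrease(default_table):
    X, y = default_table.X, default_table.labels
    ranking = rank_signs(X, y)
    total_importance = sum(imp for _, imp in ranking.entries)
    tree = grow_tree(X, y)

    def total(node):
        if isinstance(node, Leaf):
            return 0.0
        return (node.n_samples / X.shape[0] * node.split.impurity_decrease
                + total(node.left) + total(node.right))

    assert total_importance == pytest.approx(total(tree.root), rel=1e-9)
    assert all(imp >= 0 for _, imp in ranking.entries)
    assert len(top_signs(ranking, 13)) == 13


def test_single_leaf_guideline_is_one_line():
    tree = GuidelineTree(root=Leaf(label=0, purity=1.0, n_samples=10),
                         n_splits=0, pruned=False)
    text = export_guideline(tree, ["P1"])
    assert text.strip() == "-> benign (purity 1.00, n=10)"


def test_guideline_text_matches_expected_flowchart():
    X = np.array([[1, 1], [1, 2], [2, 1], [2, 2]] * 5, dtype=float)
    y = np.array([0, 0, 0, 1] * 5)
    tree = grow_tree(X, y)
    text = export_guideline(tree, ["P4", "P22"],
                            {"P4": (1, 2), "P22": (1, 2)})
    expected = (
        "if P4 in {1}:\n"
        "  -> benign (purity 1.00, n=10)\n"
        "if P4 in {2}:\n"
        "  if P22 in {1}:\n"
        "    -> benign (purity 1.00, n=5)\n"
        "  if P22 in {2}:\n"
        "    -> malignant (purity 1.00, n=5)\n"
    )
    assert text == expected


def test_dot_export_has_matching_node_and_edge_counts(default_table):
    tree = grow_tree(default_table.X, default_table.labels, max_splits=7)
    dot = export_dot(tree, [f"P{i}" for i in range(1, 28)])
    n_nodes = dot.count("[label=")
    n_edges = dot.count("->")
    # a binary tree with s splits has s internal + s+1 leaf nodes, 2s edges
    s = tree.n_splits
    assert n_nodes == (2 * s + 1) + 2 * s   # node declarations + edge labels
    assert n_edges == 2 * s
    assert dot.startswith("digraph") and dot.rstrip().endswith("}")
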
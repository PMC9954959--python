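"""CART-style Gini decision trees for sign ranking and CAD guidelines.

A binary classification tree over the coded sonographic signs serves three
purposes: ranking the 27 signs by total impurity decrease, building a
readable risk-stratification flowchart (the "guideline"), and prepruning
that flowchart to a small split budget (7 splits in the reference
guideline) so a physician can walk it at the bedside.

Sub-feature codes are treated as ordinal numerics with threshold splits —
a branch condition such as "P3 < 3.5" reads as "echogenicity code in
{1, 2, 3}".  Growth is best-first: the frontier node whose best split buys
the largest impurity decrease is always expanded next, so a tight split
budget is spent where it pays most.  Without a budget, growth continues
until every leaf is pure or no split has positive decrease.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplitRecord",
    "Leaf",
    "Node",
    "GuidelineTree",
    "SignRanking",
    "gini",
    "best_split",
    "grow_tree",
    "predict_tree",
    "classification_loss",
    "rank_signs",
    "top_signs",
    "export_guideline",
    "export_dot",
]


def gini(class_counts) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node's class counts."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("gini of an empty node is undefined")
    p = counts / total
    return float(1.0 - np.sum(p * p))


@dataclass(frozen=True)
class SplitRecord:
    """One decision: ``sign < threshold`` goes left, ``>=`` goes right."""

    sign_index: int
    threshold: float
    impurity_decrease: float


@dataclass(frozen=True)
class Leaf:
    label: int            # 0 benign, 1 malignant
    purity: float         # training fraction of the majority class
    n_samples: int


@dataclass(frozen=True)
class Node:
    split: SplitRecord
    left: "Node | Leaf"
    right: "Node | Leaf"
    n_samples: int = 0


@dataclass(frozen=True)
class GuidelineTree:
    root: Node | Leaf
    n_splits: int
    pruned: bool
    max_splits: int | None = None
    n_training: int = 0


@dataclass(frozen=True)
class SignRanking:
    """(sign_index, importance) pairs sorted by descending importance."""

    entries: tuple[tuple[int, float], ...]


def _node_counts(labels: np.ndarray) -> np.ndarray:
    return np.array([np.sum(labels == 0), np.sum(labels == 1)], dtype=float)


def best_split(
    data: np.ndarray, labels: np.ndarray, candidate_signs
) -> SplitRecord | None:
    """Exhaustive best threshold split over the candidate signs.

    Thresholds are midpoints between consecutive observed values of a sign;
    the winner maximizes parent impurity minus the sample-weighted mean
    child impurity.  Ties break toward the lowest sign index, then the
    lowest threshold.  Returns None when no split has positive decrease
    (including single-class nodes).
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = y.size
    if n < 2 or np.all(y == y[0]):
        return None
    parent = gini(_node_counts(y))
    n_pos = int(np.sum(y))

    best: SplitRecord | None = None
    for j in candidate_signs:
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        xs, ys = col[order], y[order]
        # cumulative positives left of each cut between consecutive rows
        cum_pos = np.cumsum(ys)
        boundary = np.flatnonzero(np.diff(xs) > 0)   # cut after these rows
        for b in boundary:
            n_left = b + 1
            pos_left = int(cum_pos[b])
            left_counts = (n_left - pos_left, pos_left)
            right_counts = (n - n_left - (n_pos - pos_left), n_pos - pos_left)
            child = (n_left * gini(left_counts)
                     + (n - n_left) * gini(right_counts)) / n
            dec = parent - child
            thr = (xs[b] + xs[b + 1]) / 2.0
            if dec > 1e-12 and (
                best is None
                or dec > best.impurity_decrease + 1e-12
                or (abs(dec - best.impurity_decrease) <= 1e-12
                    and (j, thr) < (best.sign_index, best.threshold))
            ):
                best = SplitRecord(sign_index=int(j), threshold=float(thr),
                                   impurity_decrease=float(dec))
    return best


def _make_leaf(labels: np.ndarray) -> Leaf:
    counts = _node_counts(labels)
    # tie in the majority vote goes to malignant: the conservative call
    label = 1 if counts[1] >= counts[0] else 0
    return Leaf(label=label, purity=float(counts[label] / counts.sum()),
                n_samples=int(counts.sum()))


def grow_tree(
    data: np.ndarray,
    labels: np.ndarray,
    max_splits: int | None = None,
    candidate_signs=None,
) -> GuidelineTree:
    """Grow a binary Gini tree, best-first, under an optional split budget.

    The frontier node whose best available split yields the largest
    impurity decrease is expanded first; growth stops at ``max_splits``
    splits (prepruning) or when no frontier node has a positive-decrease
    split.  Leaves carry the majority class (ties called malignant) and
    their training purity.
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] == 0:
        raise ValueError("cannot grow a tree on an empty table")
    if candidate_signs is None:
        candidate_signs = list(range(X.shape[1]))

    # mutable node slots so children can be attached as the frontier expands
    slots: dict[int, Node | Leaf] = {}
    parent_link: dict[int, tuple[int, str]] = {}
    counter = 0
    heap: list[tuple[float, int, int, np.ndarray]] = []

    def push(idx: np.ndarray, slot: int) -> None:
        nonlocal counter
        rec = best_split(X[idx], y[idx], candidate_signs)
        slots[slot] = _make_leaf(y[idx])   # stays a leaf if the budget runs out
        if rec is not None:
            heapq.heappush(heap, (-rec.impurity_decrease, counter, slot, idx, rec))
            counter += 1

    def attach(slot: int, node: Node | Leaf) -> None:
        slots[slot] = node

    next_slot = 0
    root_slot = next_slot
    next_slot += 1
    push(np.arange(X.shape[0]), root_slot)

    n_splits = 0
    while heap and (max_splits is None or n_splits < max_splits):
        _, _, slot, idx, rec = heapq.heappop(heap)
        go_left = X[idx, rec.sign_index] < rec.threshold
        left_slot, right_slot = next_slot, next_slot + 1
        next_slot += 2
        push(idx[go_left], left_slot)
        push(idx[~go_left], right_slot)
        parent_link[left_slot] = (slot, "left")
        parent_link[right_slot] = (slot, "right")
        attach(slot, Node(split=rec, left=left_slot, right=right_slot,
                          n_samples=int(idx.size)))
        n_splits += 1

    def materialize(slot: int) -> Node | Leaf:
        node = slots[slot]
        if isinstance(node, Node):
            return Node(split=node.split,
                        left=materialize(node.left),
                        right=materialize(node.right),
                        n_samples=node.n_samples)
        return node

    return GuidelineTree(
        root=materialize(root_slot),
        n_splits=n_splits,
        pruned=max_splits is not None,
        max_splits=max_splits,
        n_training=int(X.shape[0]),
    )


def predict_tree(tree: GuidelineTree, data: np.ndarray) -> np.ndarray:
    """0/1 predictions by walking each row from the root to a leaf."""
    X = np.atleast_2d(np.asarray(data, dtype=float))
    out = np.empty(X.shape[0], dtype=int)
    for i, row in enumerate(X):
        node = tree.root
        while isinstance(node, Node):
            node = (node.left if row[node.split.sign_index] < node.split.threshold
                    else node.right)
        out[i] = node.label
    return out


def classification_loss(tree: GuidelineTree, data, labels) -> float:
    """Fraction of misclassified samples (resubstitution error on the
    training table)."""
    y = np.asarray(labels, dtype=int)
    if y.size == 0:
        raise ValueError("classification loss of an empty table is undefined")
    return float(np.mean(predict_tree(tree, data) != y))


def rank_signs(data: np.ndarray, labels: np.ndarray) -> SignRanking:
    """Importance of every sign from the fully grown (unpruned) tree.

    A sign's importance is the total impurity decrease over all internal
    nodes that split on it, each weighted by the node's share of the
    training samples.  Signs the tree never uses score 0.
    """
    X = np.asarray(data, dtype=float)
    tree = grow_tree(X, labels)
    imp = np.zeros(X.shape[1])
    n_root = tree.n_training

    def walk(node) -> None:
        if isinstance(node, Node):
            imp[node.split.sign_index] += (
                node.n_samples / n_root * node.split.impurity_decrease
            )
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    order = sorted(range(X.shape[1]), key=lambda j: (-imp[j], j))
    return SignRanking(entries=tuple((j, float(imp[j])) for j in order))


def top_signs(ranking: SignRanking, k: int) -> list[int]:
    """Indices of the k highest-importance signs (the study reduces
    27 signs to the top 13 this way)."""
    return [j for j, _ in ranking.entries[:k]]


# ---------------------------------------------------------------------------
# guideline export


def _branch_label(split: SplitRecord, side: str, sign_names, code_sets) -> str:
    name = sign_names[split.sign_index]
    codes = code_sets.get(name) if code_sets else None
    if codes:
        chosen = [c for c in codes if
                  (c < split.threshold) == (side == "left")]
        return f"{name} in {{{', '.join(str(c) for c in chosen)}}}"
    op = "<" if side == "left" else ">="
    return f"{name} {op} {split.threshold:g}"


def export_guideline(
    tree: GuidelineTree, sign_names, code_sets: dict | None = None
) -> str:
    """Indented text flowchart of the tree.

    ``sign_names`` maps column indices to sign notations (P1..P27);
    ``code_sets`` optionally maps a notation to its valid sub-feature
    codes so ordinal branches are phrased as code sets rather than
    thresholds.
    """
    lines: list[str] = []

    def walk(node, depth: int, prefix: str) -> None:
        pad = "  " * depth
        if isinstance(node, Leaf):
            lines.append(
                f"{pad}{prefix}-> {('benign', 'malignant')[node.label]} "
                f"(purity {node.purity:.2f}, n={node.n_samples})"
            )
            return
        for side, child in (("left", node.left), ("right", node.right)):
            cond = _branch_label(node.split, side, sign_names, code_sets)
            lines.append(f"{pad}{prefix}if {cond}:")
            walk(child, depth + 1, "")

    walk(tree.root, 0, "")
    return "\n".join(lines) + "\n"


def export_dot(
    tree: GuidelineTree, sign_names, code_sets: dict | None = None
) -> str:
    """Graphviz DOT rendering of the tree."""
    lines = ["digraph guideline {", '  node [shape=box];']
    counter = [0]

    def walk(node) -> int:
        nid = counter[0]
        counter[0] += 1
        if isinstance(node, Leaf):
            lines.append(
                f'  n{nid} [label="{("benign", "malignant")[node.label]}\\n'
                f'purity {node.purity:.2f}", shape=ellipse];'
            )
            return nid
        name = sign_names[node.split.sign_index]
        lines.append(f'  n{nid} [label="{name}"];')
        for side, child in (("left", node.left), ("right", node.right)):
            cid = walk(child)
            label = _branch_label(node.split, side, sign_names, code_sets)
            label = label.replace(f"{name} ", "")
            lines.append(f'  n{nid} -> n{cid} [label="{label}"];')
        return nid

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines) + "\n"
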
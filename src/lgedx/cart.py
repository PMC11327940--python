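"""Classification-tree learner (CART) written from first principles.

Greedy recursive binary partitioning with Gini impurity, weakest-link
cost-complexity pruning, and stratified k-fold cross-validated subtree
selection.  Learned trees serialize to the same JSON schema as the fixed
published tree and are classified by :func:`lgedx.classifiers.tree_classify`.

Conventions (all deterministic):

* split candidates are the midpoints between consecutive distinct observed
  values of each feature (boolean features therefore split at 0.5);
* the split maximizing the Gini decrease wins; exact ties go to the
  lexicographically lowest feature name, then the lowest threshold;
* leaves take the majority class, ties broken by diagnosis declaration
  order; no class weighting (empirical priors);
* stopping: a node is not split below ``min_node_size`` samples, beyond
  ``max_depth``, or when no candidate decreases impurity by at least
  ``min_impurity_decrease``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .classifiers import DecisionTree, TreeNode, tree_classify
from .segments import FEATURE_NAMES, Diagnosis, FeatureVector

__all__ = [
    "StoppingConfig",
    "SplitCandidate",
    "PrunedTreeEntry",
    "PrunedTreeSequence",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "prune_path",
    "prune_and_select",
    "tree_error",
    "features_matrix",
    "labels_codes",
]

DIAGNOSIS_ORDER: tuple[Diagnosis, ...] = tuple(Diagnosis)
_CODE = {d: i for i, d in enumerate(DIAGNOSIS_ORDER)}

#: Default CART predictor set: the ventricular LGE parameters (extent and
#: distribution).  The extra-ventricular flag is available to callers who
#: pass ``feature_names`` explicitly but is not a tree predictor by default.
CART_FEATURES: tuple[str, ...] = tuple(n for n in FEATURE_NAMES if n != "any_misc")


def features_matrix(
    features: Sequence[FeatureVector], feature_names: Sequence[str] = CART_FEATURES
) -> np.ndarray:
    """Stack feature vectors into an (n, p) float matrix."""
    return np.array([[fv[name] for name in feature_names] for fv in features], dtype=float)


def labels_codes(labels: Sequence[Diagnosis]) -> np.ndarray:
    return np.array([_CODE[d] for d in labels], dtype=np.int64)


def gini_impurity(label_counts: dict[Diagnosis, int]) -> float:
    """Gini impurity 1 - sum p_k^2 of a node's class distribution."""
    total = sum(label_counts.values())
    if total < 1:
        raise ValueError("need at least one sample")
    if any(c < 0 for c in label_counts.values()):
        raise ValueError("counts must be non-negative")
    return 1.0 - sum((c / total) ** 2 for c in label_counts.values())


@dataclass(frozen=True)
class SplitCandidate:
    feature: str
    threshold: float
    impurity_decrease: float


@dataclass(frozen=True)
class StoppingConfig:
    min_node_size: int = 5
    min_impurity_decrease: float = 1e-9
    max_depth: int = 6


def _gini_from_sq(sum_sq: float, n: int) -> float:
    return 1.0 - sum_sq / (n * n)


def _best_split_arrays(
    X: np.ndarray, y: np.ndarray, n_classes: int, feature_names: Sequence[str]
) -> Optional[SplitCandidate]:
    """Exhaustive search over features x midpoint thresholds, vectorized.

    The Gini decrease is computed from integer class counts via
    ``decrease = (S_l/n_l + S_r/n_r - S/n) / n`` with S the sum of squared
    counts, which makes exact ties exact in floating point as well.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes).astype(np.int64)
    parent_sq = float(parent_counts @ parent_counts)
    best: Optional[tuple[float, str, float]] = None  # (decrease, name, threshold)
    onehot = np.zeros((n, n_classes), dtype=np.int64)
    onehot[np.arange(n), y] = 1
    for j in range(X.shape[1]):
        xs = X[:, j]
        order = np.argsort(xs, kind="stable")
        xs_sorted = xs[order]
        boundaries = np.nonzero(xs_sorted[:-1] != xs_sorted[1:])[0]
        if boundaries.size == 0:
            continue
        cum = np.cumsum(onehot[order], axis=0)
        left = cum[boundaries]  # class counts strictly below each threshold
        n_left = boundaries + 1
        n_right = n - n_left
        sq_left = np.einsum("ij,ij->i", left, left).astype(float)
        right = parent_counts[None, :] - left
        sq_right = np.einsum("ij,ij->i", right, right).astype(float)
        decrease = (sq_left / n_left + sq_right / n_right - parent_sq / n) / n
        thresholds = (xs_sorted[boundaries] + xs_sorted[boundaries + 1]) / 2.0
        name = feature_names[j]
        for dec, thr in zip(decrease, thresholds):
            key = (dec, name, float(thr))
            if best is None or dec > best[0] or (
                dec == best[0] and (name, float(thr)) < (best[1], best[2])
            ):
                best = key
    if best is None or best[0] <= 0.0:
        return None
    return SplitCandidate(feature=best[1], threshold=best[2], impurity_decrease=best[0])


def best_split(
    features: Sequence[FeatureVector],
    labels: Sequence[Diagnosis],
    feature_names: Sequence[str] = CART_FEATURES,
) -> Optional[SplitCandidate]:
    """The impurity-maximizing binary split of a node, or None if no split
    decreases impurity (e.g. the node is pure)."""
    if len(features) < 2:
        return None
    return _best_split_arrays(
        features_matrix(features, feature_names),
        labels_codes(labels),
        len(DIAGNOSIS_ORDER),
        feature_names,
    )


# ---------------------------------------------------------------------------
# Growing
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    """Mutable working node used during growth and pruning."""

    counts: np.ndarray
    feature_idx: int = -1
    threshold: float = 0.0
    left: Optional["_Node"] = None  # predicate false (value < threshold)
    right: Optional["_Node"] = None  # predicate true

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def prediction(self) -> int:
        return int(np.argmax(self.counts))  # argmax breaks ties to the lowest code

    @property
    def misclassified(self) -> int:
        return self.n - int(self.counts.max())

    def copy(self) -> "_Node":
        return _Node(
            counts=self.counts.copy(),
            feature_idx=self.feature_idx,
            threshold=self.threshold,
            left=self.left.copy() if self.left else None,
            right=self.right.copy() if self.right else None,
        )


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    stopping: StoppingConfig,
    depth: int,
    feature_names: Sequence[str],
) -> _Node:
    counts = np.bincount(y, minlength=len(DIAGNOSIS_ORDER)).astype(np.int64)
    node = _Node(counts=counts)
    n = len(y)
    if n < stopping.min_node_size or depth >= stopping.max_depth or counts.max() == n:
        return node
    cand = _best_split_arrays(X, y, len(DIAGNOSIS_ORDER), feature_names)
    if cand is None or cand.impurity_decrease < stopping.min_impurity_decrease:
        return node
    j = list(feature_names).index(cand.feature)
    mask = X[:, j] >= cand.threshold
    node.feature_idx = j
    node.threshold = cand.threshold
    node.right = _grow(X[mask], y[mask], stopping, depth + 1, feature_names)
    node.left = _grow(X[~mask], y[~mask], stopping, depth + 1, feature_names)
    return node


def _to_decision_tree(
    node: _Node, provenance: str, metadata: dict, feature_names: Sequence[str]
) -> DecisionTree:
    counter = [0]

    def convert(n: _Node) -> TreeNode:
        nid = f"n{counter[0]}"
        counter[0] += 1
        if n.is_leaf:
            return TreeNode(node_id=nid, leaf_label=DIAGNOSIS_ORDER[n.prediction])
        return TreeNode(
            node_id=nid,
            feature=feature_names[n.feature_idx],
            op="ge",
            threshold=float(n.threshold),
            if_false=convert(n.left),
            if_true=convert(n.right),
        )

    return DecisionTree(root=convert(node), provenance=provenance, metadata=metadata)


def grow_tree(
    features: Sequence[FeatureVector],
    labels: Sequence[Diagnosis],
    stopping: StoppingConfig = StoppingConfig(),
    feature_names: Sequence[str] = CART_FEATURES,
) -> DecisionTree:
    """Grow a tree by recursive partitioning until the stopping rules bind."""
    if len(features) == 0:
        raise ValueError("training set must be non-empty")
    root = _grow(
        features_matrix(features, feature_names), labels_codes(labels), stopping, 0,
        feature_names,
    )
    return _to_decision_tree(
        root, "learned", {"stopping": vars(stopping)}, feature_names
    )


# ---------------------------------------------------------------------------
# Cost-complexity pruning
# ---------------------------------------------------------------------------

def _subtree_stats(node: _Node) -> tuple[int, int]:
    """(misclassified over subtree leaves, number of leaves)."""
    if node.is_leaf:
        return node.misclassified, 1
    ml, ll = _subtree_stats(node.left)
    mr, lr = _subtree_stats(node.right)
    return ml + mr, ll + lr


def _weakest_links(node: _Node, total_n: int) -> list[tuple[float, _Node]]:
    """g(t) = (R(t) - R(T_t)) / (|leaves| - 1) for every internal node t,
    with R measured as misclassification count / total training size."""
    out: list[tuple[float, _Node]] = []

    def walk(n: _Node) -> None:
        if n.is_leaf:
            return
        miss_sub, leaves = _subtree_stats(n)
        g = (n.misclassified - miss_sub) / (total_n * (leaves - 1))
        out.append((g, n))
        walk(n.left)
        walk(n.right)

    walk(node)
    return out


def _collapse(node: _Node) -> None:
    node.left = None
    node.right = None
    node.feature_idx = -1


def _prune_path_nodes(root: _Node, total_n: int) -> list[tuple[float, _Node]]:
    """Weakest-link pruning path [(alpha, tree)], alphas strictly increasing,
    starting at alpha=0 with the full tree; trees are nested snapshots."""
    work = root.copy()
    path = [(0.0, work.copy())]
    while not work.is_leaf:
        links = _weakest_links(work, total_n)
        g_min = min(g for g, _ in links)
        for g, node in links:
            if g <= g_min + 1e-12 and not node.is_leaf:
                _collapse(node)
        alpha = max(g_min, 0.0)
        if alpha <= path[-1][0] + 1e-15:
            # same penalty: keep only the minimal optimal subtree
            path[-1] = (path[-1][0], work.copy())
        else:
            path.append((alpha, work.copy()))
    return path


def _prune_at(root: _Node, alpha: float, total_n: int) -> _Node:
    """Smallest optimal subtree for penalty ``alpha`` (bottom-up DP)."""
    work = root.copy()

    def walk(n: _Node) -> float:  # returns subtree cost R + alpha * leaves
        leaf_cost = n.misclassified / total_n + alpha
        if n.is_leaf:
            return leaf_cost
        sub_cost = walk(n.left) + walk(n.right)
        if leaf_cost <= sub_cost + 1e-12:
            _collapse(n)
            return leaf_cost
        return sub_cost

    walk(work)
    return work


def _predict_codes(node: _Node, X: np.ndarray) -> np.ndarray:
    out = np.empty(len(X), dtype=np.int64)
    for i, row in enumerate(X):
        n = node
        while not n.is_leaf:
            n = n.right if row[n.feature_idx] >= n.threshold else n.left
        out[i] = n.prediction
    return out


@dataclass(frozen=True)
class PrunedTreeEntry:
    tree: DecisionTree
    complexity_parameter: float
    cv_error: float
    cv_se: float
    n_leaves: int


@dataclass(frozen=True)
class PrunedTreeSequence:
    entries: tuple[PrunedTreeEntry, ...]
    selected_index: int

    @property
    def selected(self) -> DecisionTree:
        return self.entries[self.selected_index].tree


def prune_path(
    features: Sequence[FeatureVector],
    labels: Sequence[Diagnosis],
    stopping: StoppingConfig = StoppingConfig(),
    feature_names: Sequence[str] = CART_FEATURES,
) -> list[tuple[float, DecisionTree]]:
    """The nested cost-complexity path of the fully grown tree, as
    (alpha, tree) pairs with strictly increasing alpha."""
    X = features_matrix(features, feature_names)
    y = labels_codes(labels)
    root = _grow(X, y, stopping, 0, feature_names)
    path = _prune_path_nodes(root, len(y))
    return [
        (alpha, _to_decision_tree(n, "learned", {"alpha": alpha}, feature_names))
        for alpha, n in path
    ]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment per sample, stratified by label."""
    assignment = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def prune_and_select(
    features: Sequence[FeatureVector],
    labels: Sequence[Diagnosis],
    k: int = 10,
    seed: int = 0,
    stopping: StoppingConfig = StoppingConfig(),
    one_se_rule: bool = False,
    feature_names: Sequence[str] = CART_FEATURES,
) -> PrunedTreeSequence:
    """Cost-complexity path + k-fold cross-validated subtree selection.

    For each candidate alpha (geometric means of consecutive path alphas),
    a tree is grown on each training fold, pruned at that alpha, and scored
    on the held-out fold; the alpha with the lowest pooled CV
    misclassification error is selected (ties to the smaller tree).  With
    ``one_se_rule`` the smallest tree within one standard error of the
    minimum is chosen instead.
    """
    n = len(features)
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    X = features_matrix(features, feature_names)
    y = labels_codes(labels)
    root = _grow(X, y, stopping, 0, feature_names)
    path = _prune_path_nodes(root, n)
    alphas = [a for a, _ in path]
    # candidate penalties representative of each path interval
    candidates = []
    for i, a in enumerate(alphas):
        if i + 1 < len(alphas):
            nxt = alphas[i + 1]
            candidates.append(math.sqrt(a * nxt) if a > 0 else (a + nxt) / 2.0)
        else:
            candidates.append(a if a > 0 else 0.0)

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    errors = np.zeros((len(candidates), n), dtype=float)  # per-sample 0/1 loss
    for f in range(k):
        test = folds == f
        fold_root = _grow(X[~test], y[~test], stopping, 0, feature_names)
        for ci, alpha in enumerate(candidates):
            pruned = _prune_at(fold_root, alpha, int((~test).sum()))
            pred = _predict_codes(pruned, X[test])
            errors[ci, test] = pred != y[test]
    cv_err = errors.mean(axis=1)
    cv_se = errors.std(axis=1, ddof=1) / math.sqrt(n)

    best_i = 0
    for i in range(1, len(candidates)):
        if cv_err[i] < cv_err[best_i] - 1e-12:
            best_i = i
        elif abs(cv_err[i] - cv_err[best_i]) <= 1e-12:
            best_i = i  # equal error: prefer the smaller (later, more pruned) tree
    if one_se_rule:
        limit = cv_err[best_i] + cv_se[best_i]
        for i in range(len(candidates) - 1, -1, -1):
            if cv_err[i] <= limit + 1e-12:
                best_i = i
                break

    entries = []
    for (alpha, node), err, se in zip(path, cv_err, cv_se):
        tree = _to_decision_tree(node, "learned", {"alpha": alpha}, feature_names)
        miss, leaves = _subtree_stats(node)
        entries.append(PrunedTreeEntry(tree, alpha, float(err), float(se), leaves))
    return PrunedTreeSequence(entries=tuple(entries), selected_index=best_i)


def tree_error(
    tree: DecisionTree, features: Sequence[FeatureVector], labels: Sequence[Diagnosis]
) -> float:
    """Misclassification fraction of a tree on a labelled set."""
    if len(features) == 0:
        raise ValueError("need at least one sample")
    wrong = sum(
        1 for fv, lab in zip(features, labels) if tree_classify(tree, fv) is not lab
    )
    return wrong / len(features)
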
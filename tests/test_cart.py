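"""CART learner: impurity, split search vs brute force, growth, pruning, CV."""

import numpy as np
import pytest

from lgedx.cart import (
    CART_FEATURES,
    DIAGNOSIS_ORDER,
    StoppingConfig,
    best_split,
    features_matrix,
    gini_impurity,
    grow_tree,
    labels_codes,
    prune_and_select,
    prune_path,
    tree_error,
)
from lgedx.classifiers import tree_classify, tree_from_json, tree_to_json
from lgedx.segments import Diagnosis, extract_features
from lgedx.synthetic import default_prevalence_spec, generate_cohort

from conftest import make_fv


def random_node(rng, n, features=("a", "b", "c", "d")):
    """A random small node: integer features in 0-7, labels over 5 classes."""
    X = rng.integers(0, 8, size=(n, len(features))).astype(float)
    y = rng.integers(0, 5, size=n)
    return X, y


def brute_force_best(X, y, names):
    """Naive enumeration oracle over every (feature, midpoint threshold)."""
    n = len(y)
    parent = np.bincount(y, minlength=5)
    parent_sq = float(parent @ parent)
    best = None
    for j, name in enumerate(names):
        values = sorted(set(X[:, j]))
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2.0
            right = X[:, j] >= thr
            cr = np.bincount(y[right], minlength=5)
            cl = parent - cr
            nl, nr = int(cl.sum()), int(cr.sum())
            dec = (float(cl @ cl) / nl + float(cr @ cr) / nr - parent_sq / n) / n
            key = (dec, name, thr)
            if best is None or dec > best[0] or (
                dec == best[0] and (name, thr) < (best[1], best[2])
            ):
                best = key
    if best is None or best[0] <= 0:
        return None
    return best


class TestGini:
    def test_pure_node_is_zero(self):
        assert gini_impurity({Diagnosis.ARVC: 10}) == 0.0

    def test_even_two_class_split_is_half(self):
        assert gini_impurity({Diagnosis.ARVC: 5, Diagnosis.DCM: 5}) == 0.5

    def test_study_root_node_distribution(self):
        counts = dict(zip(DIAGNOSIS_ORDER, (55, 25, 13, 20, 19)))
        expected = 1 - sum((c / 132) ** 2 for c in counts.values())
        assert gini_impurity(counts) == pytest.approx(expected)
        assert gini_impurity(counts) == pytest.approx(0.737144, abs=1e-6)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity({})


class TestBestSplit:
    def test_pure_node_has_no_split(self):
        fvs = [make_fv(lv_segment_count=i, any_lv=i > 0) for i in range(6)]
        labels = [Diagnosis.ARVC] * 6
        assert best_split(fvs, labels) is None

    def test_perfect_binary_separator_takes_full_parent_gini(self):
        fvs = [make_fv(anteroseptal_lv=(i < 5)) for i in range(10)]
        labels = [Diagnosis.AMYLOIDOSIS] * 5 + [Diagnosis.ARVC] * 5
        cand = best_split(fvs, labels)
        assert cand.feature == "anteroseptal_lv" and cand.threshold == 0.5
        assert cand.impurity_decrease == pytest.approx(0.5)

    def test_matches_brute_force_on_random_nodes(self):
        """Vectorized search == naive enumeration, including tie-breaks."""
        from lgedx.cart import _best_split_arrays

        rng = np.random.default_rng(2024)
        names = ("a", "b", "c", "d")
        for _ in range(300):
            n = int(rng.integers(2, 31))
            X, y = random_node(rng, n)
            got = _best_split_arrays(X, y, 5, names)
            want = brute_force_best(X, y, names)
            if want is None:
                assert got is None
            else:
                assert (got.impurity_decrease, got.feature, got.threshold) == want


class TestGrowTree:
    def test_pure_training_set_is_single_leaf(self):
        fvs = [make_fv(rv_segment_count=i % 3, any_rv=i % 3 > 0) for i in range(10)]
        tree = grow_tree(fvs, [Diagnosis.SARCOIDOSIS] * 10)
        assert tree.root.is_leaf and tree.root.leaf_label is Diagnosis.SARCOIDOSIS

    def test_separable_toy_set_zero_training_error_depth_one(self):
        fvs = [make_fv(lv_midmyo_count=i, lv_segment_count=i, any_lv=i > 0) for i in range(10)]
        labels = [Diagnosis.ARVC if i < 5 else Diagnosis.DCM for i in range(10)]
        tree = grow_tree(fvs, labels)
        assert tree.n_leaves() == 2
        assert tree_error(tree, fvs, labels) == 0.0

    def test_training_error_non_increasing_in_depth(self):
        coh = generate_cohort(default_prevalence_spec().scaled(60), seed=5)
        fvs = [extract_features(p) for p in coh]
        labels = [p.diagnosis for p in coh]
        errs = [
            tree_error(
                grow_tree(fvs, labels, StoppingConfig(max_depth=d, min_node_size=2)),
                fvs,
                labels,
            )
            for d in range(0, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_learned_tree_round_trips_through_json(self):
        coh = generate_cohort(default_prevalence_spec().scaled(40), seed=8)
        fvs = [extract_features(p) for p in coh]
        labels = [p.diagnosis for p in coh]
        tree = grow_tree(fvs, labels)
        text = tree_to_json(tree)
        again = tree_from_json(text)
        assert tree_to_json(again) == text
        for fv in fvs:  # identical routing
            assert tree_classify(tree, fv) is tree_classify(again, fv)


def _is_pruned_subtree(small, big):
    """True iff `small` equals `big` with some internal nodes collapsed."""
    if small.is_leaf:
        return True
    if big.is_leaf:
        return False
    if (small.feature, small.threshold) != (big.feature, big.threshold):
        return False
    return _is_pruned_subtree(small.if_false, big.if_false) and _is_pruned_subtree(
        small.if_true, big.if_true
    )


@pytest.fixture(scope="module")
def noisy_cohort():
    coh = generate_cohort(default_prevalence_spec().scaled(60), seed=13)
    fvs = [extract_features(p) for p in coh]
    labels = [p.diagnosis for p in coh]
    # 30% label noise forces pruning to act
    rng = np.random.default_rng(99)
    noisy = [
        DIAGNOSIS_ORDER[rng.integers(0, 5)] if rng.random() < 0.3 else lab
        for lab in labels
    ]
    return fvs, noisy


class TestPruning:
    def test_single_leaf_tree_path_is_trivial(self):
        fvs = [make_fv() for _ in range(8)]
        labels = [Diagnosis.ARVC] * 8
        seq = prune_and_select(fvs, labels, k=2, seed=0)
        assert len(seq.entries) == 1
        assert seq.selected.root.is_leaf

    def test_path_alphas_strictly_increase_and_leaves_decrease(self, noisy_cohort):
        fvs, labels = noisy_cohort
        path = prune_path(fvs, labels)
        alphas = [a for a, _ in path]
        leaves = [t.n_leaves() for _, t in path]
        assert all(a < b for a, b in zip(alphas, alphas[1:]))
        assert all(a >= b for a, b in zip(leaves, leaves[1:]))
        assert leaves[-1] == 1

    def test_path_trees_are_nested(self, noisy_cohort):
        fvs, labels = noisy_cohort
        path = prune_path(fvs, labels)
        for (_, smaller), (_, bigger) in zip(path[1:], path):
            assert _is_pruned_subtree(smaller.root, bigger.root)

    def test_noiseless_separable_data_selects_zero_cv_error(self):
        fvs = [make_fv(lv_segment_count=i % 10, any_lv=i % 10 > 0) for i in range(80)]
        labels = [Diagnosis.ARVC if i % 10 < 5 else Diagnosis.DCM for i in range(80)]
        seq = prune_and_select(fvs, labels, k=10, seed=3)
        assert seq.entries[seq.selected_index].cv_error == 0.0

    def test_label_noise_shrinks_the_selected_tree(self, noisy_cohort):
        fvs, labels = noisy_cohort
        seq = prune_and_select(fvs, labels, k=10, seed=7)
        full_leaves = seq.entries[0].n_leaves
        assert seq.entries[seq.selected_index].n_leaves < full_leaves

    def test_cv_errors_reproducible_for_fixed_seed(self, noisy_cohort):
        fvs, labels = noisy_cohort
        a = prune_and_select(fvs, labels, k=10, seed=21)
        b = prune_and_select(fvs, labels, k=10, seed=21)
        assert [e.cv_error for e in a.entries] == [e.cv_error for e in b.entries]
        assert a.selected_index == b.selected_index

    def test_k_out_of_range_rejected(self):
        fvs = [make_fv() for _ in range(4)]
        labels = [Diagnosis.ARVC] * 4
        with pytest.raises(ValueError):
            prune_and_select(fvs, labels, k=5, seed=0)


class TestTreeError:
    def test_stump_error_is_minority_fraction(self):
        fvs = [make_fv() for _ in range(10)]
        labels = [Diagnosis.ARVC] * 6 + [Diagnosis.DCM] * 4
        tree = grow_tree(fvs, labels)  # no split possible -> majority leaf
        assert tree_error(tree, fvs, labels) == pytest.approx(0.4)

    def test_training_error_close_to_sklearn_reference(self):
        """External-oracle smoke test on one fixed synthetic cohort."""
        from sklearn.tree import DecisionTreeClassifier

        coh = generate_cohort(default_prevalence_spec().scaled(80), seed=17)
        fvs = [extract_features(p) for p in coh]
        labels = [p.diagnosis for p in coh]
        mine = grow_tree(fvs, labels, StoppingConfig(min_node_size=5, max_depth=6))
        X = features_matrix(fvs, CART_FEATURES)
        y = labels_codes(labels)
        ref = DecisionTreeClassifier(
            criterion="gini", max_depth=6, min_samples_split=5, random_state=0
        ).fit(X, y)
        ref_err = float((ref.predict(X) != y).mean())
        assert tree_error(mine, fvs, labels) == pytest.approx(ref_err, abs=0.02)
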
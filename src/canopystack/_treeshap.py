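"""Exact path-dependent SHAP values for scikit-learn decision-tree ensembles.

Implements the polynomial-time tree traversal that tracks, for each unique
feature on the current path, the fraction of subsets flowing down (one/zero
fractions) and the permutation weights, yielding exact Shapley values under
the tree's own cover-weighted conditional expectation. Satisfies local
accuracy: ``phi.sum() + expected_value == prediction`` for every row.
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "expected_value"]


def _extend(pd, pz, po, pw, unique_depth, zero_fraction, one_fraction, feature_index):
    pd[unique_depth] = feature_index
    pz[unique_depth] = zero_fraction
    po[unique_depth] = one_fraction
    pw[unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[i + 1] += one_fraction * pw[i] * (i + 1) / (unique_depth + 1)
        pw[i] = zero_fraction * pw[i] * (unique_depth - i) / (unique_depth + 1)


def _unwind(pd, pz, po, pw, unique_depth, path_index):
    one_fraction = po[path_index]
    zero_fraction = pz[path_index]
    next_one_portion = pw[unique_depth]
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[i]
            pw[i] = next_one_portion * (unique_depth + 1) / ((i + 1) * one_fraction)
            next_one_portion = tmp - pw[i] * zero_fraction * (unique_depth - i) / (
                unique_depth + 1
            )
        else:
            pw[i] = pw[i] * (unique_depth + 1) / (zero_fraction * (unique_depth - i))
    for i in range(path_index, unique_depth):
        pd[i] = pd[i + 1]
        pz[i] = pz[i + 1]
        po[i] = po[i + 1]


def _unwound_sum(pz, po, pw, unique_depth, path_index):
    one_fraction = po[path_index]
    zero_fraction = pz[path_index]
    next_one_portion = pw[unique_depth]
    total = 0.0
    for i in range(unique_depth - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one_portion * (unique_depth + 1) / ((i + 1) * one_fraction)
            total += tmp
            next_one_portion = pw[i] - tmp * zero_fraction * (unique_depth - i) / (
                unique_depth + 1
            )
        else:
            total += pw[i] / (zero_fraction * (unique_depth - i) / (unique_depth + 1))
    return total


def _shap_single_tree(tree, x, phi, scale=1.0):
    left = tree.children_left
    right = tree.children_right
    feature = tree.feature
    threshold = tree.threshold
    cover = tree.weighted_n_node_samples
    values = tree.value.reshape(-1)

    max_len = int(tree.max_depth) + 2

    def recurse(node, pd, pz, po, pw, unique_depth, pzf, pof, pif):
        pd = pd.copy()
        pz = pz.copy()
        po = po.copy()
        pw = pw.copy()
        _extend(pd, pz, po, pw, unique_depth, pzf, pof, pif)
        if left[node] < 0:  # leaf
            leaf_val = values[node] * scale
            for i in range(1, unique_depth + 1):
                w = _unwound_sum(pz, po, pw, unique_depth, i)
                phi[pd[i]] += w * (po[i] - pz[i]) * leaf_val
            return
        f = feature[node]
        if x[f] <= threshold[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        hot_zero = cover[hot] / cover[node]
        cold_zero = cover[cold] / cover[node]
        iz = io = 1.0
        k = -1
        for i in range(1, unique_depth + 1):
            if pd[i] == f:
                k = i
                break
        if k >= 0:
            iz, io = pz[k], po[k]
            _unwind(pd, pz, po, pw, unique_depth, k)
            unique_depth -= 1
        recurse(hot, pd, pz, po, pw, unique_depth + 1, iz * hot_zero, io, f)
        recurse(cold, pd, pz, po, pw, unique_depth + 1, iz * cold_zero, 0.0, f)

    zeros = [0.0] * max_len
    recurse(0, [-1] * max_len, zeros.copy(), zeros.copy(), zeros.copy(), 0, 1.0, 1.0, -1)


def _iter_trees(model):
    if hasattr(model, "estimators_"):  # forest: prediction is the tree mean
        trees = [est.tree_ for est in model.estimators_]
        scale = 1.0 / len(trees)
        return trees, scale
    return [model.tree_], 1.0


def expected_value(model) -> float:
    """Cover-weighted mean prediction of the ensemble (empty-set value)."""
    total = 0.0
    trees, scale = _iter_trees(model)
    for tree in trees:
        values = tree.value.reshape(-1)
        cover = tree.weighted_n_node_samples
        leaves = tree.children_left < 0
        total += scale * float(
            np.sum(values[leaves] * cover[leaves]) / cover[0]
        )
    return total


def tree_shap_values(model, X) -> np.ndarray:
    """Per-row, per-feature SHAP values for a fitted tree regressor/forest."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    phi = np.zeros((n, m))
    trees, scale = _iter_trees(model)
    for tree in trees:
        for r in range(n):
            _shap_single_tree(tree, X[r], phi[r], scale)
    return phi
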
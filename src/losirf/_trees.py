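"""Numba kernels for feature-weighted classification trees on dosage data.

Dosages are ternary {0,1,2}, so the only informative split thresholds are 0.5
and 1.5; restricting to them makes the sign semantics of a split exact (the
``> t`` branch is the carrier/homozygote branch). Candidate features at each
node are drawn without replacement with probability proportional to the
feature weights via the Gumbel top-k trick, which is what makes the forest
"feature-weighted" and hence iterable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _grow_tree(X, y, boot, weights, mtry, min_node, seed):
    """Grow one tree on the bootstrap ``boot`` (row indices into X).

    Returns (feature, threshold, left, right, count0, count1, imp_dec,
    row_leaf): flat node arrays (leaf iff left == -1), per-feature
    impurity-decrease totals, and each training row's leaf (-1 if out of bag).
    """
    np.random.seed(seed)
    m = boot.shape[0]
    p = X.shape[1]
    max_nodes = 2 * m + 1
    feature = np.full(max_nodes, -1, dtype=np.int32)
    threshold = np.zeros(max_nodes, dtype=np.float32)
    left = np.full(max_nodes, -1, dtype=np.int32)
    right = np.full(max_nodes, -1, dtype=np.int32)
    count0 = np.zeros(max_nodes, dtype=np.int64)
    count1 = np.zeros(max_nodes, dtype=np.int64)
    imp_dec = np.zeros(p, dtype=np.float64)
    row_leaf = np.full(X.shape[0], -1, dtype=np.int32)

    idx = boot.copy()
    stack_node = np.empty(max_nodes, dtype=np.int32)
    stack_start = np.empty(max_nodes, dtype=np.int64)
    stack_end = np.empty(max_nodes, dtype=np.int64)
    keys = np.empty(p, dtype=np.float64)

    stack_node[0] = 0
    stack_start[0] = 0
    stack_end[0] = m
    top = 1
    node_count = 1
    while top > 0:
        top -= 1
        node = stack_node[top]
        start = stack_start[top]
        end = stack_end[top]
        s = end - start
        c1 = 0
        for i in range(start, end):
            c1 += y[idx[i]]
        c0 = s - c1
        count0[node] = c0
        count1[node] = c1
        if c0 == 0 or c1 == 0 or s < 2 * min_node or s < 2:
            for i in range(start, end):
                row_leaf[idx[i]] = node
            continue

        # Gumbel top-k: weighted sampling of mtry distinct candidate features
        n_pos = 0
        for j in range(p):
            if weights[j] > 0.0:
                u = np.random.random()
                keys[j] = np.log(weights[j]) - np.log(-np.log(u))
                n_pos += 1
            else:
                keys[j] = -np.inf
        m_try = mtry if mtry < n_pos else n_pos

        parent_imp = 1.0 - (c0 / s) ** 2 - (c1 / s) ** 2
        best_gain = 0.0
        best_f = -1
        best_thr = np.float32(0.0)
        for _t in range(m_try):
            f = int(np.argmax(keys))
            keys[f] = -np.inf
            c00 = 0
            c01 = 0
            c10 = 0
            c11 = 0
            for i in range(start, end):
                r = idx[i]
                d = X[r, f]
                if y[r] == 1:
                    if d == 0:
                        c01 += 1
                    elif d == 1:
                        c11 += 1
                else:
                    if d == 0:
                        c00 += 1
                    elif d == 1:
                        c10 += 1
            for thr_i in range(2):
                if thr_i == 0:
                    l0 = c00
                    l1 = c01
                else:
                    l0 = c00 + c10
                    l1 = c01 + c11
                sl = l0 + l1
                sr = s - sl
                if sl < min_node or sr < min_node or sl == 0 or sr == 0:
                    continue
                r0 = c0 - l0
                r1 = c1 - l1
                il = 1.0 - (l0 / sl) ** 2 - (l1 / sl) ** 2
                ir = 1.0 - (r0 / sr) ** 2 - (r1 / sr) ** 2
                gain = parent_imp - (sl / s) * il - (sr / s) * ir
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_f = f
                    best_thr = np.float32(0.5) if thr_i == 0 else np.float32(1.5)

        if best_f < 0 or best_gain <= 0.0:
            for i in range(start, end):
                row_leaf[idx[i]] = node
            continue

        thr_int = 0 if best_thr < 1.0 else 1
        i = start
        j = end - 1
        while i <= j:
            if X[idx[i], best_f] <= thr_int:
                i += 1
            else:
                tmp = idx[i]
                idx[i] = idx[j]
                idx[j] = tmp
                j -= 1
        mid = i
        feature[node] = best_f
        threshold[node] = best_thr
        lid = node_count
        rid = node_count + 1
        node_count += 2
        left[node] = lid
        right[node] = rid
        imp_dec[best_f] += (s / m) * best_gain
        stack_node[top] = rid
        stack_start[top] = mid
        stack_end[top] = end
        top += 1
        stack_node[top] = lid
        stack_start[top] = start
        stack_end[top] = mid
        top += 1

    return (
        feature[:node_count],
        threshold[:node_count],
        left[:node_count],
        right[:node_count],
        count0[:node_count],
        count1[:node_count],
        imp_dec,
        row_leaf,
    )


@njit(cache=True)
def _apply_tree(feature, threshold, left, right, X):
    """Route rows of X to leaf node ids."""
    n = X.shape[0]
    out = np.empty(n, dtype=np.int32)
    for i in range(n):
        node = 0
        while left[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node
    return out


@njit(cache=True)
def _signed_group_usage(feature, threshold, left, right, X, group, out):
    """Mark which signed feature groups each row's decision path uses.

    ``group`` maps feature index -> group index (e.g. locus); ``out`` is a
    zeroed (n, 2*n_groups) uint8 array. Column 2g records the minus sign
    (a ``<= t`` branch on a variant of group g), column 2g+1 the plus sign.
    """
    for i in range(X.shape[0]):
        node = 0
        while left[node] >= 0:
            f = feature[node]
            g = group[f]
            if X[i, f] <= threshold[node]:
                out[i, 2 * g] = 1
                node = left[node]
            else:
                out[i, 2 * g + 1] = 1
                node = right[node]
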
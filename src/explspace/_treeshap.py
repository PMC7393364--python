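"""Numba kernels for path-dependent Shapley attribution of decision trees.

The algorithm maintains, along each root-to-leaf path, the set of unique
features split on so far together with the fraction of weight that flows
down when the feature is unknown (``zero_fraction``, the cover ratio) and
when it is known (``one_fraction``, 0 or 1 by routing).  ``pweight`` holds,
for each possible subset size, the permutation weight of subsets of that
size drawn from the path's unique features.  Extending and unwinding the
path keeps the computation polynomial in depth instead of exponential in
the number of features.

Paths are stored in four flat parallel arrays (feature index, zero fraction,
one fraction, permutation weight); each recursion level owns a contiguous
segment, emulated here with an explicit stack so the kernels compile in
nopython mode.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _extend(pf, pz, po, pw, off, ud, zero_fraction, one_fraction, feature_index):
    pf[off + ud] = feature_index
    pz[off + ud] = zero_fraction
    po[off + ud] = one_fraction
    pw[off + ud] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        pw[off + i + 1] += one_fraction * pw[off + i] * (i + 1.0) / (ud + 1.0)
        pw[off + i] = zero_fraction * pw[off + i] * (ud - i) / (ud + 1.0)


@njit(cache=True)
def _unwind(pf, pz, po, pw, off, ud, path_index):
    one_fraction = po[off + path_index]
    zero_fraction = pz[off + path_index]
    next_one = pw[off + ud]
    for i in range(ud - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = pw[off + i]
            pw[off + i] = next_one * (ud + 1.0) / ((i + 1.0) * one_fraction)
            next_one = tmp - pw[off + i] * zero_fraction * (ud - i) / (ud + 1.0)
        else:
            pw[off + i] = pw[off + i] * (ud + 1.0) / (zero_fraction * (ud - i))
    for i in range(path_index, ud):
        pf[off + i] = pf[off + i + 1]
        pz[off + i] = pz[off + i + 1]
        po[off + i] = po[off + i + 1]


@njit(cache=True)
def _unwound_sum(pf, pz, po, pw, off, ud, path_index):
    one_fraction = po[off + path_index]
    zero_fraction = pz[off + path_index]
    next_one = pw[off + ud]
    total = 0.0
    for i in range(ud - 1, -1, -1):
        if one_fraction != 0.0:
            tmp = next_one * (ud + 1.0) / ((i + 1.0) * one_fraction)
            total += tmp
            next_one = pw[off + i] - tmp * zero_fraction * (ud - i) / (ud + 1.0)
        else:
            total += pw[off + i] / zero_fraction * (ud + 1.0) / (ud - i)
    return total


@njit(cache=True)
def _tree_shap_single(
    children_left,
    children_right,
    split_feature,
    split_threshold,
    leaf_value,
    node_cover,
    max_depth,
    x,
    phi,
):
    """Accumulate attributions of one tree for one instance into phi."""
    cap = max_depth + 3
    bufsize = cap * (cap + 1) // 2 + cap
    pf = np.empty(bufsize, dtype=np.int64)
    pz = np.empty(bufsize, dtype=np.float64)
    po = np.empty(bufsize, dtype=np.float64)
    pw = np.empty(bufsize, dtype=np.float64)

    stacksize = 2 * cap + 4
    s_node = np.empty(stacksize, dtype=np.int64)
    s_ud = np.empty(stacksize, dtype=np.int64)
    s_poff = np.empty(stacksize, dtype=np.int64)
    s_pz = np.empty(stacksize, dtype=np.float64)
    s_po = np.empty(stacksize, dtype=np.float64)
    s_pi = np.empty(stacksize, dtype=np.int64)

    top = 0
    s_node[0] = 0
    s_ud[0] = 0
    s_poff[0] = 0
    s_pz[0] = 1.0
    s_po[0] = 1.0
    s_pi[0] = -1

    while top >= 0:
        node = s_node[top]
        ud = s_ud[top]
        parent_off = s_poff[top]
        parent_zero = s_pz[top]
        parent_one = s_po[top]
        parent_feat = s_pi[top]
        top -= 1

        off = parent_off + ud + 1
        for i in range(ud):
            pf[off + i] = pf[parent_off + i]
            pz[off + i] = pz[parent_off + i]
            po[off + i] = po[parent_off + i]
            pw[off + i] = pw[parent_off + i]
        _extend(pf, pz, po, pw, off, ud, parent_zero, parent_one, parent_feat)

        left = children_left[node]
        if left < 0:
            v = leaf_value[node]
            for i in range(1, ud + 1):
                w = _unwound_sum(pf, pz, po, pw, off, ud, i)
                phi[pf[off + i]] += w * (po[off + i] - pz[off + i]) * v
        else:
            right = children_right[node]
            f = split_feature[node]
            if x[f] <= split_threshold[node]:
                hot, cold = left, right
            else:
                hot, cold = right, left
            hot_zero = node_cover[hot] / node_cover[node]
            cold_zero = node_cover[cold] / node_cover[node]

            incoming_zero = 1.0
            incoming_one = 1.0
            path_index = -1
            for i in range(ud + 1):
                if pf[off + i] == f:
                    path_index = i
                    break
            d2 = ud
            if path_index >= 0:
                incoming_zero = pz[off + path_index]
                incoming_one = po[off + path_index]
                _unwind(pf, pz, po, pw, off, d2, path_index)
                d2 -= 1

            # push cold first so the hot branch (and its whole subtree) is
            # processed before the cold sibling re-reads this node's path
            top += 1
            s_node[top] = cold
            s_ud[top] = d2 + 1
            s_poff[top] = off
            s_pz[top] = cold_zero * incoming_zero
            s_po[top] = 0.0
            s_pi[top] = f

            top += 1
            s_node[top] = hot
            s_ud[top] = d2 + 1
            s_poff[top] = off
            s_pz[top] = hot_zero * incoming_zero
            s_po[top] = incoming_one
            s_pi[top] = f


@njit(cache=True)
def ensemble_shap_matrix(
    tree_offsets,
    children_left,
    children_right,
    split_feature,
    split_threshold,
    leaf_value,
    node_cover,
    max_depths,
    X,
):
    """Shapley attribution matrix for all rows of X, averaged over trees."""
    n, p = X.shape
    n_trees = tree_offsets.shape[0] - 1
    phi = np.zeros((n, p), dtype=np.float64)
    scratch = np.zeros(p, dtype=np.float64)
    for i in range(n):
        x = X[i]
        row = phi[i]
        for t in range(n_trees):
            a, b = tree_offsets[t], tree_offsets[t + 1]
            scratch[:] = 0.0
            _tree_shap_single(
                children_left[a:b],
                children_right[a:b],
                split_feature[a:b],
                split_threshold[a:b],
                leaf_value[a:b],
                node_cover[a:b],
                max_depths[t],
                x,
                scratch,
            )
            row += scratch
        row /= n_trees
    return phi
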
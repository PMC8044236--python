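"""Exact SHAP attributions for scikit-learn decision-tree ensembles.

Implements the path-dependent polynomial-time algorithm for Shapley values
of tree models: for each sample the attribution of feature *i* is the exact
Shapley value of the conditional-expectation game defined by tree traversal,
where features absent from the conditioning set are marginalised by the
training-sample weights stored at each split. For a forest, attributions are
averaged over trees (each tree explains its positive-class leaf fraction),
so ``base + phi.sum(axis=1) == predict_proba[:, 1]`` exactly.

The traversal keeps a "unique path" of the features encountered between the
root and the current node, together with the fraction of weight that flows
down when each feature is known (one_fraction) or marginalised
(zero_fraction), and the permutation weights needed for the Shapley sum.
The descent is an explicit-stack DFS over a shared triangular path buffer:
each visit owns the segment ``buf[off : off + len + 1]``, children use the
segment that follows, and a node's segment is never written by its
descendants, so a pending sibling frame stays valid until popped. All
kernels address that buffer through explicit offsets — never through
overlapping array views, which the JIT is free to assume non-aliasing.
Complexity is O(trees x leaves x depth^2) per sample.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_shap_values", "tree_shap_values"]


@njit(cache=False)
def _extend(m_d, m_z, m_o, m_w, o, l, pz, po, pi):
    # append a feature to the path segment starting at o (current length l)
    m_d[o + l] = pi
    m_z[o + l] = pz
    m_o[o + l] = po
    m_w[o + l] = 1.0 if l == 0 else 0.0
    for i in range(l - 1, -1, -1):
        m_w[o + i + 1] += po * m_w[o + i] * (i + 1) / (l + 1)
        m_w[o + i] = pz * m_w[o + i] * (l - i) / (l + 1)


@njit(cache=False)
def _unwound_sum(m_z, m_o, m_w, o, l, i):
    # total permutation weight with path entry i removed, w/o materializing
    one = m_o[o + i]
    zero = m_z[o + i]
    total = 0.0
    if one != 0.0:
        n = m_w[o + l - 1]
        for j in range(l - 2, -1, -1):
            tmp = n / ((j + 1) * one)
            total += tmp
            n = m_w[o + j] - tmp * zero * (l - 1 - j)
    else:
        for j in range(l - 2, -1, -1):
            total += m_w[o + j] / (zero * (l - 1 - j))
    return total * l


@njit(cache=False)
def _unwind(m_d, m_z, m_o, m_w, o, l, i):
    # remove path entry i in place; new length l-1
    one = m_o[o + i]
    zero = m_z[o + i]
    n = m_w[o + l - 1]
    if one != 0.0:
        for j in range(l - 2, -1, -1):
            tmp = m_w[o + j]
            m_w[o + j] = n * l / ((j + 1) * one)
            n = tmp - m_w[o + j] * zero * (l - 1 - j) / l
    else:
        for j in range(l - 2, -1, -1):
            m_w[o + j] = m_w[o + j] * l / (zero * (l - 1 - j))
    for j in range(i, l - 1):
        m_d[o + j] = m_d[o + j + 1]
        m_z[o + j] = m_z[o + j + 1]
        m_o[o + j] = m_o[o + j + 1]


@njit(cache=False)
def _tree_shap(cl, cr, feat, thresh, leafval, nodew, a, x, phi,
               m_d, m_z, m_o, m_w,
               st_node, st_off, st_len, st_pz, st_po, st_pi):
    """One tree (nodes at global indices a..), one sample, accumulate phi."""
    st_node[0] = 0
    st_off[0] = 0
    st_len[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    top = 1
    while top > 0:
        top -= 1
        node = st_node[top]
        parent_off = st_off[top]
        l = st_len[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]

        off = parent_off + l
        for i in range(l):
            m_d[off + i] = m_d[parent_off + i]
            m_z[off + i] = m_z[parent_off + i]
            m_o[off + i] = m_o[parent_off + i]
            m_w[off + i] = m_w[parent_off + i]
        _extend(m_d, m_z, m_o, m_w, off, l, pz, po, pi)
        l += 1

        g = a + node
        if cl[g] < 0:  # leaf
            v = leafval[g]
            for i in range(1, l):
                w = _unwound_sum(m_z, m_o, m_w, off, l, i)
                phi[m_d[off + i]] += w * (m_o[off + i] - m_z[off + i]) * v
            continue

        d = feat[g]
        if x[d] <= thresh[g]:
            hot, cold = cl[g], cr[g]
        else:
            hot, cold = cr[g], cl[g]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, l):
            if m_d[off + i] == d:
                k = i
                break
        if k >= 0:
            iz = m_z[off + k]
            io = m_o[off + k]
            _unwind(m_d, m_z, m_o, m_w, off, l, k)
            l -= 1
        rj = nodew[g]
        # cold pushed first so the hot child is processed first (LIFO)
        st_node[top] = cold
        st_off[top] = off
        st_len[top] = l
        st_pz[top] = iz * nodew[a + cold] / rj
        st_po[top] = 0.0
        st_pi[top] = d
        top += 1
        st_node[top] = hot
        st_off[top] = off
        st_len[top] = l
        st_pz[top] = iz * nodew[a + hot] / rj
        st_po[top] = io
        st_pi[top] = d
        top += 1


@njit(cache=False)
def _forest_shap(cl, cr, feat, thresh, leafval, nodew, offsets, maxdepth, X):
    n, d = X.shape
    n_trees = offsets.shape[0] - 1
    phi = np.zeros((n, d))
    maxd = maxdepth + 2
    bufsize = maxd * (maxd + 1) // 2 + maxd
    m_d = np.full(bufsize, -1, dtype=np.int64)
    m_z = np.zeros(bufsize)
    m_o = np.zeros(bufsize)
    m_w = np.zeros(bufsize)
    stacksize = 2 * maxd + 2
    st_node = np.empty(stacksize, dtype=np.int64)
    st_off = np.empty(stacksize, dtype=np.int64)
    st_len = np.empty(stacksize, dtype=np.int64)
    st_pz = np.empty(stacksize)
    st_po = np.empty(stacksize)
    st_pi = np.empty(stacksize, dtype=np.int64)
    for t in range(n_trees):
        for s in range(n):
            _tree_shap(cl, cr, feat, thresh, leafval, nodew, offsets[t],
                       X[s], phi[s], m_d, m_z, m_o, m_w,
                       st_node, st_off, st_len, st_pz, st_po, st_pi)
    return phi / n_trees


def _flatten_forest(estimators):
    cls, crs, feats, threshs, vals, ws = [], [], [], [], [], []
    offsets = [0]
    maxdepth = 1
    for est in estimators:
        t = est.tree_
        cls.append(t.children_left)
        crs.append(t.children_right)
        feats.append(t.feature)
        threshs.append(t.threshold)
        counts = t.value[:, 0, :]
        vals.append(counts[:, 1] / counts.sum(axis=1))
        ws.append(t.weighted_n_node_samples)
        offsets.append(offsets[-1] + t.node_count)
        maxdepth = max(maxdepth, int(t.max_depth))
    return (
        np.ascontiguousarray(np.concatenate(cls).astype(np.int64)),
        np.ascontiguousarray(np.concatenate(crs).astype(np.int64)),
        np.ascontiguousarray(np.concatenate(feats).astype(np.int64)),
        np.ascontiguousarray(np.concatenate(threshs)),
        np.ascontiguousarray(np.concatenate(vals)),
        np.ascontiguousarray(np.concatenate(ws)),
        np.asarray(offsets, dtype=np.int64),
        maxdepth,
    )


def forest_shap_values(forest, X):
    """Per-sample, per-feature SHAP values for a fitted binary
    ``RandomForestClassifier`` (or any sklearn forest of classification
    trees), explaining the positive-class probability.

    Returns ``(phi, base)`` where ``phi`` has shape ``(n_samples,
    n_features)`` and ``base`` is the expected positive-class fraction, so
    that ``base + phi.sum(1)`` reproduces ``predict_proba(X)[:, 1]``.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    cl, cr, feat, thresh, leafval, nodew, offsets, maxdepth = _flatten_forest(
        forest.estimators_
    )
    phi = _forest_shap(cl, cr, feat, thresh, leafval, nodew, offsets, maxdepth, X)
    base = float(np.mean([leafval[offsets[t]] for t in range(len(offsets) - 1)]))
    return phi, base


def tree_shap_values(tree, X):
    """SHAP values for a single fitted ``DecisionTreeClassifier``."""

    class _One:
        estimators_ = None

    holder = _One()
    holder.estimators_ = [tree]
    return forest_shap_values(holder, X)
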
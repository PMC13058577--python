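"""Bagged regression-tree kernel for the turnover model.

One call grows a full bootstrap ensemble for a single response (locus) and
returns (a) out-of-bag prediction sums/counts per row and (b) every split as
a (feature, threshold, impurity-decrease) triple. Keeping the kernel flat and
numba-compiled makes per-locus ensembles cheap enough to fit hundreds of
loci x hundreds of trees on a single CPU.

Impurity decrease of a split is the reduction in summed squared error,
normalized by the bootstrap sample size (so per-tree gains are comparable
across loci). Out-of-bag predictions reuse the recursive partition: OOB rows
are routed down the tree alongside the bootstrap rows, so no explicit tree
structure is stored.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forest_kernel"]


@njit(cache=True)
def _partition(idx, lo, hi, X, feat, thr, scratch):
    """Stable partition of idx[lo:hi] by X[idx, feat] <= thr; returns the split point."""
    m = lo
    k = 0
    for i in range(lo, hi):
        if X[idx[i], feat] <= thr:
            idx[m] = idx[i]
            m += 1
        else:
            scratch[k] = idx[i]
            k += 1
    for i in range(k):
        idx[m + i] = scratch[i]
    return m


@njit(cache=True)
def forest_kernel(X, y, n_trees, mtry, min_leaf, seed):
    """Grow ``n_trees`` bagged trees for response ``y``.

    Returns (oob_sum, oob_cnt, split_feature, split_threshold, split_gain,
    n_splits).
    """
    n, p = X.shape
    np.random.seed(seed)
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    max_splits = n_trees * max(n - 1, 1)
    sp_feat = np.empty(max_splits, dtype=np.int64)
    sp_thr = np.empty(max_splits)
    sp_gain = np.empty(max_splits)
    n_splits = 0

    b_idx = np.empty(n, dtype=np.int64)
    o_idx = np.empty(n, dtype=np.int64)
    in_bag = np.zeros(n, dtype=np.uint8)
    feats = np.empty(p, dtype=np.int64)
    scratch = np.empty(n, dtype=np.int64)
    vals = np.empty(n)
    ys = np.empty(n)

    cap = 2 * n + 16
    st_b0 = np.empty(cap, dtype=np.int64)
    st_b1 = np.empty(cap, dtype=np.int64)
    st_o0 = np.empty(cap, dtype=np.int64)
    st_o1 = np.empty(cap, dtype=np.int64)

    for _tree in range(n_trees):
        for i in range(n):
            in_bag[i] = 0
        for i in range(n):
            j = np.random.randint(0, n)
            b_idx[i] = j
            in_bag[j] = 1
        n_oob = 0
        for i in range(n):
            if in_bag[i] == 0:
                o_idx[n_oob] = i
                n_oob += 1

        top = 0
        st_b0[top] = 0
        st_b1[top] = n
        st_o0[top] = 0
        st_o1[top] = n_oob
        top = 1
        while top > 0:
            top -= 1
            b0, b1 = st_b0[top], st_b1[top]
            o0, o1 = st_o0[top], st_o1[top]
            nb = b1 - b0
            s = 0.0
            s2 = 0.0
            for ii in range(b0, b1):
                v = y[b_idx[ii]]
                s += v
                s2 += v * v
            mean = s / nb
            sse = s2 - s * s / nb
            if nb < 2 * min_leaf or sse <= 1e-14:
                for ii in range(o0, o1):
                    r = o_idx[ii]
                    oob_sum[r] += mean
                    oob_cnt[r] += 1
                continue

            for k in range(p):
                feats[k] = k
            for k in range(mtry):
                j = k + np.random.randint(0, p - k)
                tmp = feats[k]
                feats[k] = feats[j]
                feats[j] = tmp

            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            for k in range(mtry):
                f = feats[k]
                for ii in range(nb):
                    r = b_idx[b0 + ii]
                    vals[ii] = X[r, f]
                    ys[ii] = y[r]
                order = np.argsort(vals[:nb], kind="mergesort")
                csum = 0.0
                for pos in range(nb - 1):
                    csum += ys[order[pos]]
                    nl = pos + 1
                    nr = nb - nl
                    if nl < min_leaf or nr < min_leaf:
                        continue
                    if vals[order[pos]] == vals[order[pos + 1]]:
                        continue
                    gain = (csum * csum / nl
                            + (s - csum) * (s - csum) / nr
                            - s * s / nb)
                    if gain > best_gain + 1e-15:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (vals[order[pos]]
                                          + vals[order[pos + 1]])

            if best_f < 0:
                for ii in range(o0, o1):
                    r = o_idx[ii]
                    oob_sum[r] += mean
                    oob_cnt[r] += 1
                continue

            sp_feat[n_splits] = best_f
            sp_thr[n_splits] = best_thr
            sp_gain[n_splits] = best_gain / n
            n_splits += 1

            bm = _partition(b_idx, b0, b1, X, best_f, best_thr, scratch)
            om = _partition(o_idx, o0, o1, X, best_f, best_thr, scratch)
            st_b0[top] = b0
            st_b1[top] = bm
            st_o0[top] = o0
            st_o1[top] = om
            top += 1
            st_b0[top] = bm
            st_b1[top] = b1
            st_o0[top] = om
            st_o1[top] = o1
            top += 1

    return oob_sum, oob_cnt, sp_feat[:n_splits], sp_thr[:n_splits], \
        sp_gain[:n_splits], n_splits
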
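"""Numba kernels for the random-forest classifier.

Standard Breiman forest: each of ``n_trees`` CART trees is grown on a
bootstrap resample of the training rows, splitting on the best Gini
decrease among ``mtry`` features drawn without replacement at each node,
until nodes are pure.  Importance is the out-of-bag permutation importance
(mean decrease in OOB accuracy when a feature's OOB values are shuffled);
features a tree never splits on contribute exactly zero for that tree and
are skipped.

Trees are stored as flat arrays (feature / threshold / children / leaf
class) so fitting and prediction avoid per-tree Python overhead entirely.
All randomness comes from numba's own RNG, seeded explicitly at each entry
point, so results are reproducible and independent of numpy's global state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def build_forest(X, y, n_trees, mtry, seed):
    """Grow the forest.  X: (n, p) float64; y: (n,) int64 in {0, 1}.

    Returns (feat, thr, left, right, leaf, inbag): per-tree flat node arrays
    plus the in-bag count of every training row.
    """
    np.random.seed(seed)
    n, p = X.shape
    max_nodes = 2 * n + 1
    feat = np.full((n_trees, max_nodes), -1, np.int64)
    thr = np.zeros((n_trees, max_nodes), np.float64)
    left = np.full((n_trees, max_nodes), -1, np.int64)
    right = np.full((n_trees, max_nodes), -1, np.int64)
    leaf = np.full((n_trees, max_nodes), -1, np.int64)
    inbag = np.zeros((n_trees, n), np.int64)

    idx = np.empty(n, np.int64)
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    featperm = np.empty(p, np.int64)

    for t in range(n_trees):
        for i in range(n):
            j = np.random.randint(0, n)
            idx[i] = j
            inbag[t, j] += 1
        nn = 1
        stack_node[0] = 0
        stack_lo[0] = 0
        stack_hi[0] = n
        sp = 1
        while sp > 0:
            sp -= 1
            node = stack_node[sp]
            lo = stack_lo[sp]
            hi = stack_hi[sp]
            m = hi - lo
            npos = 0
            for i in range(lo, hi):
                npos += y[idx[i]]
            if npos == 0 or npos == m or m < 2:
                leaf[t, node] = 1 if 2 * npos >= m else 0
                continue
            for j in range(p):
                featperm[j] = j
            best_gain = 0.0
            best_f = -1
            best_thr = 0.0
            parent_imp = npos * (m - npos) / (m * 1.0)
            for k in range(mtry):
                r = k + np.random.randint(0, p - k)
                tmp = featperm[k]
                featperm[k] = featperm[r]
                featperm[r] = tmp
                f = featperm[k]
                vals = np.empty(m, np.float64)
                ys = np.empty(m, np.int64)
                for i in range(m):
                    vals[i] = X[idx[lo + i], f]
                    ys[i] = y[idx[lo + i]]
                order = np.argsort(vals)
                lpos = 0
                for i in range(m - 1):
                    o = order[i]
                    lpos += ys[o]
                    v0 = vals[o]
                    v1 = vals[order[i + 1]]
                    if v1 <= v0:
                        continue
                    nl = i + 1
                    nr = m - nl
                    gain = (
                        parent_imp
                        - lpos * (nl - lpos) / (nl * 1.0)
                        - (npos - lpos) * (nr - (npos - lpos)) / (nr * 1.0)
                    )
                    if gain > best_gain + 1e-12:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (v0 + v1)
            if best_f < 0:
                # all sampled features constant on this node
                leaf[t, node] = 1 if 2 * npos >= m else 0
                continue
            tmpidx = np.empty(m, np.int64)
            nl = 0
            for i in range(lo, hi):
                if X[idx[i], best_f] <= best_thr:
                    tmpidx[nl] = idx[i]
                    nl += 1
            nr = nl
            for i in range(lo, hi):
                if X[idx[i], best_f] > best_thr:
                    tmpidx[nr] = idx[i]
                    nr += 1
            for i in range(m):
                idx[lo + i] = tmpidx[i]
            feat[t, node] = best_f
            thr[t, node] = best_thr
            left[t, node] = nn
            right[t, node] = nn + 1
            nn += 2
            stack_node[sp] = nn - 2
            stack_lo[sp] = lo
            stack_hi[sp] = lo + nl
            sp += 1
            stack_node[sp] = nn - 1
            stack_lo[sp] = lo + nl
            stack_hi[sp] = hi
            sp += 1
    return feat, thr, left, right, leaf, inbag


@njit(cache=True, inline="always")
def _predict_row(feat, thr, left, right, leaf, x):
    node = 0
    while feat[node] >= 0:
        if x[feat[node]] <= thr[node]:
            node = left[node]
        else:
            node = right[node]
    return leaf[node]


@njit(cache=True)
def forest_votes(feat, thr, left, right, leaf, X):
    """Number of trees voting for class 1, per row of X."""
    n_trees = feat.shape[0]
    n = X.shape[0]
    votes = np.zeros(n, np.int64)
    for t in range(n_trees):
        for i in range(n):
            votes[i] += _predict_row(feat[t], thr[t], left[t], right[t], leaf[t], X[i])
    return votes


@njit(cache=True)
def oob_importance(feat, thr, left, right, leaf, inbag, X, y, seed):
    """Mean decrease in out-of-bag accuracy per feature (raw, unscaled)."""
    np.random.seed(seed)
    n_trees = feat.shape[0]
    n, p = X.shape
    imp = np.zeros(p, np.float64)
    used = np.empty(p, np.int64)
    xbuf = np.empty(p, np.float64)
    oob = np.empty(n, np.int64)
    for t in range(n_trees):
        noob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob[noob] = i
                noob += 1
        if noob == 0:
            continue
        base = 0
        for ii in range(noob):
            i = oob[ii]
            if _predict_row(feat[t], thr[t], left[t], right[t], leaf[t], X[i]) == y[i]:
                base += 1
        nused = 0
        usedmask = np.zeros(p, np.int64)
        for nd in range(feat.shape[1]):
            f = feat[t, nd]
            if f >= 0 and usedmask[f] == 0:
                usedmask[f] = 1
                used[nused] = f
                nused += 1
        permvals = np.empty(noob, np.float64)
        for uu in range(nused):
            f = used[uu]
            for ii in range(noob):
                permvals[ii] = X[oob[ii], f]
            for ii in range(noob - 1, 0, -1):
                jj = np.random.randint(0, ii + 1)
                tv = permvals[ii]
                permvals[ii] = permvals[jj]
                permvals[jj] = tv
            correct = 0
            for ii in range(noob):
                i = oob[ii]
                for q in range(p):
                    xbuf[q] = X[i, q]
                xbuf[f] = permvals[ii]
                if _predict_row(feat[t], thr[t], left[t], right[t], leaf[t], xbuf) == y[i]:
                    correct += 1
            imp[f] += (base - correct) / noob
    return imp / n_trees
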
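"""Compiled kernels for honest tree building and ensemble traversal.

Trees are stored as flat parallel arrays (feature, threshold, left, right,
value, depth).  ``feature == -1`` marks a leaf.  Routing rule: ``x <=
threshold`` goes left.  Candidate thresholds are midpoints between consecutive
distinct observed values on the split half, scanned in ascending feature index
then ascending threshold order with strict improvement, so builds are
deterministic given the per-tree seed.

Two modes share one code path:

* ``MODE_CAUSAL`` (0): split criterion maximizes the between-child spread of
  the within-child difference-in-means treatment effect,
  sum_child n_child * tau_child^2 (the parent term is constant for a fixed
  node); leaf values are the honest estimate-half difference in arm means.
* ``MODE_REG`` (1): ordinary variance-reduction regression splits
  (sum_child n_child * mean_child^2); callers pass ``d`` as all zeros.

Every candidate split must leave at least ``min_leaf`` rows per arm in each
child on BOTH the split half and the estimate half.
"""

import numpy as np
from numba import njit

MODE_CAUSAL = 0
MODE_REG = 1


@njit(cache=True)
def _node_stats(y, d, idx, lo, hi):
    n1 = 0
    n0 = 0
    s1 = 0.0
    s0 = 0.0
    for k in range(lo, hi):
        i = idx[k]
        if d[i] == 1:
            n1 += 1
            s1 += y[i]
        else:
            n0 += 1
            s0 += y[i]
    return n1, s1, n0, s0


@njit(cache=True)
def build_tree(X, y, d, sidx, eidx, min_leaf, mtry, max_depth, mode, seed,
               feat, thr, left, right, value, depth, leaf_n1, leaf_n0):
    """Build one honest tree in place; returns the number of nodes used.

    ``sidx``/``eidx`` are row-index arrays for the split and estimate halves;
    they are permuted in place during partitioning.
    """
    np.random.seed(seed)
    p = X.shape[1]
    max_nodes = feat.shape[0]
    stack = np.empty((max_nodes + 1, 6), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = sidx.shape[0]
    stack[0, 3] = 0
    stack[0, 4] = eidx.shape[0]
    stack[0, 5] = 0
    top = 1
    n_nodes = 1
    featbuf = np.empty(p, dtype=np.int64)
    chosen = np.empty(p, dtype=np.int64)

    while top > 0:
        top -= 1
        node = stack[top, 0]
        s_lo = stack[top, 1]
        s_hi = stack[top, 2]
        e_lo = stack[top, 3]
        e_hi = stack[top, 4]
        dep = stack[top, 5]

        ns = s_hi - s_lo
        ne = e_hi - e_lo

        # honest leaf value from the estimate half
        en1, es1, en0, es0 = _node_stats(y, d, eidx, e_lo, e_hi)
        if mode == MODE_CAUSAL:
            m1 = es1 / en1 if en1 > 0 else 0.0
            m0 = es0 / en0 if en0 > 0 else 0.0
            value[node] = m1 - m0
        else:
            value[node] = es0 / en0 if en0 > 0 else 0.0
        feat[node] = -1
        thr[node] = 0.0
        left[node] = -1
        right[node] = -1
        depth[node] = dep
        leaf_n1[node] = en1
        leaf_n0[node] = en0

        # split-half totals
        sn1, ss1, sn0, ss0 = _node_stats(y, d, sidx, s_lo, s_hi)

        # feasibility
        if max_depth >= 0 and dep >= max_depth:
            continue
        if n_nodes + 2 > max_nodes:
            continue
        if mode == MODE_CAUSAL:
            if (sn1 < 2 * min_leaf or sn0 < 2 * min_leaf
                    or en1 < 2 * min_leaf or en0 < 2 * min_leaf):
                continue
        else:
            if sn0 < 2 * min_leaf or en0 < 2 * min_leaf:
                continue

        # draw mtry candidate features, scanned in ascending index order
        for j in range(p):
            featbuf[j] = j
        m = mtry if mtry < p else p
        for j in range(m):
            k = j + np.random.randint(0, p - j)
            tmpv = featbuf[j]
            featbuf[j] = featbuf[k]
            featbuf[k] = tmpv
        for j in range(m):
            chosen[j] = featbuf[j]
        chosen[:m].sort()

        sv = np.empty(ns)
        syv = np.empty(ns)
        sdv = np.empty(ns, dtype=np.int64)
        e1v = np.empty(ne)
        e0v = np.empty(ne)

        best_crit = -np.inf
        best_f = -1
        best_thr = 0.0

        for jj in range(m):
            f = chosen[jj]
            for k in range(ns):
                i = sidx[s_lo + k]
                sv[k] = X[i, f]
                syv[k] = y[i]
                sdv[k] = d[i]
            order = np.argsort(sv)
            c1 = 0
            c0 = 0
            for k in range(e_lo, e_hi):
                i = eidx[k]
                if d[i] == 1:
                    e1v[c1] = X[i, f]
                    c1 += 1
                else:
                    e0v[c0] = X[i, f]
                    c0 += 1
            e1s = np.sort(e1v[:c1])
            e0s = np.sort(e0v[:c0])

            nL1 = 0
            nL0 = 0
            sL1 = 0.0
            sL0 = 0.0
            for ii in range(ns - 1):
                o = order[ii]
                if sdv[o] == 1:
                    nL1 += 1
                    sL1 += syv[o]
                else:
                    nL0 += 1
                    sL0 += syv[o]
                v_here = sv[o]
                v_next = sv[order[ii + 1]]
                if v_here >= v_next:
                    continue
                t = 0.5 * (v_here + v_next)
                nR1 = sn1 - nL1
                nR0 = sn0 - nL0
                if mode == MODE_CAUSAL:
                    if (nL1 < min_leaf or nL0 < min_leaf
                            or nR1 < min_leaf or nR0 < min_leaf):
                        continue
                    eL1 = np.searchsorted(e1s, t, side="right")
                    eL0 = np.searchsorted(e0s, t, side="right")
                    if (eL1 < min_leaf or eL0 < min_leaf
                            or c1 - eL1 < min_leaf or c0 - eL0 < min_leaf):
                        continue
                    tauL = sL1 / nL1 - sL0 / nL0
                    tauR = (ss1 - sL1) / nR1 - (ss0 - sL0) / nR0
                    crit = ((nL1 + nL0) * tauL * tauL
                            + (nR1 + nR0) * tauR * tauR)
                else:
                    if nL0 < min_leaf or nR0 < min_leaf:
                        continue
                    eL0 = np.searchsorted(e0s, t, side="right")
                    if eL0 < min_leaf or c0 - eL0 < min_leaf:
                        continue
                    mL = sL0 / nL0
                    mR = (ss0 - sL0) / nR0
                    crit = nL0 * mL * mL + nR0 * mR * mR
                if crit > best_crit:
                    best_crit = crit
                    best_f = f
                    best_thr = t

        if best_f < 0:
            continue

        # partition both halves in place: x <= thr goes left
        s_mid = _partition(X, sidx, s_lo, s_hi, best_f, best_thr)
        e_mid = _partition(X, eidx, e_lo, e_hi, best_f, best_thr)

        nl = n_nodes
        nr = n_nodes + 1
        n_nodes += 2
        feat[node] = best_f
        thr[node] = best_thr
        left[node] = nl
        right[node] = nr

        stack[top, 0] = nl
        stack[top, 1] = s_lo
        stack[top, 2] = s_mid
        stack[top, 3] = e_lo
        stack[top, 4] = e_mid
        stack[top, 5] = dep + 1
        top += 1
        stack[top, 0] = nr
        stack[top, 1] = s_mid
        stack[top, 2] = s_hi
        stack[top, 3] = e_mid
        stack[top, 4] = e_hi
        stack[top, 5] = dep + 1
        top += 1

    return n_nodes


@njit(cache=True)
def _partition(X, idx, lo, hi, f, t):
    i = lo
    j = hi - 1
    while i <= j:
        if X[idx[i], f] <= t:
            i += 1
        else:
            tmp = idx[i]
            idx[i] = idx[j]
            idx[j] = tmp
            j -= 1
    return i


@njit(cache=True)
def apply_ensemble(feat, thr, left, right, offsets, X, out):
    """Fill ``out[i, b]`` with the global node index of row i's leaf in tree b."""
    B = offsets.shape[0] - 1
    n = X.shape[0]
    for b in range(B):
        base = offsets[b]
        for i in range(n):
            node = 0
            while feat[base + node] >= 0:
                if X[i, feat[base + node]] <= thr[base + node]:
                    node = left[base + node]
                else:
                    node = right[base + node]
            out[i, b] = base + node
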
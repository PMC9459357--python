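"""Independent brute-force oracles used to check the tree machinery.

Everything here is written in plain Python loops, deliberately sharing no
code with the package's compiled kernels.
"""

from __future__ import annotations


def _mean(xs):
    return sum(xs) / len(xs)


def brute_force_best_split(X, y, d, split_ids, est_ids, min_leaf):
    """Exhaustively score every (variable, threshold) candidate.

    Criterion: sum over children of n_child * tau_child^2, where tau_child is
    the split-half difference in arm means and n_child the split-half child
    size; thresholds are midpoints between consecutive distinct split-half
    values; each child must keep >= min_leaf rows per arm in both halves.
    First strict maximum wins (features ascending, thresholds ascending).
    Returns (feature, threshold, criterion) or None.
    """
    best = None
    p = X.shape[1]
    for f in range(p):
        vals = sorted({float(X[i, f]) for i in split_ids})
        for a, b in zip(vals, vals[1:]):
            thr = 0.5 * (a + b)
            groups = {}
            ok = True
            for name, ids in (("s", split_ids), ("e", est_ids)):
                for side in (True, False):
                    sel = [i for i in ids if (X[i, f] <= thr) == side]
                    t = [y[i] for i in sel if d[i] == 1]
                    c = [y[i] for i in sel if d[i] == 0]
                    if len(t) < min_leaf or len(c) < min_leaf:
                        ok = False
                    groups[(name, side)] = (t, c)
            if not ok:
                continue
            tL, cL = groups[("s", True)]
            tR, cR = groups[("s", False)]
            tauL = _mean(tL) - _mean(cL)
            tauR = _mean(tR) - _mean(cR)
            crit = ((len(tL) + len(cL)) * tauL * tauL
                    + (len(tR) + len(cR)) * tauR * tauR)
            if best is None or crit > best[2]:
                best = (f, thr, crit)
    return best


def honest_leaf_effect(X, y, d, est_ids, path):
    """Difference in arm means over the estimate-half rows satisfying a path.

    ``path`` is a list of (feature, threshold, go_left) conditions.
    """
    sel = []
    for i in est_ids:
        keep = True
        for f, thr, go_left in path:
            if (X[i, f] <= thr) != go_left:
                keep = False
                break
        if keep:
            sel.append(i)
    t = [y[i] for i in sel if d[i] == 1]
    c = [y[i] for i in sel if d[i] == 0]
    return _mean(t) - _mean(c)


def tree_paths(tree):
    """(path, node_index) for every leaf of a fitted CausalTree."""
    out = []

    def rec(node, path):
        if tree.feature[node] < 0:
            out.append((path, node))
            return
        f = int(tree.feature[node])
        thr = float(tree.threshold[node])
        rec(int(tree.left[node]), path + [(f, thr, True)])
        rec(int(tree.right[node]), path + [(f, thr, False)])

    rec(0, [])
    return out
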
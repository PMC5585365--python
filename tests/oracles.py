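"""Independent brute-force reference implementations used only by tests.

Everything here recomputes a quantity by direct enumeration — O(n^2)
pairwise AUC, exhaustive split search, leave-one-out by hand — so the
package's fast implementations can be checked against code that shares
none of their structure.
"""

from __future__ import annotations

import numpy as np


def pairwise_auc(scores, labels) -> float:
    """AUC by direct enumeration of all (positive, negative) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def delong_variance(scores_a, scores_b, labels):
    """DeLong AUCs and var(AUC_a - AUC_b) from the O(n^2) placement matrix."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    m, n = int(pos.sum()), int(neg.sum())

    def components(s):
        P = s[pos][:, None]
        N = s[neg][None, :]
        psi = (P > N).astype(float) + 0.5 * (P == N)
        return psi.mean(), psi.mean(axis=1), psi.mean(axis=0)

    auc_a, va_pos, va_neg = components(scores_a)
    auc_b, vb_pos, vb_neg = components(scores_b)
    s_pos = np.cov(np.vstack([va_pos, vb_pos]), ddof=1)
    s_neg = np.cov(np.vstack([va_neg, vb_neg]), ddof=1)
    cov = s_pos / m + s_neg / n
    return float(auc_a), float(auc_b), float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])


def exhaustive_best_split(X, y, min_leaf):
    """Best threshold split by scanning every midpoint of every covariate.

    Complete data only.  Tie rules: covariate earlier in column order,
    then smaller threshold.  Returns ``(j, threshold, delta)`` or None.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    best = None
    for j in range(X.shape[1]):
        u = np.unique(X[:, j])
        for a, b in zip(u[:-1], u[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] < thr
            nl = int(left.sum())
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            s = y.sum()
            sl = y[left].sum()
            sr = s - sl
            delta = (s - s * s / n) - (sl - sl * sl / nl) - (sr - sr * sr / nr)
            if delta <= 0:
                continue
            if best is None or delta > best[2]:
                best = (j, thr, delta)
    return best


def exhaustive_grow(X, y, min_split, min_leaf, max_depth, cp_abs, depth=0):
    """Recursive exhaustive-search tree as nested tuples.

    A leaf is ``('leaf', n, n_pos)``; an internal node is
    ``('split', j, threshold, left, right)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    n_pos = int(y.sum())
    leaf = ("leaf", n, n_pos)
    if depth >= max_depth or n < min_split or n_pos in (0, n):
        return leaf
    found = exhaustive_best_split(X, y, min_leaf)
    if found is None or found[2] < cp_abs:
        return leaf
    j, thr, _ = found
    left = X[:, j] < thr
    return (
        "split",
        j,
        thr,
        exhaustive_grow(X[left], y[left], min_split, min_leaf, max_depth, cp_abs, depth + 1),
        exhaustive_grow(X[~left], y[~left], min_split, min_leaf, max_depth, cp_abs, depth + 1),
    )


def tree_to_tuples(tree, nid=None):
    """Flatten a RegressionTree into the oracle's tuple form."""
    node = tree.nodes[tree.root_id if nid is None else nid]
    if node.is_leaf:
        return ("leaf", node.n, node.n_pos)
    return (
        "split",
        node.split.cov_index,
        node.split.threshold,
        tree_to_tuples(tree, node.children[0]),
        tree_to_tuples(tree, node.children[1]),
    )
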
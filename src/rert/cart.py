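"""Binary regression trees on a 0/1 outcome.

Growing, weakest-link cost-complexity pruning, v-fold cross-validated
subtree selection, prediction, and JSON serialization.  The outcome is
binary but the trees are *regression* trees: node impurity is the
squared-error (ANOVA) deviance ``n * p * (1 - p)`` and each leaf predicts
the relative frequency of positives among its members, so leaf values are
event probabilities.

Missing covariate values are handled structurally: a split is scored on
the observed values only, and rows missing the split covariate are routed
with the majority of the observed rows (the direction is frozen at fit
time on each internal node).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import NOMINAL, Cohort

THRESHOLD = "threshold"
LEVEL_SUBSET = "level-subset"


@dataclass(frozen=True)
class SplitRule:
    """A binary split on one covariate.

    Threshold form sends ``value < threshold`` left; level-subset form
    sends level indices in ``left_levels`` left.  ``surrogate_direction``
    is where rows with a missing value go.
    """

    covariate: str
    cov_index: int
    form: str = THRESHOLD
    threshold: float | None = None
    left_levels: frozenset[int] | None = None
    surrogate_direction: str = "left"

    def __post_init__(self) -> None:
        if self.form == THRESHOLD:
            if self.threshold is None or not math.isfinite(self.threshold):
                raise ValueError("threshold split needs a finite threshold")
        elif self.form == LEVEL_SUBSET:
            if not self.left_levels:
                raise ValueError("level-subset split needs a nonempty left level set")
            object.__setattr__(self, "left_levels", frozenset(self.left_levels))
        else:
            raise ValueError(f"unknown split form {self.form!r}")
        if self.surrogate_direction not in ("left", "right"):
            raise ValueError("surrogate_direction must be 'left' or 'right'")

    def goes_left(self, value: float) -> bool:
        """Route one (possibly missing) value; NaN follows the surrogate."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return self.surrogate_direction == "left"
        if self.form == THRESHOLD:
            return value < self.threshold
        return int(value) in self.left_levels

    def describe(self, direction: str = "left") -> str:
        if self.form == THRESHOLD:
            op = "<" if direction == "left" else ">="
            return f"{self.covariate} {op} {self.threshold:g}"
        levels = sorted(self.left_levels)
        prefix = "in" if direction == "left" else "not in"
        return f"{self.covariate} {prefix} {{{', '.join(map(str, levels))}}}"


@dataclass
class TreeNode:
    id: int
    n: int
    n_pos: int
    yhat: float
    impurity: float
    depth: int = 0
    split: SplitRule | None = None
    children: tuple[int, int] | None = None
    #: realized impurity decrease I(node) - I(left) - I(right) over all
    #: members (missing rows included after routing); None for leaves
    decrease: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class GrowParams:
    """Stopping and pruning controls for tree growing.

    Defaults follow the conventions of R's rpart: a node needs at least
    ``min_split`` members to be considered for splitting, each child keeps
    at least ``min_leaf`` members, and a split must reduce impurity by at
    least ``cp`` times the root impurity.
    """

    min_split: int = 20
    min_leaf: int = 7
    max_depth: int = 30
    cp: float = 0.01
    v_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.min_split < 2 * self.min_leaf:
            raise ValueError("min_split must be >= 2 * min_leaf")
        if self.v_folds < 2:
            raise ValueError("v_folds must be >= 2")
        if self.cp < 0:
            raise ValueError("cp must be >= 0")


@dataclass
class RegressionTree:
    nodes: dict[int, TreeNode]
    root_id: int = 0
    grow_params: GrowParams | None = None
    covariate_names: list[str] = field(default_factory=list)

    # -- structure -------------------------------------------------------
    def node(self, nid: int) -> TreeNode:
        return self.nodes[nid]

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def leaf_ids(self, start: int | None = None) -> list[int]:
        """Leaf ids in left-to-right order under ``start`` (default root)."""
        out: list[int] = []
        stack = [self.root_id if start is None else start]
        while stack:
            node = self.nodes[stack.pop()]
            if node.is_leaf:
                out.append(node.id)
            else:
                stack.extend(reversed(node.children))
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    def internal_ids(self) -> list[int]:
        return [nid for nid, nd in self.nodes.items() if not nd.is_leaf]

    def descendant_ids(self, start: int) -> list[int]:
        out: list[int] = []
        stack = list(self.nodes[start].children or ())
        while stack:
            nid = stack.pop()
            out.append(nid)
            ch = self.nodes[nid].children
            if ch:
                stack.extend(ch)
        return out

    def collapse(self, nid: int) -> None:
        """Turn an internal node into a leaf, dropping its subtree."""
        for d in self.descendant_ids(nid):
            del self.nodes[d]
        node = self.nodes[nid]
        node.split = None
        node.children = None
        node.decrease = None

    # -- prediction ------------------------------------------------------
    def predict_row(self, row: np.ndarray) -> float:
        node = self.root
        while not node.is_leaf:
            child = node.children[0] if node.split.goes_left(row[node.split.cov_index]) else node.children[1]
            node = self.nodes[child]
        return node.yhat

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Vectorized prediction for an (n, p) covariate matrix."""
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        stack = [(self.root_id, np.arange(len(X)))]
        while stack:
            nid, idx = stack.pop()
            node = self.nodes[nid]
            if node.is_leaf:
                out[idx] = node.yhat
                continue
            rule = node.split
            col = X[idx, rule.cov_index]
            if rule.form == THRESHOLD:
                left = col < rule.threshold
            else:
                left = np.isin(col.astype(np.int64, copy=False, casting="unsafe"), list(rule.left_levels))
                left &= ~np.isnan(col)
            miss = np.isnan(col)
            if rule.surrogate_direction == "left":
                left |= miss
            else:
                left &= ~miss
            stack.append((node.children[0], idx[left]))
            stack.append((node.children[1], idx[~left]))
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []
        for nid in sorted(self.nodes):
            nd = self.nodes[nid]
            entry: dict = {
                "id": nd.id,
                "n": nd.n,
                "n_pos": nd.n_pos,
                "yhat": nd.yhat,
                "impurity": nd.impurity,
                "depth": nd.depth,
            }
            if not nd.is_leaf:
                entry["children"] = list(nd.children)
                entry["decrease"] = nd.decrease
                rule = nd.split
                entry["split"] = {
                    "covariate": rule.covariate,
                    "cov_index": rule.cov_index,
                    "form": rule.form,
                    "threshold": rule.threshold,
                    "left_levels": sorted(rule.left_levels) if rule.left_levels else None,
                    "surrogate_direction": rule.surrogate_direction,
                }
            nodes.append(entry)
        return {
            "root_id": self.root_id,
            "covariates": list(self.covariate_names),
            "nodes": nodes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, doc: dict) -> "RegressionTree":
        nodes: dict[int, TreeNode] = {}
        for entry in doc["nodes"]:
            split = None
            children = None
            if "split" in entry:
                s = entry["split"]
                split = SplitRule(
                    covariate=s["covariate"],
                    cov_index=s["cov_index"],
                    form=s["form"],
                    threshold=s["threshold"],
                    left_levels=frozenset(s["left_levels"]) if s["left_levels"] else None,
                    surrogate_direction=s["surrogate_direction"],
                )
                children = tuple(entry["children"])
            nodes[entry["id"]] = TreeNode(
                id=entry["id"],
                n=entry["n"],
                n_pos=entry["n_pos"],
                yhat=entry["yhat"],
                impurity=entry["impurity"],
                depth=entry["depth"],
                split=split,
                children=children,
                decrease=entry.get("decrease"),
            )
        return cls(nodes=nodes, root_id=doc["root_id"], covariate_names=list(doc["covariates"]))

    @classmethod
    def from_json(cls, text: str) -> "RegressionTree":
        return cls.from_dict(json.loads(text))

    def render_text(self) -> str:
        """Human-readable root-to-leaf path listing."""
        lines: list[str] = []

        def walk(nid: int, conds: list[str]) -> None:
            node = self.nodes[nid]
            if node.is_leaf:
                path = " and ".join(conds) if conds else "(all)"
                lines.append(f"{path} -> yhat={node.yhat:.3f} (n={node.n}, pos={node.n_pos})")
                return
            walk(node.children[0], conds + [node.split.describe("left")])
            walk(node.children[1], conds + [node.split.describe("right")])

        walk(self.root_id, [])
        return "\n".join(lines)


def clone_tree(tree: RegressionTree) -> RegressionTree:
    """Fast structural copy (split rules are immutable and shared)."""
    nodes = {
        nid: TreeNode(
            id=nd.id,
            n=nd.n,
            n_pos=nd.n_pos,
            yhat=nd.yhat,
            impurity=nd.impurity,
            depth=nd.depth,
            split=nd.split,
            children=nd.children,
            decrease=nd.decrease,
        )
        for nid, nd in tree.nodes.items()
    }
    return RegressionTree(
        nodes=nodes,
        root_id=tree.root_id,
        grow_params=tree.grow_params,
        covariate_names=list(tree.covariate_names),
    )


@dataclass
class ComplexityPath:
    """Weakest-link pruning sequence with optional cross-validation errors."""

    alphas: list[float]
    subtrees: list[RegressionTree]
    cv_error: np.ndarray | None = None
    cv_se: np.ndarray | None = None


# ---------------------------------------------------------------------------
# impurity and split search


def node_impurity(y_members) -> float:
    """Sum of squared deviations from the node mean, ``n * p * (1 - p)``."""
    y = np.asarray(list(y_members) if not isinstance(y_members, np.ndarray) else y_members)
    n = y.size
    if n == 0:
        raise ValueError("impurity of an empty node is undefined")
    s = float(y.sum())
    return s - s * s / n if n else 0.0


def _impurity_counts(n: int, n_pos: int) -> float:
    return n_pos - n_pos * n_pos / n


def _scan_threshold(v: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best threshold split of one numeric column (observed values only).

    Returns ``(delta, threshold, n_left_obs)`` or ``None``.  Thresholds sit
    at midpoints between consecutive distinct observed values; ties on
    delta resolve to the smallest threshold.
    """
    n = v.size
    if n < 2 * min_leaf:
        return None
    order = np.argsort(v, kind="stable")
    sv = v[order]
    cy = np.cumsum(y[order])
    total = cy[-1]
    if total == 0 or total == n:
        return None
    parent = total - total * total / n
    # candidate boundary after position i (1-based count i+1 on the left)
    nl = np.arange(1, n)
    boundary = sv[:-1] < sv[1:]
    ok = boundary & (nl >= min_leaf) & (n - nl >= min_leaf)
    if not ok.any():
        return None
    cl = cy[:-1]
    left_imp = cl - cl * cl / nl
    cr = total - cl
    nr = n - nl
    right_imp = cr - cr * cr / nr
    delta = np.where(ok, parent - left_imp - right_imp, -np.inf)
    best = int(np.argmax(delta))  # first max -> smallest threshold
    if not np.isfinite(delta[best]) or delta[best] <= 0:
        return None
    thr = 0.5 * (sv[best] + sv[best + 1])
    return float(delta[best]), float(thr), int(best + 1)


def _scan_nominal(v: np.ndarray, y: np.ndarray, n_levels: int, min_leaf: int):
    """Best level-subset split of a nominal column via level-mean ordering.

    Sorting levels by their within-level outcome mean and scanning the
    ordered cuts is exact for squared-error impurity.  Returns
    ``(delta, left_levels, cut_position)`` or ``None``.
    """
    n = v.size
    if n < 2 * min_leaf:
        return None
    vi = v.astype(np.int64)
    counts = np.bincount(vi, minlength=n_levels).astype(float)
    sums = np.bincount(vi, weights=y, minlength=n_levels)
    present = counts > 0
    if present.sum() < 2:
        return None
    means = np.where(present, sums / np.maximum(counts, 1), np.inf)
    # stable order: by mean, then by level index
    order = np.lexsort((np.arange(n_levels), means))
    order = [int(k) for k in order if present[k]]
    total = float(sums.sum())
    if total == 0 or total == n:
        return None
    parent = total - total * total / n
    best = None
    nl = 0.0
    cl = 0.0
    for cut in range(len(order) - 1):
        k = order[cut]
        nl += counts[k]
        cl += sums[k]
        nr = n - nl
        cr = total - cl
        if nl < min_leaf or nr < min_leaf:
            continue
        delta = parent - (cl - cl * cl / nl) - (cr - cr * cr / nr)
        if delta > 0 and (best is None or delta > best[0]):
            best = (float(delta), frozenset(order[: cut + 1]), cut)
    return best


try:  # compiled fast path for the threshold scans (the growing hot loop)
    import numba as _numba

    @_numba.njit(cache=False)
    def _scan_columns_fast(Xn, y, cand, min_leaf):  # pragma: no cover - compiled
        n = Xn.shape[0]
        best_j = -1
        best_delta = -np.inf
        best_thr = 0.0
        v = np.empty(n)
        w = np.empty(n)
        for jj in range(cand.size):
            j = cand[jj]
            m = 0
            for i in range(n):
                x = Xn[i, j]
                if not np.isnan(x):
                    v[m] = x
                    w[m] = y[i]
                    m += 1
            if m < 2 * min_leaf:
                continue
            order = np.argsort(v[:m])
            sv = v[:m][order]
            sy = w[:m][order]
            total = 0.0
            for i in range(m):
                total += sy[i]
            if total == 0.0 or total == m:
                continue
            parent = total - total * total / m
            cl = 0.0
            loc_delta = -np.inf
            loc_i = -1
            for i in range(m - 1):
                cl += sy[i]
                if sv[i] < sv[i + 1]:
                    nl = float(i + 1)
                    nr = float(m - i - 1)
                    if nl >= min_leaf and nr >= min_leaf:
                        cr = total - cl
                        delta = parent - (cl - cl * cl / nl) - (cr - cr * cr / nr)
                        if delta > loc_delta:
                            loc_delta = delta
                            loc_i = i
            if loc_i >= 0 and loc_delta > best_delta:
                best_j = j
                best_delta = loc_delta
                best_thr = 0.5 * (sv[loc_i] + sv[loc_i + 1])
        return best_j, best_delta, best_thr

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _scan_columns_slow(Xn, y, cand, min_leaf):
    """numpy fallback with the same contract and tie rules as the kernel."""
    best_j, best_delta, best_thr = -1, -np.inf, 0.0
    for j in cand:
        col = Xn[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2 * min_leaf:
            continue
        found = _scan_threshold(col[obs], y[obs], min_leaf)
        if found is not None and found[0] > best_delta:
            best_j, best_delta, best_thr = int(j), found[0], found[1]
    return best_j, best_delta, best_thr


def _best_split_arrays(
    X: np.ndarray,
    y: np.ndarray,
    schema,
    params: GrowParams,
    cp_abs: float,
    candidates: np.ndarray | None = None,
) -> SplitRule | None:
    """Best split over candidate covariates for the rows given.

    ``cp_abs`` is the absolute impurity-decrease floor (``cp`` times the
    root impurity of the tree being grown).  Tie rule: larger delta wins;
    on exact ties the covariate earlier in schema order, then the smaller
    threshold.
    """
    cols = list(range(X.shape[1])) if candidates is None else [int(j) for j in candidates]
    numeric = np.array([j for j in cols if schema[j].kind != NOMINAL], dtype=np.int64)
    nominal = [j for j in cols if schema[j].kind == NOMINAL]

    yf = np.ascontiguousarray(y, dtype=float)
    scan = _scan_columns_fast if _HAVE_NUMBA else _scan_columns_slow
    bj, bdelta, bthr = scan(np.ascontiguousarray(X), yf, numeric, params.min_leaf)

    best_rule = None
    best_delta = -np.inf
    if bj >= 0 and np.isfinite(bdelta):
        best_delta = bdelta
        best_rule = SplitRule(covariate=schema[bj].name, cov_index=bj, threshold=bthr)
    for j in nominal:
        col = X[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2 * params.min_leaf:
            continue
        found = _scan_nominal(col[obs], yf[obs], len(schema[j].levels), params.min_leaf)
        if found is None:
            continue
        delta, left_levels, _ = found
        # equal delta: the covariate earlier in schema order wins
        if delta > best_delta or (delta == best_delta and best_rule is not None and j < best_rule.cov_index):
            best_delta = delta
            best_rule = SplitRule(
                covariate=schema[j].name,
                cov_index=int(j),
                form=LEVEL_SUBSET,
                left_levels=left_levels,
            )
    if best_rule is None or best_delta < cp_abs or best_delta <= 0:
        return None
    return best_rule


def best_split(cohort: Cohort, params: GrowParams) -> SplitRule | None:
    """Best single split of the whole cohort (the root split of a tree).

    The impurity floor is ``params.cp`` times the cohort's own impurity;
    returns ``None`` when no admissible split reduces impurity enough.
    """
    root_imp = _impurity_counts(cohort.n, int(cohort.y.sum()))
    rule = _best_split_arrays(
        cohort.X, cohort.y, cohort.schema, params, params.cp * root_imp
    )
    if rule is None:
        return None
    return _freeze_surrogate(rule, cohort.X)


def _freeze_surrogate(rule: SplitRule, X: np.ndarray) -> SplitRule:
    """Set the missing-value direction to the majority of observed rows."""
    col = X[:, rule.cov_index]
    obs = ~np.isnan(col)
    if rule.form == THRESHOLD:
        n_left = int((col[obs] < rule.threshold).sum())
    else:
        n_left = int(np.isin(col[obs].astype(np.int64), list(rule.left_levels)).sum())
    direction = "left" if n_left >= obs.sum() - n_left else "right"
    if direction != rule.surrogate_direction:
        rule = SplitRule(
            covariate=rule.covariate,
            cov_index=rule.cov_index,
            form=rule.form,
            threshold=rule.threshold,
            left_levels=rule.left_levels,
            surrogate_direction=direction,
        )
    return rule


def _route(rule: SplitRule, X: np.ndarray, idx: np.ndarray):
    col = X[idx, rule.cov_index]
    if rule.form == THRESHOLD:
        left = col < rule.threshold
    else:
        left = np.isin(
            np.nan_to_num(col, nan=-1.0).astype(np.int64), list(rule.left_levels)
        )
    miss = np.isnan(col)
    if rule.surrogate_direction == "left":
        left |= miss
    else:
        left &= ~miss
    return idx[left], idx[~left]


def grow_tree(
    cohort: Cohort,
    params: GrowParams,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegressionTree:
    """Grow a tree by recursive partitioning until no admissible split.

    ``mtry`` (with ``rng``) samples that many covariates uniformly without
    replacement at every split — the random-forest hook; by default all
    covariates compete at every split.
    """
    X = cohort.X
    y = cohort.y
    p = cohort.p
    if mtry is not None and not (1 <= mtry <= p):
        raise ValueError(f"mtry must be in [1, {p}]")
    root_imp = _impurity_counts(cohort.n, int(y.sum()))
    cp_abs = params.cp * root_imp
    tree = RegressionTree(nodes={}, root_id=0, grow_params=params, covariate_names=cohort.names)
    next_id = 0

    def new_node(idx: np.ndarray, depth: int) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        n = len(idx)
        n_pos = int(y[idx].sum())
        tree.nodes[nid] = TreeNode(
            id=nid,
            n=n,
            n_pos=n_pos,
            yhat=n_pos / n,
            impurity=_impurity_counts(n, n_pos),
            depth=depth,
        )
        return nid

    stack = [(new_node(np.arange(cohort.n), 0), np.arange(cohort.n))]
    while stack:
        nid, idx = stack.pop()
        node = tree.nodes[nid]
        if (
            node.depth >= params.max_depth
            or node.n < params.min_split
            or node.n_pos in (0, node.n)
        ):
            continue
        cand = None
        if mtry is not None and mtry < p:
            cand = np.sort(rng.choice(p, size=mtry, replace=False))
        rule = _best_split_arrays(X[idx], y[idx], cohort.schema, params, cp_abs, cand)
        if rule is None:
            continue
        rule = _freeze_surrogate(rule, X[idx])
        left_idx, right_idx = _route(rule, X, idx)
        if len(left_idx) == 0 or len(right_idx) == 0:
            continue  # all observed on one side after missing routing
        lid = new_node(left_idx, node.depth + 1)
        rid = new_node(right_idx, node.depth + 1)
        node.split = rule
        node.children = (lid, rid)
        node.decrease = node.impurity - tree.nodes[lid].impurity - tree.nodes[rid].impurity
        stack.append((rid, right_idx))
        stack.append((lid, left_idx))
    return tree


# ---------------------------------------------------------------------------
# cost-complexity pruning


def _subtree_stats(tree: RegressionTree):
    """Per-internal-node (leaf impurity sum, leaf count) of its subtree."""
    stats: dict[int, tuple[float, int]] = {}

    def walk(nid: int) -> tuple[float, int]:
        node = tree.nodes[nid]
        if node.is_leaf:
            return node.impurity, 1
        li, lc = walk(node.children[0])
        ri, rc = walk(node.children[1])
        stats[nid] = (li + ri, lc + rc)
        return li + ri, lc + rc

    walk(tree.root_id)
    return stats


def _weakest_links(tree: RegressionTree):
    """g(t) for every internal node; returns (min_g, ids attaining it)."""
    stats = _subtree_stats(tree)
    gs = {
        nid: (tree.nodes[nid].impurity - leaf_imp) / (leaf_count - 1)
        for nid, (leaf_imp, leaf_count) in stats.items()
    }
    m = min(gs.values())
    tol = 1e-12 * max(1.0, abs(m))
    ids = [nid for nid, g in gs.items() if g <= m + tol]
    return m, ids


def cost_complexity_path(tree: RegressionTree) -> ComplexityPath:
    """Weakest-link pruning sequence from the full tree to the root-only tree.

    Each step collapses every internal node attaining the minimal
    ``g(t) = (I(t) - sum of subtree leaf impurities) / (leaves - 1)``;
    the alphas are the successive minima, strictly increasing from 0.
    """
    work = clone_tree(tree)
    alphas = [0.0]
    subtrees = [clone_tree(work)]
    while work.internal_ids():
        g, ids = _weakest_links(work)
        # collapse top-most nodes only; descendants vanish with them
        idset = set(ids)
        for nid in ids:
            if nid not in work.nodes or nid not in idset:
                continue
            for d in work.descendant_ids(nid):
                idset.discard(d)
        for nid in sorted(idset):
            if nid in work.nodes and not work.nodes[nid].is_leaf:
                work.collapse(nid)
        alpha = max(g, 0.0)
        if alpha <= alphas[-1] and len(alphas) > 1:
            # merge a non-increasing step into the previous one
            subtrees[-1] = clone_tree(work)
        else:
            alphas.append(alpha)
            subtrees.append(clone_tree(work))
    if len(alphas) >= 2 and alphas[1] <= 0.0:
        # a zero-gain collapse merges into the starting point
        alphas.pop(0)
        subtrees.pop(0)
        alphas[0] = 0.0
    return ComplexityPath(alphas=alphas, subtrees=subtrees)


def prune_at_alpha(tree: RegressionTree, alpha: float, inplace: bool = False) -> RegressionTree:
    """Smallest optimal subtree for complexity penalty ``alpha``."""
    work = tree if inplace else clone_tree(tree)
    while work.internal_ids():
        g, ids = _weakest_links(work)
        if g > alpha:
            break
        idset = set(ids)
        for nid in ids:
            if nid not in idset:
                continue
            for d in work.descendant_ids(nid):
                idset.discard(d)
        for nid in sorted(idset):
            if nid in work.nodes and not work.nodes[nid].is_leaf:
                work.collapse(nid)
    return work


def stratified_fold_ids(y: np.ndarray, v: int, rng: np.random.Generator) -> np.ndarray:
    """Outcome-stratified fold assignment in {0..v-1}, one id per row.

    Fold ids continue round-robin across classes so every fold is
    populated even when ``v`` exceeds a class count (``v = n`` gives
    leave-one-out).
    """
    fold = np.empty(len(y), dtype=np.int64)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = (offset + np.arange(len(idx))) % v
        offset += len(idx)
    return fold


def select_subtree_cv(
    cohort: Cohort,
    params: GrowParams,
    return_path: bool = False,
):
    """Grow, prune, and pick the subtree minimizing v-fold CV squared error.

    Folds are outcome-stratified and seeded by ``params.seed``.  For each
    candidate alpha the fold trees are pruned at the geometric mean of
    consecutive alphas (the standard cross-validation trick for nested
    pruning sequences).  Ties in CV error go to the smaller subtree.
    """
    if cohort.n < params.v_folds:
        raise ValueError(f"n={cohort.n} is smaller than v_folds={params.v_folds}")
    full = grow_tree(cohort, params)
    path = cost_complexity_path(full)
    K = len(path.alphas)
    if K == 1:
        path.cv_error = np.zeros(1)
        path.cv_se = np.zeros(1)
        sel = clone_tree(path.subtrees[0])
        return (sel, path) if return_path else sel

    betas = []
    for k in range(K):
        if k < K - 1:
            betas.append(math.sqrt(path.alphas[k] * path.alphas[k + 1]))
        else:
            betas.append(np.inf)

    rng = np.random.default_rng(params.seed)
    fold = stratified_fold_ids(cohort.y, params.v_folds, rng)
    sq_err = np.empty((cohort.n, K))
    for f in range(params.v_folds):
        test = fold == f
        train = ~test
        sub = cohort.subset(np.flatnonzero(train))
        fold_tree = grow_tree(sub, params)
        pruned = fold_tree
        Xtest = cohort.X[test]
        for k, beta in enumerate(betas):
            # betas increase, so pruning the same tree in place is safe
            pruned = prune_at_alpha(pruned, beta, inplace=True)
            pred = pruned.predict_matrix(Xtest)
            sq_err[test, k] = (cohort.y[test] - pred) ** 2
    path.cv_error = sq_err.mean(axis=0)
    path.cv_se = sq_err.std(axis=0, ddof=1) / math.sqrt(cohort.n)

    best = path.cv_error.min()
    tol = 1e-12 * max(1.0, best)
    k_best = max(k for k in range(K) if path.cv_error[k] <= best + tol)
    sel = clone_tree(path.subtrees[k_best])
    return (sel, path) if return_path else sel


def predict(tree: RegressionTree, record) -> float:
    """Predict one record (dict keyed by covariate name, or an array)."""
    if isinstance(record, dict):
        row = np.full(len(tree.covariate_names), np.nan)
        for name, value in record.items():
            if name not in tree.covariate_names:
                raise KeyError(f"covariate {name!r} not in the tree's schema")
            row[tree.covariate_names.index(name)] = np.nan if value is None else float(value)
    else:
        row = np.asarray(record, dtype=float)
        if row.shape != (len(tree.covariate_names),):
            raise ValueError(
                f"record length {row.shape} does not match {len(tree.covariate_names)} covariates"
            )
    return tree.predict_row(row)
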
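"""Random forest of regression trees with impurity-based variable importance.

The forest is the screening step of the two-step procedure: grow many
unpruned regression trees on bootstrap samples with per-split covariate
subsampling, then rank covariates by Total Decrease in Node Impurity
(TDNI) — the mean over trees of the summed impurity decreases of every
split made on the covariate — rescaled so the top covariate sits at 100.
Covariates above a cutoff (60 by default) are the "drivers" carried into
the representative-tree step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import GrowParams, RegressionTree, grow_tree
from .data_io import Cohort


@dataclass
class ForestParams:
    """Forest size and tree-shape controls.

    ``mtry`` defaults to ``max(1, p // 3)`` — the regression-forest
    convention — and is resolved against the cohort at fit time.
    """

    n_trees: int = 10_000
    mtry: int | None = None
    min_leaf: int = 5
    max_depth: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class Forest:
    trees: list[RegressionTree]
    params: ForestParams
    covariate_names: list[str]
    mtry_used: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Mean of the per-tree predictions (plain forest average)."""
        out = np.zeros(len(X))
        for tree in self.trees:
            out += tree.predict_matrix(X)
        return out / len(self.trees)


@dataclass
class ImportanceTable:
    """Per-covariate TDNI, raw and rescaled to ``max = 100``."""

    names: list[str]
    raw_tdni: np.ndarray
    relative: np.ndarray
    degenerate: bool = False  # all-zero raw importances (root-only forest)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"covariate": self.names, "raw_tdni": self.raw_tdni, "relative": self.relative}
        )


def grow_forest(cohort: Cohort, params: ForestParams, bootstrap: bool = True) -> Forest:
    """Grow ``n_trees`` unpruned trees on (unstratified) bootstrap samples.

    ``bootstrap=False`` is a testing hook that grows every tree on the
    full cohort.  Each tree's sample and split-covariate draws come from
    an independent stream derived from ``(seed, tree index)``, so tree b
    is identical whatever ``n_trees`` is.
    """
    cohort.require_both_classes()
    p = cohort.p
    mtry = params.mtry if params.mtry is not None else max(1, p // 3)
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds the {p} covariates")
    grow = GrowParams(
        min_split=2 * params.min_leaf,
        min_leaf=params.min_leaf,
        max_depth=params.max_depth,
        cp=0.0,
        seed=params.seed,
    )
    trees = []
    for b in range(params.n_trees):
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, b)))
        if bootstrap:
            idx = rng.integers(0, cohort.n, cohort.n)
            sample = cohort.subset(idx)
        else:
            sample = cohort
        trees.append(grow_tree(sample, grow, mtry=mtry, rng=rng))
    return Forest(trees=trees, params=params, covariate_names=cohort.names, mtry_used=mtry)


def tdni_importance(forest: Forest) -> ImportanceTable:
    """Total Decrease in Node Impurity, averaged over trees.

    ``raw[j]`` is the mean over trees of the summed realized impurity
    decreases of all splits on covariate ``j``; ``relative`` rescales so
    the largest value is 100.  A forest of root-only trees yields an
    all-zero table with ``degenerate`` set (and a warning).
    """
    p = len(forest.covariate_names)
    raw = np.zeros(p)
    for tree in forest.trees:
        for node in tree.nodes.values():
            if node.split is not None:
                raw[node.split.cov_index] += node.decrease
    raw /= forest.n_trees
    top = raw.max()
    if top <= 0:
        warnings.warn("forest made no splits; importance is undefined (reported as zero)")
        return ImportanceTable(list(forest.covariate_names), raw, np.zeros(p), degenerate=True)
    # divide before scaling so the maximum is exactly 100 and never above
    return ImportanceTable(list(forest.covariate_names), raw, 100.0 * (raw / top))


def select_drivers(importance: ImportanceTable, cutoff: float = 60.0) -> list[str]:
    """Covariates with relative importance >= cutoff, strongest first.

    Covariates the forest never split (zero raw TDNI) are never drivers,
    whatever the cutoff.
    """
    order = np.argsort(-importance.relative, kind="stable")
    return [
        importance.names[j]
        for j in order
        if importance.relative[j] >= cutoff and importance.raw_tdni[j] > 0
    ]


def permutation_importance(
    forest: Forest, cohort: Cohort, seed: int = 0
) -> pd.DataFrame:
    """Permutation cross-check for TDNI: rise in MSE when a covariate is shuffled.

    A utility for sanity checks only; the headline ranking is TDNI.
    """
    rng = np.random.default_rng(seed)
    base_pred = forest.predict_matrix(cohort.X)
    base_mse = float(np.mean((cohort.y - base_pred) ** 2))
    rows = []
    for j, name in enumerate(forest.covariate_names):
        Xp = cohort.X.copy()
        Xp[:, j] = Xp[rng.permutation(cohort.n), j]
        mse = float(np.mean((cohort.y - forest.predict_matrix(Xp)) ** 2))
        rows.append({"covariate": name, "mse_increase": mse - base_mse})
    return pd.DataFrame(rows)
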
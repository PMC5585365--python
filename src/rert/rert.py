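"""The representative regression tree: best-of-ensemble tree selection.

A single regression tree is unstable: small perturbations of the data
can change the fitted structure.  The procedure here stabilizes it by
drawing B bootstrap samples stratified by histotype, growing and
CV-pruning a tree on each, scoring every candidate by its AUC on the
full original cohort, and keeping the best performer — the
representative tree.  Because that selection maximizes an apparent AUC,
the module also computes honest out-of-fold scores by rerunning the
entire B-candidate selection inside each fold of an outcome-stratified
cross-validation; both numbers are exposed and they are not
interchangeable.
"""

from __future__ import annotations

import logging
from dataclasses import replace as _dc_replace
from dataclasses import dataclass, field

import numpy as np

from .cart import GrowParams, RegressionTree, clone_tree, select_subtree_cv, stratified_fold_ids
from .data_io import Cohort
from .metrics import mann_whitney_auc

log = logging.getLogger(__name__)

#: sub-seed tag reserved for the evaluation fold assignment (stages use 0..eval_folds)
_EVAL_TAG = 1_000_003


@dataclass
class RERTParams:
    """Ensemble size, growing controls, and evaluation folds."""

    n_boot: int = 1000
    grow: GrowParams = field(default_factory=GrowParams)
    eval_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.eval_folds < 2:
            raise ValueError("eval_folds must be >= 2")


@dataclass
class CandidateSummary:
    index: int
    auc: float
    n_leaves: int
    root_covariate: str | None
    root_threshold: float | None


@dataclass
class RERTResult:
    representative: RegressionTree
    selection_auc: float
    ensemble_aucs: np.ndarray
    candidate_summaries: list[CandidateSummary]
    cv_scores: np.ndarray | None = None  # honest out-of-fold yhat per row
    nested_cv_auc: float | None = None

    def __post_init__(self) -> None:
        if abs(self.selection_auc - float(np.max(self.ensemble_aucs))) > 1e-12:
            raise ValueError("selection_auc must equal the best ensemble AUC")


def stratified_bootstrap(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """Bootstrap resample preserving stratum counts exactly.

    Each stratum of size ``n_s`` contributes ``n_s`` rows drawn with
    replacement from itself.
    """
    idx = stratified_bootstrap_indices(cohort.stratum, rng)
    return cohort.subset(idx)


def stratified_bootstrap_indices(stratum: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    parts = []
    for lab in np.unique(stratum):
        rows = np.flatnonzero(stratum == lab)
        parts.append(rows[rng.integers(0, len(rows), len(rows))])
    return np.concatenate(parts)


def _candidate_seed(seed: int, stage: int, b: int, retry: int = 0):
    """Splittable per-candidate seeding: stage 0 is the selection run,
    stages 1..eval_folds the nested-CV reruns.  Independent of B."""
    return np.random.SeedSequence((seed, stage, b, retry))


def _fit_candidate(cohort: Cohort, params: RERTParams, stage: int, b: int) -> RegressionTree:
    """One bootstrap candidate: stratified resample, grow, CV-prune.

    A resample that loses an outcome class cannot be pruned by CV; it is
    discarded and redrawn with an incremented retry sub-seed.
    """
    for retry in range(100):
        ss = _candidate_seed(params.seed, stage, b, retry)
        rng = np.random.default_rng(ss)
        idx = stratified_bootstrap_indices(cohort.stratum, rng)
        if len(np.unique(cohort.y[idx])) < 2:
            log.info("bootstrap %d (stage %d) drew a single-class sample; redrawing", b, stage)
            continue
        sample = cohort.subset(idx)
        grow = _dc_replace(params.grow, seed=int(rng.integers(0, 2**31 - 1)))
        return select_subtree_cv(sample, grow)
    raise RuntimeError(f"bootstrap candidate {b} degenerate after 100 redraws")


def _root_summary(tree: RegressionTree):
    if tree.root.is_leaf:
        return None, None
    rule = tree.root.split
    return rule.covariate, rule.threshold


def fit_rert(cohort: Cohort, params: RERTParams, compute_cv_scores: bool = True) -> RERTResult:
    """Fit the representative tree and, optionally, honest CV scores.

    Selection: B stratified-bootstrap candidates, each scored by the AUC
    of its predictions on the full original cohort; the representative is
    the argmax, ties broken by fewer leaves then lower replicate index.
    ``selection_auc`` is an apparent (optimistic) number.

    Honest evaluation: when ``compute_cv_scores`` is on, the whole
    B-candidate selection is rerun on each training part of an
    outcome-stratified ``eval_folds`` CV and the held-out rows are scored
    by that fold's representative; ``cv_scores`` holds exactly one
    out-of-fold prediction per row.
    """
    cohort.require_both_classes()
    best_tree, aucs, summaries = _run_selection(cohort, cohort, params, stage=0)

    cv_scores = None
    nested_auc = None
    if compute_cv_scores:
        cv_scores = np.full(cohort.n, np.nan)
        fold_rng = np.random.default_rng(np.random.SeedSequence((params.seed, _EVAL_TAG)))
        fold = stratified_fold_ids(cohort.y, params.eval_folds, fold_rng)
        for f in range(params.eval_folds):
            test = fold == f
            train_cohort = cohort.subset(np.flatnonzero(~test))
            if len(np.unique(train_cohort.y)) < 2:
                raise ValueError(f"evaluation fold {f}: training part lost an outcome class")
            fold_best, _, _ = _run_selection(train_cohort, train_cohort, params, stage=f + 1)
            cv_scores[test] = fold_best.predict_matrix(cohort.X[test])
        nested_auc = float(mann_whitney_auc(cv_scores, cohort.y))

    return RERTResult(
        representative=best_tree,
        selection_auc=float(np.max(aucs)),
        ensemble_aucs=aucs,
        candidate_summaries=summaries,
        cv_scores=cv_scores,
        nested_cv_auc=nested_auc,
    )


def _run_selection(fit_cohort: Cohort, score_cohort: Cohort, params: RERTParams, stage: int):
    """Grow B candidates on ``fit_cohort`` and score each on ``score_cohort``."""
    aucs = np.empty(params.n_boot)
    summaries: list[CandidateSummary] = []
    best_tree = None
    best_key = None
    for b in range(params.n_boot):
        tree = _fit_candidate(fit_cohort, params, stage, b)
        pred = tree.predict_matrix(score_cohort.X)
        auc = float(mann_whitney_auc(pred, score_cohort.y))
        aucs[b] = auc
        root_cov, root_thr = _root_summary(tree)
        summaries.append(CandidateSummary(b, auc, tree.n_leaves, root_cov, root_thr))
        # best AUC; ties -> fewer leaves, then lower replicate index
        key = (-auc, tree.n_leaves, b)
        if best_key is None or key < best_key:
            best_key = key
            best_tree = tree
    return clone_tree(best_tree), aucs, summaries


@dataclass
class ConsensusReport:
    """Agreement among high-AUC candidates about the root split."""

    n_above_floor: int
    modal_root_covariate: str | None
    agreement_fraction: float
    threshold_iqr: tuple[float, float] | None
    empty: bool = False


def consensus_report(result: RERTResult, auc_floor: float = 0.80) -> ConsensusReport:
    """Summarize how similar the good candidates are.

    Among candidates with AUC strictly above ``auc_floor``: the modal
    root covariate, the fraction of candidates whose root agrees with
    it, and the interquartile range of their root thresholds.
    """
    good = [c for c in result.candidate_summaries if c.auc > auc_floor and c.root_covariate]
    if not good:
        return ConsensusReport(0, None, 0.0, None, empty=True)
    counts: dict[str, int] = {}
    for c in good:
        counts[c.root_covariate] = counts.get(c.root_covariate, 0) + 1
    modal = max(sorted(counts), key=counts.get)
    share = [c for c in good if c.root_covariate == modal]
    frac = len(share) / len(good)
    thrs = np.array([c.root_threshold for c in share if c.root_threshold is not None])
    iqr = None
    if thrs.size:
        iqr = (float(np.percentile(thrs, 25)), float(np.percentile(thrs, 75)))
    return ConsensusReport(len(good), modal, frac, iqr)
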
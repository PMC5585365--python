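"""ROC/AUC machinery, operating points, and model-comparison tests.

Everything needed to fill a performance table: the ROC curve and its
area (tie-corrected Mann-Whitney form), the Youden-index operating
threshold, confusion-matrix metrics at a threshold, the DeLong test and
a paired stratified-bootstrap test for comparing two correlated AUCs, a
main-effects logistic baseline, and the nonparametric association tests
(Wilcoxon-Mann-Whitney, Kruskal-Wallis, Pearson chi-squared, Pearson
correlation).

Conventions: a prediction is positive iff ``score >= threshold``;
reported thresholds are midpoints between consecutive distinct scores;
all p-values are two-sided with no multiplicity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCCurve:
    """Empirical ROC curve; points ordered from (0,0) to (1,1)."""

    thresholds: np.ndarray  # decreasing; +inf sentinel first
    tpr: np.ndarray
    fpr: np.ndarray
    n_pos: int
    n_neg: int
    auc: float
    scores: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d and the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    labels = labels.astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUC is undefined with a single outcome class")
    return scores, labels, n_pos, len(labels) - n_pos


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the tie-corrected pairwise Mann-Whitney statistic.

    Mean over all (positive, negative) pairs of ``1`` if the positive
    scores higher, ``1/2`` on ties.  Computed through midranks in
    O(n log n).
    """
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    ranks = stats.rankdata(scores)  # midranks
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_auc(scores, labels) -> ROCCurve:
    """Build the ROC curve; its trapezoid area is the reported AUC."""
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(s[:-1] > s[1:]), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    thresholds = np.r_[np.inf, s[distinct]]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        n_pos=n_pos,
        n_neg=n_neg,
        auc=auc,
        scores=scores,
        labels=labels,
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, with +-inf sentinels."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2 if len(u) > 1 else np.empty(0)
    return np.r_[-np.inf, mids, np.inf]


def youden_threshold(curve: ROCCurve) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are midpoints between consecutive distinct scores plus the
    two infinite sentinels; ties resolve to the smallest threshold, which
    favors sensitivity.  Returns ``(threshold, J)``.
    """
    # curve point k calls "score >= thresholds[k]" positive, so
    # J(k) = tpr[k] - fpr[k]; scanning k from the all-positive end keeps
    # the smallest threshold on ties
    js = curve.tpr - curve.fpr
    K = len(curve.thresholds) - 1
    best_t, best_j = -np.inf, js[K]
    for k in range(K - 1, -1, -1):
        if js[k] > best_j + 1e-12:
            best_j = js[k]
            if k == 0:
                best_t = np.inf
            else:
                best_t = 0.5 * (curve.thresholds[k] + curve.thresholds[k + 1])
    return float(best_t), float(max(best_j, 0.0))


@dataclass
class MetricsReport:
    """One column of a performance table (all metrics at one threshold)."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    youden_j: float = float("nan")
    undefined: tuple[str, ...] = ()  # metrics with a zero denominator

    def as_series(self, name: str = "value") -> pd.Series:
        return pd.Series(
            {
                "ROC-AUC": self.auc,
                "Threshold (Youden Index)": self.threshold,
                "Specificity": self.specificity,
                "Sensitivity": self.sensitivity,
                "Accuracy": self.accuracy,
                "PPV": self.ppv,
                "NPV": self.npv,
            },
            name=name,
        )


def confusion_metrics(scores, labels, threshold: float, auc: float | None = None) -> MetricsReport:
    """Confusion-matrix metrics with positives called at ``score >= threshold``.

    Ratios with a zero denominator are NaN and listed in ``undefined``.
    """
    scores, labels, n_pos, n_neg = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = n_pos - tp
    tn = n_neg - fp
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "ppv")
    npv = ratio(tn, tn + fn, "npv")
    acc = (tp + tn) / len(labels)
    if auc is None:
        auc = roc_auc(scores, labels).auc
    j = (sens if not math.isnan(sens) else 0.0) + (spec if not math.isnan(spec) else 0.0) - 1
    return MetricsReport(
        auc=float(auc),
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ppv=ppv,
        npv=npv,
        youden_j=j,
        undefined=tuple(undefined),
    )


def evaluate_scores(scores, labels) -> MetricsReport:
    """Full report at the Youden-optimal threshold."""
    curve = roc_auc(scores, labels)
    thr, _ = youden_threshold(curve)
    return confusion_metrics(scores, labels, thr, auc=curve.auc)


# ---------------------------------------------------------------------------
# paired AUC comparisons


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    statistic: float
    p_value: float
    method: str
    var_diff: float = float("nan")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (placement values) via midranks."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.r_[pos, neg])
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v_pos = (all_ranks[:m] - pos_ranks) / n  # P(score_neg < pos_i) + ties/2
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v_pos, v_neg


def delong_test(scores_a, scores_b, labels) -> AUCComparison:
    """DeLong's test for two correlated AUCs measured on the same rows.

    Placement values give each AUC and the covariance of the pair; the
    statistic is ``(AUC_a - AUC_b) / sqrt(var(diff))`` referred to the
    standard normal, two-sided.
    """
    scores_a, labels, m, n = _check_scores_labels(scores_a, labels)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_b.shape != scores_a.shape:
        raise ValueError("scores_a and scores_b must be paired")
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 observations per class")
    va_pos, va_neg = _placements(scores_a, labels)
    vb_pos, vb_neg = _placements(scores_b, labels)
    auc_a = float(va_pos.mean())
    auc_b = float(vb_pos.mean())
    s_pos = np.cov(np.vstack([va_pos, vb_pos]))  # 2x2, ddof=1
    s_neg = np.cov(np.vstack([va_neg, vb_neg]))
    cov = s_pos / m + s_neg / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            log.info("DeLong: zero variance with equal AUCs; p = 1 by convention")
            return AUCComparison(auc_a, auc_b, 0.0, 1.0, "delong", 0.0)
        raise ValueError("DeLong variance degenerate with unequal AUCs")
    z = diff / math.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a, auc_b, float(z), float(max(p, np.finfo(float).tiny)), "delong", var_diff)


def bootstrap_auc_test(
    scores_a, scores_b, labels, n_rep: int = 2000, seed: int = 0
) -> AUCComparison:
    """Paired bootstrap test for two correlated AUCs.

    Rows are resampled within each label class (so every replicate keeps
    both classes); the p-value is the normal approximation applied to the
    bootstrap distribution of ``AUC_a - AUC_b``.
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    scores_a, labels, n_pos, n_neg = _check_scores_labels(scores_a, labels)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_b.shape != scores_a.shape:
        raise ValueError("scores_a and scores_b must be paired")
    auc_a = mann_whitney_auc(scores_a, labels)
    auc_b = mann_whitney_auc(scores_b, labels)
    diff = auc_a - auc_b
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    diffs = np.empty(n_rep)
    for r in range(n_rep):
        idx = np.r_[
            pos_idx[rng.integers(0, n_pos, n_pos)],
            neg_idx[rng.integers(0, n_neg, n_neg)],
        ]
        lab = labels[idx]
        diffs[r] = mann_whitney_auc(scores_a[idx], lab) - mann_whitney_auc(scores_b[idx], lab)
    sd = float(diffs.std(ddof=1))
    if sd == 0:
        return AUCComparison(float(auc_a), float(auc_b), 0.0, 1.0, "bootstrap", 0.0)
    z = diff / sd
    p = 2 * stats.norm.sf(abs(z))
    return AUCComparison(float(auc_a), float(auc_b), float(z), float(p), "bootstrap", sd**2)


# ---------------------------------------------------------------------------
# logistic baseline


@dataclass
class LogisticResult:
    """Logistic fit on complete cases: scores plus fit diagnostics."""

    scores: np.ndarray  # fitted probabilities for retained rows
    kept_rows: np.ndarray  # indices into the cohort
    n_dropped: int
    converged: bool
    separation: bool
    params: pd.Series


def _design_matrix(cohort, covariates: list[str] | None):
    from .data_io import NOMINAL

    names = covariates if covariates is not None else cohort.names
    cols = {}
    for name in names:
        j = cohort.index_of(name)
        spec = cohort.schema[j]
        col = cohort.X[:, j]
        if spec.kind == NOMINAL and len(spec.levels) > 2:
            for k in range(1, len(spec.levels)):
                cols[f"{name}[{spec.levels[k]}]"] = (col == k).astype(float) + np.where(
                    np.isnan(col), np.nan, 0.0
                )
        else:
            cols[name] = col
    return pd.DataFrame(cols, index=range(cohort.n))


def logistic_baseline(cohort, covariates: list[str] | None = None) -> LogisticResult:
    """Main-effects logistic regression on complete cases.

    Rows with any missing covariate are dropped (listwise deletion, with
    the count logged and reported).  Quasi-separation is detected from
    fitted probabilities pinned at 0/1 and flagged, never silently.
    """
    design = _design_matrix(cohort, covariates)
    keep = ~design.isna().any(axis=1).to_numpy()
    kept_rows = np.flatnonzero(keep)
    n_dropped = cohort.n - len(kept_rows)
    if n_dropped:
        log.info("logistic baseline: dropped %d incomplete rows of %d", n_dropped, cohort.n)
    y = cohort.y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must survive listwise deletion")
    Xd = sm.add_constant(design.iloc[keep], has_constant="add")
    converged = True
    separation = False
    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        try:
            fit = sm.GLM(y, Xd, family=sm.families.Binomial()).fit(maxiter=100)
            converged = bool(fit.converged)
        except Exception as exc:  # perfect separation raises in some versions
            log.warning("logistic baseline failed to fit: %s", exc)
            p0 = y.mean()
            return LogisticResult(
                scores=np.full(len(y), p0),
                kept_rows=kept_rows,
                n_dropped=n_dropped,
                converged=False,
                separation=True,
                params=pd.Series(dtype=float),
            )
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    prob = np.asarray(fit.fittedvalues)
    eps = 1e-10
    if ((prob < eps) | (prob > 1 - eps)).any():
        separation = True
    return LogisticResult(
        scores=prob,
        kept_rows=kept_rows,
        n_dropped=n_dropped,
        converged=converged,
        separation=separation,
        params=fit.params,
    )


# ---------------------------------------------------------------------------
# association tests


@dataclass
class AssocResult:
    test: str
    statistic: float
    p_value: float
    n_used: int


def assoc_tests(cohort, covariate: str, group_by: str) -> AssocResult:
    """Association between a covariate and a grouping variable.

    Quantitative covariate: Wilcoxon-Mann-Whitney for two groups (exact
    enumeration when both groups have <= 8 observations and no ties,
    tie-corrected normal approximation otherwise), Kruskal-Wallis beyond
    two groups.  Two categorical variables: Pearson chi-squared without
    continuity correction.  Missing values are excluded pairwise.
    """
    jx = cohort.index_of(covariate)
    if group_by == cohort.outcome_name:
        g = cohort.y.astype(float)
        group_levels = None
    elif group_by == cohort.stratum_name:
        labs, g = np.unique(cohort.stratum, return_inverse=True)
        g = g.astype(float)
        group_levels = list(labs)
    else:
        jg = cohort.index_of(group_by)
        g = cohort.X[:, jg]
        group_levels = cohort.schema[jg].levels
    x = cohort.X[:, jx]
    ok = ~np.isnan(x) & ~np.isnan(g)
    x, g = x[ok], g[ok]
    spec = cohort.schema[jx]

    if spec.is_categorical:
        table = pd.crosstab(x, g).to_numpy()
        if (table.sum(axis=1) == 0).any() or table.shape[0] < 2 or table.shape[1] < 2:
            raise ValueError(f"association table between {covariate!r} and {group_by!r} is degenerate")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return AssocResult("chi-squared", float(chi2), float(p), int(ok.sum()))

    groups = [x[g == lvl] for lvl in np.unique(g)]
    if len(groups) < 2:
        raise ValueError(f"grouping {group_by!r} has fewer than 2 non-missing groups")
    for k, arr in enumerate(groups):
        if len(arr) < 2:
            name = group_levels[k] if group_levels is not None else k
            raise ValueError(f"group {name!r} of {group_by!r} has < 2 observations")
    if len(groups) == 2:
        a, b = groups
        ties = len(np.unique(np.r_[a, b])) < len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return AssocResult(f"wilcoxon-mann-whitney ({method})", float(res.statistic), float(res.pvalue), int(ok.sum()))
    res = stats.kruskal(*groups)
    return AssocResult("kruskal-wallis", float(res.statistic), float(res.pvalue), int(ok.sum()))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson rho with its t-distribution p-value; pairwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined: zero variance")
    rho, p = stats.pearsonr(xs, ys)
    return float(rho), float(p)
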
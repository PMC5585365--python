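"""Two-step run orchestration and artifact export.

``run_two_step`` performs the whole published pipeline on one dataset:
random-forest importance screening, representative-tree fitting with
honest cross-validated scores, a performance table for the tree and the
requested comparators (each at its own Youden threshold), pairwise AUC
comparison tests, and a DOT flow-chart of the representative tree.  All
randomness is seeded from the run config and a manifest records every
parameter, so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cart import GrowParams, RegressionTree, select_subtree_cv, stratified_fold_ids
from .data_io import Cohort
from .forest import ForestParams, grow_forest, select_drivers, tdni_importance
from .metrics import (
    bootstrap_auc_test,
    delong_test,
    evaluate_scores,
    logistic_baseline,
    roc_auc,
    youden_threshold,
)
from .rert import RERTParams, RERTResult, consensus_report, fit_rert

log = logging.getLogger(__name__)

COMPARATORS = ("he4", "ca125", "clinical_stage", "logistic", "single_cv_tree")
METRIC_ROWS = (
    "ROC-AUC",
    "Threshold (Youden Index)",
    "Specificity",
    "Sensitivity",
    "Accuracy",
    "PPV",
    "NPV",
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    output_dir: str
    forest: ForestParams = field(default_factory=ForestParams)
    rert: RERTParams = field(default_factory=RERTParams)
    comparators: tuple[str, ...] = COMPARATORS
    driver_cutoff: float = 60.0
    risk_threshold: float | None = None  # flow-chart coloring; default Youden on CV scores
    make_plot: bool = True

    def __post_init__(self) -> None:
        for c in self.comparators:
            if c not in COMPARATORS:
                raise ValueError(f"unknown comparator {c!r}; choose from {COMPARATORS}")


# ---------------------------------------------------------------------------
# flow-chart export


def export_flowchart(tree: RegressionTree, risk_threshold: float = 0.5) -> str:
    """Render a tree as DOT text, mirroring the published flow-chart style.

    Internal nodes carry the split condition; leaves are numbered left to
    right and show their event frequency and size.  Every root-to-leaf
    path is colored red when the leaf probability is at or above
    ``risk_threshold`` (high risk) and green otherwise.
    """
    lines = [
        "digraph rert {",
        '  node [shape=box, style="rounded,filled", fillcolor=white, fontname="Helvetica"];',
        '  edge [fontname="Helvetica"];',
    ]
    leaf_order = {nid: k + 1 for k, nid in enumerate(tree.leaf_ids())}

    # color each edge by the "riskiest" requirement below it: an edge is on
    # a red path iff some leaf under it is red; leaves fix their own color
    def leaf_color(nid: int) -> str:
        return "red" if tree.nodes[nid].yhat >= risk_threshold else "green"

    path_color: dict[int, str] = {}

    def walk(nid: int) -> None:
        node = tree.nodes[nid]
        if node.is_leaf:
            k = leaf_order[nid]
            color = leaf_color(nid)
            lines.append(
                f'  n{nid} [label="Leaf {k}\\nyhat = {node.yhat:.2f}\\nn = {node.n}", color={color}, penwidth=2];'
            )
            path_color[nid] = color
            return
        rule = node.split
        lines.append(f'  n{nid} [label="{_dot_escape(rule.describe("right"))}?"];')
        for child, answer, side in (
            (node.children[1], "yes", "right"),
            (node.children[0], "no", "left"),
        ):
            walk(child)
            lines.append(
                f'  n{nid} -> n{child} [label="{answer}", color={path_color[child]}, penwidth=2];'
            )
        path_color[nid] = (
            "red" if "red" in (path_color[node.children[0]], path_color[node.children[1]]) else "green"
        )

    walk(tree.root_id)
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


# ---------------------------------------------------------------------------
# comparator scoring


def single_cv_tree_scores(cohort: Cohort, grow: GrowParams, folds: int, seed: int) -> np.ndarray:
    """Honest out-of-fold scores of a single CV-pruned regression tree."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x51C)))
    fold = stratified_fold_ids(cohort.y, folds, rng)
    out = np.full(cohort.n, np.nan)
    from dataclasses import replace

    for f in range(folds):
        test = fold == f
        sub = cohort.subset(np.flatnonzero(~test))
        tree = select_subtree_cv(sub, replace(grow, seed=int(rng.integers(0, 2**31 - 1))))
        out[test] = tree.predict_matrix(cohort.X[test])
    return out


def comparator_scores(cohort: Cohort, name: str, config: RunConfig):
    """Scores and usable-row mask for one comparator.

    Single biomarkers are scored as the raw serum value (higher =
    riskier); clinical stage as its 0/1 code; rows missing the needed
    value are excluded from that comparator's metrics.
    """
    if name in ("he4", "ca125", "clinical_stage"):
        col = cohort.col(name)
        ok = ~np.isnan(col)
        return col[ok], ok
    if name == "logistic":
        fit = logistic_baseline(cohort)
        ok = np.zeros(cohort.n, dtype=bool)
        ok[fit.kept_rows] = True
        return fit.scores, ok
    if name == "single_cv_tree":
        scores = single_cv_tree_scores(
            cohort, config.rert.grow, config.rert.eval_folds, config.rert.seed
        )
        return scores, np.ones(cohort.n, dtype=bool)
    raise ValueError(f"unknown comparator {name!r}")


# ---------------------------------------------------------------------------
# the full run


def run_two_step(cohort: Cohort, config: RunConfig) -> dict:
    """Run importance screening then representative-tree fitting; write artifacts.

    Writes into ``config.output_dir``: ``importance.csv`` (+ ``importance.svg``
    when plotting is on), ``model.json``, ``metrics.csv``, ``auc_tests.csv``,
    ``flowchart.dot`` and ``manifest.json``.  Returns the artifact paths.
    On any stage failure the partial outputs are removed and the error is
    re-raised with the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        # step (i): forest screening
        stage = "forest importance"
        forest = grow_forest(cohort, config.forest)
        importance = tdni_importance(forest)
        drivers = select_drivers(importance, config.driver_cutoff)
        path = outdir / "importance.csv"
        importance.to_frame().to_csv(path, index=False)
        written.append(path)
        if config.make_plot:
            plot_path = _importance_plot(importance, outdir / "importance.svg")
            if plot_path is not None:
                written.append(plot_path)

        # step (ii): representative tree with honest CV scores
        stage = "representative tree"
        result = fit_rert(cohort, config.rert, compute_cv_scores=True)
        consensus = consensus_report(result)

        stage = "evaluation"
        table = {}
        rert_report = evaluate_scores(result.cv_scores, cohort.y)
        table["RERT with CV"] = rert_report.as_series()
        score_sets: dict[str, tuple[np.ndarray, np.ndarray]] = {
            "RERT with CV": (result.cv_scores, np.ones(cohort.n, dtype=bool))
        }
        names = {
            "he4": "HE4",
            "ca125": "CA125",
            "clinical_stage": "Clinical Stage",
            "logistic": "Logistic Regression",
            "single_cv_tree": "RT with CV",
        }
        for comp in config.comparators:
            scores, ok = comparator_scores(cohort, comp, config)
            table[names[comp]] = evaluate_scores(scores, cohort.y[ok]).as_series()
            full = np.full(cohort.n, np.nan)
            full[ok] = scores
            score_sets[names[comp]] = (full, ok)
        metrics_frame = pd.DataFrame(table).reindex(list(METRIC_ROWS))
        path = outdir / "metrics.csv"
        metrics_frame.to_csv(path, float_format="%.6g")
        written.append(path)

        stage = "AUC comparison tests"
        tests = []
        base_scores, base_ok = score_sets["RERT with CV"]
        for label, (scores, ok) in score_sets.items():
            if label == "RERT with CV":
                continue
            both = base_ok & ok
            a = base_scores[both]
            b = scores[both]
            labels = cohort.y[both]
            dl = delong_test(a, b, labels)
            bt = bootstrap_auc_test(a, b, labels, n_rep=2000, seed=config.rert.seed)
            tests.append(
                {
                    "comparison": f"RERT with CV vs {label}",
                    "auc_rert": dl.auc_a,
                    "auc_other": dl.auc_b,
                    "delong_z": dl.statistic,
                    "delong_p": dl.p_value,
                    "bootstrap_p": bt.p_value,
                    "n": int(both.sum()),
                }
            )
        path = outdir / "auc_tests.csv"
        pd.DataFrame(tests).to_csv(path, index=False, float_format="%.6g")
        written.append(path)

        stage = "model export"
        risk_thr = config.risk_threshold
        if risk_thr is None:
            risk_thr, _ = youden_threshold(roc_auc(result.cv_scores, cohort.y))
        model_doc = {
            "version": __version__,
            "representative": result.representative.to_dict(),
            "selection_auc": result.selection_auc,
            "nested_cv_auc": result.nested_cv_auc,
            "ensemble_auc_histogram": _histogram(result.ensemble_aucs),
            "consensus": {
                "n_above_floor": consensus.n_above_floor,
                "modal_root_covariate": consensus.modal_root_covariate,
                "agreement_fraction": consensus.agreement_fraction,
                "threshold_iqr": consensus.threshold_iqr,
            },
            "cv_scores": [round(float(s), 10) for s in result.cv_scores],
            "drivers": drivers,
            "risk_threshold": risk_thr,
        }
        path = outdir / "model.json"
        path.write_text(json.dumps(model_doc, indent=1, sort_keys=True))
        written.append(path)

        path = outdir / "flowchart.dot"
        path.write_text(export_flowchart(result.representative, risk_thr))
        written.append(path)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "n": cohort.n,
            "outcome_prevalence": float(cohort.y.mean()),
            "forest_params": asdict(config.forest),
            "rert_params": asdict(config.rert),
            "driver_cutoff": config.driver_cutoff,
            "comparators": list(config.comparators),
            "seeds": {"forest": config.forest.seed, "rert": config.rert.seed},
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        written.append(path)
    except Exception as exc:
        for p in written:
            try:
                os.unlink(p)
            except OSError:
                pass
        raise RuntimeError(f"two-step run failed during stage: {stage}") from exc

    return {p.name: str(p) for p in written}


def _histogram(values: np.ndarray, bins: int = 20) -> dict:
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return {"counts": counts.tolist(), "edges": [round(float(e), 10) for e in edges]}


def _importance_plot(importance, path: Path) -> Path | None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is optional
        log.info("matplotlib unavailable; skipping importance plot")
        return None
    frame = importance.to_frame().sort_values("relative")
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(frame) + 1))
    ax.barh(frame["covariate"], frame["relative"], color="steelblue")
    ax.axvline(60, color="firebrick", linestyle="--", linewidth=1)
    ax.set_xlabel("Relative importance (TDNI, max = 100)")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return path
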
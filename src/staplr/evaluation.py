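"""Repeated double (nested) cross-validation, metrics, selection-frequency
summaries, and the flat elastic-net benchmark.

The protocol: in every repeat, subjects are split into ``outer_folds``
stratified folds; for each outer fold the *entire* training procedure —
including every internal cross-validation loop that selects tuning
parameters — runs on the training portion, and the held-out portion is used
only to compute AUC and accuracy. Repeats redraw the fold allocation from a
fresh seed; the data are never reshuffled in place. With the defaults
(10 outer folds × 10 repeats) this yields 100 fitted models and 100 metric
rows, and per-view coefficient snapshots from which selection proportions
(the fraction of fits with a nonzero coefficient) are computed.

The benchmark fits one logistic elastic net over the flat feature matrix,
ignoring the view structure entirely, selecting the mixing weight α (grid
0, 0.1, …, 1) and the penalty λ (100-value log-spaced path with
λ_min/λ_max = 0.01) jointly on the inner loop, and summarizes each fitted
model per view by the number of nonzero coefficients and the L2 norm of the
view's coefficient sub-vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .data import FoldPlan, MultiViewDataset, ViewHierarchy, make_folds
from .glm import (
    PenaltySpec,
    binomial_deviance,
    compute_lambda_path,
    fit_path,
    fit_penalized_logistic,
)
from .stacking import StaplrConfig, _derive_seed, coefficient_table, fit_staplr, predict_stacked

logger = logging.getLogger("staplr")

__all__ = [
    "EvaluationConfig",
    "EvaluationResult",
    "auc",
    "accuracy",
    "nested_cv_evaluate",
    "selection_proportions",
    "elastic_net_benchmark",
]

ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))  # 0, 0.1, ..., 1.0


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Probability a random case outscores a random control, ties credited ½
    (the rank / Mann–Whitney estimator of the area under the ROC curve)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def accuracy(y: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of subjects with (score >= threshold) equal to y; scores
    exactly at the threshold predict class 1."""
    y = np.asarray(y)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float((pred == y).mean())


@dataclass(frozen=True)
class EvaluationConfig:
    """Nested-CV protocol settings.

    ``inner_folds`` is the λ-selection (and, for the benchmark, (α, λ))
    loop; ``learner`` is one of ``hierarchical``, ``two_level`` (all leaves
    directly under the root) or ``elastic_net``. ``staplr`` carries solver
    settings for the stacked learners; its fold counts default to this
    config's.
    """

    outer_folds: int = 10
    inner_folds: int = 10
    repeats: int = 10
    seed: int = 0
    learner: str = "hierarchical"
    staplr: StaplrConfig | None = None
    n_lambda: int = 100
    epsilon: float = 0.01
    alpha_grid: tuple = ALPHA_GRID
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.learner not in {"hierarchical", "two_level", "elastic_net"}:
            raise ValueError(f"unknown learner '{self.learner}'")


@dataclass
class EvaluationResult:
    """Metrics and coefficient snapshots across repeats × outer folds.

    ``metrics`` has one row per (repeat, fold) with AUC and accuracy;
    ``coefficients`` holds combiner-level snapshots for stacked learners;
    ``view_summary`` holds per-view nonzero counts and L2 norms for the
    elastic-net benchmark; ``fold_records`` is the instrumented bookkeeping
    of train/test row membership used to audit protocol isolation.
    """

    metrics: pd.DataFrame
    coefficients: pd.DataFrame | None = None
    view_summary: pd.DataFrame | None = None
    fold_records: list = field(default_factory=list)
    config: EvaluationConfig | None = None

    def summary(self) -> dict:
        out = {
            "mean_auc": float(self.metrics["auc"].mean()),
            "sd_auc": float(self.metrics["auc"].std(ddof=1)) if len(self.metrics) > 1 else 0.0,
            "mean_accuracy": float(self.metrics["accuracy"].mean()),
            "sd_accuracy": float(self.metrics["accuracy"].std(ddof=1)) if len(self.metrics) > 1 else 0.0,
            "n_fits": int(len(self.metrics)),
        }
        return out


def _staplr_config_for(eval_config: EvaluationConfig, seed: int) -> StaplrConfig:
    base = eval_config.staplr or StaplrConfig(
        prediction_folds=eval_config.inner_folds,
        lambda_folds=eval_config.inner_folds,
        n_lambda=eval_config.n_lambda,
        epsilon=eval_config.epsilon,
    )
    return replace(base, seed=seed)


def nested_cv_evaluate(
    dataset: MultiViewDataset,
    hierarchy: ViewHierarchy,
    eval_config: EvaluationConfig | None = None,
) -> EvaluationResult:
    """Run the repeated double (nested) cross-validation protocol.

    For each repeat × outer fold the full training procedure (with all its
    internal cross-validation) sees only the training ~90%; the held-out fold
    contributes nothing but the final metric evaluation.
    """
    eval_config = eval_config or EvaluationConfig()
    if eval_config.learner == "elastic_net":
        return elastic_net_benchmark(dataset, eval_config)
    if eval_config.learner == "two_level":
        hierarchy = ViewHierarchy.from_nested({hierarchy.root: list(hierarchy.leaves)})
    hierarchy.validate_against(dataset)
    metric_rows = []
    coef_rows = []
    records = []
    for rep in range(eval_config.repeats):
        outer = make_folds(dataset.y, eval_config.outer_folds, _derive_seed(eval_config.seed, "outer", rep))
        for f in range(outer.n_folds):
            tr, te = outer.train_rows(f), outer.test_rows(f)
            train = dataset.subset(tr)
            cfg = _staplr_config_for(eval_config, _derive_seed(eval_config.seed, "fit", rep, f))
            try:
                model = fit_staplr(train, hierarchy, cfg)
            except Exception as exc:
                raise RuntimeError(f"training failed at repeat {rep}, outer fold {f}: {exc}") from exc
            test_frame = pd.DataFrame(dataset.X[te], columns=dataset.feature_ids)
            scores = predict_stacked(model, test_frame)
            metric_rows.append(
                (rep, f, auc(dataset.y[te], scores), accuracy(dataset.y[te], scores, eval_config.threshold))
            )
            snap = coefficient_table(model, "all")
            snap = snap[snap["level"] != "base"]
            for _, r in snap.iterrows():
                coef_rows.append((rep, f, r["node"], r["child"], r["level"], r["coefficient"]))
            records.append({"repeat": rep, "fold": f, "train_rows": tr, "test_rows": te})
    return EvaluationResult(
        metrics=pd.DataFrame(metric_rows, columns=["repeat", "fold", "auc", "accuracy"]),
        coefficients=pd.DataFrame(
            coef_rows, columns=["repeat", "fold", "node", "child", "level", "coefficient"]
        ),
        fold_records=records,
        config=eval_config,
    )


def selection_proportions(result: EvaluationResult) -> pd.DataFrame:
    """Per view/node: the fraction of fitted models in which its coefficient
    was nonzero (the numbers printed atop the coefficient box plots)."""
    if result.coefficients is not None and len(result.coefficients):
        g = (
            result.coefficients.assign(selected=lambda d: d["coefficient"] != 0.0)
            .groupby(["node", "child", "level"], sort=False)["selected"]
            .mean()
            .reset_index()
            .rename(columns={"selected": "proportion_nonzero"})
        )
        return g
    if result.view_summary is not None:
        g = (
            result.view_summary.assign(selected=lambda d: d["n_nonzero"] > 0)
            .groupby("view", sort=False)["selected"]
            .mean()
            .reset_index()
            .rename(columns={"selected": "proportion_nonzero"})
        )
        return g
    raise ValueError("result holds no coefficient snapshots")


# -- elastic-net benchmark ---------------------------------------------------


def _select_alpha_lambda(
    X: np.ndarray,
    y: np.ndarray,
    inner_plan: FoldPlan,
    alpha_grid: Sequence[float],
    n_lambda: int,
    epsilon: float,
) -> tuple[float, float]:
    """Joint (α, λ) selection minimizing inner-CV deviance; shared inner folds
    across α; ties go to the larger α (sparser), then the larger λ."""
    best = None
    for alpha in alpha_grid:
        penalty = PenaltySpec(alpha=float(alpha), standardize=True)
        path = compute_lambda_path(X, y, penalty, n_lambda=n_lambda, epsilon=epsilon)
        lams = path.values
        oof = np.empty((y.shape[0], lams.size))
        for f in range(inner_plan.n_folds):
            tr, te = inner_plan.train_rows(f), inner_plan.test_rows(f)
            b0s, coefs = fit_path(X[tr], y[tr], penalty, lams)
            oof[te, :] = expit(X[te] @ coefs.T + b0s)
        curve = np.array([binomial_deviance(y, oof[:, k]) for k in range(lams.size)])
        k = int(np.argmin(curve))
        dev = float(curve[k])
        if best is None or dev <= best[0]:  # <=: later (larger) alpha wins ties
            best = (dev, float(alpha), float(lams[k]))
    return best[1], best[2]


def elastic_net_benchmark(
    dataset: MultiViewDataset,
    eval_config: EvaluationConfig | None = None,
) -> EvaluationResult:
    """Nested-CV evaluation of the flat logistic elastic net.

    Ignores the hierarchy entirely: one model over all features. Besides the
    usual metrics, every fitted model is summarized per leaf view by the
    count of nonzero coefficients and the L2 norm of that view's coefficient
    sub-vector.
    """
    eval_config = eval_config or EvaluationConfig(learner="elastic_net")
    X, y = dataset.X, dataset.y
    view_cols = {v: dataset.view_columns(v) for v in dataset.views}
    metric_rows, summary_rows, records = [], [], []
    for rep in range(eval_config.repeats):
        outer = make_folds(y, eval_config.outer_folds, _derive_seed(eval_config.seed, "outer", rep))
        for f in range(outer.n_folds):
            tr, te = outer.train_rows(f), outer.test_rows(f)
            inner = make_folds(
                y[tr], eval_config.inner_folds, _derive_seed(eval_config.seed, "inner", rep, f)
            )
            alpha, lam = _select_alpha_lambda(
                X[tr], y[tr].astype(float), inner, eval_config.alpha_grid,
                eval_config.n_lambda, eval_config.epsilon,
            )
            model = fit_penalized_logistic(
                X[tr], y[tr].astype(float), PenaltySpec(alpha=alpha, standardize=True), lam,
                feature_names=dataset.feature_ids, raise_on_nonconvergence=False,
            )
            scores = model.predict_proba(X[te])
            metric_rows.append(
                (rep, f, auc(y[te], scores), accuracy(y[te], scores, eval_config.threshold))
            )
            for v, cols in view_cols.items():
                sub = model.coefficients[cols]
                summary_rows.append(
                    (rep, f, v, alpha, lam, int(np.count_nonzero(sub)), float(np.linalg.norm(sub)))
                )
            records.append({"repeat": rep, "fold": f, "train_rows": tr, "test_rows": te})
    return EvaluationResult(
        metrics=pd.DataFrame(metric_rows, columns=["repeat", "fold", "auc", "accuracy"]),
        view_summary=pd.DataFrame(
            summary_rows,
            columns=["repeat", "fold", "view", "alpha", "lambda", "n_nonzero", "l2_norm"],
        ),
        fold_records=records,
        config=eval_config,
    )
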
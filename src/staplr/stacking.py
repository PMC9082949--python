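"""Hierarchical stacked penalized logistic regression over a rooted tree of views.

The algorithm, for each node of the hierarchy from the leaves up:

1. leaves: fit a base learner (ridge by default, λ chosen by internal
   cross-validation) on the view's own feature block, and produce a vector
   of cross-validated out-of-sample predictions — each subject's value comes
   from a model whose training data, *including* its internal λ-selection
   loop, excluded that subject's fold;
2. internal nodes: collect the children's cross-validated predictions
   column-wise into a prediction matrix, fit the combiner (nonnegative
   lasso by default) on it, and produce that node's own cross-validated
   predictions for its parent;
3. root: fit the meta learner on its children's prediction matrix.

Depth 2 (all leaves under the root) recovers the original two-level stacked
model with a single combiner over all leaf predictions; deeper and
mixed-depth trees are handled by the same recursion.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import FoldPlan, MultiViewDataset, ViewHierarchy, make_folds
from .glm import (
    NONNEGATIVE_LASSO,
    RIDGE,
    PenalizedLogisticModel,
    PenaltySpec,
    fit_cv_logistic,
)

logger = logging.getLogger("staplr")

__all__ = [
    "StaplrConfig",
    "PredictionMatrix",
    "StackedClassifier",
    "cross_validated_predictions",
    "fit_staplr",
    "predict_stacked",
    "coefficient_table",
]


def _derive_seed(base: int, *tokens) -> int:
    """Deterministic, platform-stable sub-seed below 2**31."""
    h = zlib.crc32(repr(tokens).encode())
    return int(np.random.SeedSequence([int(base) % (2**31), h]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class StaplrConfig:
    """Configuration of the stacked fit.

    ``prediction_folds`` is the cross-validation used to generate each node's
    out-of-sample predictions for its parent; ``lambda_folds`` the nested loop
    selecting λ inside every single fit. Penalties default to ridge at the
    leaves and the nonnegative lasso at every internal node and the root, but
    any node level is configurable. ``reuse_level_folds`` re-uses the
    base-level fold partition at every level instead of drawing a fresh one
    per level.
    """

    prediction_folds: int = 10
    lambda_folds: int = 10
    seed: int = 0
    leaf_penalty: PenaltySpec = RIDGE
    node_penalty: PenaltySpec = NONNEGATIVE_LASSO
    n_lambda: int = 100
    epsilon: float = 0.01
    reuse_level_folds: bool = False
    max_iter: int = 200
    tol: float = 1e-8
    fold_plans: Mapping[int, FoldPlan] | None = None  # per tree level overrides

    def __post_init__(self) -> None:
        if self.prediction_folds < 2 or self.lambda_folds < 2:
            raise ValueError("fold counts must be >= 2")


@dataclass
class PredictionMatrix:
    """Cross-validated probabilities of one node's children, one column per
    child in hierarchy order; all entries in [0, 1]."""

    node_id: str
    child_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.child_ids):
            raise ValueError("one column per child required")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("prediction matrix entries must lie in [0, 1]")


@dataclass
class StackedClassifier:
    """A fitted hierarchical stacked model.

    ``base_models`` maps each leaf view to its feature-level model;
    ``node_models`` maps every internal node (including the root) to the
    combiner fitted on its children's cross-validated predictions — all
    combiner slopes are >= 0 under the default nonnegative lasso. ``ybar`` is
    the training class-1 proportion, the default clamp value of the minority
    report measure. ``cv_predictions`` keeps each non-root node's
    cross-validated prediction vector (used e.g. for empirical importance
    bounds).
    """

    hierarchy: ViewHierarchy
    base_models: dict[str, PenalizedLogisticModel]
    node_models: dict[str, PenalizedLogisticModel]
    ybar: float
    config: StaplrConfig
    cv_predictions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def meta_model(self) -> PenalizedLogisticModel:
        return self.node_models[self.hierarchy.root]

    def predict_proba(self, X_new, feature_ids: Sequence[str] | None = None) -> np.ndarray:
        return predict_stacked(self, X_new, feature_ids=feature_ids)

    # -- serialization -------------------------------------------------------

    def to_dict(self, include_predictions: bool = True) -> dict:
        return {
            "hierarchy": self.hierarchy.to_nested(),
            "ybar": self.ybar,
            "base_models": {v: m.to_dict() for v, m in self.base_models.items()},
            "node_models": {s: m.to_dict() for s, m in self.node_models.items()},
            "cv_predictions": (
                {k: v.tolist() for k, v in self.cv_predictions.items()}
                if include_predictions
                else {}
            ),
            "config": {
                "prediction_folds": self.config.prediction_folds,
                "lambda_folds": self.config.lambda_folds,
                "seed": self.config.seed,
                "n_lambda": self.config.n_lambda,
                "epsilon": self.config.epsilon,
                "reuse_level_folds": self.config.reuse_level_folds,
            },
        }

    def save(self, path: str | Path, include_predictions: bool = True) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_predictions), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "StackedClassifier":
        hier = ViewHierarchy.from_nested(d["hierarchy"])
        cfg = StaplrConfig(**d.get("config", {}))
        return cls(
            hierarchy=hier,
            base_models={v: PenalizedLogisticModel.from_dict(m) for v, m in d["base_models"].items()},
            node_models={s: PenalizedLogisticModel.from_dict(m) for s, m in d["node_models"].items()},
            ybar=float(d["ybar"]),
            config=cfg,
            cv_predictions={k: np.asarray(v) for k, v in d.get("cv_predictions", {}).items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "StackedClassifier":
        return cls.from_dict(json.loads(Path(path).read_text()))


def cross_validated_predictions(
    X: np.ndarray,
    y: np.ndarray,
    penalty: PenaltySpec,
    fold_plan: FoldPlan,
    *,
    lambda_folds: int = 10,
    n_lambda: int = 100,
    epsilon: float = 0.01,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> np.ndarray:
    """Out-of-sample probabilities under ``fold_plan``.

    For every fold, a model is trained on the remaining folds — with its own
    nested λ-selection cross-validation over the *training* rows only — and
    evaluated on the held-out fold. A held-out subject's label therefore
    cannot influence its own prediction (given the fold plan); the nested
    fold seeds depend only on ``seed`` and the fold index, never on ``y``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.empty(y.shape[0])
    for f in range(fold_plan.n_folds):
        tr = fold_plan.train_rows(f)
        te = fold_plan.test_rows(f)
        inner_plan = make_folds(y[tr].astype(int), lambda_folds, _derive_seed(seed, "inner", f))
        try:
            model = fit_cv_logistic(
                X[tr], y[tr], penalty,
                n_lambda=n_lambda, epsilon=epsilon, fold_plan=inner_plan,
                max_iter=max_iter, tol=tol,
            )
        except Exception as exc:  # annotate with the fold for diagnosis
            raise RuntimeError(f"base fit failed in prediction fold {f}: {exc}") from exc
        out[te] = model.predict_proba(X[te])
    return out


def fit_staplr(
    dataset: MultiViewDataset,
    hierarchy: ViewHierarchy,
    config: StaplrConfig | None = None,
) -> StackedClassifier:
    """Fit the hierarchical stacked classifier.

    Works bottom-up through the tree: every node's model is fitted (with
    internal λ cross-validation) on its input block, and every non-root node
    additionally produces cross-validated predictions consumed by its parent.
    All nodes at the same tree level share one fold partition so the
    combiner's training columns are comparable; fresh partitions are drawn
    per level unless ``reuse_level_folds`` is set.
    """
    config = config or StaplrConfig()
    hierarchy.validate_against(dataset)
    y = dataset.y.astype(float)

    # one prediction fold plan per tree level
    fold_plans: dict[int, FoldPlan] = dict(config.fold_plans or {})

    def level_plan(level: int) -> FoldPlan:
        key = 0 if config.reuse_level_folds else level
        if key not in fold_plans:
            fold_plans[key] = make_folds(
                dataset.y, config.prediction_folds, _derive_seed(config.seed, "level", key)
            )
        return fold_plans[key]

    base_models: dict[str, PenalizedLogisticModel] = {}
    node_models: dict[str, PenalizedLogisticModel] = {}
    cv_predictions: dict[str, np.ndarray] = {}

    def fit_node(node: str) -> None:
        is_leaf = hierarchy.is_leaf(node)
        if is_leaf:
            Xn = dataset.view_matrix(node)
            names = dataset.view_feature_ids(node)
            penalty = config.leaf_penalty
        else:
            for child in hierarchy.children[node]:
                fit_node(child)
            Xn = np.column_stack([cv_predictions[c] for c in hierarchy.children[node]])
            names = list(hierarchy.children[node])
            penalty = config.node_penalty
        lam_plan = make_folds(dataset.y, config.lambda_folds, _derive_seed(config.seed, "lambda", node))
        try:
            model = fit_cv_logistic(
                Xn, y, penalty,
                n_lambda=config.n_lambda, epsilon=config.epsilon,
                fold_plan=lam_plan, feature_names=names,
                max_iter=config.max_iter, tol=config.tol,
            )
        except Exception as exc:
            raise RuntimeError(f"fit failed at node '{node}': {exc}") from exc
        if is_leaf:
            base_models[node] = model
        else:
            node_models[node] = model
        if node != hierarchy.root:
            plan = level_plan(hierarchy.node_depth(node))
            cv_predictions[node] = cross_validated_predictions(
                Xn, y, penalty, plan,
                lambda_folds=config.lambda_folds,
                n_lambda=config.n_lambda, epsilon=config.epsilon,
                seed=_derive_seed(config.seed, "cvpred", node),
                max_iter=config.max_iter, tol=config.tol,
            )

    fit_node(hierarchy.root)
    return StackedClassifier(
        hierarchy=hierarchy,
        base_models=base_models,
        node_models=node_models,
        ybar=dataset.ybar,
        config=config,
        cv_predictions=cv_predictions,
    )


def predict_stacked(
    model: StackedClassifier,
    X_new,
    feature_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Evaluate the composed classifier: each leaf model's probabilities are
    fed to its parent combiner, recursively up to the root, every stage
    applying ψ(intercept + weighted inputs).

    ``X_new`` may be a DataFrame (columns matched by name), a
    :class:`MultiViewDataset`, or an array whose columns follow
    ``feature_ids`` (defaulting to the training feature order).
    """
    if isinstance(X_new, MultiViewDataset):
        frame = pd.DataFrame(X_new.X, columns=X_new.feature_ids)
    elif isinstance(X_new, pd.DataFrame):
        frame = X_new
    else:
        arr = np.asarray(X_new, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if feature_ids is None:
            feature_ids = [n for v in model.hierarchy.leaves for n in model.base_models[v].feature_names]
        frame = pd.DataFrame(arr, columns=list(feature_ids))

    hier = model.hierarchy

    def rec(node: str) -> np.ndarray:
        if hier.is_leaf(node):
            return model.base_models[node].predict_proba(frame)
        kids = hier.children[node]
        Z = np.column_stack([rec(k) for k in kids])
        m = model.node_models[node]
        return expit(m.intercept + Z @ m.coefficients)

    return rec(hier.root)


def coefficient_table(model: StackedClassifier, level: str = "all") -> pd.DataFrame:
    """Per-level coefficient listing as ``(node, child_view, level, coefficient)``.

    ``level`` is one of ``meta`` (root combiner), ``intermediate`` (other
    internal nodes), ``base`` (per-feature leaf coefficients) or ``all``.
    """
    if level not in {"meta", "intermediate", "base", "all"}:
        raise ValueError(f"unknown level '{level}'")
    rows = []
    hier = model.hierarchy
    if level in {"meta", "all"}:
        m = model.node_models[hier.root]
        for child, c in zip(m.feature_names, m.coefficients):
            rows.append((hier.root, child, "meta", float(c)))
    if level in {"intermediate", "all"}:
        for node in hier.internal_nodes:
            m = model.node_models[node]
            for child, c in zip(m.feature_names, m.coefficients):
                rows.append((node, child, "intermediate", float(c)))
    if level in {"base", "all"}:
        for v in hier.leaves:
            m = model.base_models[v]
            for feat, c in zip(m.feature_names, m.coefficients):
                rows.append((v, feat, "base", float(c)))
    return pd.DataFrame(rows, columns=["node", "child", "level", "coefficient"])
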
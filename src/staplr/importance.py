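"""View-importance measures for a fitted stacked classifier.

The central quantity is the *minority report measure* (MRM): the change in
the stacked classifier's final output when a single leaf view's prediction
moves from a baseline value ``a`` to a probe value ``b`` while every other
leaf's prediction is clamped at ``c``. For the default depth-3 tree with
intermediate intercepts β̂0[s], coefficients β̂i[s], meta intercept ω̂0 and
meta weights ω̂s, probing leaf (s, i) at value b gives

    g(X[s,i], b, c) = ψ( ω̂0 + ω̂s ψ(β̂0[s] + β̂i[s] b + Σ_{j≠i} β̂j[s] c)
                         + Σ_{k≠s} ω̂k ψ(β̂0[k] + Σ_j β̂j[k] c) ),

and MRM = g(b, c) − g(a, c). Defaults are a = 0, b = 1 (the theoretical
extremes) and c = ȳ, the training class-1 proportion; an empirical mode uses
each view's own cross-validated predictions' observed min/max as (a, b)
instead. The measure depends only on the stored coefficients — no
resampling or refitting — and, because the combiner weights are
nonnegative, lies in [0, 1), making leaf views comparable *across* branches
where raw combiner coefficients are not.

For trees of arbitrary depth the same definition applies recursively: set
the target leaf's prediction to the probe value, clamp every other leaf at
``c``, and evaluate the composed classifier; for depth-3 trees this reduces
exactly to the formula above.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.special import expit

from .data import MultiViewDataset
from .stacking import StackedClassifier

__all__ = ["MRMConfig", "MRMResult", "mrm_g", "mrm_view", "mrm_all", "mrm_node"]


@dataclass(frozen=True)
class MRMConfig:
    """(a, b, c) choice for the minority report measure.

    ``mode='theoretical'`` uses (a, b) as given (defaults 0 and 1);
    ``mode='empirical'`` replaces them per view with the observed min/max of
    that view's cross-validated predictions. ``c=None`` means the training
    class-1 proportion stored in the model.
    """

    a: float = 0.0
    b: float = 1.0
    c: float | None = None
    mode: str = "theoretical"

    def __post_init__(self) -> None:
        if self.mode not in {"theoretical", "empirical"}:
            raise ValueError(f"unknown mode '{self.mode}'")
        for name, v in (("a", self.a), ("b", self.b)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.c is not None and not 0.0 <= self.c <= 1.0:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if self.b < self.a:
            raise ValueError("b must not be below a")  # b == a is the degenerate MRM = 0


@dataclass
class MRMResult:
    """Per-leaf-view MRM values under a common (a, b, c)."""

    table: pd.DataFrame  # columns: view, branch, mrm, a, b, c

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("mrm", ascending=False).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _resolve_c(model: StackedClassifier, config: MRMConfig) -> float:
    return model.ybar if config.c is None else float(config.c)


def _check_leaf(model: StackedClassifier, view: str) -> None:
    if view not in model.hierarchy.leaves:
        raise KeyError(f"'{view}' is not a leaf view of the fitted model")


def mrm_g(model: StackedClassifier, view: str, value: float, c: float) -> float:
    """Root output with leaf ``view``'s prediction set to ``value`` and every
    other leaf clamped at ``c``; computed purely from stored coefficients."""
    _check_leaf(model, view)
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c}")
    hier = model.hierarchy

    def rec(node: str) -> float:
        if hier.is_leaf(node):
            return float(value) if node == view else float(c)
        m = model.node_models[node]
        vals = np.array([rec(k) for k in hier.children[node]])
        return float(expit(m.intercept + float(m.coefficients @ vals)))

    return rec(hier.root)


def mrm_node(model: StackedClassifier, node: str, value: float, c: float) -> float:
    """Experimental: root output probing an *internal* node's prediction
    (clamping all other root-ward inputs at ``c``), extending the measure to
    non-leaf views."""
    hier = model.hierarchy
    if node not in hier.nodes or node == hier.root:
        raise KeyError(f"'{node}' is not a non-root node")

    def rec(nd: str) -> float:
        if nd == node:
            return float(value)
        if hier.is_leaf(nd):
            return float(c)
        m = model.node_models[nd]
        vals = np.array([rec(k) for k in hier.children[nd]])
        return float(expit(m.intercept + float(m.coefficients @ vals)))

    return rec(hier.root)


def mrm_view(
    model: StackedClassifier,
    view: str,
    config: MRMConfig | None = None,
    *,
    node: bool = False,
) -> float:
    """MRM of one leaf view: g(view, b, c) − g(view, a, c)."""
    config = config or MRMConfig()
    c = _resolve_c(model, config)
    a, b = config.a, config.b
    if config.mode == "empirical":
        if view not in model.cv_predictions:
            raise ValueError(
                "empirical mode needs the view's stored cross-validated predictions"
            )
        z = model.cv_predictions[view]
        a, b = float(np.min(z)), float(np.max(z))
    probe = mrm_node if node else mrm_g
    return probe(model, view, b, c) - probe(model, view, a, c)


def mrm_all(
    model: StackedClassifier,
    dataset: MultiViewDataset | None = None,
    config: MRMConfig | None = None,
) -> MRMResult:
    """One MRM per leaf view under a common (a, b, c), sortable across branches.

    ``dataset`` may supply ȳ for the clamp value c when the model was loaded
    without one; otherwise the training ȳ stored in the model is used.
    """
    config = config or MRMConfig()
    if config.mode == "empirical" and not model.cv_predictions and dataset is None:
        raise ValueError("empirical mode requires stored predictions or a dataset")
    c = model.ybar if config.c is None else float(config.c)
    if config.c is None and dataset is not None and model.ybar is None:
        c = dataset.ybar
    rows = []
    for view in model.hierarchy.leaves:
        a, b = config.a, config.b
        if config.mode == "empirical":
            z = model.cv_predictions.get(view)
            if z is None:
                raise ValueError(f"no stored cross-validated predictions for view '{view}'")
            a, b = float(np.min(z)), float(np.max(z))
        val = mrm_g(model, view, b, c) - mrm_g(model, view, a, c)
        branch = model.hierarchy.branch_of(view)
        rows.append((view, branch, val, a, b, c))
    return MRMResult(pd.DataFrame(rows, columns=["view", "branch", "mrm", "a", "b", "c"]))


def plot_mrm(result: MRMResult, ax=None):
    """Optional bar plot of MRM values grouped by branch (requires matplotlib)."""
    import matplotlib.pyplot as plt

    table = result.table
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.4 * len(table)), 3))
    branches = {b: i for i, b in enumerate(table["branch"].unique())}
    colors = plt.cm.tab10(np.linspace(0, 1, max(len(branches), 2)))
    order = table.sort_values(["branch"], kind="stable")
    ax.bar(
        np.arange(len(order)),
        order["mrm"],
        color=[colors[branches[b]] for b in order["branch"]],
    )
    ax.set_xticks(np.arange(len(order)))
    ax.set_xticklabels(order["view"], rotation=90)
    ax.set_ylabel("minority report measure")
    return ax
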
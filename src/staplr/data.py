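"""Domain containers and I/O for multi-view binary-classification data.

A *view* is a named set of feature columns treated as a unit. Views may be
nested inside higher-level views (e.g. MRI measures nested inside scan
types), described by a rooted :class:`ViewHierarchy` whose leaves are the
views that actually own features.

Subjects are rows, features are columns. Features are matched by column
name between training and prediction, never by position. The outcome is
coded {0, 1} with 1 = case. Missing values are a hard error: this package
never imputes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger("staplr")

__all__ = [
    "MultiViewDataset",
    "ViewHierarchy",
    "FoldPlan",
    "load_multiview",
    "save_multiview",
    "load_hierarchy",
    "make_folds",
]


class DataValidationError(ValueError):
    """Raised when a dataset or hierarchy violates a structural invariant."""


@dataclass
class MultiViewDataset:
    """A subjects × features table with a binary outcome and a feature→view map.

    Parameters
    ----------
    X : (n_subjects, p_features) float array
        Feature values, no missing entries allowed.
    y : (n_subjects,) int array
        Binary outcome, 1 = case, 0 = control; both classes must occur.
    feature_ids : sequence of str
        Column names, one per feature, unique.
    view_of_feature : sequence of str
        Leaf-view id of each feature (parallel to ``feature_ids``).
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    view_of_feature: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.view_of_feature = [str(v) for v in self.view_of_feature]
        self._validate()
        # column indices per leaf view, insertion-ordered
        self._view_cols: dict[str, np.ndarray] = {}
        for j, v in enumerate(self.view_of_feature):
            self._view_cols.setdefault(v, [])  # type: ignore[arg-type]
        for v in self._view_cols:
            self._view_cols[v] = np.array(
                [j for j, w in enumerate(self.view_of_feature) if w == v], dtype=int
            )

    def _validate(self) -> None:
        if self.X.ndim != 2:
            raise DataValidationError("X must be a 2-d matrix")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise DataValidationError(
                f"outcome length {self.y.shape} does not match {n} subjects"
            )
        if not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise DataValidationError(
                f"missing/non-finite value in feature "
                f"'{self.feature_ids[bad[1]]}' (row {bad[0]}); imputation is not supported"
            )
        uniq = np.unique(self.y)
        if not np.isin(uniq, [0, 1]).all():
            bad_val = uniq[~np.isin(uniq, [0, 1])][0]
            raise DataValidationError(f"non-binary outcome value {bad_val!r}")
        if uniq.size < 2:
            raise DataValidationError("outcome must contain both classes 0 and 1")
        self.y = self.y.astype(np.int64)
        if len(self.feature_ids) != p or len(self.view_of_feature) != p:
            raise DataValidationError("feature_ids / view_of_feature length mismatch")
        if len(set(self.feature_ids)) != p:
            seen: set[str] = set()
            dup = next(f for f in self.feature_ids if f in seen or seen.add(f))
            raise DataValidationError(f"duplicate feature id '{dup}'")

    # -- accessors -----------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def views(self) -> list[str]:
        """Leaf-view ids in first-appearance order."""
        return list(self._view_cols)

    @property
    def ybar(self) -> float:
        """Class-1 proportion of the outcome."""
        return float(self.y.mean())

    def view_columns(self, view: str) -> np.ndarray:
        try:
            return self._view_cols[view]
        except KeyError:
            raise KeyError(f"unknown leaf view '{view}'") from None

    def view_matrix(self, view: str) -> np.ndarray:
        return self.X[:, self.view_columns(view)]

    def view_feature_ids(self, view: str) -> list[str]:
        return [self.feature_ids[j] for j in self.view_columns(view)]

    def subset(self, rows: np.ndarray) -> "MultiViewDataset":
        """Row subset sharing the feature/view structure (may drop a class;
        validation of the class invariant is re-run and will complain)."""
        return MultiViewDataset(
            self.X[rows], self.y[rows], list(self.feature_ids), list(self.view_of_feature)
        )

    def to_frame(self, outcome_name: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_ids)
        df[outcome_name] = self.y
        return df


@dataclass
class ViewHierarchy:
    """Rooted tree over view ids: leaves own features, internal nodes group views.

    Depth 2 (all leaves directly under the root) is the original two-level
    stacked model; depth 3 adds an intermediate level. Mixed depths are
    allowed: a leaf attached directly to the root skips intermediate
    combination.
    """

    root: str
    children: dict[str, list[str]]
    parent: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.parent = {}
        seen = {self.root}
        for node, kids in self.children.items():
            if not kids:
                raise DataValidationError(f"internal node '{node}' has no children")
            for k in kids:
                if k in self.parent or k == self.root or (k in seen and k not in self.children):
                    raise DataValidationError(f"node '{k}' appears under two parents: not a tree")
                if k in seen:
                    raise DataValidationError(f"duplicate node id '{k}': not a tree")
                self.parent[k] = node
                seen.add(k)
        if self.root in self.parent:
            raise DataValidationError("root must not have a parent")
        for node in self.children:
            if node != self.root and node not in self.parent:
                raise DataValidationError(f"internal node '{node}' is not reachable from the root")
        # reachability / acyclicity: walk down from root
        reached: set[str] = set()
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd in reached:
                raise DataValidationError(f"cycle through node '{nd}'")
            reached.add(nd)
            stack.extend(self.children.get(nd, []))
        if reached != seen:
            missing = sorted(seen - reached)
            raise DataValidationError(f"nodes not reachable from root: {missing}")
        if self.root not in self.children:
            raise DataValidationError("hierarchy must have depth >= 2 (root needs children)")

    # -- structure queries ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return {self.root} | set(self.parent)

    def is_leaf(self, node: str) -> bool:
        return node not in self.children

    @property
    def leaves(self) -> list[str]:
        out: list[str] = []

        def rec(node: str) -> None:
            if self.is_leaf(node):
                out.append(node)
            else:
                for k in self.children[node]:
                    rec(k)

        rec(self.root)
        return out

    @property
    def internal_nodes(self) -> list[str]:
        """Non-root internal nodes, pre-order."""
        out: list[str] = []

        def rec(node: str) -> None:
            if not self.is_leaf(node):
                if node != self.root:
                    out.append(node)
                for k in self.children[node]:
                    rec(k)

        rec(self.root)
        return out

    def node_depth(self, node: str) -> int:
        d = 0
        while node != self.root:
            node = self.parent[node]
            d += 1
        return d

    @property
    def depth(self) -> int:
        return 1 + max(self.node_depth(v) for v in self.leaves)

    def level_of(self, node: str) -> str:
        if node == self.root:
            return "root"
        return "leaf" if self.is_leaf(node) else "intermediate"

    def branch_of(self, leaf: str) -> str:
        """The root child on the path from ``leaf`` to the root."""
        node = leaf
        while self.parent[node] != self.root:
            node = self.parent[node]
        return node

    def validate_against(self, dataset: MultiViewDataset) -> None:
        tree_leaves = set(self.leaves)
        for v in dataset.views:
            if v not in tree_leaves:
                raise DataValidationError(f"dataset leaf view '{v}' missing from hierarchy")
        for v in tree_leaves:
            if v not in dataset.views:
                raise DataValidationError(f"hierarchy leaf '{v}' has no features in the dataset")

    # -- construction --------------------------------------------------------

    @classmethod
    def from_nested(cls, mapping: Mapping) -> "ViewHierarchy":
        """Build from a nested mapping ``{root: {s1: [v1, v2], s2: [v3]}}``.

        Lists denote leaf views; nested mappings denote internal nodes. A flat
        ``{root: [v1, v2, v3]}`` gives the original depth-2 shape.
        """
        if len(mapping) != 1:
            raise DataValidationError("hierarchy file must have exactly one root key")
        root = str(next(iter(mapping)))
        children: dict[str, list[str]] = {}

        def rec(node: str, spec) -> None:
            if isinstance(spec, Mapping):
                kids = []
                for name, sub in spec.items():
                    name = str(name)
                    kids.append(name)
                    if isinstance(sub, (Mapping, list, tuple)):
                        rec(name, sub)
                    elif sub is not None:
                        raise DataValidationError(
                            f"node '{name}': expected mapping, list or null, got {type(sub).__name__}"
                        )
                children[node] = kids
            elif isinstance(spec, (list, tuple)):
                kids = []
                for item in spec:
                    if isinstance(item, Mapping):
                        for name, sub in item.items():
                            kids.append(str(name))
                            rec(str(name), sub)
                    else:
                        kids.append(str(item))
                children[node] = kids
            else:
                raise DataValidationError(f"node '{node}': cannot interpret {spec!r}")

        rec(root, mapping[root])
        return cls(root=root, children=children)

    def to_nested(self) -> dict:
        def rec(node: str):
            kids = self.children[node]
            if all(self.is_leaf(k) for k in kids):
                return list(kids)
            return {k: (None if self.is_leaf(k) else rec(k)) for k in kids}

        return {self.root: rec(self.root)}


@dataclass(frozen=True)
class FoldPlan:
    """A partition of subjects into cross-validation folds.

    ``assignment[i]`` is the fold index of subject *i*. Stratified by class
    whenever each class has at least ``n_folds`` members, so per-class fold
    sizes differ by at most one.
    """

    n_folds: int
    assignment: np.ndarray
    seed: int
    stratified: bool = True

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def make_folds(y: np.ndarray, n_folds: int, seed: int) -> FoldPlan:
    """Stratified fold assignment, deterministic given ``(y, n_folds, seed)``.

    Falls back to unstratified folds (with a logged warning) when a class has
    fewer members than ``n_folds``.
    """
    y = np.asarray(y)
    n = y.shape[0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds the {n} subjects")
    counts = np.bincount(y.astype(int), minlength=2)
    assignment = np.empty(n, dtype=int)
    stratified = bool((counts[counts > 0] >= n_folds).all())
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)), y)
    else:
        logger.warning(
            "class counts %s too small for %d stratified folds; using unstratified folds",
            counts.tolist(), n_folds,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros((n, 1)))
    for f, (_, test_idx) in enumerate(split):
        assignment[test_idx] = f
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=int(seed), stratified=stratified)


# -- file I/O ----------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def load_multiview(
    feature_table_path: str | Path,
    view_map_path: str | Path,
    outcome_name: str = "outcome",
) -> MultiViewDataset:
    """Read a feature table (CSV/TSV, header of feature ids, one outcome
    column) and a two-column view map ``(feature_id, leaf_view_id)``."""
    df = _read_table(feature_table_path)
    if outcome_name not in df.columns:
        raise DataValidationError(f"outcome column '{outcome_name}' not found in {feature_table_path}")
    vmap = _read_table(view_map_path)
    if vmap.shape[1] < 2:
        raise DataValidationError("view map needs two columns: feature_id, leaf_view_id")
    mapping = dict(zip(vmap.iloc[:, 0].astype(str), vmap.iloc[:, 1].astype(str)))
    feature_cols = [c for c in df.columns if c != outcome_name]
    for c in feature_cols:
        if str(c) not in mapping:
            raise DataValidationError(f"feature '{c}' is not mapped to any leaf view")
    y = df[outcome_name].to_numpy()
    if not np.isin(np.unique(y[~pd.isna(y)]), [0, 1]).all():
        raise DataValidationError(f"non-binary outcome in column '{outcome_name}'")
    X = df[feature_cols].to_numpy(dtype=float)
    return MultiViewDataset(
        X=X,
        y=y,
        feature_ids=[str(c) for c in feature_cols],
        view_of_feature=[mapping[str(c)] for c in feature_cols],
    )


def save_multiview(
    dataset: MultiViewDataset,
    feature_table_path: str | Path,
    view_map_path: str | Path,
    outcome_name: str = "outcome",
) -> None:
    dataset.to_frame(outcome_name).to_csv(feature_table_path, index=False)
    pd.DataFrame(
        {"feature_id": dataset.feature_ids, "leaf_view_id": dataset.view_of_feature}
    ).to_csv(view_map_path, index=False)


def load_hierarchy(config_path: str | Path) -> ViewHierarchy:
    """Read a view hierarchy from a JSON or YAML nested mapping."""
    path = Path(config_path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        mapping = json.loads(text)
    else:
        mapping = yaml.safe_load(text)
    if not isinstance(mapping, Mapping):
        raise DataValidationError(f"{config_path} does not encode a mapping")
    return ViewHierarchy.from_nested(mapping)


def save_hierarchy(hierarchy: ViewHierarchy, config_path: str | Path) -> None:
    path = Path(config_path)
    nested = hierarchy.to_nested()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(nested, indent=2))
    else:
        path.write_text(yaml.safe_dump(nested))
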
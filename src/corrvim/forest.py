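"""Instrumented regression random forest.

CART-style regression trees (variance-reduction splitting, a fresh uniform
draw of ``mtry`` candidate predictors at every node) grown on subsamples
drawn WITHOUT replacement — 63.2% of the observations by default, so the
out-of-bag (OOB) complement is exactly 36.8% per tree.  A node with fewer
in-bag observations than ``min_node_size`` is never split.

Tree induction is delegated to scikit-learn's ``DecisionTreeRegressor``
(criterion='squared_error', per-node ``max_features``); this module owns the
subsampling, the seed bookkeeping, and the instrumentation every downstream
consumer reads: per-tree split records (node, depth, feature, threshold),
in-bag/OOB index lists, and fast per-tree prediction for permutation
importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .synthetic_data import derive_seed

__all__ = [
    "FittedTree",
    "ForestConfig",
    "ForestModel",
    "OOBPredictions",
    "TreeSplitRecord",
    "fit_forest",
    "fit_tree",
    "predict_oob",
    "split_records_dataframe",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest tuning parameters.

    Study defaults: 5000 trees, minimum node size 20, 63.2% subsampling
    without replacement, mtry in {1, 3, 8}.
    """

    ntree: int = 5000
    mtry: int = 3
    min_node_size: int = 20
    subsample_fraction: float = 0.632
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 2:
            raise ValueError("min_node_size must be >= 2")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TreeSplitRecord:
    node_id: int
    depth: int
    feature: int
    threshold: float
    is_first_split: bool


@dataclass
class FittedTree:
    """One tree plus its instrumentation.

    ``split_records`` lists every internal node; ``subsample_indices`` and
    ``oob_indices`` partition the training rows; ``features_used`` is the set
    of predictors appearing in any split.
    """

    split_records: list[TreeSplitRecord]
    subsample_indices: np.ndarray
    oob_indices: np.ndarray
    features_used: frozenset[int]
    _estimator: DecisionTreeRegressor = field(repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._estimator.predict(np.asarray(X, dtype=np.float64))

    def predict_fast(self, X32: np.ndarray) -> np.ndarray:
        """Prediction without input validation; X32 must be C-contiguous float32."""
        return self._estimator.tree_.predict(X32).ravel()

    def thresholds_by_feature(self) -> dict[int, np.ndarray]:
        """Sorted distinct split thresholds per feature used in this tree."""
        out: dict[int, list[float]] = {}
        for rec in self.split_records:
            out.setdefault(rec.feature, []).append(rec.threshold)
        return {f: np.unique(np.asarray(t)) for f, t in out.items()}


@dataclass
class ForestModel:
    trees: list[FittedTree]
    config: ForestConfig
    p: int

    @property
    def ntree(self) -> int:
        return len(self.trees)


def _extract_split_records(est: DecisionTreeRegressor) -> tuple[list[TreeSplitRecord], frozenset[int]]:
    t = est.tree_
    records: list[TreeSplitRecord] = []
    # depth-first walk computing node depths
    stack: list[tuple[int, int]] = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        if t.children_left[node] == -1:
            continue
        records.append(
            TreeSplitRecord(
                node_id=int(node),
                depth=depth,
                feature=int(t.feature[node]),
                threshold=float(t.threshold[node]),
                is_first_split=depth == 0,
            )
        )
        stack.append((int(t.children_right[node]), depth + 1))
        stack.append((int(t.children_left[node]), depth + 1))
    used = frozenset(r.feature for r in records)
    return records, used


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    row_indices: Sequence[int] | np.ndarray,
    config: ForestConfig,
    tree_seed: int,
) -> FittedTree:
    """Grow one CART regression tree on the given in-bag rows.

    At each node a uniform random subset of ``config.mtry`` predictors is
    drawn and the variance-reducing split with midpoint thresholds is chosen
    among them; nodes with fewer than ``config.min_node_size`` in-bag rows
    are terminal.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = np.asarray(row_indices, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("row_indices must be non-empty")
    if config.mtry > X.shape[1]:
        raise ValueError(f"mtry={config.mtry} exceeds number of predictors p={X.shape[1]}")
    est = DecisionTreeRegressor(
        criterion="squared_error",
        splitter="best",
        min_samples_split=config.min_node_size,
        max_features=config.mtry,
        random_state=int(tree_seed),
    )
    est.fit(X[rows], y[rows])
    records, used = _extract_split_records(est)
    oob = np.setdiff1d(np.arange(X.shape[0], dtype=np.intp), rows, assume_unique=False)
    return FittedTree(
        split_records=records,
        subsample_indices=np.sort(rows),
        oob_indices=oob,
        features_used=used,
        _estimator=est,
    )


def fit_forest(X: np.ndarray, y: np.ndarray, config: ForestConfig) -> ForestModel:
    """Fit the full ensemble: independent subsamples without replacement.

    Tree t draws round(subsample_fraction * n) in-bag rows with the stream
    ``derive_seed(config.seed, t, 0)`` and grows with tree seed
    ``derive_seed(config.seed, t, 1)``; runs are deterministic given
    ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if config.mtry > p:
        raise ValueError(f"mtry={config.mtry} exceeds number of predictors p={p}")
    m = int(round(config.subsample_fraction * n))
    m = max(1, min(m, n))
    trees: list[FittedTree] = []
    for t in range(config.ntree):
        rng = np.random.default_rng(derive_seed(config.seed, t, 0))
        inbag = rng.choice(n, size=m, replace=False)
        trees.append(fit_tree(X, y, inbag, config, derive_seed(config.seed, t, 1)))
    return ForestModel(trees=trees, config=config, p=p)


def split_records_dataframe(forest: ForestModel):
    """Long-format export of every split: tree_id, node_id, depth, feature, threshold."""
    import pandas as pd

    rows = [
        (t, rec.node_id, rec.depth, rec.feature, rec.threshold, rec.is_first_split)
        for t, tree in enumerate(forest.trees)
        for rec in tree.split_records
    ]
    return pd.DataFrame(
        rows, columns=["tree_id", "node_id", "depth", "feature", "threshold", "is_first_split"]
    )


@dataclass
class OOBPredictions:
    """Per-tree and aggregated out-of-bag predictions on the training matrix."""

    per_tree: list[tuple[np.ndarray, np.ndarray]]  # (oob_indices, predictions)
    mean_prediction: np.ndarray  # NaN where a row was OOB in zero trees
    n_trees_oob: np.ndarray

    @property
    def uncovered_rows(self) -> np.ndarray:
        return np.flatnonzero(self.n_trees_oob == 0)


def predict_oob(forest: ForestModel, X: np.ndarray) -> OOBPredictions:
    """OOB prediction table: each tree predicts exactly its own OOB rows.

    The forest-level prediction for a row is the mean over the trees holding
    that row out of bag; rows OOB in no tree are NaN and flagged.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    per_tree = []
    for tree in forest.trees:
        oob = tree.oob_indices
        preds = tree.predict(X[oob])
        per_tree.append((oob, preds))
        sums[oob] += preds
        counts[oob] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return OOBPredictions(per_tree=per_tree, mean_prediction=mean, n_trees_oob=counts)
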
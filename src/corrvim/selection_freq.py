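"""Split-variable selection frequencies across trees and forests.

Counts, per predictor, how often it is chosen at the first (root) split and
across all internal nodes of all trees.  Correlated predictors win the root
split more often when they are marginally associated with the response,
while competition within a correlated block slightly depresses their share
of splits deeper in the trees — the two counts this module separates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import stats

from .forest import FittedTree, ForestModel

__all__ = ["SelectionFrequencies", "first_split_uniformity", "tally_selection", "tally_trees"]


@dataclass
class SelectionFrequencies:
    first_split_counts: np.ndarray
    all_split_counts: np.ndarray
    n_trees_total: int
    settings: dict = field(default_factory=dict)

    @property
    def first_split_shares(self) -> np.ndarray:
        """Share of root splits per predictor (among trees with >= 1 split)."""
        total = self.first_split_counts.sum()
        return self.first_split_counts / total if total else self.first_split_counts * 0.0

    @property
    def all_split_shares(self) -> np.ndarray:
        total = self.all_split_counts.sum()
        return self.all_split_counts / total if total else self.all_split_counts * 0.0

    def add(self, other: "SelectionFrequencies") -> "SelectionFrequencies":
        return SelectionFrequencies(
            first_split_counts=self.first_split_counts + other.first_split_counts,
            all_split_counts=self.all_split_counts + other.all_split_counts,
            n_trees_total=self.n_trees_total + other.n_trees_total,
            settings=self.settings,
        )

    def to_dataframe(self):
        import pandas as pd

        p = len(self.first_split_counts)
        df = pd.DataFrame(
            {
                "predictor": [f"x{i + 1}" for i in range(p)],
                "first_split_count": self.first_split_counts,
                "all_split_count": self.all_split_counts,
                "first_split_share": self.first_split_shares,
                "all_split_share": self.all_split_shares,
            }
        )
        for k, v in self.settings.items():
            df[k] = v
        return df


def tally_trees(trees: Iterable[FittedTree], p: int, settings: dict | None = None) -> SelectionFrequencies:
    """Exact integer counts over an iterable of fitted trees."""
    first = np.zeros(p, dtype=np.int64)
    allc = np.zeros(p, dtype=np.int64)
    ntrees = 0
    for tree in trees:
        ntrees += 1
        for rec in tree.split_records:
            allc[rec.feature] += 1
            if rec.is_first_split:
                first[rec.feature] += 1
    return SelectionFrequencies(first, allc, ntrees, settings or {})


def tally_selection(forests: list[ForestModel]) -> SelectionFrequencies:
    """Aggregate selection counts over a list of forests sharing p."""
    if not forests:
        raise ValueError("need at least one forest")
    p = forests[0].p
    if any(f.p != p for f in forests):
        raise ValueError("all forests must share the same number of predictors")
    out = tally_trees([], p)
    for f in forests:
        out = out.add(tally_trees(f.trees, p))
    return out


def first_split_uniformity(freq: SelectionFrequencies) -> tuple[float, float]:
    """Chi-square goodness-of-fit of the first-split counts against uniform.

    Returns (statistic, p-value).  Note the multinomial assumption treats
    root splits as independent draws; trees grown on the same replicate share
    data, so for data-driven split selection this test is conservative only
    at the tree level, not the replicate level.
    """
    counts = freq.first_split_counts
    res = stats.chisquare(counts)
    return float(res.statistic), float(res.pvalue)
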
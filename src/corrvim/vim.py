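"""Permutation-based variable importance measures (VIMs) over the forest.

For each tree and predictor the raw importance is

    diff = MSE_oob(permuted x_j) - MSE_oob(original),

with the predictor permuted among that tree's OOB rows only (one fresh
uniform permutation per tree x predictor).  Averaging the per-tree
differences gives the *unconditional* VIM; dividing that mean by its
standard error over trees (sd / sqrt(ntree)) gives the *scaled* VIM, which
therefore grows with forest size.  The *conditional* VIM permutes a
predictor only within strata defined by the predictors correlated with it
(|r| >= a threshold), so its marginal association with y is broken while the
conditioning structure is preserved.

Strata come from the tree's own split points on the conditioning variables
(``strata_source='tree_splits'``); a conditioning variable the tree never
split on contributes no partition refinement.  A quantile-bin stratification
is available as an alternative.  Predictors never used in a tree have a
per-tree difference of exactly 0 (permutation cannot change predictions), a
fact the implementation exploits.

Permutation randomness is drawn per (tree, predictor) from a stream derived
from ``perm_seed`` and independent of the forest-growing streams, so forest
structure is invariant to VIM settings and the conditional VIM of a
predictor with an empty conditioning set is bitwise equal to its
unconditional VIM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import ForestModel
from .synthetic_data import derive_seed

__all__ = [
    "ConditioningScheme",
    "VIMResult",
    "conditional_vim",
    "median_group_gap",
    "unconditional_vim",
    "vim_replicate_table",
    "vim_study_summary",
]

_PERM_STREAM = 0x5EED  # namespace word separating VIM streams from forest streams


@dataclass(frozen=True)
class ConditioningScheme:
    """How the conditional VIM builds its permutation strata.

    ``threshold``: absolute-correlation cutoff; the conditioning set of
    predictor i is every j != i with |cor(x_i, x_j)| >= threshold.
    """

    threshold: float = 0.2
    strata_source: str = "tree_splits"
    n_bins: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.strata_source not in ("tree_splits", "quantile_bins"):
            raise ValueError("strata_source must be 'tree_splits' or 'quantile_bins'")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def conditioning_sets(self, X: np.ndarray) -> list[np.ndarray]:
        R = np.corrcoef(np.asarray(X, dtype=float), rowvar=False)
        p = R.shape[0]
        sets = []
        for i in range(p):
            mask = np.abs(R[i]) >= self.threshold
            mask[i] = False
            sets.append(np.flatnonzero(mask))
        return sets


@dataclass(frozen=True)
class VIMResult:
    """Per-predictor importances plus the raw per-tree difference matrix."""

    per_tree_differences: np.ndarray  # (ntree, p)
    unconditional: np.ndarray | None = None
    scaled: np.ndarray | None = None
    conditional: np.ndarray | None = None
    settings: dict = field(default_factory=dict)


def _stratified_permutation(rng: np.random.Generator, m: int, labels: np.ndarray | None) -> np.ndarray:
    """A permutation of range(m); if labels given, a product of within-stratum permutations."""
    if labels is None:
        return rng.permutation(m)
    perm = np.arange(m)
    for s in np.unique(labels):
        idx = np.flatnonzero(labels == s)
        perm[idx] = idx[rng.permutation(idx.size)]
    return perm


def _tree_strata_labels(tree, X_oob: np.ndarray, cond_set: np.ndarray, scheme: ConditioningScheme, X_train: np.ndarray) -> np.ndarray | None:
    """Mixed-radix stratum labels of the OOB rows, or None for a single stratum."""
    labels = np.zeros(X_oob.shape[0], dtype=np.int64)
    refined = False
    if scheme.strata_source == "tree_splits":
        cuts_by_feature = tree.thresholds_by_feature()
        for j in cond_set:
            cuts = cuts_by_feature.get(int(j))
            if cuts is None or cuts.size == 0:
                continue
            bins = np.digitize(X_oob[:, j], cuts)
            labels = labels * (cuts.size + 1) + bins
            refined = True
    else:
        qs = np.linspace(0, 1, scheme.n_bins + 1)[1:-1]
        for j in cond_set:
            cuts = np.unique(np.quantile(X_train[:, j], qs))
            bins = np.digitize(X_oob[:, j], cuts)
            labels = labels * (cuts.size + 1) + bins
            refined = True
    return labels if refined else None


def _per_tree_differences(
    forest: ForestModel,
    X: np.ndarray,
    y: np.ndarray,
    perm_seed: int,
    cond_sets: list[np.ndarray] | None,
    scheme: ConditioningScheme | None,
    nperm: int,
) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = forest.p
    diffs = np.zeros((forest.ntree, p))
    for t_idx, tree in enumerate(forest.trees):
        oob = tree.oob_indices
        Xo = X[oob]
        Xo32 = np.ascontiguousarray(Xo, dtype=np.float32)
        yo = y[oob]
        m = oob.size
        base = tree.predict_fast(Xo32)
        mse0 = float(np.mean((yo - base) ** 2))
        for j in range(p):
            if j not in tree.features_used:
                continue  # identical predictions under any permutation: difference exactly 0
            rng = np.random.default_rng(derive_seed(perm_seed, _PERM_STREAM, t_idx, j))
            if cond_sets is None or cond_sets[j].size == 0:
                labels = None
            else:
                labels = _tree_strata_labels(tree, Xo, cond_sets[j], scheme, X)
            col = Xo32[:, j].copy()
            acc = 0.0
            for _ in range(nperm):
                perm = _stratified_permutation(rng, m, labels)
                Xo32[:, j] = col[perm]
                acc += float(np.mean((yo - tree.predict_fast(Xo32)) ** 2))
            Xo32[:, j] = col
            diffs[t_idx, j] = acc / nperm - mse0
    return diffs


def unconditional_vim(
    forest: ForestModel, X: np.ndarray, y: np.ndarray, perm_seed: int, nperm: int = 1
) -> VIMResult:
    """Unconditional OOB-permutation VIM with its scaled (mean / SE) variant.

    Returns the per-tree difference matrix, the per-predictor means, and the
    scaled values mean / (sd / sqrt(ntree)).  With a single tree the scaled
    value is undefined and reported as None.
    """
    diffs = _per_tree_differences(forest, X, y, perm_seed, None, None, nperm)
    mean = diffs.mean(axis=0)
    if forest.ntree >= 2:
        sd = diffs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(sd > 0, mean / (sd / np.sqrt(forest.ntree)), 0.0)
    else:
        scaled = None
    return VIMResult(
        per_tree_differences=diffs,
        unconditional=mean,
        scaled=scaled,
        settings={"perm_seed": int(perm_seed), "nperm": nperm, "kind": "unconditional"},
    )


def conditional_vim(
    forest: ForestModel,
    X: np.ndarray,
    y: np.ndarray,
    scheme: ConditioningScheme | None = None,
    perm_seed: int = 0,
    nperm: int = 1,
) -> VIMResult:
    """Conditional VIM: permute each predictor within correlation-defined strata.

    Predictors with empty conditioning sets reduce exactly to the
    unconditional value for the same ``perm_seed``.  Singleton strata leave
    their row fixed (the identity is the only permutation).
    """
    if scheme is None:
        scheme = ConditioningScheme()
    cond_sets = scheme.conditioning_sets(X)
    diffs = _per_tree_differences(forest, X, y, perm_seed, cond_sets, scheme, nperm)
    return VIMResult(
        per_tree_differences=diffs,
        conditional=diffs.mean(axis=0),
        settings={
            "perm_seed": int(perm_seed),
            "nperm": nperm,
            "kind": "conditional",
            "threshold": scheme.threshold,
            "strata_source": scheme.strata_source,
        },
    )


def _values(result: VIMResult, kind: str) -> np.ndarray:
    v = getattr(result, kind)
    if v is None:
        raise ValueError(f"VIMResult does not carry a {kind!r} component")
    return v


def vim_study_summary(results: list[VIMResult], kind: str = "unconditional"):
    """Per-predictor median and quartiles of one VIM component across replicates."""
    import pandas as pd

    if len(results) == 0:
        raise ValueError("need at least one VIMResult")
    vals = np.vstack([_values(r, kind) for r in results])  # (R, p)
    q1, med, q3 = np.percentile(vals, [25, 50, 75], axis=0)
    p = vals.shape[1]
    return pd.DataFrame(
        {
            "predictor": [f"x{i + 1}" for i in range(p)],
            "median": med,
            "q1": q1,
            "q3": q3,
            "kind": kind,
            "n_replicates": len(results),
        }
    )


def vim_replicate_table(results: list[VIMResult], conditional_results: list[VIMResult] | None = None):
    """Long-format per-replicate VIM export: replicate_id, predictor, one column per component."""
    import pandas as pd

    frames = []
    for rep, res in enumerate(results):
        p = res.per_tree_differences.shape[1]
        df = pd.DataFrame({"replicate_id": rep, "predictor": [f"x{i + 1}" for i in range(p)]})
        df["unconditional"] = res.unconditional
        df["scaled"] = res.scaled if res.scaled is not None else np.nan
        if conditional_results is not None:
            df["conditional"] = conditional_results[rep].conditional
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def median_group_gap(
    results: list[VIMResult],
    correlated: np.ndarray,
    kind: str = "unconditional",
) -> float:
    """Median VIM of the correlated group minus that of the uncorrelated group.

    Values are pooled over replicates and over the predictors in each group
    before taking medians — the group-level summary used to quantify null
    inflation.
    """
    vals = np.vstack([_values(r, kind) for r in results])
    correlated = np.asarray(correlated)
    if correlated.dtype != bool:
        mask = np.zeros(vals.shape[1], dtype=bool)
        mask[correlated] = True
        correlated = mask
    return float(np.median(vals[:, correlated]) - np.median(vals[:, ~correlated]))
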
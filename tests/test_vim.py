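"""Permutation importance: exactness, stratified permutation, scaling law."""

import itertools

import numpy as np
import pytest

import corrvim as cv
from corrvim.forest import ForestConfig, ForestModel
from corrvim.vim import _stratified_permutation, _tree_strata_labels


def make_stump_forest(x_extra_cols=1):
    """A single stump on feature 0 (train rows 0..5), OOB rows 6..8.

    Training y is +-10 split cleanly at x0 = 0, so the stump predicts -10 for
    x0 < 0 and +10 for x0 > 0.
    """
    rng = np.random.default_rng(123)
    X = rng.standard_normal((9, 1 + x_extra_cols))
    X[:6, 0] = [-2.0, -1.5, -1.0, 1.0, 1.5, 2.0]
    y = np.empty(9)
    y[:6] = [-10, -10, -10, 10, 10, 10]
    # OOB rows: two left of the split, one right, with known responses
    X[6:, 0] = [-1.0, -2.0, 2.0]
    y[6:] = [-10.0, -10.0, 10.0]
    cfg = ForestConfig(ntree=1, mtry=1 + x_extra_cols, min_node_size=2, subsample_fraction=0.5, seed=0)
    tree = cv.fit_tree(X, y, np.arange(6), cfg, tree_seed=0)
    return ForestModel([tree], cfg, X.shape[1]), X, y


def test_stump_difference_matches_hand_enumeration():
    """The per-tree value is (permuted MSE - original MSE); with 3 OOB rows all
    6 permutations of x0 are enumerable, so the result must be one of the two
    hand-computed MSE differences (0 when the lone right-side row stays put,
    or the value obtained when it crosses the split)."""
    forest, X, y = make_stump_forest()
    tree = forest.trees[0]
    assert [r.feature for r in tree.split_records] == [0]
    oob = tree.oob_indices
    assert list(oob) == [6, 7, 8]
    x0 = X[oob, 0]
    yo = y[oob]
    thr = tree.split_records[0].threshold

    def mse_for(perm):
        preds = np.where(x0[list(perm)] <= thr, -10.0, 10.0)
        return np.mean((yo - preds) ** 2)

    mse0 = mse_for((0, 1, 2))
    assert mse0 == 0.0  # the stump classifies all OOB rows perfectly
    possible = {round(mse_for(p) - mse0, 10) for p in itertools.permutations(range(3))}
    res = cv.unconditional_vim(forest, X, y, perm_seed=7)
    assert round(float(res.per_tree_differences[0, 0]), 10) in possible
    # identical OOB column values => every permutation is a no-op
    X2 = X.copy()
    X2[oob, 0] = -1.0
    y2 = y.copy()
    y2[oob] = -10.0
    cfg = forest.config
    tree2 = cv.fit_tree(X2, y2, np.arange(6), cfg, tree_seed=0)
    res2 = cv.unconditional_vim(ForestModel([tree2], cfg, X2.shape[1]), X2, y2, perm_seed=7)
    assert res2.per_tree_differences[0, 0] == 0.0


def test_unused_predictor_difference_exactly_zero(h0_model):
    ds = cv.simulate_dataset(h0_model, 300, seed=1)
    forest = cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=10, mtry=1, min_node_size=50, seed=2))
    res = cv.unconditional_vim(forest, ds.X, ds.y, perm_seed=3)
    saw_unused = False
    for t, tree in enumerate(forest.trees):
        for j in range(12):
            if j not in tree.features_used:
                saw_unused = True
                assert res.per_tree_differences[t, j] == 0.0
    assert saw_unused


def test_self_consistency_and_scaled_formula(small_ha_dataset):
    ds = small_ha_dataset
    forest = cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=20, mtry=3, seed=4))
    res = cv.unconditional_vim(forest, ds.X, ds.y, perm_seed=5)
    diffs = res.per_tree_differences
    assert np.array_equal(res.unconditional, diffs.mean(axis=0))
    se = diffs.std(axis=0, ddof=1) / np.sqrt(20)
    expect = np.where(se > 0, diffs.mean(axis=0) / np.where(se > 0, se, 1.0), 0.0)
    assert np.allclose(res.scaled, expect)


def test_scaled_undefined_for_single_tree(small_ha_dataset):
    ds = small_ha_dataset
    forest = cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=1, mtry=3, seed=6))
    res = cv.unconditional_vim(forest, ds.X, ds.y, perm_seed=7)
    assert res.scaled is None
    assert res.unconditional is not None


def test_scaled_vim_grows_with_forest_size(small_ha_dataset):
    """Doubling ntree leaves the unconditional VIM stable but inflates the
    scaled VIM by ~sqrt(2) per doubling (here: x4 forests -> factor ~2)."""
    ds = small_ha_dataset
    r_small = cv.unconditional_vim(
        cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=100, mtry=3, seed=8)), ds.X, ds.y, perm_seed=9
    )
    r_big = cv.unconditional_vim(
        cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=400, mtry=3, seed=8)), ds.X, ds.y, perm_seed=9
    )
    j = 0  # strongly influential predictor
    assert 0.7 < r_big.unconditional[j] / r_small.unconditional[j] < 1.4
    assert 1.3 < r_big.scaled[j] / r_small.scaled[j] < 3.0


class TestConditioningScheme:
    def test_conditioning_sets_from_sample_correlation(self, ha_model):
        ds = cv.simulate_dataset(ha_model, 2000, seed=10)
        sets = cv.ConditioningScheme(threshold=0.2).conditioning_sets(ds.X)
        assert [list(s) for s in sets[:4]] == [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]
        assert all(s.size == 0 for s in sets[4:])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cv.ConditioningScheme(threshold=1.5)
        with pytest.raises(ValueError):
            cv.ConditioningScheme(strata_source="nope")


def test_conditional_equals_unconditional_when_sets_empty(small_ha_dataset):
    """With the threshold above every sample correlation all conditioning sets
    are empty and the shared permutation stream makes the two VIMs identical."""
    ds = small_ha_dataset
    forest = cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=15, mtry=3, seed=11))
    unc = cv.unconditional_vim(forest, ds.X, ds.y, perm_seed=12)
    cond = cv.conditional_vim(forest, ds.X, ds.y, cv.ConditioningScheme(threshold=0.999), perm_seed=12)
    assert np.array_equal(cond.per_tree_differences, unc.per_tree_differences)
    assert np.array_equal(cond.conditional, unc.unconditional)


def test_stratified_permutation_preserves_strata():
    rng = np.random.default_rng(0)
    labels = np.array([0, 0, 1, 1, 2, 2, 2, 0])
    for _ in range(20):
        perm = _stratified_permutation(rng, len(labels), labels)
        assert sorted(perm) == list(range(len(labels)))
        assert np.array_equal(labels[perm], labels)


def test_tree_split_strata_never_cross_threshold():
    """A stump splitting only on the conditioning variable partitions the OOB
    rows at its threshold; within-stratum permutation of the target predictor
    can then never move a value across that threshold (enumerated 2x2)."""
    rng = np.random.default_rng(5)
    X = rng.standard_normal((10, 2))
    X[:6, 1] = [-2, -1.5, -1, 1, 1.5, 2]
    y = np.empty(10)
    y[:6] = [-1, -1, -1, 1, 1, 1]
    X[6:, 1] = [-1.0, -0.5, 0.5, 1.0]  # OOB: 2 per side of the split
    y[6:] = [-1, -1, 1, 1]
    cfg = ForestConfig(ntree=1, mtry=2, min_node_size=2, subsample_fraction=0.6, seed=0)
    tree = cv.fit_tree(X, y, np.arange(6), cfg, tree_seed=3)
    assert [r.feature for r in tree.split_records] == [1]
    thr = tree.split_records[0].threshold
    oob_X = X[tree.oob_indices]
    labels = _tree_strata_labels(tree, oob_X, np.array([1]), cv.ConditioningScheme(), X)
    side = oob_X[:, 1] > thr
    # the stratum labels refine exactly the two sides of the split
    assert len(np.unique(labels[side])) == 1 and len(np.unique(labels[~side])) == 1
    assert labels[side][0] != labels[~side][0]
    rng2 = np.random.default_rng(1)
    for _ in range(16):
        perm = _stratified_permutation(rng2, 4, labels)
        assert np.array_equal(side[perm], side)


def test_nperm_averaging_recorded(small_ha_dataset):
    ds = small_ha_dataset
    forest = cv.fit_forest(ds.X, ds.y, ForestConfig(ntree=5, mtry=3, seed=13))
    res = cv.unconditional_vim(forest, ds.X, ds.y, perm_seed=14, nperm=3)
    assert res.settings["nperm"] == 3
    assert res.per_tree_differences.shape == (5, 12)


def test_vim_replicate_table_long_format(small_ha_dataset):
    ds = small_ha_dataset
    forest = cv.fit_forest(ds.X, ds.y, cv.ForestConfig(ntree=4, mtry=3, seed=15))
    unc = cv.unconditional_vim(forest, ds.X, ds.y, perm_seed=16)
    cond = cv.conditional_vim(forest, ds.X, ds.y, perm_seed=16)
    df = cv.vim_replicate_table([unc, unc], [cond, cond])
    assert len(df) == 24
    assert set(df.replicate_id) == {0, 1}
    assert np.allclose(df[df.replicate_id == 0]["unconditional"], unc.unconditional)
    assert np.allclose(df[df.replicate_id == 1]["conditional"], cond.conditional)


def test_vim_study_summary_and_gap():
    diffs = np.zeros((3, 4))
    r = cv.VIMResult(per_tree_differences=diffs, unconditional=np.array([1.0, 2.0, 0.1, 0.2]))
    df = cv.vim_study_summary([r, r, r], "unconditional")
    assert np.allclose(df["q3"] - df["q1"], 0.0)  # identical replicates: IQR 0
    assert np.allclose(df["median"], [1.0, 2.0, 0.1, 0.2])
    gap = cv.median_group_gap([r, r], np.array([True, True, False, False]))
    assert gap == pytest.approx(1.5 - 0.15)
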
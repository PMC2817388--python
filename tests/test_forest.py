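"""Random forest: bootstrap structure, OOB error, importance scores."""

import numpy as np
import pytest

import flowtrees as ft

from .conftest import TARGET_1, make_panel_matrix


def _noise_data(n, p, seed, resp=0.25):
    rng = np.random.default_rng(seed)
    return (
        rng.integers(0, 2, (n, p)).astype(np.int8),
        (rng.uniform(size=n) < resp).astype(int),
    )


def test_forest_determinism():
    X, y = _noise_data(100, 10, 0)
    a = ft.grow_forest(X, y, ft.ForestConfig(B=50, seed=7))
    b = ft.grow_forest(X, y, ft.ForestConfig(B=50, seed=7))
    for ta, tb in zip(a.trees, b.trees):
        assert ta.render() == tb.render()
    for ma, mb in zip(a.oob_masks, b.oob_masks):
        np.testing.assert_array_equal(ma, mb)


def test_seed_stream_extension_preserves_early_trees():
    """Increasing B extends the forest without reshuffling earlier trees."""
    X, y = _noise_data(80, 8, 1)
    small = ft.grow_forest(X, y, ft.ForestConfig(B=10, seed=3))
    big = ft.grow_forest(X, y, ft.ForestConfig(B=25, seed=3))
    for ta, tb in zip(small.trees, big.trees[:10]):
        assert ta.render() == tb.render()


def test_oob_fraction_matches_bootstrap_theory():
    """Mean per-tree OOB fraction ~ (1 - 1/n)^n at n = 78."""
    X, y = _noise_data(78, 5, 2)
    forest = ft.grow_forest(X, y, ft.ForestConfig(B=2000, seed=4))
    frac = np.mean([m.mean() for m in forest.oob_masks])
    assert abs(frac - (1 - 1 / 78) ** 78) < 0.01


def test_reduces_to_cart_with_mtry_p():
    """B = 1 with mtry = p grows exactly the unpruned CART tree on the
    same bootstrap sample."""
    X, y = _noise_data(60, 6, 5, resp=0.4)
    forest = ft.grow_forest(X, y, ft.ForestConfig(B=1, mtry=6, min_node=1, seed=9))
    counts = forest.inbag_counts[0]
    Xb = np.repeat(X, counts, axis=0)
    yb = np.repeat(y, counts)
    direct = ft.grow_tree(Xb, yb, min_node=1)
    assert [(n.split_var, n.n, n.n_resp) for n in forest.trees[0].nodes.values()] == [
        (n.split_var, n.n, n.n_resp) for n in direct.nodes.values()
    ]


def test_oob_error_null_base_rate():
    """On pure-noise data the aggregate OOB error sits at or slightly
    above the 0.25 base-rate floor (fully grown trees overfit noise, so
    the vote cannot reach the floor exactly); the reference implementation
    (sklearn, same data) behaves the same way and no better."""
    from sklearn.ensemble import RandomForestClassifier

    X, y = _noise_data(1000, 10, 6, resp=0.25)
    forest = ft.grow_forest(X, y, ft.ForestConfig(B=500, seed=10))
    agg, per_tree = ft.oob_error(forest, X, y)
    assert agg >= 0.25 - 0.02  # Bayes floor, up to outcome sampling noise
    assert abs(agg - 0.25) < 0.06
    assert np.nanmean(per_tree) > agg  # single trees are noisier than the vote

    oracle = RandomForestClassifier(
        n_estimators=500, oob_score=True, random_state=0, max_features="sqrt"
    ).fit(X, y)
    assert agg <= (1 - oracle.oob_score_) + 0.02


def test_oob_error_separable_signal():
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, (300, 5)).astype(np.int8)
    y = X[:, 2].astype(int)
    forest = ft.grow_forest(X, y, ft.ForestConfig(B=100, seed=11))
    agg, _ = ft.oob_error(forest, X, y)
    assert agg == 0.0


def test_oob_is_a_test_set_proxy():
    """Aggregate OOB error within 0.05 of error on an independent sample."""
    spec = ft.OutcomeSpec.marginal(TARGET_1, 0.10, 0.65)
    matrix, y = make_panel_matrix(spec, n=400, seed=40)
    forest = ft.grow_forest(matrix, y, ft.ForestConfig(B=300, seed=41))
    agg, _ = ft.oob_error(forest, matrix, y)

    test_m, test_y = make_panel_matrix(spec, n=2000, seed=42)
    votes = np.zeros(len(test_y.y))
    Xt = test_m.X[matrix.variable_names].to_numpy()
    for tree in forest.trees:
        votes += tree.predict(Xt)
    pred = (votes * 2 > forest.B).astype(int)
    test_err = (pred != test_y.y).mean()
    assert abs(agg - test_err) < 0.05


def test_unused_variable_importance_exactly_zero():
    """With a perfectly separating predictor always available (mtry = p),
    no tree splits elsewhere, so other variables score exactly 0."""
    rng = np.random.default_rng(8)
    X = rng.integers(0, 2, (200, 4)).astype(np.int8)
    y = X[:, 0].astype(int)
    forest = ft.grow_forest(X, y, ft.ForestConfig(B=50, mtry=4, seed=12))
    imp = ft.permutation_importance(forest, X, y, seed=13)
    assert (imp["permutation_importance"].to_numpy()[1:] == 0.0).all()
    gi = ft.gini_importance(forest)
    assert (gi["gini_importance"].to_numpy()[1:] == 0.0).all()
    assert gi["gini_importance"].iloc[0] > 0


def test_null_importance_centred_at_zero():
    X, y = _noise_data(200, 15, 9)
    forest = ft.grow_forest(X, y, ft.ForestConfig(B=500, seed=14))
    imp = ft.permutation_importance(forest, X, y, seed=15)
    theta = imp["permutation_importance"].to_numpy()
    se = imp["permutation_se"].to_numpy()
    # per-variable deltas are correlated across variables within a tree,
    # so the honest scale for the grand mean is the per-variable SE
    assert abs(theta.mean()) < 2 * se.mean()
    assert np.abs(theta).max() < 6 * se.max()


def test_gini_importance_nonnegative(null_small):
    matrix, y = null_small
    forest = ft.grow_forest(matrix, y, ft.ForestConfig(B=100, seed=16))
    gi = ft.gini_importance(forest)
    assert (gi["gini_importance"] >= 0).all()


def test_planted_effect_tops_both_importance_rankings():
    """The planted marginal effect (reconstructed study rates) ranks first
    on permutation and on impurity-decrease importance."""
    spec = ft.OutcomeSpec.marginal(TARGET_1, 4 / 39, 15 / 39)
    matrix, y = make_panel_matrix(spec, n=400, seed=43)
    forest = ft.grow_forest(matrix, y, ft.ForestConfig(B=500, seed=44))
    table = ft.importance_table(forest, matrix, y, seed=45)
    assert table.iloc[0]["variable"] == TARGET_1
    assert table.sort_values("gini_importance", ascending=False).iloc[0][
        "variable"
    ] == TARGET_1


def test_duplicated_predictor_dilutes_importance():
    """A byte-identical copy of the informative predictor can only dilute
    each copy's permutation importance — the correlation-masking effect."""
    rng = np.random.default_rng(20)
    n, p = 400, 10
    X = rng.integers(0, 2, (n, p)).astype(np.int8)
    probs = np.where(X[:, 0] == 1, 0.75, 0.2)
    y = (rng.uniform(size=n) < probs).astype(int)

    forest = ft.grow_forest(X, y, ft.ForestConfig(B=300, mtry=3, seed=21))
    solo = ft.permutation_importance(forest, X, y, seed=22)
    solo_theta = solo.loc[0, "permutation_importance"]

    X_dup = np.column_stack([X, X[:, 0]])
    forest_dup = ft.grow_forest(X_dup, y, ft.ForestConfig(B=300, mtry=3, seed=21))
    dup = ft.permutation_importance(forest_dup, X_dup, y, seed=22)
    assert dup.loc[0, "permutation_importance"] < solo_theta
    assert dup.loc[p, "permutation_importance"] < solo_theta


def test_config_validation():
    X, y = _noise_data(30, 4, 10)
    with pytest.raises(ValueError):
        ft.grow_forest(X, y, ft.ForestConfig(B=5, mtry=10, seed=0))
    with pytest.raises(ValueError):
        ft.ForestConfig(B=0)


def test_model_results_interface():
    X, y = _noise_data(120, 6, 11, resp=0.4)
    res = ft.RandomForestModel(y, X, B=50, seed=1).fit()
    assert 0.0 <= res.oob_error_ <= 1.0
    assert len(res.importance) == 6
    assert "OOB error" in res.summary()
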
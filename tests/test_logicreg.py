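"""Logic regression: Boolean trees, GLM fitting, annealing search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowtrees as ft
from flowtrees.logicreg import MOVE_TYPES, AnnealConfig, LogicTree

from .conftest import TARGET_1, TARGET_2, make_panel_matrix, subset_matrix

WORKED = "(X1 and X2) or (X3 and not X4)"


@pytest.mark.parametrize(
    "x, expected",
    [
        ((1, 1, 0, 1), 1),  # first conjunct true
        ((0, 1, 1, 0), 1),  # second conjunct true
        ((0, 1, 0, 1), 0),  # both false
    ],
)
def test_evaluate_worked_expression(x, expected):
    tree = ft.parse_expression(WORKED)
    assert ft.evaluate_tree(tree, np.array(x)) == expected


def test_unknown_variable_raises():
    tree = ft.LogicTree.leaf(10)
    with pytest.raises(IndexError):
        tree.evaluate(np.zeros((3, 4), dtype=np.int8))


def test_truth_table_equivalences():
    assert ft.truth_table_equivalence(
        ft.parse_expression("(X1 and X2)"), ft.parse_expression("(X2 and X1)")
    )
    # De Morgan: not(X1 or X2) == (not X1 and not X2)
    assert ft.truth_table_equivalence(
        ft.parse_expression("(X1 or X2)").complement(),
        ft.parse_expression("(not X1 and not X2)"),
    )
    assert not ft.truth_table_equivalence(
        ft.parse_expression("X1"), ft.parse_expression("not X1")
    )


@st.composite
def random_trees(draw):
    n_leaves = draw(st.integers(1, 6))
    tree = LogicTree.leaf(draw(st.integers(0, 7)), draw(st.booleans()))
    for _ in range(n_leaves - 1):
        op = draw(st.sampled_from(["and", "or"]))
        leaf = LogicTree.leaf(draw(st.integers(0, 7)), draw(st.booleans()))
        if draw(st.booleans()):
            tree = LogicTree.combine(op, tree, leaf)
        else:
            tree = LogicTree.combine(op, leaf, tree)
    return tree


@given(random_trees())
@settings(max_examples=150, deadline=None, derandomize=True)
def test_render_parse_round_trip(tree):
    back = ft.parse_expression(tree.render())
    assert ft.truth_table_equivalence(tree, back)
    # complement is an involution
    assert ft.truth_table_equivalence(tree.complement().complement(), tree)


def test_fit_single_leaf_equals_log_odds_ratio():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 2, (300, 3)).astype(np.int8)
    y = (rng.uniform(size=300) < np.where(X[:, 0] == 1, 0.7, 0.3)).astype(int)
    fr = ft.fit_coefficients([LogicTree.leaf(0)], X, y)
    t = ft.tabulate(X[:, 0], y)
    assert fr.coefficients[0] == pytest.approx(np.log(ft.odds_ratio(t)), abs=1e-8)
    assert fr.intercept == pytest.approx(np.log(t.c / t.d), abs=1e-8)


def test_fit_drops_degenerate_trees():
    rng = np.random.default_rng(1)
    X = rng.integers(0, 2, (100, 3)).astype(np.int8)
    y = rng.integers(0, 2, 100)
    all_zero = LogicTree.combine("and", LogicTree.leaf(0), LogicTree.leaf(0, True))
    fr = ft.fit_coefficients([all_zero], X, y)
    assert fr.dropped == [0] and fr.coefficients[0] == 0.0
    assert fr.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-8)
    # duplicate columns: second tree dropped
    fr2 = ft.fit_coefficients([LogicTree.leaf(1), LogicTree.leaf(1)], X, y)
    assert fr2.dropped == [1]
    # complement of an earlier column is collinear with the intercept
    fr3 = ft.fit_coefficients([LogicTree.leaf(1), LogicTree.leaf(1, True)], X, y)
    assert fr3.dropped == [1]


def test_separation_is_capped_and_flagged():
    X = np.array([[1], [1], [0], [0]], dtype=np.int8)
    y = np.array([1, 1, 0, 0])
    fr = ft.fit_coefficients([LogicTree.leaf(0)], X, y, coef_cap=10.0)
    assert fr.separation
    assert np.abs(fr.coefficients).max() <= 10.0


def test_deviance_matches_glm_oracle():
    """100 random small instances against statsmodels GLM (logit) and OLS
    (identity), deviance agreement to 1e-6."""
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    for trial in range(100):
        n = int(rng.integers(40, 120))
        X = rng.integers(0, 2, (n, 6)).astype(np.int8)
        trees = [
            LogicTree.combine(
                "and" if rng.integers(2) else "or",
                LogicTree.leaf(int(rng.integers(6)), bool(rng.integers(2))),
                LogicTree.leaf(int(rng.integers(6)), bool(rng.integers(2))),
            )
            for _ in range(2)
        ]
        cols = np.column_stack([t.evaluate(X) for t in trees])
        eta = -0.5 + cols @ np.array([1.0, -1.2])
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fr = ft.fit_coefficients(trees, X, y)
        if fr.dropped or fr.separation or y.sum() in (0, n):
            continue
        Z = sm.add_constant(cols.astype(float))
        oracle = sm.GLM(y, Z, family=sm.families.Binomial()).fit()
        assert fr.deviance == pytest.approx(oracle.deviance, abs=1e-6)
        np.testing.assert_allclose(
            np.r_[fr.intercept, fr.coefficients], oracle.params, atol=1e-5
        )


def test_identity_link_matches_least_squares():
    rng = np.random.default_rng(3)
    X = rng.integers(0, 2, (80, 4)).astype(np.int8)
    y = rng.uniform(size=80)
    trees = [LogicTree.leaf(0), LogicTree.leaf(2, True)]
    fr = ft.fit_coefficients(trees, X, y, link="identity")
    Z = np.column_stack([np.ones(80)] + [t.evaluate(X) for t in trees])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    np.testing.assert_allclose(np.r_[fr.intercept, fr.coefficients], beta, atol=1e-10)
    assert fr.deviance == pytest.approx(((y - Z @ beta) ** 2).sum())


# ------------------------------------------------------------------ moves
def test_grow_rejected_at_leaf_budget():
    trees = (ft.parse_expression("(X1 and X2) or X3"), ft.parse_expression("X4"))
    out, applied = ft.propose_move(trees, "grow_branch", 0, p=8, max_leaves=4)
    assert not applied and out == trees


def test_delete_only_leaf_empties_tree():
    trees = (LogicTree.leaf(0),)
    rng = np.random.default_rng(1)
    out, applied = ft.propose_move(trees, "split_delete_leaf", rng, p=8, max_leaves=6)
    assert applied and out[0].is_empty


def test_moves_change_leaf_count_by_at_most_one():
    rng = np.random.default_rng(4)
    trees = (ft.parse_expression("(X1 and X2) or X3"), LogicTree.leaf(4))
    for _ in range(300):
        move = MOVE_TYPES[rng.integers(6)]
        before = sum(t.n_leaves for t in trees)
        trees, applied = ft.propose_move(trees, move, rng, p=8, max_leaves=6)
        after = sum(t.n_leaves for t in trees)
        assert abs(after - before) <= 1
        assert after <= 6


# ------------------------------------------------------------------ search
def test_anneal_best_score_monotone_and_deterministic():
    rng = np.random.default_rng(5)
    X = rng.integers(0, 2, (150, 8)).astype(np.int8)
    y = (rng.uniform(size=150) < np.where(X[:, 1] == 1, 0.8, 0.25)).astype(int)
    cfg = AnnealConfig(iterations=1500, seed=6)
    model, hist = ft.anneal_search(X, y, cfg)
    best = hist["best_score"].to_numpy()
    assert (np.diff(best) <= 1e-9).all()
    model2, _ = ft.anneal_search(X, y, cfg)
    assert model.render() == model2.render()
    assert model.deviance == pytest.approx(model2.deviance)


def test_single_leaf_search_reduces_to_logistic_regression():
    """One tree of one leaf: the search is single-variable model selection,
    and the winner matches the closed-form logistic fit on that variable."""
    rng = np.random.default_rng(7)
    X = rng.integers(0, 2, (300, 6)).astype(np.int8)
    y = (rng.uniform(size=300) < np.where(X[:, 3] == 1, 0.75, 0.3)).astype(int)
    cfg = AnnealConfig(iterations=800, n_trees=1, max_leaves=1, seed=8)
    model, _ = ft.anneal_search(X, y, cfg)
    tree = model.trees[0]
    assert tree.n_leaves == 1
    leaf = tree.leaves()[0]
    col = X[:, leaf.variable] if not leaf.complemented else 1 - X[:, leaf.variable]
    t = ft.tabulate(col, y)
    assert model.coefficients[0] == pytest.approx(np.log(ft.odds_ratio(t)), abs=1e-6)


def test_null_data_deviance_near_intercept_only():
    """On pure noise, the best deviance found cannot beat the
    intercept-only deviance by more than model-selection-sized chance
    (a handful of effective degrees of freedom over the searched space)."""
    rng = np.random.default_rng(9)
    X = rng.integers(0, 2, (300, 15)).astype(np.int8)
    y = (rng.uniform(size=300) < 0.3).astype(int)
    null_dev = ft.fit_coefficients([], X, y).deviance
    cfg = AnnealConfig(iterations=4000, seed=10)
    model, _ = ft.anneal_search(X, y, cfg)
    assert model.deviance <= null_dev + 1e-9
    assert null_dev - model.deviance < 30.0


def test_recovers_planted_and_rule():
    """(target1 high AND target2 low) planted at strong effect is recovered
    truth-table-exactly (up to complement/sign) on a 20-variable panel."""
    spec = ft.OutcomeSpec.conditional(
        TARGET_1, TARGET_2, {"10": 0.75, "11": 0.25, "01": 0.25, "00": 0.25}
    )
    matrix, y = make_panel_matrix(spec, n=500, seed=61, missing_rate=0.0)
    X = subset_matrix(matrix, [TARGET_1, TARGET_2], 20)
    res = ft.LogicRegressionModel(y, X).fit(iterations=5000, restarts=4, seed=62)
    planted = LogicTree.combine("and", LogicTree.leaf(0), LogicTree.leaf(1, True))
    hit = False
    for beta, tree in zip(res.model.coefficients, res.model.trees):
        if tree.is_empty or abs(beta) < 0.5:
            continue
        cand = tree if beta > 0 else tree.complement()
        hit = hit or ft.truth_table_equivalence(cand, planted)
    assert hit
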
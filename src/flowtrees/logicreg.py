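"""Logic regression: generalized linear models over Boolean trees.

The model is g(E[Y|X]) = beta0 + sum_j beta_j L_j where each L_j is a
Boolean combination of binary predictors built from AND, OR and leaf-level
complements (De Morgan's laws make internal complements redundant).  The
tree structures are searched by simulated annealing over six local moves
(alternate a leaf's variable, toggle its complement, alternate an
operator, grow a branch, prune a branch, split/delete a leaf), scoring
each visited state by the deviance (-2 log-likelihood) of the maximum
likelihood fit with the evaluated trees as covariates.  Unlike splitting
methods that enter variables one at a time, this search can pick up pure
interactions — e.g. an XOR — whose components have no marginal effect.

The default model size follows the motivating analysis: two trees with at
most six leaves in total, fixed for interpretability rather than selected
automatically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Iterable

import numpy as np
import pandas as pd

from .preprocess import AnalysisMatrix, OutcomeVector

__all__ = [
    "BooleanLeaf",
    "LogicTree",
    "LogicModel",
    "AnnealConfig",
    "FitResult",
    "evaluate_tree",
    "fit_coefficients",
    "propose_move",
    "anneal_search",
    "truth_table_equivalence",
    "parse_expression",
    "LogicRegressionModel",
    "LogicRegressionResults",
    "MOVE_TYPES",
]

MOVE_TYPES = (
    "alternate_leaf",
    "toggle_complement",
    "alternate_operator",
    "grow_branch",
    "prune_branch",
    "split_delete_leaf",
)

# internal tree encoding: ("leaf", var, complemented) | (op, left, right)
_LEAF = "leaf"
_OPS = ("and", "or")


@dataclass(frozen=True)
class BooleanLeaf:
    variable: int
    complemented: bool = False


class LogicTree:
    """One Boolean tree; ``root=None`` is the constant-0 (empty) tree."""

    def __init__(self, root: tuple | None):
        self.root = root

    # -- constructors -------------------------------------------------
    @classmethod
    def leaf(cls, variable: int, complemented: bool = False) -> "LogicTree":
        return cls((_LEAF, int(variable), bool(complemented)))

    @classmethod
    def combine(cls, op: str, left: "LogicTree", right: "LogicTree") -> "LogicTree":
        if op not in _OPS:
            raise ValueError(f"operator must be one of {_OPS}")
        if left.root is None or right.root is None:
            raise ValueError("cannot combine empty trees")
        return cls((op, left.root, right.root))

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def n_leaves(self) -> int:
        def count(node) -> int:
            if node[0] == _LEAF:
                return 1
            return count(node[1]) + count(node[2])

        return 0 if self.root is None else count(self.root)

    def variables(self) -> set[int]:
        out: set[int] = set()

        def walk(node) -> None:
            if node[0] == _LEAF:
                out.add(node[1])
            else:
                walk(node[1])
                walk(node[2])

        if self.root is not None:
            walk(self.root)
        return out

    def leaves(self) -> list[BooleanLeaf]:
        out: list[BooleanLeaf] = []

        def walk(node) -> None:
            if node[0] == _LEAF:
                out.append(BooleanLeaf(node[1], node[2]))
            else:
                walk(node[1])
                walk(node[2])

        if self.root is not None:
            walk(self.root)
        return out

    def complement(self) -> "LogicTree":
        """The negation, pushed to the leaves by De Morgan's laws."""

        def neg(node) -> tuple:
            if node[0] == _LEAF:
                return (_LEAF, node[1], not node[2])
            op = "or" if node[0] == "and" else "and"
            return (op, neg(node[1]), neg(node[2]))

        if self.root is None:
            raise ValueError("the empty tree has no complement in this encoding")
        return LogicTree(neg(self.root))

    def evaluate(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Vectorised Boolean evaluation; returns an int8 0/1 column."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X)
        if self.root is None:
            return np.zeros(len(X), dtype=np.int8)
        p = X.shape[1]

        def ev(node) -> np.ndarray:
            if node[0] == _LEAF:
                if node[1] >= p:
                    raise IndexError(f"variable index {node[1]} out of range")
                col = X[:, node[1]].astype(np.int8)
                return (1 - col) if node[2] else col
            a, b = ev(node[1]), ev(node[2])
            return (a & b) if node[0] == "and" else (a | b)

        return ev(self.root)

    def render(self, names: list[str] | None = None) -> str:
        def name(j: int) -> str:
            return names[j] if names is not None else f"X{j+1}"

        def walk(node) -> str:
            if node[0] == _LEAF:
                return f"not {name(node[1])}" if node[2] else name(node[1])
            return f"({walk(node[1])} {node[0]} {walk(node[2])})"

        return "0" if self.root is None else walk(self.root)

    def __repr__(self) -> str:
        return f"LogicTree({self.render()})"

    def __eq__(self, other) -> bool:
        return isinstance(other, LogicTree) and self.root == other.root

    def __hash__(self) -> int:
        return hash(self.root)


def evaluate_tree(tree: LogicTree, x: np.ndarray) -> int | np.ndarray:
    """Evaluate one tree on a single binary row (or a matrix of rows)."""
    x = np.asarray(x)
    if x.ndim == 1:
        return int(tree.evaluate(x[None, :])[0])
    return tree.evaluate(x)


# ---------------------------------------------------------------------
# parsing


def parse_expression(text: str, names: list[str] | None = None) -> LogicTree:
    """Parse ``"(X1 and X2) or (X3 and not X4)"`` back into a tree.

    Accepts the same grammar ``render`` emits; ``and``/``or`` chains are
    left-associative.  Variable tokens are matched against ``names`` when
    given, else against the ``X<k>`` convention.
    """
    tokens = re.findall(r"\(|\)|[^\s()]+", text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def var_index(tok: str) -> int:
        if names is not None:
            try:
                return names.index(tok)
            except ValueError:
                raise ValueError(f"unknown variable {tok!r}") from None
        m = re.fullmatch(r"X(\d+)", tok)
        if not m:
            raise ValueError(f"unknown variable {tok!r}")
        return int(m.group(1)) - 1

    def atom() -> tuple:
        tok = take()
        if tok == "(":
            node = expr()
            if take() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if tok == "not":
            inner = atom()
            if inner[0] != _LEAF:
                raise ValueError("complement is only allowed at leaves")
            return (_LEAF, inner[1], not inner[2])
        return (_LEAF, var_index(tok), False)

    def expr() -> tuple:
        node = atom()
        while peek() in _OPS:
            op = take()
            node = (op, node, atom())
        return node

    if text.strip() == "0":
        return LogicTree(None)
    root = expr()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens at {tokens[pos:]}")
    return LogicTree(root)


# ---------------------------------------------------------------------
# model fitting


@dataclass
class FitResult:
    """MLE of the GLM on the evaluated tree columns.

    ``coefficients`` has one entry per input tree; trees dropped for being
    empty/constant/collinear get coefficient 0 and a flag.
    """

    intercept: float
    coefficients: np.ndarray
    deviance: float
    dropped: list[int]
    separation: bool
    link: str


def _irls_binomial(
    Z: np.ndarray, w: np.ndarray, s: np.ndarray, coef_cap: float
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for grouped binomial data; flags separation via the cap."""
    beta = np.zeros(Z.shape[1])
    separation = False
    for _ in range(60):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (s - w * mu)
        W = w * mu * (1.0 - mu)
        H = (Z * W[:, None]).T @ Z
        H.flat[:: H.shape[0] + 1] += 1e-12
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(beta).max() > coef_cap:
            separation = True
            beta = np.clip(beta, -coef_cap, coef_cap)
        if np.abs(grad).max() < 1e-11 or separation:
            break
    return beta, separation


def _binomial_deviance(Z, w, s, beta) -> float:
    eta = Z @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(s * np.log(mu) + (w - s) * np.log(1.0 - mu)))


def fit_coefficients(
    trees: Iterable[LogicTree],
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | OutcomeVector,
    link: str = "logit",
    coef_cap: float = 10.0,
) -> FitResult:
    """Maximum-likelihood fit of the GLM with tree columns as covariates.

    Logit link uses IRLS on the (at most 2^t) strata the binary columns
    induce — exactly equivalent to, and much faster than, the per-subject
    fit.  Identity link uses least squares with deviance = RSS.  Empty,
    constant and collinear columns (duplicates or complements of earlier
    columns / the intercept) are dropped with a flag; under separation the
    coefficients are capped at ``+-coef_cap`` and flagged.
    """
    if link not in ("logit", "identity"):
        raise ValueError("link must be 'logit' or 'identity'")
    trees = list(trees)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    yv = y.y if isinstance(y, OutcomeVector) else np.asarray(y, dtype=float)
    n = len(yv)

    cols: list[np.ndarray] = []
    active: list[int] = []
    dropped: list[int] = []
    for j, tree in enumerate(trees):
        col = tree.evaluate(X)
        total = int(col.sum())
        degenerate = tree.is_empty or total == 0 or total == n
        if not degenerate:
            for prev in cols:
                if np.array_equal(col, prev) or np.array_equal(col, 1 - prev):
                    degenerate = True
                    break
        if degenerate:
            dropped.append(j)
        else:
            cols.append(col)
            active.append(j)

    coeffs = np.zeros(len(trees))
    if link == "identity":
        Z = np.column_stack([np.ones(n)] + [c.astype(float) for c in cols])
        beta, *_ = np.linalg.lstsq(Z, yv, rcond=None)
        resid = yv - Z @ beta
        dev = float(resid @ resid)
        separation = False
    else:
        # aggregate subjects into strata defined by the tree columns
        t = len(cols)
        strata = np.zeros(n, dtype=np.int64)
        for j, c in enumerate(cols):
            strata |= c.astype(np.int64) << j
        k = 1 << t
        w = np.bincount(strata, minlength=k).astype(float)
        s = np.bincount(strata, weights=yv, minlength=k)
        keep = w > 0
        pattern = ((np.arange(k)[:, None] >> np.arange(max(t, 1))) & 1).astype(float)
        Z = np.column_stack([np.ones(k), pattern[:, :t]])[keep]
        beta, separation = _irls_binomial(Z, w[keep], s[keep], coef_cap)
        dev = _binomial_deviance(Z, w[keep], s[keep], beta)
    for i, j in enumerate(active):
        coeffs[j] = beta[1 + i]
    return FitResult(
        intercept=float(beta[0]),
        coefficients=coeffs,
        deviance=dev,
        dropped=dropped,
        separation=separation,
        link=link,
    )


@dataclass
class LogicModel:
    """Fitted logic model: link, intercept, coefficients and trees."""

    link: str
    intercept: float
    coefficients: np.ndarray
    trees: tuple[LogicTree, ...]
    deviance: float
    dropped: list[int] = field(default_factory=list)
    separation: bool = False

    @property
    def n_leaves(self) -> int:
        return sum(t.n_leaves for t in self.trees)

    def linear_predictor(self, X) -> np.ndarray:
        eta = np.full(len(X), self.intercept)
        for beta, tree in zip(self.coefficients, self.trees):
            eta = eta + beta * tree.evaluate(X)
        return eta

    def predict_proba(self, X) -> np.ndarray:
        eta = self.linear_predictor(X)
        if self.link == "identity":
            return eta
        return 1.0 / (1.0 + np.exp(-eta))

    def render(self, names: list[str] | None = None) -> str:
        parts = [f"{self.link}(E[y|x]) = {self.intercept:+.3f}"]
        for beta, tree in zip(self.coefficients, self.trees):
            parts.append(f"{beta:+.3f} * {tree.render(names)}")
        return " ".join(parts)


def _refit(trees, X, y, link, coef_cap) -> LogicModel:
    fr = fit_coefficients(trees, X, y, link=link, coef_cap=coef_cap)
    return LogicModel(
        link=link,
        intercept=fr.intercept,
        coefficients=fr.coefficients,
        trees=tuple(trees),
        deviance=fr.deviance,
        dropped=fr.dropped,
        separation=fr.separation,
    )


# ---------------------------------------------------------------------
# annealing moves


def _leaf_positions(node, path=()) -> list[tuple]:
    if node[0] == _LEAF:
        return [path]
    return _leaf_positions(node[1], path + (1,)) + _leaf_positions(node[2], path + (2,))


def _op_positions(node, path=()) -> list[tuple]:
    if node[0] == _LEAF:
        return []
    return (
        [path]
        + _op_positions(node[1], path + (1,))
        + _op_positions(node[2], path + (2,))
    )


def _get(node, path):
    for step in path:
        node = node[step]
    return node


def _set(node, path, new) -> tuple:
    if not path:
        return new
    head, *rest = path
    if head == 1:
        return (node[0], _set(node[1], rest, new), node[2])
    return (node[0], node[1], _set(node[2], rest, new))


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing settings.

    Geometric cooling from ``t_start`` to ``t_end`` over ``iterations``
    proposals; ``move_probs`` orders over :data:`MOVE_TYPES` and must sum
    to 1.  ``n_trees`` and ``max_leaves`` are the model-size constraints
    (two trees, six leaves total by default).
    """

    t_start: float = 2.0
    t_end: float = 0.001
    iterations: int = 50_000
    restarts: int = 1
    move_probs: tuple[float, ...] = (1 / 6,) * 6
    n_trees: int = 2
    max_leaves: int = 6
    seed: int = 0
    link: str = "logit"
    coef_cap: float = 10.0

    def __post_init__(self) -> None:
        if not (self.t_start > 0 and self.t_end > 0 and self.t_start >= self.t_end):
            raise ValueError("temperatures must be positive and decreasing")
        if self.iterations < 1 or self.restarts < 1:
            raise ValueError("iteration budget and restarts must be >= 1")
        if len(self.move_probs) != 6 or abs(sum(self.move_probs) - 1.0) > 1e-9:
            raise ValueError("move_probs must be 6 probabilities summing to 1")
        if self.n_trees < 1 or self.max_leaves < self.n_trees:
            raise ValueError("need n_trees >= 1 and max_leaves >= n_trees")


def _apply_move(
    trees: tuple[LogicTree, ...],
    move: str,
    rng: np.random.Generator,
    p: int,
    max_leaves: int,
) -> tuple[LogicTree, ...] | None:
    """One random application of the move type, or None if inapplicable."""
    total_leaves = sum(t.n_leaves for t in trees)
    nonempty = [i for i, t in enumerate(trees) if not t.is_empty]

    def replace_tree(i: int, new: LogicTree) -> tuple[LogicTree, ...]:
        out = list(trees)
        out[i] = new
        return tuple(out)

    if move == "alternate_leaf":
        if not nonempty or p < 2:
            return None
        i = int(rng.choice(nonempty))
        root = trees[i].root
        paths = _leaf_positions(root)
        path = paths[rng.integers(len(paths))]
        leaf = _get(root, path)
        new_var = int(rng.integers(p - 1))
        if new_var >= leaf[1]:
            new_var += 1
        return replace_tree(i, LogicTree(_set(root, path, (_LEAF, new_var, leaf[2]))))

    if move == "toggle_complement":
        if not nonempty:
            return None
        i = int(rng.choice(nonempty))
        root = trees[i].root
        paths = _leaf_positions(root)
        path = paths[rng.integers(len(paths))]
        leaf = _get(root, path)
        return replace_tree(i, LogicTree(_set(root, path, (_LEAF, leaf[1], not leaf[2]))))

    if move == "alternate_operator":
        with_ops = [i for i in nonempty if _op_positions(trees[i].root)]
        if not with_ops:
            return None
        i = int(rng.choice(with_ops))
        root = trees[i].root
        paths = _op_positions(root)
        path = paths[rng.integers(len(paths))]
        node = _get(root, path)
        flipped = ("or" if node[0] == "and" else "and", node[1], node[2])
        return replace_tree(i, LogicTree(_set(root, path, flipped)))

    if move in ("grow_branch", "split_delete_leaf") and move == "grow_branch":
        if total_leaves >= max_leaves or not nonempty:
            return None
        i = int(rng.choice(nonempty))
        root = trees[i].root
        paths = _leaf_positions(root)
        path = paths[rng.integers(len(paths))]
        leaf = _get(root, path)
        op = _OPS[rng.integers(2)]
        new_leaf = (_LEAF, int(rng.integers(p)), bool(rng.integers(2)))
        grown = (op, leaf, new_leaf)
        return replace_tree(i, LogicTree(_set(root, path, grown)))

    if move == "prune_branch":
        # remove one leaf that hangs off an operator, promoting its sibling
        candidates = []
        for i in nonempty:
            root = trees[i].root
            for path in _op_positions(root):
                node = _get(root, path)
                for child, sibling in ((1, 2), (2, 1)):
                    if node[child][0] == _LEAF:
                        candidates.append((i, path, sibling))
        if not candidates:
            return None
        i, path, sibling = candidates[rng.integers(len(candidates))]
        root = trees[i].root
        node = _get(root, path)
        return replace_tree(i, LogicTree(_set(root, path, node[sibling])))

    if move == "split_delete_leaf":
        # split: revive an empty tree with a fresh leaf; delete: drop the
        # only leaf of a single-leaf tree (the tree becomes constant 0)
        empties = [i for i, t in enumerate(trees) if t.is_empty]
        singles = [i for i in nonempty if trees[i].root[0] == _LEAF]
        options = []
        if empties and total_leaves < max_leaves:
            options.append("split")
        if singles:
            options.append("delete")
        if not options:
            return None
        choice = options[rng.integers(len(options))]
        if choice == "split":
            i = int(rng.choice(empties))
            return replace_tree(
                i, LogicTree.leaf(int(rng.integers(p)), bool(rng.integers(2)))
            )
        i = int(rng.choice(singles))
        return replace_tree(i, LogicTree(None))

    raise ValueError(f"unknown move type {move!r}")


def propose_move(
    trees: tuple[LogicTree, ...],
    move: str,
    rng: np.random.Generator | int,
    p: int,
    max_leaves: int = 6,
) -> tuple[tuple[LogicTree, ...], bool]:
    """Apply one move; returns (new trees, applied flag).

    Inapplicable moves (e.g. grow at a full leaf budget) return the state
    unchanged with ``applied=False``.
    """
    if move not in MOVE_TYPES:
        raise ValueError(f"unknown move type {move!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence(int(rng)))
    out = _apply_move(tuple(trees), move, rng, p, max_leaves)
    if out is None:
        return tuple(trees), False
    return out, True


def anneal_search(
    X, y, config: AnnealConfig | None = None
) -> tuple[LogicModel, pd.DataFrame]:
    """Simulated annealing over logic-tree moves, scored by deviance.

    Moves are drawn from ``config.move_probs``; a proposal with score
    increase ``d`` is accepted with probability exp(-d / T) under the
    geometric cooling schedule.  ``restarts`` independent chains are run
    (pure-interaction signals leave single leaves with no marginal effect,
    so chains can stall; restarting is the standard remedy) and the best
    state over all chains is refitted and returned, together with the
    concatenated iteration history (best score monotone within a chain).
    """
    config = config or AnnealConfig()
    if isinstance(X, AnalysisMatrix):
        X = X.X
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=np.int8)
    yv = y.y if isinstance(y, OutcomeVector) else np.asarray(y, dtype=float)

    best_model, best_hist, best_score = None, None, np.inf
    for chain, ss in enumerate(np.random.SeedSequence(config.seed).spawn(config.restarts)):
        model, hist = _anneal_chain(X, yv, config, np.random.default_rng(ss))
        hist["chain"] = chain
        if model.deviance < best_score:
            best_model, best_score = model, model.deviance
        best_hist = hist if best_hist is None else pd.concat(
            [best_hist, hist], ignore_index=True
        )
    return best_model, best_hist


def _anneal_chain(
    X: np.ndarray, yv: np.ndarray, config: AnnealConfig, rng: np.random.Generator
) -> tuple[LogicModel, pd.DataFrame]:
    n, p = X.shape
    start_vars = rng.choice(p, size=min(config.n_trees, p), replace=False)
    trees = tuple(LogicTree.leaf(int(v)) for v in start_vars)
    while len(trees) < config.n_trees:
        trees = trees + (LogicTree.leaf(int(rng.integers(p))),)

    def score(state) -> float:
        return fit_coefficients(
            state, X, yv, link=config.link, coef_cap=config.coef_cap
        ).deviance

    cur_score = score(trees)
    best_trees, best_score = trees, cur_score
    cooling = (config.t_end / config.t_start) ** (1.0 / max(config.iterations - 1, 1))
    temp = config.t_start
    history = {"iteration": [], "temperature": [], "score": [], "best_score": []}
    accepted = 0
    checkpoint = max(config.iterations // 200, 1)

    for it in range(config.iterations):
        move = MOVE_TYPES[rng.choice(6, p=config.move_probs)]
        proposal, applied = propose_move(trees, move, rng, p, config.max_leaves)
        if applied:
            new_score = score(proposal)
            delta = new_score - cur_score
            if delta <= 0 or rng.uniform() < np.exp(-delta / temp):
                trees, cur_score = proposal, new_score
                accepted += 1
                if cur_score < best_score - 1e-12:
                    best_trees, best_score = trees, cur_score
        if it % checkpoint == 0 or it == config.iterations - 1:
            history["iteration"].append(it)
            history["temperature"].append(temp)
            history["score"].append(cur_score)
            history["best_score"].append(best_score)
        temp *= cooling

    model = _refit(best_trees, X, yv, config.link, config.coef_cap)
    hist = pd.DataFrame(history)
    hist.attrs["accepted"] = accepted
    return model, hist


def truth_table_equivalence(t1: LogicTree, t2: LogicTree) -> bool:
    """Exhaustive equivalence over all assignments of referenced variables."""
    variables = sorted(t1.variables() | t2.variables())
    k = len(variables)
    if k > 20:
        raise ValueError("truth-table check limited to 20 distinct variables")
    if k == 0:
        return t1.is_empty == t2.is_empty
    width = max(variables) + 1
    assignments = np.zeros((2**k, width), dtype=np.int8)
    for j, v in enumerate(variables):
        assignments[:, v] = (np.arange(2**k) >> j) & 1
    return bool(np.array_equal(t1.evaluate(assignments), t2.evaluate(assignments)))


# ---------------------------------------------------------------------
# model-style interface


class LogicRegressionResults:
    """Best logic model found by annealing, plus the search history."""

    def __init__(self, model: LogicModel, history: pd.DataFrame, names: list[str]):
        self.model = model
        self.history = history
        self.var_names = names

    @property
    def deviance(self) -> float:
        return self.model.deviance

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.model.intercept], self.model.coefficients])

    def expression(self) -> str:
        return self.model.render(self.var_names)

    def summary(self) -> str:
        lines = [
            f"Logic regression ({self.model.link} link): deviance = "
            f"{self.model.deviance:.3f}, {self.model.n_leaves} leaves",
            f"  intercept: {self.model.intercept:+.3f}",
        ]
        for j, (beta, tree) in enumerate(
            zip(self.model.coefficients, self.model.trees), start=1
        ):
            flag = " [dropped]" if j - 1 in self.model.dropped else ""
            lines.append(f"  tree {j}: beta = {beta:+.3f}  L{j} = "
                         f"{tree.render(self.var_names)}{flag}")
        if self.model.separation:
            lines.append("  note: separation detected; coefficients capped")
        return "\n".join(lines)


class LogicRegressionModel:
    """Model-style interface: ``LogicRegressionModel(y, X).fit(seed=...)``."""

    def __init__(
        self,
        endog,
        exog,
        n_trees: int = 2,
        max_leaves: int = 6,
        link: str = "logit",
    ):
        if isinstance(exog, AnalysisMatrix):
            self.var_names = exog.variable_names
            self.exog = exog.X.to_numpy(dtype=np.int8)
        elif isinstance(exog, pd.DataFrame):
            self.var_names = [str(c) for c in exog.columns]
            self.exog = exog.to_numpy(dtype=np.int8)
        else:
            self.exog = np.asarray(exog, dtype=np.int8)
            self.var_names = [f"X{j+1}" for j in range(self.exog.shape[1])]
        self.endog = endog.y if isinstance(endog, OutcomeVector) else np.asarray(endog)
        self.n_trees = n_trees
        self.max_leaves = max_leaves
        self.link = link

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome_column: str, **kwargs
    ) -> "LogicRegressionModel":
        return cls(
            data[outcome_column].to_numpy(),
            data.drop(columns=[outcome_column]),
            **kwargs,
        )

    def fit(
        self, config: AnnealConfig | None = None, seed: int | None = None, **overrides
    ) -> LogicRegressionResults:
        if config is None:
            config = AnnealConfig(
                n_trees=self.n_trees,
                max_leaves=self.max_leaves,
                link=self.link,
                **overrides,
            )
        if seed is not None:
            config = _dc_replace(config, seed=seed)
        model, history = anneal_search(self.exog, self.endog, config)
        return LogicRegressionResults(model, history, self.var_names)
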
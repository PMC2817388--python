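"""Classification trees on binary predictors: Gini growing, weakest-link
cost-complexity pruning, cross-validated subtree selection.

Splits maximise the impurity reduction

    phi = i(node) - pi_L i(left) - pi_R i(right),

with i the Gini index 2 p (1 - p) and pi_L, pi_R the within-node child
fractions.  Because every predictor is an above/below-median indicator,
each variable admits exactly one split, so the search is exhaustive over
variables.  A split is admissible only if phi > 0 and both children hold
at least ``min_node`` subjects (the child-size floor).

Pruning follows the classical cost-complexity scheme: for alpha >= 0 the
penalised risk is R_alpha(T) = R(T) + alpha |T|, with R(T) the
leaf-probability-weighted misclassification rate; repeatedly collapsing
the weakest link (smallest per-leaf risk increase g) yields the nested
sequence of alpha-optimal subtrees.  The final subtree is chosen by
stratified cross-validation with either the minimum-error or the
one-standard-error rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import AnalysisMatrix, OutcomeVector

__all__ = [
    "gini",
    "TreeNode",
    "ClassificationTree",
    "SplitEvaluation",
    "PruneStep",
    "best_split",
    "grow_tree",
    "risk",
    "prune_sequence",
    "select_subtree_cv",
    "ClassificationTreeModel",
    "TreeResults",
]

_PHI_EPS = 1e-12


def gini(p_hat: float) -> float:
    """Gini impurity 2 p (1 - p) of a binary node."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    return 2.0 * p_hat * (1.0 - p_hat)


@dataclass
class TreeNode:
    """One node: counts, root-fraction pi, responder fraction, prediction.

    ``left`` is the child with predictor value 1 ("high"), ``right`` the
    child with value 0.
    """

    id: int
    n: int
    n_resp: int
    pi: float
    depth: int = 0
    split_var: int | None = None
    split_name: str | None = None
    left: int | None = None
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    @property
    def p_hat(self) -> float:
        return self.n_resp / self.n if self.n else 0.0

    @property
    def prediction(self) -> int:
        # majority class; exact tie predicts 0
        return int(self.n_resp * 2 > self.n)

    @property
    def misclassified(self) -> int:
        return min(self.n_resp, self.n - self.n_resp)


@dataclass
class ClassificationTree:
    nodes: dict[int, TreeNode]
    root: int
    var_names: list[str]
    min_node: int

    @property
    def n(self) -> int:
        return self.nodes[self.root].n

    def leaf_ids(self, collapsed: frozenset[int] = frozenset()) -> list[int]:
        """Terminal nodes of the (optionally pruned) tree, in BFS order."""
        out, queue = [], [self.root]
        while queue:
            nid = queue.pop(0)
            node = self.nodes[nid]
            if node.is_leaf or nid in collapsed:
                out.append(nid)
            else:
                queue.extend([node.left, node.right])
        return out

    def internal_ids(self, collapsed: frozenset[int] = frozenset()) -> list[int]:
        out, queue = [], [self.root]
        while queue:
            nid = queue.pop(0)
            node = self.nodes[nid]
            if node.is_leaf or nid in collapsed:
                continue
            out.append(nid)
            queue.extend([node.left, node.right])
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids())

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense (split_var, left, right, prediction) arrays keyed by id."""
        cached = getattr(self, "_arr_cache", None)
        if cached is not None:
            return cached
        size = max(self.nodes) + 1
        sv = np.full(size, -1, dtype=np.int64)
        lc = np.zeros(size, dtype=np.int64)
        rc = np.zeros(size, dtype=np.int64)
        pred = np.zeros(size, dtype=np.int64)
        for nid, node in self.nodes.items():
            pred[nid] = node.prediction
            if not node.is_leaf:
                sv[nid] = node.split_var
                lc[nid] = node.left
                rc[nid] = node.right
        self._arr_cache = (sv, lc, rc, pred)
        return self._arr_cache

    def predict(
        self, X: np.ndarray | pd.DataFrame, collapsed: frozenset[int] = frozenset()
    ) -> np.ndarray:
        leaf = self.apply(X, collapsed)
        _, _, _, pred = self._arrays()
        return pred[leaf]

    def apply(
        self, X: np.ndarray | pd.DataFrame, collapsed: frozenset[int] = frozenset()
    ) -> np.ndarray:
        """Leaf id reached by each row (iterative array descent)."""
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.asarray(X)
        sv, lc, rc, _ = self._arrays()
        if collapsed:
            sv = sv.copy()
            sv[list(collapsed)] = -1
        ids = np.full(len(X), self.root, dtype=np.int64)
        idx = np.flatnonzero(sv[ids] >= 0)
        while idx.size:
            cur = ids[idx]
            high = X[idx, sv[cur]] == 1
            ids[idx] = np.where(high, lc[cur], rc[cur])
            idx = idx[sv[ids[idx]] >= 0]
        return ids

    def prune_to(self, collapsed: frozenset[int]) -> "ClassificationTree":
        """Materialise a pruned subtree (collapsed nodes become leaves)."""
        keep: dict[int, TreeNode] = {}
        queue = [self.root]
        while queue:
            nid = queue.pop()
            src = self.nodes[nid]
            if src.is_leaf or nid in collapsed:
                keep[nid] = TreeNode(
                    id=nid, n=src.n, n_resp=src.n_resp, pi=src.pi, depth=src.depth
                )
            else:
                keep[nid] = TreeNode(
                    id=nid,
                    n=src.n,
                    n_resp=src.n_resp,
                    pi=src.pi,
                    depth=src.depth,
                    split_var=src.split_var,
                    split_name=src.split_name,
                    left=src.left,
                    right=src.right,
                )
                queue.extend([src.left, src.right])
        return ClassificationTree(
            nodes=keep, root=self.root, var_names=self.var_names, min_node=self.min_node
        )

    def split_variables(self) -> set[int]:
        return {n.split_var for n in self.nodes.values() if not n.is_leaf}

    def render(self) -> str:
        """Indented text rendering: split variable and `responders/n` per node."""
        lines: list[str] = []

        def walk(nid: int, indent: int, label: str) -> None:
            node = self.nodes[nid]
            tag = f"{node.n_resp}/{node.n} ({100 * node.p_hat:.1f}%)"
            if node.is_leaf:
                lines.append(f"{'  ' * indent}{label}leaf {tag} -> class {node.prediction}")
            else:
                lines.append(f"{'  ' * indent}{label}split on {node.split_name} {tag}")
                walk(node.left, indent + 1, "[high] ")
                walk(node.right, indent + 1, "[low]  ")

        walk(self.root, 0, "")
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "root": self.root,
            "min_node": self.min_node,
            "var_names": self.var_names,
            "nodes": [
                {
                    "id": n.id,
                    "n": n.n,
                    "n_resp": n.n_resp,
                    "pi": n.pi,
                    "depth": n.depth,
                    "split_var": n.split_var,
                    "split_name": n.split_name,
                    "left": n.left,
                    "right": n.right,
                }
                for n in self.nodes.values()
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClassificationTree":
        d = json.loads(text)
        nodes = {int(n["id"]): TreeNode(**n) for n in d["nodes"]}
        return cls(
            nodes=nodes,
            root=int(d["root"]),
            var_names=list(d["var_names"]),
            min_node=int(d["min_node"]),
        )


@dataclass(frozen=True)
class SplitEvaluation:
    """Best split of one node: variable, phi, child impurities/weights."""

    variable: int
    name: str
    phi: float
    impurity_left: float
    impurity_right: float
    weight_left: float
    weight_right: float
    n_left: int
    n_right: int


def _as_arrays(X, y) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(X, AnalysisMatrix):
        names = X.variable_names
        X = X.X.to_numpy(dtype=np.int8)
    elif isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=np.int8)
    else:
        X = np.asarray(X, dtype=np.int8)
        names = [f"X{j+1}" for j in range(X.shape[1])]
    yv = y.y if isinstance(y, OutcomeVector) else np.asarray(y, dtype=int)
    return X, yv, names


def _best_split_arrays(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    min_node: int,
    candidates: np.ndarray,
) -> tuple[int, float, np.ndarray] | None:
    """Vectorised phi over candidate columns; returns (col, phi, stats)."""
    Xn = X[np.ix_(rows, candidates)]
    yn = y[rows]
    n = len(yn)
    resp = int(yn.sum())
    i_node = gini(resp / n)
    if i_node <= 0.0:
        return None
    n1 = Xn.sum(axis=0, dtype=np.int64)
    r1 = yn @ Xn
    n0 = n - n1
    r0 = resp - r1
    valid = (n1 >= min_node) & (n0 >= min_node)
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, r1 / np.maximum(n1, 1), 0.0)
        p0 = np.where(n0 > 0, r0 / np.maximum(n0, 1), 0.0)
    phi = i_node - (n1 / n) * 2 * p1 * (1 - p1) - (n0 / n) * 2 * p0 * (1 - p0)
    phi = np.where(valid, phi, -np.inf)
    k = int(np.argmax(phi))  # ties -> lowest candidate index (candidates sorted)
    if phi[k] <= _PHI_EPS:
        return None
    stats = np.array([n1[k], r1[k], n0[k], r0[k]], dtype=np.int64)
    return int(candidates[k]), float(phi[k]), stats


def best_split(
    X, y, min_node: int = 1, candidates: np.ndarray | None = None
) -> SplitEvaluation | None:
    """Exhaustive best split of the given subjects, or None.

    Returns None when the node is pure, no split has phi > 0, or every
    split violates the child-size floor.  Ties in phi resolve to the
    lowest variable index.
    """
    Xa, yv, names = _as_arrays(X, y)
    if len(yv) < 2:
        return None
    cand = np.arange(Xa.shape[1]) if candidates is None else np.sort(candidates)
    hit = _best_split_arrays(Xa, yv, np.ones(len(yv), bool), min_node, cand)
    if hit is None:
        return None
    col, phi, (n1, r1, n0, r0) = hit
    n = len(yv)
    return SplitEvaluation(
        variable=col,
        name=names[col],
        phi=phi,
        impurity_left=gini(r1 / n1) if n1 else 0.0,
        impurity_right=gini(r0 / n0) if n0 else 0.0,
        weight_left=n1 / n,
        weight_right=n0 / n,
        n_left=int(n1),
        n_right=int(n0),
    )


def grow_tree(
    X,
    y,
    min_node: int = 5,
    mtry: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClassificationTree:
    """Recursive Gini partitioning until no admissible split remains.

    ``mtry`` restricts each node's candidate set to a fresh random subset
    of predictors (random-forest mode); ``mtry=None`` searches all.
    """
    Xa, yv, names = _as_arrays(X, y)
    n, p = Xa.shape
    if n == 0:
        raise ValueError("empty input")
    if mtry is not None and not 1 <= mtry <= p:
        raise ValueError("mtry must be in [1, p]")
    if min_node < 1:
        raise ValueError("min_node must be >= 1")
    use_mtry = mtry is not None and mtry < p

    Xf = Xa.astype(np.float64)
    yf = yv.astype(np.float64)
    nodes: dict[int, TreeNode] = {
        0: TreeNode(id=0, n=n, n_resp=int(yv.sum()), pi=1.0, depth=0)
    }
    node_of = np.zeros(n, dtype=np.int64)
    next_id = 1
    # frontier: node ids that could still be split, processed level-wise so
    # the per-level split search is a pair of matrix products
    frontier = [0] if (n >= 2 * min_node and nodes[0].misclassified > 0) else []
    while frontier:
        act = np.asarray(frontier, dtype=np.int64)
        k = len(act)
        slot = np.full(next_id, -1, dtype=np.int64)
        slot[act] = np.arange(k)
        srows = slot[node_of]
        live = np.flatnonzero(srows >= 0)
        M = np.zeros((k, n))
        M[srows[live], live] = 1.0
        n1 = M @ Xf  # k x p: high-count per (node, variable)
        r1 = (M * yf) @ Xf  # responders among the highs
        nn = np.array([nodes[i].n for i in act], dtype=np.float64)
        rr = np.array([nodes[i].n_resp for i in act], dtype=np.float64)
        n0 = nn[:, None] - n1
        r0 = rr[:, None] - r1
        p_node = rr / nn
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(n1 > 0, r1 / np.maximum(n1, 1), 0.0)
            p0 = np.where(n0 > 0, r0 / np.maximum(n0, 1), 0.0)
        phi = (
            (2 * p_node * (1 - p_node))[:, None]
            - (n1 / nn[:, None]) * 2 * p1 * (1 - p1)
            - (n0 / nn[:, None]) * 2 * p0 * (1 - p0)
        )
        valid = (n1 >= min_node) & (n0 >= min_node)
        if use_mtry:
            draws = rng.random((k, p))
            chosen = np.argpartition(draws, mtry - 1, axis=1)[:, :mtry]
            cmask = np.zeros((k, p), dtype=bool)
            np.put_along_axis(cmask, chosen, True, axis=1)
            valid &= cmask
        phi = np.where(valid, phi, -np.inf)
        best = np.argmax(phi, axis=1)  # ties -> lowest variable index
        best_phi = phi[np.arange(k), best]

        frontier = []
        for i, nid in enumerate(act):
            if best_phi[i] <= _PHI_EPS:
                continue
            col = int(best[i])
            node = nodes[nid]
            in_node = node_of == nid
            high = in_node & (Xa[:, col] == 1)
            low = in_node & ~high
            node.split_var = col
            node.split_name = names[col]
            stats = (
                ((int(n1[i, col]), int(round(r1[i, col]))), high, "left"),
                ((int(n0[i, col]), int(round(r0[i, col]))), low, "right"),
            )
            for (cn, cr), child_rows, attr in stats:
                cid = next_id
                next_id += 1
                child = TreeNode(
                    id=cid, n=cn, n_resp=cr, pi=cn / n, depth=node.depth + 1
                )
                nodes[cid] = child
                setattr(node, attr, cid)
                node_of[child_rows] = cid
                if cn >= 2 * min_node and child.misclassified > 0:
                    frontier.append(cid)

    return ClassificationTree(nodes=nodes, root=0, var_names=names, min_node=min_node)


def risk(
    tree: ClassificationTree, collapsed: frozenset[int] = frozenset()
) -> float:
    """Training risk R(T): leaf-probability-weighted misclassification.

    Equals the overall training misclassification proportion of the
    majority-rule tree.
    """
    n = tree.n
    return sum(tree.nodes[i].misclassified for i in tree.leaf_ids(collapsed)) / n


@dataclass(frozen=True)
class PruneStep:
    """One element of the nested pruning sequence."""

    alpha: float
    collapsed: frozenset[int]
    n_leaves: int
    risk: float


def _branch_stats(
    tree: ClassificationTree, nid: int, collapsed: frozenset[int]
) -> tuple[float, int]:
    """(risk contribution, leaf count) of the branch rooted at nid."""
    r, leaves, queue = 0.0, 0, [nid]
    while queue:
        cur = queue.pop()
        node = tree.nodes[cur]
        if node.is_leaf or cur in collapsed:
            r += node.misclassified / tree.n
            leaves += 1
        else:
            queue.extend([node.left, node.right])
    return r, leaves


def prune_sequence(tree: ClassificationTree) -> list[PruneStep]:
    """Weakest-link cost-complexity pruning sequence.

    Each step collapses every internal node attaining the minimal
    g(t) = (r(t as leaf) - R(branch t)) / (|branch leaves| - 1); recording
    the critical alpha.  Steps with tied alpha merge, so alphas are
    strictly increasing, subtree sizes strictly decreasing, and each
    step's subtree minimises R + alpha|T| at its alpha.
    """
    collapsed: frozenset[int] = frozenset()
    steps = [PruneStep(0.0, collapsed, len(tree.leaf_ids()), risk(tree))]
    while True:
        internal = tree.internal_ids(collapsed)
        if not internal:
            break
        gs = {}
        for nid in internal:
            node = tree.nodes[nid]
            r_branch, n_leaves = _branch_stats(tree, nid, collapsed)
            gs[nid] = (node.misclassified / tree.n - r_branch) / (n_leaves - 1)
        g_min = min(gs.values())
        weakest = {nid for nid, g in gs.items() if g <= g_min + 1e-12}
        collapsed = frozenset(collapsed | weakest)
        step = PruneStep(
            alpha=max(g_min, 0.0),
            collapsed=collapsed,
            n_leaves=len(tree.leaf_ids(collapsed)),
            risk=risk(tree, collapsed),
        )
        if steps and abs(steps[-1].alpha - step.alpha) <= 1e-12:
            steps[-1] = step
        else:
            steps.append(step)
    return steps


def _subtree_for_alpha(steps: list[PruneStep], alpha: float) -> PruneStep:
    chosen = steps[0]
    for s in steps:
        if s.alpha <= alpha + 1e-12:
            chosen = s
    return chosen


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    assignments = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignments[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignments == f) for f in range(folds)]


def select_subtree_cv(
    X,
    y,
    min_node: int = 5,
    folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
) -> tuple[ClassificationTree, pd.DataFrame]:
    """Cross-validated cost-complexity subtree selection.

    Candidate alphas are geometric midpoints of the main sequence's
    critical values; per-fold trees are grown and pruned independently and
    scored on the held-out fold.  ``rule="min"`` picks the error-minimising
    alpha (ties toward the smaller tree); ``rule="1se"`` the smallest tree
    within one binomial standard error of the minimum.  Returns the
    materialised subtree and the CV table.
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    Xa, yv, names = _as_arrays(X, y)
    n = len(yv)
    if not 2 <= folds <= n:
        raise ValueError("folds must be in [2, n]")

    full = grow_tree(X, y, min_node=min_node)
    steps = prune_sequence(full)
    alphas = [s.alpha for s in steps]
    cand = []
    for k in range(len(alphas)):
        if k + 1 < len(alphas):
            cand.append(float(np.sqrt(max(alphas[k], 0.0) * alphas[k + 1])))
        else:
            cand.append(alphas[k] if alphas[k] > 0 else 0.0)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    misclassified = np.zeros(len(cand))
    for test_idx in _stratified_folds(yv, folds, rng):
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        ft = grow_tree(Xa[train], yv[train], min_node=min_node)
        fsteps = prune_sequence(ft)
        for k, a in enumerate(cand):
            s = _subtree_for_alpha(fsteps, a)
            pred = ft.predict(Xa[test_idx], collapsed=s.collapsed)
            misclassified[k] += int((pred != yv[test_idx]).sum())

    cv_err = misclassified / n
    cv_se = np.sqrt(np.maximum(cv_err * (1 - cv_err), 0.0) / n)
    table = pd.DataFrame(
        {
            "alpha": cand,
            "n_leaves": [s.n_leaves for s in steps],
            "train_risk": [s.risk for s in steps],
            "cv_error": cv_err,
            "cv_se": cv_se,
        }
    )
    k_min = len(cand) - 1 - int(np.argmin(cv_err[::-1]))  # ties -> smaller tree
    if rule == "1se":
        limit = cv_err[k_min] + cv_se[k_min]
        eligible = np.flatnonzero(cv_err <= limit + 1e-12)
        k_sel = int(eligible.max())
    else:
        k_sel = k_min
    selected = full.prune_to(steps[k_sel].collapsed)
    table["selected"] = [i == k_sel for i in range(len(cand))]
    return selected, table


class TreeResults:
    """Fitted classification tree plus its pruning/CV diagnostics."""

    def __init__(
        self,
        tree: ClassificationTree,
        full_tree: ClassificationTree,
        steps: list[PruneStep],
        cv_table: pd.DataFrame | None,
    ):
        self.tree = tree
        self.full_tree = full_tree
        self.prune_steps = steps
        self.cv_table = cv_table

    @property
    def train_risk(self) -> float:
        return risk(self.tree)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, AnalysisMatrix):
            X = X.X
        return self.tree.predict(X)

    def summary(self) -> str:
        parts = [
            f"Classification tree: {self.tree.n_leaves} leaves, "
            f"training risk {self.train_risk:.4f}",
            self.tree.render(),
        ]
        if self.cv_table is not None:
            parts.append("\nCost-complexity cross-validation:")
            parts.append(self.cv_table.to_string(index=False, float_format="%.4f"))
        return "\n".join(parts)


class ClassificationTreeModel:
    """Model-style interface: ``ClassificationTreeModel(y, X).fit()``."""

    def __init__(self, endog, exog, min_node: int = 5):
        self.endog = endog
        self.exog = exog
        self.min_node = min_node

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome_column: str, min_node: int = 5
    ) -> "ClassificationTreeModel":
        return cls(
            data[outcome_column].to_numpy(),
            data.drop(columns=[outcome_column]),
            min_node=min_node,
        )

    def fit(
        self,
        prune: str = "cv",
        folds: int = 10,
        rule: str = "1se",
        seed: int = 0,
    ) -> TreeResults:
        """Grow the full tree; ``prune="cv"`` also selects a CV subtree,
        ``prune="none"`` returns the unpruned tree."""
        full = grow_tree(self.exog, self.endog, min_node=self.min_node)
        steps = prune_sequence(full)
        if prune == "none":
            return TreeResults(full, full, steps, None)
        if prune != "cv":
            raise ValueError("prune must be 'cv' or 'none'")
        selected, table = select_subtree_cv(
            self.exog,
            self.endog,
            min_node=self.min_node,
            folds=folds,
            rule=rule,
            seed=seed,
        )
        return TreeResults(selected, full, steps, table)
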
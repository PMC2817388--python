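"""Random forests of unpruned Gini trees with out-of-bag importance.

Each of B trees is grown on a bootstrap sample of size n (with
replacement, so ~63.2% unique subjects are in-bag and the rest are that
tree's out-of-bag test set) restricting every node's split search to a
fresh random subset of ``mtry`` predictors.  Two importance flavours are
computed side by side:

* permutation importance: delta_bj = OOB error of tree b after permuting
  predictor j within its OOB set, minus the unpermuted OOB error; the
  score theta_j is the mean of delta_bj over trees — larger means more
  important;
* mean decrease in node impurity: the count-weighted Gini reduction
  n_node * phi summed over the splits on j, averaged over trees.

A variable never sampled into any tree has permutation importance exactly
zero: permuting it cannot change a single prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cart import ClassificationTree, gini, grow_tree
from .preprocess import AnalysisMatrix, OutcomeVector

__all__ = [
    "ForestConfig",
    "Forest",
    "grow_forest",
    "oob_error",
    "permutation_importance",
    "gini_importance",
    "importance_table",
    "RandomForestModel",
    "ForestResults",
]


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; ``mtry=None`` means ceil(sqrt(p))."""

    B: int = 500
    mtry: int | None = None
    min_node: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is None:
            return int(np.ceil(np.sqrt(p)))
        if self.mtry > p:
            raise ValueError(f"mtry={self.mtry} exceeds p={p}")
        return self.mtry


@dataclass
class Forest:
    """Fitted ensemble: trees plus in-bag counts and OOB masks."""

    trees: list[ClassificationTree]
    inbag_counts: list[np.ndarray]
    oob_masks: list[np.ndarray]
    config: ForestConfig
    var_names: list[str]
    n: int

    @property
    def B(self) -> int:
        return len(self.trees)

    @property
    def p(self) -> int:
        return len(self.var_names)

    def oob_coverage(self) -> np.ndarray:
        """Number of trees for which each subject is out-of-bag."""
        return np.sum(self.oob_masks, axis=0)


def _prep(X, y):
    if isinstance(X, AnalysisMatrix):
        names = X.variable_names
        Xa = X.X.to_numpy(dtype=np.int8)
    elif isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(dtype=np.int8)
    else:
        Xa = np.asarray(X, dtype=np.int8)
        names = [f"X{j+1}" for j in range(Xa.shape[1])]
    yv = y.y if isinstance(y, OutcomeVector) else np.asarray(y, dtype=int)
    return Xa, yv, names


def grow_forest(X, y, config: ForestConfig | None = None) -> Forest:
    """Grow B unpruned trees on independent bootstrap samples.

    One master seed spawns an independent stream per tree, so increasing B
    extends the forest without reshuffling earlier trees.
    """
    config = config or ForestConfig()
    Xa, yv, names = _prep(X, y)
    n, p = Xa.shape
    mtry = config.resolve_mtry(p)
    streams = np.random.SeedSequence(config.seed).spawn(config.B)

    trees, inbag, oob = [], [], []
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        counts = np.bincount(idx, minlength=n)
        tree = grow_tree(
            Xa[idx], yv[idx], min_node=config.min_node, mtry=mtry, rng=rng
        )
        tree.var_names = names
        trees.append(tree)
        inbag.append(counts)
        oob.append(counts == 0)
    forest = Forest(
        trees=trees,
        inbag_counts=inbag,
        oob_masks=oob,
        config=config,
        var_names=names,
        n=n,
    )
    if (forest.oob_coverage() == 0).any():
        warnings.warn(
            "some subjects are never out-of-bag; aggregate OOB error will "
            "exclude them — increase B",
            stacklevel=2,
        )
    return forest


def oob_error(forest: Forest, X, y) -> tuple[float, np.ndarray]:
    """(aggregate OOB error, per-tree OOB errors pi_b).

    The aggregate error scores each subject by majority vote over the
    trees for which it is out-of-bag (vote ties predict class 0); subjects
    never OOB are excluded with a warning.
    """
    Xa, yv, _ = _prep(X, y)
    n = forest.n
    votes1 = np.zeros(n)
    nvotes = np.zeros(n)
    per_tree = np.empty(forest.B)
    for b, (tree, mask) in enumerate(zip(forest.trees, forest.oob_masks)):
        pred = tree.predict(Xa[mask])
        per_tree[b] = float((pred != yv[mask]).mean()) if mask.any() else np.nan
        votes1[mask] += pred
        nvotes[mask] += 1
    covered = nvotes > 0
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} subject(s) never out-of-bag; excluded",
            stacklevel=2,
        )
    agg_pred = (votes1[covered] * 2 > nvotes[covered]).astype(int)
    return float((agg_pred != yv[covered]).mean()), per_tree


def permutation_importance(forest: Forest, X, y, seed: int = 0) -> pd.DataFrame:
    """OOB permutation importance per predictor.

    Within each tree, only variables that tree actually splits on are
    permuted (others contribute delta = 0 exactly).  Returns a DataFrame
    with the mean delta over trees and its standard error.
    """
    Xa, yv, _ = _prep(X, y)
    p = forest.p
    deltas = np.zeros((forest.B, p))
    streams = np.random.SeedSequence(seed).spawn(forest.B)
    for b, (tree, mask) in enumerate(zip(forest.trees, forest.oob_masks)):
        if not mask.any():
            continue
        rng = np.random.default_rng(streams[b])
        Xo = Xa[mask]
        yo = yv[mask]
        m = len(yo)
        base_err = float((tree.predict(Xo) != yo).mean())
        used = sorted(tree.split_variables())
        if not used:
            continue
        # one batched prediction pass: block v has variable used[v] permuted
        Xbig = np.repeat(Xo[None, :, :], len(used), axis=0)
        for v, j in enumerate(used):
            Xbig[v, :, j] = rng.permutation(Xo[:, j])
        preds = tree.predict(Xbig.reshape(len(used) * m, p)).reshape(len(used), m)
        deltas[b, used] = (preds != yo).mean(axis=1) - base_err
    theta = deltas.mean(axis=0)
    se = deltas.std(axis=0, ddof=1) / np.sqrt(forest.B) if forest.B > 1 else np.zeros(p)
    return pd.DataFrame(
        {
            "variable": forest.var_names,
            "permutation_importance": theta,
            "permutation_se": se,
        }
    )


def _tree_impurity_decrease(tree: ClassificationTree, p: int) -> np.ndarray:
    """Count-weighted Gini decrease per variable for one tree."""
    out = np.zeros(p)
    for node in tree.nodes.values():
        if node.is_leaf:
            continue
        left, right = tree.nodes[node.left], tree.nodes[node.right]
        phi = (
            gini(node.p_hat)
            - (left.n / node.n) * gini(left.p_hat)
            - (right.n / node.n) * gini(right.p_hat)
        )
        out[node.split_var] += node.n * phi
    return out


def gini_importance(forest: Forest) -> pd.DataFrame:
    """Mean decrease in node impurity per predictor (>= 0 by construction)."""
    acc = np.zeros(forest.p)
    for tree in forest.trees:
        acc += _tree_impurity_decrease(tree, forest.p)
    return pd.DataFrame(
        {
            "variable": forest.var_names,
            "gini_importance": acc / forest.B,
        }
    )


def importance_table(forest: Forest, X, y, seed: int = 0) -> pd.DataFrame:
    """Both importance flavours side by side, sorted by permutation score."""
    perm = permutation_importance(forest, X, y, seed=seed)
    gi = gini_importance(forest)
    table = perm.merge(gi, on="variable")
    table = table.sort_values(
        ["permutation_importance", "variable"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


class ForestResults:
    """Fitted forest with OOB diagnostics and importance tables."""

    def __init__(self, forest: Forest, X, y, importance_seed: int = 0):
        self.forest = forest
        self._X, self._y, _ = _prep(X, y)
        self.oob_error_, self.per_tree_oob_ = oob_error(forest, self._X, self._y)
        self._importance_seed = importance_seed
        self._importance: pd.DataFrame | None = None

    @property
    def importance(self) -> pd.DataFrame:
        if self._importance is None:
            self._importance = importance_table(
                self.forest, self._X, self._y, seed=self._importance_seed
            )
        return self._importance

    def summary(self, top: int = 10) -> str:
        imp = self.importance.head(top)
        lines = [
            f"Random forest: B = {self.forest.B}, "
            f"mtry = {self.forest.config.resolve_mtry(self.forest.p)}, "
            f"OOB error = {self.oob_error_:.4f}",
            f"{'variable':<28}{'perm. imp.':>12}{'(se)':>10}{'gini imp.':>12}",
        ]
        for _, r in imp.iterrows():
            lines.append(
                f"{r['variable'][:27]:<28}{r['permutation_importance']:>12.5f}"
                f"{r['permutation_se']:>10.5f}{r['gini_importance']:>12.3f}"
            )
        return "\n".join(lines)

    def plot_importance(self, top: int = 20, ax=None):
        """Horizontal bar chart of permutation importances (needs matplotlib)."""
        import matplotlib.pyplot as plt

        imp = self.importance.head(top).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.35 * top + 1))
        ax.barh(imp["variable"], imp["permutation_importance"])
        ax.set_xlabel("permutation importance (OOB error increase)")
        return ax


class RandomForestModel:
    """Model-style interface: ``RandomForestModel(y, X, B=500).fit()``."""

    def __init__(
        self,
        endog,
        exog,
        B: int = 500,
        mtry: int | None = None,
        min_node: int = 1,
        seed: int = 0,
    ):
        self.endog = endog
        self.exog = exog
        self.config = ForestConfig(B=B, mtry=mtry, min_node=min_node, seed=seed)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome_column: str, **kwargs
    ) -> "RandomForestModel":
        return cls(
            data[outcome_column].to_numpy(),
            data.drop(columns=[outcome_column]),
            **kwargs,
        )

    def fit(self, importance_seed: int | None = None) -> ForestResults:
        forest = grow_forest(self.exog, self.endog, self.config)
        seed = self.config.seed + 1 if importance_seed is None else importance_seed
        return ForestResults(forest, self.exog, self.endog, importance_seed=seed)
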
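"""End-to-end orchestration: simulate -> preprocess -> screen -> tree ->
forest -> logic regression, with a JSON-configurable, seed-stable run.

One master seed spawns an independent sub-seed per stochastic stage
(simulation, tree cross-validation, forest, forest importance, logic
search), so changing one stage's seed override leaves every other stage's
output byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cart import ClassificationTreeModel
from .forest import RandomForestModel
from .logicreg import AnnealConfig, LogicRegressionModel
from .panel import CD4_WEEK36, default_design
from .preprocess import build_analysis_matrix
from .simulate import OutcomeSpec, SimulationConfig, simulate_dataset
from .univariate import UnivariateScreen

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "read_dataset",
    "run_pipeline",
]

logger = logging.getLogger("flowtrees")


class DatasetError(ValueError):
    pass


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class PipelineConfig:
    """Single-document configuration of a full run.

    Either ``input_csv`` (a raw percent/count table containing the
    outcome column) or ``simulation`` (SimulationConfig fields plus an
    optional ``outcome`` OutcomeSpec document) must be given.  Unknown
    keys anywhere are rejected.
    """

    output_dir: str = "flowtrees_output"
    seed: int = 0
    input_csv: str | None = None
    simulation: dict = field(default_factory=dict)
    univariate: dict = field(default_factory=dict)
    cart: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    logicreg: dict = field(default_factory=dict)

    _STAGE_KEYS = {
        "simulation": {
            "n_subjects",
            "concentration",
            "replicate_noise_sd",
            "n_acquisitions",
            "missing_rate",
            "outcome",
            "seed",
        },
        "univariate": {"continuity_correction", "pi0"},
        "cart": {"min_node", "folds", "rule", "seed"},
        "forest": {"B", "mtry", "min_node", "seed", "importance_seed"},
        "logicreg": {
            "n_trees",
            "max_leaves",
            "iterations",
            "t_start",
            "t_end",
            "seed",
            "link",
        },
    }

    def __post_init__(self) -> None:
        for stage, allowed in self._STAGE_KEYS.items():
            _check_keys(getattr(self, stage), allowed, stage)
        if self.input_csv is None and not self.simulation:
            self.simulation = {}  # defaults: simulate the default panel

    @classmethod
    def from_json(cls, path_or_text: str | Path) -> "PipelineConfig":
        text = (
            Path(path_or_text).read_text()
            if Path(str(path_or_text)).exists()
            else str(path_or_text)
        )
        doc = json.loads(text)
        _check_keys(doc, {f.name for f in dataclasses.fields(cls)}, "pipeline config")
        return cls(**doc)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class AnalysisReport:
    """The four result artifacts plus run metadata."""

    screen_table: pd.DataFrame
    tree_text: str
    importance_table: pd.DataFrame
    logic_text: str
    metadata: dict

    def render(self) -> str:
        sections = [
            "=== Univariate screen (top 10) ===",
            self.screen_table.head(10).to_string(index=False, float_format="%.4f"),
            "\n=== Classification tree ===",
            self.tree_text,
            "\n=== Random forest importance (top 10) ===",
            self.importance_table.head(10).to_string(index=False, float_format="%.5f"),
            "\n=== Logic regression ===",
            self.logic_text,
        ]
        return "\n".join(sections)


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a CSV dataset: header row, numeric or empty cells.

    Raises with the offending row/column on non-numeric cells, on
    duplicate column names, and on a header-only file.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise DatasetError(f"duplicate column name(s): {dupes}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.empty:
        raise DatasetError("dataset has a header but no rows")
    out = {}
    for col in raw.columns:
        vals = raw[col].str.strip()
        numeric = pd.to_numeric(vals.replace("", np.nan), errors="coerce")
        bad = vals.ne("") & numeric.isna()
        if bad.any():
            r = int(np.flatnonzero(bad)[0])
            raise DatasetError(
                f"non-numeric cell at row {r + 2}, column {col!r}: {vals.iloc[r]!r}"
            )
        out[col] = numeric
    return pd.DataFrame(out)


def _spawn_seeds(master: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(master).spawn(n)
    ]


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all four analyses on one preprocessed matrix.

    Writes dataset, analysis matrix, per-stage artifacts (CSV/JSON/text)
    and a machine-readable ``summary.json`` under ``config.output_dir``.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[flowtrees:%(stage)s] %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    seeds = dict(
        zip(
            ["simulation", "cart", "forest", "forest_importance", "logicreg"],
            _spawn_seeds(config.seed, 5),
        )
    )
    timings: dict[str, float] = {}
    summary: dict = {"version": __version__, "master_seed": config.seed}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("start", extra={"stage": name})
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("done in %.2fs" % timings[name], extra={"stage": name})

        return _Ctx()

    # ---- data -------------------------------------------------------
    with stage("data"):
        if config.input_csv is not None:
            raw = read_dataset(config.input_csv)
        else:
            sim = dict(config.simulation)
            outcome_doc = sim.pop("outcome", None)
            sim.setdefault("seed", seeds["simulation"])
            if outcome_doc is not None:
                outcome = OutcomeSpec.from_dict(outcome_doc)
            else:
                outcome = OutcomeSpec.null()
            ds = simulate_dataset(
                default_design(), SimulationConfig(outcome=outcome, **sim)
            )
            ds.to_csv(out / "dataset.csv")
            raw = ds.values
        summary["n_rows_raw"] = int(len(raw))

    # ---- preprocess -------------------------------------------------
    with stage("preprocess"):
        matrix, y, dropped = build_analysis_matrix(raw, outcome_column=CD4_WEEK36)
        matrix.to_csv(out / "analysis_matrix.csv")
        if dropped:
            logger.warning(
                "dropped %d subject(s) with missing outcome" % len(dropped),
                extra={"stage": "preprocess"},
            )
        summary["n_subjects"] = matrix.n
        summary["n_predictors"] = matrix.p
        summary["n_responders"] = y.n_responders
        summary["n_dropped_missing_outcome"] = len(dropped)
        summary["n_imputed_cells"] = len(matrix.imputations)

    # ---- univariate screen -----------------------------------------
    with stage("univariate"):
        screen = UnivariateScreen(y, matrix).fit(**config.univariate)
        screen.to_csv(out / "screen.csv")
        summary["univariate"] = {
            "top_variable": screen.table.iloc[0]["variable"],
            "top_odds_ratio": float(screen.table.iloc[0]["odds_ratio"]),
            "top_p_value": float(screen.table.iloc[0]["p_value"]),
            "min_adjusted_p_by": screen.min_adjusted_p,
        }

    # ---- classification tree ---------------------------------------
    with stage("cart"):
        copts = dict(config.cart)
        min_node = copts.pop("min_node", 5)
        copts.setdefault("seed", seeds["cart"])
        tree_res = ClassificationTreeModel(y, matrix, min_node=min_node).fit(
            prune="cv", **copts
        )
        (out / "tree.txt").write_text(tree_res.summary() + "\n")
        (out / "tree.json").write_text(tree_res.tree.to_json())
        (out / "tree_full.txt").write_text(tree_res.full_tree.render() + "\n")
        summary["cart"] = {
            "n_leaves_full": tree_res.full_tree.n_leaves,
            "n_leaves_selected": tree_res.tree.n_leaves,
            "train_risk": tree_res.train_risk,
            "root_split": tree_res.full_tree.nodes[
                tree_res.full_tree.root
            ].split_name,
        }

    # ---- random forest ---------------------------------------------
    with stage("forest"):
        fopts = dict(config.forest)
        fopts.setdefault("seed", seeds["forest"])
        imp_seed = fopts.pop("importance_seed", seeds["forest_importance"])
        rf = RandomForestModel(y, matrix, **fopts).fit(importance_seed=imp_seed)
        rf.importance.to_csv(out / "importance.csv", index=False)
        summary["forest"] = {
            "oob_error": rf.oob_error_,
            "top_variable": rf.importance.iloc[0]["variable"],
            "top_permutation_importance": float(
                rf.importance.iloc[0]["permutation_importance"]
            ),
        }

    # ---- logic regression ------------------------------------------
    with stage("logicreg"):
        lopts = dict(config.logicreg)
        lopts.setdefault("seed", seeds["logicreg"])
        anneal = AnnealConfig(
            n_trees=lopts.pop("n_trees", 2),
            max_leaves=lopts.pop("max_leaves", 6),
            **lopts,
        )
        lr = LogicRegressionModel(
            y, matrix, n_trees=anneal.n_trees, max_leaves=anneal.max_leaves
        ).fit(config=anneal)
        (out / "logic_model.txt").write_text(lr.summary() + "\n")
        summary["logicreg"] = {
            "deviance": lr.deviance,
            "expression": lr.expression(),
            "n_leaves": lr.model.n_leaves,
        }

    summary["seeds"] = seeds
    summary["timings_s"] = timings
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))

    report = AnalysisReport(
        screen_table=screen.table,
        tree_text=tree_res.tree.render(),
        importance_table=rf.importance,
        logic_text=lr.summary(),
        metadata=summary,
    )
    (out / "report.txt").write_text(report.render() + "\n")
    return report
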
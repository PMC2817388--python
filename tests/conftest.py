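"""Shared fixtures: reconstructed study quantities and panel simulators."""

from __future__ import annotations

import numpy as np
import pytest

import flowtrees as ft

# the two variables used as planted-signal targets throughout: the NK
# quadrant that dominated the motivating analysis and the lineage-negative
# DR- fraction (its second-ranked variable)
TARGET_1 = "CD3-DR-CD56+CD16+"
TARGET_2 = "Lin-DR-"


@pytest.fixture(scope="session")
def root_split_table() -> ft.ContingencyTable2x2:
    """2x2 table reconstructed from the reported root-split responder
    fractions: 4 of 39 above-median subjects and 15 of 39 below-median
    subjects responded (n = 78, 19 responders)."""
    return ft.ContingencyTable2x2(a=4, b=35, c=15, d=24)


@pytest.fixture(scope="session")
def root_split_columns() -> tuple[np.ndarray, np.ndarray]:
    """Binary exposure/outcome columns realising the (4, 35, 15, 24) table."""
    x = np.array([1] * 39 + [0] * 39)
    y = np.array([1] * 4 + [0] * 35 + [1] * 15 + [0] * 24)
    return x, y


def make_panel_matrix(
    spec: ft.OutcomeSpec | None,
    n: int,
    seed: int,
    missing_rate: float = 0.05,
):
    """Simulate a default panel with the given outcome and preprocess it."""
    cfg = ft.SimulationConfig(
        n_subjects=n, outcome=spec, missing_rate=missing_rate, seed=seed
    )
    ds = ft.simulate_dataset(config=cfg)
    matrix, y, _ = ft.build_analysis_matrix(ds.values)
    return matrix, y


def subset_matrix(matrix, first: list[str], n_vars: int):
    """Columns ``first`` plus enough others to reach ``n_vars`` columns."""
    rest = [v for v in matrix.variable_names if v not in first]
    return matrix.X[first + rest[: n_vars - len(first)]]


@pytest.fixture(scope="session")
def null_small():
    """n = 78 null-outcome panel matrix (the study's cohort size)."""
    return make_panel_matrix(ft.OutcomeSpec.null(19 / 78), n=78, seed=11)
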
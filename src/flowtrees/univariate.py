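"""Univariate 2x2 contingency screen with FDR-style multiplicity control.

For each dichotomised predictor the screen builds the exposure x outcome
table, reports the odds ratio

    OR = [Pr(D+|E+)/(1-Pr(D+|E+))] / [Pr(D+|E-)/(1-Pr(D+|E-))] = ad/bc,

tests independence with the 1-df Pearson chi-square (Yates continuity
correction on by default), and adjusts across predictors with the
Benjamini-Yekutieli step-up (valid under arbitrary dependence — quadrant
variables are strongly correlated by construction) and with q-values
(positive-FDR; with pi0 = 1 these reduce to Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .preprocess import AnalysisMatrix, OutcomeVector

__all__ = [
    "DegenerateTableError",
    "ContingencyTable2x2",
    "tabulate",
    "odds_ratio",
    "chi_square_test",
    "adjust_benjamini_yekutieli",
    "qvalue_pfdr",
    "univariate_screen",
    "UnivariateScreen",
    "ScreenResults",
    "load_published_screen",
]


class DegenerateTableError(ValueError):
    """A zero margin makes the chi-square test undefined."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (D+E+, D-E+, D+E-, D-E-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def tabulate(x: np.ndarray, y: np.ndarray | OutcomeVector) -> ContingencyTable2x2:
    """Cross-tabulate a binary exposure against the binary outcome."""
    if isinstance(y, OutcomeVector):
        y = y.y
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("exposure and outcome lengths differ")
    return ContingencyTable2x2(
        a=int(((x == 1) & (y == 1)).sum()),
        b=int(((x == 1) & (y == 0)).sum()),
        c=int(((x == 0) & (y == 1)).sum()),
        d=int(((x == 0) & (y == 0)).sum()),
    )


def odds_ratio(t: ContingencyTable2x2, haldane: bool = False) -> float:
    """Cross-product odds ratio ad/bc.

    Degenerate tables return +inf (bc = 0 < ad) or 0.0 (ad = 0 < bc) or
    NaN (both products zero).  ``haldane=True`` adds 0.5 to every cell
    instead (off by default; the screen reports raw ORs).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    ad, bc = a * d, b * c
    if bc == 0:
        return np.inf if ad > 0 else np.nan
    return ad / bc


def chi_square_test(
    t: ContingencyTable2x2, continuity_correction: bool = True
) -> tuple[float, float]:
    """1-df Pearson chi-square for a 2x2 table.

    statistic = n (|ad - bc| - h)^2 / [(a+b)(c+d)(a+c)(b+d)], h = n/2 with
    the Yates correction (clamped so over-correction cannot go negative),
    h = 0 without.  Returns (statistic, upper-tail p from chi2_1).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    margins = ((a + b), (c + d), (a + c), (b + d))
    if n == 0 or any(m == 0 for m in margins):
        raise DegenerateTableError("zero margin in 2x2 table")
    h = n / 2.0 if continuity_correction else 0.0
    diff = max(abs(a * d - b * c) - h, 0.0)
    stat = n * diff**2 / np.prod([float(m) for m in margins])
    return float(stat), float(_chi2_dist.sf(stat, df=1))


def _check_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def _step_up(p: np.ndarray, factor: float) -> np.ndarray:
    """Generic step-up adjustment min_{i>=j} factor * m * p_(i) / i, <= 1."""
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * factor * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def adjust_benjamini_yekutieli(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values (input order kept).

    Uses the harmonic correction c(m) = sum_{k=1}^m 1/k, which makes the
    FDR bound valid under arbitrary dependence between tests.
    """
    p = _check_pvalues(p_values)
    c_m = float(np.sum(1.0 / np.arange(1, p.size + 1)))
    return _step_up(p, c_m)


def qvalue_pfdr(p_values, pi0: float | str = 1.0) -> np.ndarray:
    """q-values under a positive-FDR adjustment.

    With ``pi0`` fixed at 1 this is exactly the Benjamini-Hochberg
    adjustment.  ``pi0="storey"`` plugs in the Storey estimator at
    lambda = 0.5, pi0_hat = #{p > 0.5} / (m/2), clipped to (0, 1].
    """
    p = _check_pvalues(p_values)
    if isinstance(pi0, str):
        if pi0 != "storey":
            raise ValueError(f"unknown pi0 mode {pi0!r}")
        lam = 0.5
        pi0_val = (p > lam).sum() / (p.size * (1 - lam))
        pi0_val = float(min(max(pi0_val, 1.0 / p.size), 1.0))
    else:
        pi0_val = float(pi0)
        if not 0.0 < pi0_val <= 1.0:
            raise ValueError("pi0 must be in (0, 1]")
    return _step_up(p, pi0_val)


def univariate_screen(
    matrix: AnalysisMatrix | pd.DataFrame,
    y: OutcomeVector | np.ndarray,
    continuity_correction: bool = True,
    pi0: float | str = 1.0,
) -> pd.DataFrame:
    """One row per predictor: OR, chi2, p, BY-adjusted p, q-value, rank.

    Sorted ascending by p-value, ties broken by variable name.  Rows whose
    table has a zero margin get a NaN statistic/p and sort last.
    """
    X = matrix.X if isinstance(matrix, AnalysisMatrix) else matrix
    yv = y.y if isinstance(y, OutcomeVector) else np.asarray(y, dtype=int)
    rows = []
    for name in X.columns:
        t = tabulate(X[name].to_numpy(), yv)
        try:
            stat, p = chi_square_test(t, continuity_correction)
        except DegenerateTableError:
            stat, p = np.nan, np.nan
        rows.append(
            {
                "variable": str(name),
                "odds_ratio": odds_ratio(t),
                "chi2_statistic": stat,
                "p_value": p,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
            }
        )
    table = pd.DataFrame(rows)
    valid = ~table["p_value"].isna()
    adj = np.full(len(table), np.nan)
    qv = np.full(len(table), np.nan)
    if valid.any():
        adj[valid] = adjust_benjamini_yekutieli(table.loc[valid, "p_value"])
        qv[valid] = qvalue_pfdr(table.loc[valid, "p_value"], pi0=pi0)
    table["adjusted_p_by"] = adj
    table["q_value"] = qv
    table = table.sort_values(
        ["p_value", "variable"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


class ScreenResults:
    """Fitted univariate screen; ``table`` is the per-variable DataFrame."""

    def __init__(self, table: pd.DataFrame, n: int):
        self.table = table
        self.nobs = n

    @property
    def min_adjusted_p(self) -> float:
        return float(np.nanmin(self.table["adjusted_p_by"]))

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.DataFrame:
        col = "adjusted_p_by" if adjusted else "p_value"
        return self.table[self.table[col] < alpha]

    def summary(self, top: int | None = 10) -> str:
        t = self.table if top is None else self.table.head(top)
        lines = [
            f"Univariate screen: {len(self.table)} predictors, n = {self.nobs}",
            f"{'variable':<28}{'OR':>8}{'chi2':>8}{'p':>8}{'p(BY)':>8}{'q':>8}",
        ]
        for _, r in t.iterrows():
            lines.append(
                f"{r['variable'][:27]:<28}{r['odds_ratio']:>8.3f}"
                f"{r['chi2_statistic']:>8.2f}{r['p_value']:>8.3f}"
                f"{r['adjusted_p_by']:>8.3f}{r['q_value']:>8.3f}"
            )
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        cols = [
            "variable",
            "odds_ratio",
            "p_value",
            "adjusted_p_by",
            "q_value",
            "rank",
        ]
        self.table[cols].to_csv(path, index=False)


class UnivariateScreen:
    """Model-style wrapper: ``UnivariateScreen(y, X).fit()``.

    ``exog`` is the binary analysis matrix (AnalysisMatrix or DataFrame),
    ``endog`` the binary outcome.
    """

    def __init__(self, endog, exog: AnalysisMatrix | pd.DataFrame):
        self.endog = endog.y if isinstance(endog, OutcomeVector) else np.asarray(endog)
        self.exog = exog

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome_column: str
    ) -> "UnivariateScreen":
        X = data.drop(columns=[outcome_column])
        return cls(data[outcome_column].to_numpy(), X)

    def fit(
        self, continuity_correction: bool = True, pi0: float | str = 1.0
    ) -> ScreenResults:
        table = univariate_screen(
            self.exog, self.endog, continuity_correction, pi0
        )
        return ScreenResults(table, n=len(self.endog))


def load_published_screen() -> pd.DataFrame:
    """Published per-variable odds ratios and p-values (64 predictors)
    from the motivating antiretroviral-therapy trial analysis, used as a
    fixed input for multiplicity checks."""
    with resources.files("flowtrees.data").joinpath(
        "published_univariate_screen.csv"
    ).open() as fh:
        return pd.read_csv(fh)
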
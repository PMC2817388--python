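"""Staining-panel description for a 4-colour flow-cytometry variable set.

A panel is a collection of *quadrant groups*.  Each group corresponds to one
2-colour quadrant analysis performed on a staining plate (possibly inside a
parent gate): four marker-combination regions (``++``, ``+-``, ``-+``,
``--``) whose percent-of-gated values sum to 100 for every subject.  The
default design mirrors an eight-staining immunophenotyping panel for
HIV-infected adults starting antiretroviral therapy: primary CD3/CD8,
CD3/HLA-DR, CD45/CD3 and Lin/HLA-DR gates, plus secondary quadrants for
memory (CD45RA/CD62L), activation (CD38/CD28, HLA-DR/CD95, CD7/CD154), NK
(CD56/CD16), T-subset (CD8/CD4) and dendritic-cell (CD123/CD11c) markers.

The CD3/CD8 primary quadrants are acquired four times per subject and
averaged downstream.  One quadrant of the CD3+CD8+ CD7/CD154 set is
simulated but not reported, so the default design exposes exactly 63 flow
variables; a baseline CD4+ cell count (cells/uL) completes the predictor
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["QuadrantGroup", "PanelDesign", "default_design", "CD4_BASELINE", "CD4_WEEK36"]

#: column name of the baseline CD4 count predictor (cells/uL, not a percent)
CD4_BASELINE = "CD4+"
#: column name of the simulated week-36 CD4 count that defines the outcome
CD4_WEEK36 = "CD4_week36"


@dataclass(frozen=True)
class QuadrantGroup:
    """One 2-colour quadrant set whose four percentages sum to 100.

    Parameters
    ----------
    name
        Identifier for the group, e.g. ``"CD3-DR-:CD56/CD16"``.
    staining
        Name of the staining plate the group is read from.
    variables
        The four quadrant variable names in ``(++, +-, -+, --)`` order of
        the two fluorochromes.
    reported
        Which of the four quadrants appear in the exported dataset.  The
        composition is always simulated for all four.
    replicated
        Whether the group is acquired four times per subject (independent
        acquisitions, averaged during preprocessing).
    """

    name: str
    staining: str
    variables: tuple[str, str, str, str]
    reported: tuple[bool, bool, bool, bool] = (True, True, True, True)
    replicated: bool = False

    def __post_init__(self) -> None:
        if len(self.variables) != 4 or len(set(self.variables)) != 4:
            raise ValueError(f"group {self.name!r} needs 4 distinct variables")


@dataclass(frozen=True)
class PanelDesign:
    """A full panel: quadrant groups plus count-valued columns."""

    groups: tuple[QuadrantGroup, ...]
    count_variables: tuple[str, ...] = (CD4_BASELINE,)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g in self.groups:
            for v in g.variables:
                if v in seen:
                    raise ValueError(
                        f"variable {v!r} in both {seen[v]!r} and {g.name!r}"
                    )
                seen[v] = g.name

    @property
    def flow_variables(self) -> list[str]:
        """Reported percent-of-gated variable names, in panel order."""
        return [
            v
            for g in self.groups
            for v, rep in zip(g.variables, g.reported)
            if rep
        ]

    @property
    def variable_names(self) -> list[str]:
        """All reported predictor columns: flow variables then counts."""
        return self.flow_variables + list(self.count_variables)

    @property
    def replicated_groups(self) -> list[QuadrantGroup]:
        return [g for g in self.groups if g.replicated]

    def group_of(self, variable: str) -> QuadrantGroup:
        for g in self.groups:
            if variable in g.variables:
                return g
        raise KeyError(variable)


def _quads(prefix: str, m1: str, m2: str) -> tuple[str, str, str, str]:
    return (
        f"{prefix}{m1}+{m2}+",
        f"{prefix}{m1}+{m2}-",
        f"{prefix}{m1}-{m2}+",
        f"{prefix}{m1}-{m2}-",
    )


def default_design() -> PanelDesign:
    """The default 63-flow-variable panel (plus baseline CD4 count).

    Two quadrant names are truncated (``...CD45RA-CD62L``) and one quadrant
    (``CD3+CD8+CD7-CD154+``) is unreported, matching the published variable
    list of the motivating trial dataset.
    """
    groups = [
        QuadrantGroup(
            "CD3/CD8",
            "st2-4,6",
            ("CD3+CD8+", "CD3+CD8-", "CD3-CD8+", "CD3-CD8-"),
            replicated=True,
        ),
        QuadrantGroup(
            "CD3/DR", "st5", ("CD3+DR+", "CD3+DR-", "CD3-DR+", "CD3-DR-")
        ),
        QuadrantGroup(
            "CD45/CD3",
            "st7",
            ("CD45+CD3+", "CD45+CD3-", "CD45-CD3+", "CD45-CD3-"),
        ),
        QuadrantGroup(
            "Lin/DR", "st8", ("Lin+DR+", "Lin+DR-", "Lin-DR+", "Lin-DR-")
        ),
        QuadrantGroup(
            "CD3+CD8-:CD45RA/CD62L",
            "st2",
            (
                "CD3+CD8-CD45RA+CD62L+",
                "CD3+CD8-CD45RA+CD62L-",
                "CD3+CD8-CD45RA-CD62L+",
                "CD3+CD8-CD45RA-CD62L",
            ),
        ),
        QuadrantGroup(
            "CD3+CD8+:CD45RA/CD62L",
            "st2",
            (
                "CD3+CD8+CD45RA+CD62L+",
                "CD3+CD8+CD45RA+CD62L-",
                "CD3+CD8+CD45RA-CD62L+",
                "CD3+CD8+CD45RA-CD62L",
            ),
        ),
        QuadrantGroup("CD3+CD8-:CD38/CD28", "st3", _quads("CD3+CD8-", "CD38", "CD28")),
        QuadrantGroup("CD3+CD8+:CD38/CD28", "st3", _quads("CD3+CD8+", "CD38", "CD28")),
        QuadrantGroup("CD3+CD8-:DR/CD95", "st4", _quads("CD3+CD8-", "DR", "CD95")),
        QuadrantGroup("CD3+CD8+:DR/CD95", "st4", _quads("CD3+CD8+", "DR", "CD95")),
        QuadrantGroup("CD3-DR-:CD56/CD16", "st5", _quads("CD3-DR-", "CD56", "CD16")),
        QuadrantGroup("CD3-DR+:CD56/CD16", "st5", _quads("CD3-DR+", "CD56", "CD16")),
        QuadrantGroup("CD3+CD8-:CD7/CD154", "st6", _quads("CD3+CD8-", "CD7", "CD154")),
        QuadrantGroup(
            "CD3+CD8+:CD7/CD154",
            "st6",
            _quads("CD3+CD8+", "CD7", "CD154"),
            reported=(True, True, False, True),
        ),
        QuadrantGroup("CD45+CD3+:CD8/CD4", "st7", _quads("CD45+CD3+", "CD8", "CD4")),
        QuadrantGroup("Lin-DR+:CD123/CD11c", "st8", _quads("Lin-DR+", "CD123", "CD11c")),
    ]
    return PanelDesign(groups=tuple(groups))
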
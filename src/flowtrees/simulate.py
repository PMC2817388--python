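"""Synthetic flow-panel generator with planted outcome signals.

Quadrant compositions are drawn per group from a Dirichlet-type
distribution (independent gamma weights scaled to sum 100), which enforces
the two structural facts of quadrant data: percentages within one staining
always sum to 100, and complementary quadrants are negatively correlated.
Replicated groups are acquired four times with additive Gaussian noise
(renormalised to preserve closure) and the acquisition mean is stored.

Outcome signals are planted on the *dichotomised* (above/below median)
scale, which is the scale every downstream method operates on.  Four
scenario kinds are supported:

``null``
    one responder probability for everyone;
``marginal``
    responder probability depends on one target variable;
``conditional``
    probability depends on a 2-variable stratum (e.g. X2 matters only
    within X1 = 0), the structure a classification tree should recover;
``interaction``
    XOR of two balanced targets — both marginal effects are exactly null
    by construction, so only a method that searches over Boolean
    combinations can find the signal.

Responder status is realised as a week-36 CD4 count strictly above (or at
most) the 450 cells/uL threshold, so the generator feeds the same outcome
dichotomisation rule used on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import CD4_BASELINE, CD4_WEEK36, PanelDesign, default_design

__all__ = [
    "InvalidConfigError",
    "UnknownVariableError",
    "OutcomeSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_panel",
    "simulate_outcome",
    "inject_missing",
    "simulate_dataset",
]


class InvalidConfigError(ValueError):
    """Raised for non-positive sizes, out-of-range rates or probabilities."""


class UnknownVariableError(KeyError):
    """Raised when an outcome spec references a variable not in the data."""


#: generic quadrant concentration (++, +-, -+, --); mildly asymmetric, as
#: real quadrant distributions are.
_DEFAULT_ALPHA = (1.5, 1.0, 0.7, 0.8)
#: NK-cell group concentration; places mass on the CD56+CD16+ and
#: CD56-CD16- quadrants so their compositional correlation is ~ -0.7,
#: emulating the strong complementary-quadrant correlation seen in the
#: motivating dataset.
_NK_ALPHA = (2.0, 0.45, 0.45, 2.0)


@dataclass(frozen=True)
class OutcomeSpec:
    """Planted relationship between dichotomised targets and response.

    ``response_probabilities`` maps a stratum key — the concatenated 0/1
    codes of the dichotomised target variables, ``""`` for the null kind —
    to a responder probability in (0, 1).  ``cd4_week36_scale`` gives the
    lognormal spread of the simulated week-36 CD4 count on either side of
    the 450 cells/uL threshold.
    """

    kind: str
    target_variables: tuple[str, ...] = ()
    response_probabilities: Mapping[str, float] = field(default_factory=dict)
    cd4_week36_scale: Mapping[str, float] = field(
        default_factory=lambda: {"log_mean": 0.25, "log_sd": 0.12}
    )

    _KINDS = ("null", "marginal", "conditional", "interaction")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidConfigError(f"unknown outcome kind {self.kind!r}")
        k = len(self.target_variables)
        expected = {"null": 0, "marginal": 1, "conditional": 2, "interaction": 2}
        if k != expected[self.kind]:
            raise InvalidConfigError(
                f"kind {self.kind!r} needs {expected[self.kind]} target(s), got {k}"
            )
        for key, p in self.response_probabilities.items():
            if len(key) != k or any(ch not in "01" for ch in key):
                raise InvalidConfigError(f"bad stratum key {key!r}")
            if not 0.0 < p < 1.0:
                raise InvalidConfigError(f"probability {p} for {key!r} not in (0,1)")
        for key in self._stratum_keys():
            if key not in self.response_probabilities:
                raise InvalidConfigError(f"missing probability for stratum {key!r}")
        if self.kind == "interaction":
            p = self.response_probabilities
            if not (p["00"] == p["11"] and p["01"] == p["10"]):
                raise InvalidConfigError(
                    "interaction kind requires XOR structure: "
                    "p('00')==p('11') and p('01')==p('10')"
                )

    def _stratum_keys(self) -> list[str]:
        k = len(self.target_variables)
        return [format(i, f"0{k}b") if k else "" for i in range(2**k)]

    # -- convenience constructors ------------------------------------
    @classmethod
    def null(cls, p: float = 19 / 78) -> "OutcomeSpec":
        return cls(kind="null", response_probabilities={"": p})

    @classmethod
    def marginal(cls, variable: str, p_above: float, p_below: float) -> "OutcomeSpec":
        return cls(
            kind="marginal",
            target_variables=(variable,),
            response_probabilities={"1": p_above, "0": p_below},
        )

    @classmethod
    def conditional(
        cls, v1: str, v2: str, probabilities: Mapping[str, float]
    ) -> "OutcomeSpec":
        return cls(
            kind="conditional",
            target_variables=(v1, v2),
            response_probabilities=dict(probabilities),
        )

    @classmethod
    def xor(cls, v1: str, v2: str, p_same: float, p_diff: float) -> "OutcomeSpec":
        """XOR interaction: balanced targets make both marginals null."""
        return cls(
            kind="interaction",
            target_variables=(v1, v2),
            response_probabilities={
                "00": p_same,
                "11": p_same,
                "01": p_diff,
                "10": p_diff,
            },
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "target_variables": list(self.target_variables),
            "response_probabilities": dict(self.response_probabilities),
            "cd4_week36_scale": dict(self.cd4_week36_scale),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OutcomeSpec":
        return cls(
            kind=d["kind"],
            target_variables=tuple(d.get("target_variables", ())),
            response_probabilities=dict(d.get("response_probabilities", {})),
            cd4_week36_scale=dict(
                d.get("cd4_week36_scale", {"log_mean": 0.25, "log_sd": 0.12})
            ),
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the panel generator.

    ``concentration`` overrides the per-group Dirichlet weights by group
    name; ``replicate_noise_sd`` is the acquisition noise in percent units;
    ``missing_rate`` is the MCAR masking probability applied to flow cells.
    """

    n_subjects: int = 78
    concentration: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    replicate_noise_sd: float = 1.0
    n_acquisitions: int = 4
    missing_rate: float = 0.05
    outcome: OutcomeSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise InvalidConfigError("n_subjects must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.replicate_noise_sd < 0:
            raise InvalidConfigError("replicate_noise_sd must be nonnegative")
        if self.n_acquisitions < 1:
            raise InvalidConfigError("n_acquisitions must be >= 1")
        for name, alpha in self.concentration.items():
            if len(alpha) != 4 or any(a <= 0 for a in alpha):
                raise InvalidConfigError(
                    f"concentration for {name!r} must be 4 positive weights"
                )


@dataclass
class SyntheticDataset:
    """Simulated subjects x variables table plus the generating truth.

    ``values`` holds percent-of-gated flow variables and cells/uL CD4
    columns; ``mask`` is True where a cell was masked as missing (the
    masked cells are NaN in ``values``); ``truth`` records the outcome
    spec, realised stratum memberships and dichotomisation medians.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    truth: dict
    design: PanelDesign

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def group_sums(self, observed_only: bool = False) -> pd.DataFrame:
        """Per-subject sums of each *fully reported* quadrant group."""
        sums = {}
        for g in self.design.groups:
            if not all(g.reported):
                continue
            sums[g.name] = self.values[list(g.variables)].sum(axis=1)
        return pd.DataFrame(sums)

    # -- plain-text persistence --------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write values as CSV (empty cell = missing) + a truth sidecar JSON."""
        path = Path(path)
        self.values.to_csv(path, index=False)
        sidecar = path.with_suffix(".truth.json")
        with open(sidecar, "w") as fh:
            json.dump(self.truth, fh, indent=1)

    @classmethod
    def read_csv(
        cls, path: str | Path, design: PanelDesign | None = None
    ) -> "SyntheticDataset":
        path = Path(path)
        values = pd.read_csv(path)
        sidecar = path.with_suffix(".truth.json")
        truth = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                truth = json.load(fh)
        return cls(
            values=values,
            mask=values.isna(),
            truth=truth,
            design=design or default_design(),
        )


def _group_alpha(config: SimulationConfig, name: str) -> np.ndarray:
    if name in config.concentration:
        return np.asarray(config.concentration[name], dtype=float)
    if name == "CD3-DR-:CD56/CD16":
        return np.asarray(_NK_ALPHA, dtype=float)
    return np.asarray(_DEFAULT_ALPHA, dtype=float)


def _composition(rng: np.random.Generator, alpha: np.ndarray, n: int) -> np.ndarray:
    """n x 4 compositions summing to exactly 100 (gamma draws, normalised)."""
    w = rng.gamma(shape=alpha, scale=1.0, size=(n, 4))
    # guard against all-zero rows at tiny concentrations
    w = np.maximum(w, 1e-300)
    return 100.0 * w / w.sum(axis=1, keepdims=True)


def simulate_panel(
    design: PanelDesign | None = None, config: SimulationConfig | None = None
) -> SyntheticDataset:
    """Draw one panel dataset (no outcome, no missingness).

    Each quadrant group is an independent composition; replicated groups
    get ``n_acquisitions`` noisy, renormalised acquisitions whose mean is
    stored, so closure to 100 holds exactly for every group.  The baseline
    CD4 count is uniform on the trial's 200-350 cells/uL eligibility window.
    """
    design = design or default_design()
    config = config or SimulationConfig()
    if not design.groups:
        raise InvalidConfigError("design has no quadrant groups")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects

    cols: dict[str, np.ndarray] = {}
    for g in design.groups:
        comp = _composition(rng, _group_alpha(config, g.name), n)
        if g.replicated and config.replicate_noise_sd > 0:
            acq = np.empty((config.n_acquisitions, n, 4))
            for r in range(config.n_acquisitions):
                noisy = comp + rng.normal(0.0, config.replicate_noise_sd, (n, 4))
                noisy = np.maximum(noisy, 0.0)
                acq[r] = 100.0 * noisy / noisy.sum(axis=1, keepdims=True)
            comp = acq.mean(axis=0)
        for j, (v, rep) in enumerate(zip(g.variables, g.reported)):
            if rep:
                cols[v] = comp[:, j]
    for cv in design.count_variables:
        cols[cv] = np.round(rng.uniform(200.0, 350.0, n))

    values = pd.DataFrame(cols, columns=design.variable_names)
    truth = {"config": {"n_subjects": n, "seed": config.seed}}
    return SyntheticDataset(
        values=values,
        mask=pd.DataFrame(False, index=values.index, columns=values.columns),
        truth=truth,
        design=design,
    )


def simulate_outcome(
    dataset: SyntheticDataset, spec: OutcomeSpec, seed: int
) -> SyntheticDataset:
    """Append a week-36 CD4 count realising the planted outcome model.

    Targets are dichotomised at their sample median (strictly-greater
    rule); each subject's responder status is Bernoulli with the stratum
    probability; the CD4 count is drawn lognormally above 450 for
    responders and at or below 450 otherwise.
    """
    for v in spec.target_variables:
        if v not in dataset.values.columns:
            raise UnknownVariableError(v)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = dataset.n_subjects

    codes = np.zeros((n, len(spec.target_variables)), dtype=int)
    medians = {}
    for j, v in enumerate(spec.target_variables):
        col = dataset.values[v].to_numpy(dtype=float)
        med = float(np.nanmedian(col))
        medians[v] = med
        codes[:, j] = (col > med).astype(int)
    strata = ["".join(map(str, row)) for row in codes]
    probs = np.array([spec.response_probabilities[s] for s in strata])
    responder = rng.uniform(size=n) < probs

    mu = float(spec.cd4_week36_scale.get("log_mean", 0.25))
    sd = float(spec.cd4_week36_scale.get("log_sd", 0.12))
    spread = np.abs(rng.normal(mu, sd, n))
    cd4 = np.where(responder, 450.0 * np.exp(spread), 450.0 * np.exp(-spread))
    cd4 = np.round(cd4)
    cd4 = np.where(responder, np.maximum(cd4, 451.0), np.minimum(cd4, 450.0))

    values = dataset.values.copy()
    values[CD4_WEEK36] = cd4
    mask = dataset.mask.copy()
    mask[CD4_WEEK36] = False
    truth = dict(dataset.truth)
    truth.update(
        {
            "outcome": spec.to_dict(),
            "medians": medians,
            "strata": strata,
            "responder": [bool(r) for r in responder],
            "outcome_seed": seed,
        }
    )
    return SyntheticDataset(values=values, mask=mask, truth=truth, design=dataset.design)


def inject_missing(
    dataset: SyntheticDataset, rate: float, seed: int
) -> SyntheticDataset:
    """MCAR-mask flow-variable cells with the given probability.

    Count columns (baseline CD4) and the outcome are never masked; the
    realised mask is recorded on the returned dataset.
    """
    if not 0.0 <= rate < 1.0:
        raise InvalidConfigError("missing rate must be in [0, 1)")
    flow = [v for v in dataset.design.flow_variables if v in dataset.values.columns]
    values = dataset.values.copy()
    mask = dataset.mask.copy()
    if rate > 0.0 and flow:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        hit = rng.uniform(size=(dataset.n_subjects, len(flow))) < rate
        block = values[flow].to_numpy(dtype=float)
        block[hit] = np.nan
        values[flow] = block
        mask[flow] = mask[flow].to_numpy() | hit
    return SyntheticDataset(
        values=values, mask=mask, truth=dict(dataset.truth), design=dataset.design
    )


def simulate_dataset(
    design: PanelDesign | None = None, config: SimulationConfig | None = None
) -> SyntheticDataset:
    """Panel + outcome + missingness in one deterministic call.

    Three independent RNG streams are spawned from ``config.seed`` so each
    stage is reproducible on its own.
    """
    design = design or default_design()
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    ds = simulate_panel(design, replace(config, seed=sub_seeds[0]))
    ds.truth["config"]["seed"] = config.seed
    if config.outcome is not None:
        ds = simulate_outcome(ds, config.outcome, sub_seeds[1])
    if config.missing_rate > 0.0:
        ds = inject_missing(ds, config.missing_rate, sub_seeds[2])
    return ds
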
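"""Synthetic baseline cohorts and longitudinal ageing panels.

Emulates repeated-wave ageing panels (attributes, frailty status, event
occurrences, death) with known ground-truth risk parameters so estimation,
simulation and validation are fully testable offline.  Cross-attribute
dependence is induced by a Gaussian-copula rank coupling of the requested
marginals; this is an emulation device, not a claim about any real panel's
dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InvalidInputError
from .frailty import FrailtyCategory
from .risks import RiskParams, event_probabilities, transition_matrix_for_scenario
from .structure import EventKind, ModelStructure

__all__ = [
    "CohortSpec",
    "MarginalSpec",
    "PanelSpec",
    "default_cohort_spec",
    "generate_cohort",
    "generate_panel",
]


@dataclass(frozen=True)
class MarginalSpec:
    """One attribute's marginal distribution: family name plus parameters.

    Supported families: normal(mean, sd), uniform(low, high), bernoulli(p),
    poisson(lam), categorical(probs), constant(value).
    """

    dist: str
    params: Mapping[str, float] = field(default_factory=dict)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        p = self.params
        if self.dist == "normal":
            return stats.norm.ppf(u, loc=p["mean"], scale=p["sd"])
        if self.dist == "uniform":
            return p["low"] + u * (p["high"] - p["low"])
        if self.dist == "bernoulli":
            return (u >= 1.0 - p["p"]).astype(float)
        if self.dist == "poisson":
            return stats.poisson.ppf(u, mu=p["lam"])
        if self.dist == "categorical":
            probs = np.asarray(p["probs"], dtype=float)
            if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
                raise ConfigurationError("categorical probs must be non-negative and sum to 1")
            return np.searchsorted(np.cumsum(probs), u, side="right").clip(0, len(probs) - 1).astype(float)
        if self.dist == "constant":
            return np.full_like(u, float(p["value"]))
        raise ConfigurationError(f"unknown marginal family {self.dist!r}")


@dataclass(frozen=True)
class CohortSpec:
    n: int
    marginals: Mapping[str, MarginalSpec]
    correlations: Sequence[tuple] = ()  # (attr_a, attr_b, rho)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise InvalidInputError("cohort size must be positive")


def _correlation_matrix(spec: CohortSpec, names: Sequence[str]) -> np.ndarray:
    k = len(names)
    index = {name: i for i, name in enumerate(names)}
    R = np.eye(k)
    for a, b, rho in spec.correlations:
        if a not in index or b not in index:
            raise InvalidInputError(f"correlation references unknown attribute ({a!r}, {b!r})")
        if not -1 <= rho <= 1:
            raise InvalidInputError(f"correlation {rho} outside [-1, 1]")
        R[index[a], index[b]] = R[index[b], index[a]] = rho
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise InvalidInputError("correlation specification is not positive semi-definite")
    return R


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a baseline cohort table, one row per individual.

    Deterministic for a fixed spec (including seed).  Correlated attributes
    are produced by mapping a multivariate-normal sample through each
    marginal's quantile function.
    """
    names = list(spec.marginals)
    R = _correlation_matrix(spec, names)
    rng = np.random.default_rng(spec.seed)
    # small jitter keeps Cholesky defined for PSD-but-singular specs
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(names)))
    z = rng.standard_normal((spec.n, len(names))) @ L.T
    u = stats.norm.cdf(z)
    data = {"id": np.arange(spec.n)}
    for j, name in enumerate(names):
        data[name] = spec.marginals[name].ppf(u[:, j])
    return pd.DataFrame(data)


def default_cohort_spec(n: int, seed: int = 0) -> CohortSpec:
    """Illustrative marginals for the default structure's eleven attributes."""
    marginals = {
        "age": MarginalSpec("uniform", {"low": 65.0, "high": 90.0}),
        "gender": MarginalSpec("bernoulli", {"p": 0.55}),
        "education": MarginalSpec("categorical", {"probs": [0.4, 0.4, 0.2]}),
        "frailty_status": MarginalSpec("categorical", {"probs": [0.5, 0.3, 0.2]}),
        "n_prev_hospital_admissions": MarginalSpec("poisson", {"lam": 0.4}),
        "n_prev_fractures": MarginalSpec("poisson", {"lam": 0.2}),
        "polypharmacy": MarginalSpec("bernoulli", {"p": 0.35}),
        "stroke": MarginalSpec("bernoulli", {"p": 0.08}),
        "diabetes": MarginalSpec("bernoulli", {"p": 0.2}),
        "physical_activity": MarginalSpec("categorical", {"probs": [0.3, 0.45, 0.25]}),
        "depression": MarginalSpec("bernoulli", {"p": 0.15}),
    }
    correlations = [
        ("age", "frailty_status", 0.3),
        ("frailty_status", "depression", 0.2),
        ("age", "n_prev_hospital_admissions", 0.15),
    ]
    return CohortSpec(n=n, marginals=marginals, correlations=correlations, seed=seed)


@dataclass(frozen=True)
class PanelSpec:
    waves: int
    cycle_length: float = 1.0

    def __post_init__(self) -> None:
        if self.waves < 2:
            raise InvalidInputError("a panel needs at least two waves")
        if self.cycle_length <= 0:
            raise InvalidInputError("cycle_length must be positive")


def generate_panel(
    cohort: pd.DataFrame,
    spec: PanelSpec,
    structure: ModelStructure,
    true_params: RiskParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a longitudinal panel from the cohort at known true parameters.

    One row per individual-wave while at risk: start-of-wave attribute
    values plus indicators for events occurring during the wave.  Events are
    sampled from the same risk equations the simulation engine uses; death
    is sampled first within a wave and suppresses the non-fatal events;
    history counters, persistent states and frailty status update between
    waves; follow-up stops at the death wave.
    """
    true_params.validate_against(structure)
    missing = [a for a in structure.attribute_names if a not in cohort.columns]
    if missing:
        raise InvalidInputError(f"cohort missing attributes: {missing}")

    rng = np.random.default_rng(seed)
    n = len(cohort)
    death = structure.death_event
    if death is None:
        raise ConfigurationError("structure has no absorbing death event")
    nonfatal = [e for e in structure.events if e.kind is not EventKind.ABSORBING]

    state = {a: cohort[a].to_numpy(dtype=float).copy() for a in structure.attribute_names}
    persistent = {e.name: np.zeros(n, dtype=bool) for e in nonfatal if e.persistent}
    ids = cohort["id"].to_numpy() if "id" in cohort.columns else np.arange(n)
    alive = np.ones(n, dtype=bool)
    T = transition_matrix_for_scenario(true_params.transitions)

    rows: list[pd.DataFrame] = []
    for wave in range(spec.waves):
        at_risk = alive.copy()
        if not at_risk.any():
            break
        rec = {"id": ids[at_risk], "wave": np.full(at_risk.sum(), wave)}
        for a in structure.attribute_names:
            rec[a] = state[a][at_risk]

        q_death = np.asarray(event_probabilities(true_params.equations[death.name], state))
        died = rng.random(n) < q_death
        died &= at_risk
        occurred: dict[str, np.ndarray] = {}
        for e in nonfatal:
            p = np.asarray(event_probabilities(true_params.equations[e.name], state))
            occ = rng.random(n) < p
            occ &= at_risk & ~died
            if e.persistent:
                occ &= ~persistent[e.name]
            occurred[e.name] = occ
        # frailty transition among survivors
        u = rng.random(n)
        fs = state["frailty_status"].astype(int)
        cdf = np.cumsum(T[fs], axis=1)
        new_fs = (u[:, None] >= cdf).sum(axis=1).clip(0, 2)

        rec[death.name] = died[at_risk].astype(int)
        for e in nonfatal:
            rec[e.name] = occurred[e.name][at_risk].astype(int)
        rows.append(pd.DataFrame(rec))

        survivors = at_risk & ~died
        alive = survivors
        state["age"] = state["age"] + spec.cycle_length
        state["frailty_status"] = np.where(survivors, new_fs, fs).astype(float)
        for e in nonfatal:
            if e.history_counter is not None and e.history_counter in state:
                state[e.history_counter] = state[e.history_counter] + occurred[e.name]
            if e.persistent:
                persistent[e.name] |= occurred[e.name]
                if e.name in state:
                    state[e.name] = persistent[e.name].astype(float)
    panel = pd.concat(rows, ignore_index=True)
    return panel
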
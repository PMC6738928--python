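"""Validation harness: Markov cohort oracle, cross-model comparison, and
internal/external validation against observed panel rates.

The Markov oracle is an exact cohort trace for a memoryless configuration;
the microsimulation, run with all history coefficients at zero and
time-invariant attributes, must reproduce it within Monte-Carlo error.
Internal validation compares simulated per-cycle rates against the rates
observed in the panel used for estimation; external validation applies the
same comparison to a held-out panel generated with a different seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .frailty import FrailtyCategory
from .risks import (
    FrailtyTransitionModel,
    RiskEquation,
    RiskParams,
    cycle_probability,
)
from .structure import EventKind, HealthEvent, ModelStructure, PatientAttribute, ValueType

__all__ = [
    "CalibrationTarget",
    "CalibrationTargets",
    "OracleComparison",
    "ValidationReport",
    "compare_microsim_to_oracle",
    "external_validation",
    "internal_validation",
    "markov_oracle",
    "memoryless_test_model",
    "targets_from_panel",
]

FRAILTY_LABELS = ("non_frail", "pre_frail", "frail")


def markov_oracle(
    transition_matrix,
    initial_distribution,
    cycles: int,
) -> np.ndarray:
    """Exact cohort occupancy trace by repeated vector-matrix products.

    Returns an array of shape (cycles + 1, n_states); row 0 is the initial
    distribution.
    """
    P = np.asarray(transition_matrix, dtype=float)
    pi0 = np.asarray(initial_distribution, dtype=float)
    if cycles < 1:
        raise InvalidInputError("cycles must be >= 1")
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise InvalidInputError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise InvalidInputError("transition matrix must be row-stochastic")
    if pi0.shape != (P.shape[0],) or np.any(pi0 < 0) or not np.isclose(pi0.sum(), 1.0):
        raise InvalidInputError("initial distribution must be a probability vector")
    trace = np.empty((cycles + 1, P.shape[0]))
    trace[0] = pi0
    for c in range(cycles):
        trace[c + 1] = trace[c] @ P
    return trace


def combined_markov_kernel(
    death_probs: Sequence[float], transitions: FrailtyTransitionModel
) -> np.ndarray:
    """4-state kernel (3 frailty categories + dead) for a memoryless model.

    Matches the engine's within-cycle order: death first at probability
    ``q_s``, then the frailty transition among survivors.
    """
    q = np.asarray(death_probs, dtype=float)
    T = transitions.matrix
    P = np.zeros((4, 4))
    P[:3, :3] = (1.0 - q)[:, None] * T
    P[:3, 3] = q
    P[3, 3] = 1.0
    return P


def memoryless_test_model(
    death_probs: Sequence[float] = (0.02, 0.05, 0.12),
    transitions: Optional[FrailtyTransitionModel] = None,
    initial_distribution: Sequence[float] = (0.5, 0.3, 0.2),
):
    """A small three-category memoryless configuration for cross-model checks.

    Returns (structure, params, initial_distribution); death probability
    depends only on the current frailty category.
    """
    if transitions is None:
        transitions = FrailtyTransitionModel(
            [[0.80, 0.15, 0.05], [0.10, 0.70, 0.20], [0.02, 0.08, 0.90]]
        )
    q = np.asarray(death_probs, dtype=float)
    structure = ModelStructure(
        events=[HealthEvent(name="death", kind=EventKind.ABSORBING)],
        attributes=[
            PatientAttribute(name="age", value_type=ValueType.CONTINUOUS, time_varying=True),
            PatientAttribute(
                name="frailty_status", value_type=ValueType.CATEGORICAL, time_varying=True
            ),
        ],
        edges=[("frailty_status", "death")],
    )
    lp0 = float(np.log(q[0] / (1 - q[0])))
    lp1 = float(np.log(q[1] / (1 - q[1])))
    lp2 = float(np.log(q[2] / (1 - q[2])))
    params = RiskParams(
        equations={
            "death": RiskEquation(
                event="death",
                coefficients={"intercept": lp0, "pre_frail": lp1 - lp0, "frail": lp2 - lp0},
            )
        },
        transitions=transitions,
    )
    return structure, params, np.asarray(initial_distribution, dtype=float)


@dataclass(frozen=True)
class OracleComparison:
    trace: np.ndarray  # oracle occupancy proportions (cycles+1, 4)
    observed: np.ndarray  # microsimulation occupancy proportions
    deviations: np.ndarray  # |observed - trace|
    se: np.ndarray  # binomial standard errors at the oracle proportions
    n: int
    tolerance: float
    flagged: np.ndarray  # boolean, deviation > tolerance * se

    @property
    def max_abs_deviation(self) -> float:
        return float(self.deviations.max())

    @property
    def ok(self) -> bool:
        return not bool(self.flagged.any())


def _check_memoryless(params: RiskParams, structure: ModelStructure) -> None:
    allowed = {"intercept", "pre_frail", "frail"}
    for e in structure.events:
        eq = params.equations[e.name]
        extra = set(eq.coefficients) - allowed
        if extra:
            raise InvalidInputError(
                f"{e.name}: covariates {sorted(extra)} violate the memoryless precondition"
            )


def compare_microsim_to_oracle(
    structure: ModelStructure,
    params: RiskParams,
    initial_distribution: Sequence[float],
    n: int,
    cycles: int,
    seed: int = 0,
    tolerance: float = 3.0,
) -> OracleComparison:
    """Run the engine on a memoryless configuration and compare occupancy
    against the exact Markov trace, cycle by cycle."""
    from .engine import ScenarioConfig, SimConfig, simulate_cohort

    _check_memoryless(params, structure)
    pi0 = np.asarray(initial_distribution, dtype=float)
    rng = np.random.default_rng(seed)
    frailty0 = rng.choice(3, size=n, p=pi0)
    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "age": np.zeros(n),
            "frailty_status": frailty0.astype(float),
        }
    )
    config = SimConfig(max_age=float(cycles + 1), horizon_cycles=cycles, seed=seed + 1)
    res = simulate_cohort(cohort, structure, params, ScenarioConfig(), config)

    q = np.array(
        [
            cycle_probability(
                params.equations["death"].coefficients.get("intercept", 0.0)
                + (params.equations["death"].coefficients.get("pre_frail", 0.0) if k == 1 else 0.0)
                + (params.equations["death"].coefficients.get("frail", 0.0) if k == 2 else 0.0)
            )
            for k in range(3)
        ]
    )
    P = combined_markov_kernel(q, params.transitions)
    trace = markov_oracle(P, np.append(pi0, 0.0), cycles)

    observed = res.occupancy / n
    if observed.shape[0] < trace.shape[0]:  # everyone died early; occupancy is constant after
        pad = np.repeat(observed[-1][None, :], trace.shape[0] - observed.shape[0], axis=0)
        observed = np.vstack([observed, pad])
    observed = observed[: trace.shape[0]]

    deviations = np.abs(observed - trace)
    se = np.sqrt(trace * (1 - trace) / n)
    flagged = deviations > tolerance * np.maximum(se, 1e-12)
    return OracleComparison(
        trace=trace,
        observed=observed,
        deviations=deviations,
        se=se,
        n=n,
        tolerance=tolerance,
        flagged=flagged,
    )


# --- calibration targets and internal/external validation -----------------


@dataclass(frozen=True)
class CalibrationTarget:
    name: str  # event name, "death", or "prevalence:<category>"
    wave: int
    observed: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= 1:
            raise InvalidInputError(f"{self.name}: observed rate outside [0, 1]")
        if self.n <= 0:
            raise InvalidInputError(f"{self.name}: target count must be positive")


@dataclass(frozen=True)
class CalibrationTargets:
    targets: Sequence[CalibrationTarget] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.targets)

    def __len__(self) -> int:
        return len(self.targets)


def targets_from_panel(panel: pd.DataFrame, structure: ModelStructure) -> CalibrationTargets:
    """Observed per-wave event rates, death rates and frailty prevalences.

    Rates are computed among individuals at risk at the start of the wave;
    non-fatal event indicators are zero on death rows, matching how the
    panel is generated and how the engine counts events.
    """
    out: list[CalibrationTarget] = []
    for wave, grp in panel.groupby("wave", sort=True):
        n_risk = len(grp)
        for e in structure.events:
            if e.name in grp.columns:
                out.append(
                    CalibrationTarget(
                        name=e.name,
                        wave=int(wave),
                        observed=float(grp[e.name].mean()),
                        n=n_risk,
                    )
                )
        if "frailty_status" in grp.columns:
            fs = grp["frailty_status"].astype(int)
            for k, label in enumerate(FRAILTY_LABELS):
                out.append(
                    CalibrationTarget(
                        name=f"prevalence:{label}",
                        wave=int(wave),
                        observed=float((fs == k).mean()),
                        n=n_risk,
                    )
                )
    return CalibrationTargets(targets=tuple(out))


@dataclass(frozen=True)
class ValidationReport:
    table: pd.DataFrame
    tolerance: float

    @property
    def passed(self) -> bool:
        matched = self.table[self.table["matched"]]
        return bool(matched["passed"].all()) if len(matched) else True

    @property
    def n_failed(self) -> int:
        matched = self.table[self.table["matched"]]
        return int((~matched["passed"]).sum())


def _predicted_rate(results, name: str, wave: int):
    if wave >= len(results.cycle_alive) or results.cycle_alive[wave] == 0:
        return None, None
    n_risk = int(results.cycle_alive[wave])
    if name == "death":
        return results.cycle_deaths[wave] / n_risk, n_risk
    if name.startswith("prevalence:"):
        label = name.split(":", 1)[1]
        try:
            k = FRAILTY_LABELS.index(label)
        except ValueError:
            return None, None
        return results.cycle_frailty[wave, k] / n_risk, n_risk
    if name in results.cycle_events:
        return results.cycle_events[name][wave] / n_risk, n_risk
    return None, None


def internal_validation(
    results,
    targets: CalibrationTargets,
    tolerance: float = 3.0,
) -> ValidationReport:
    """Compare simulated per-cycle rates to observed panel rates.

    A target passes when the standardised difference — the gap divided by
    the combined binomial standard error of the observed and predicted
    rates — is below ``tolerance``.  Targets the simulation cannot produce
    are reported as unmatched rather than raising.
    """
    rows = []
    for t in targets:
        pred, n_pred = _predicted_rate(results, t.name, t.wave)
        if pred is None:
            rows.append(
                {
                    "target": t.name, "wave": t.wave, "observed": t.observed,
                    "predicted": np.nan, "diff": np.nan, "se": np.nan,
                    "std_diff": np.nan, "passed": False, "matched": False,
                }
            )
            continue
        se_obs = np.sqrt(t.observed * (1 - t.observed) / t.n)
        se_pred = np.sqrt(pred * (1 - pred) / n_pred)
        se = float(np.sqrt(se_obs**2 + se_pred**2))
        diff = float(pred - t.observed)
        std = diff / se if se > 0 else (0.0 if diff == 0 else np.inf)
        rows.append(
            {
                "target": t.name, "wave": t.wave, "observed": t.observed,
                "predicted": float(pred), "diff": diff, "se": se,
                "std_diff": float(std), "passed": bool(abs(std) < tolerance),
                "matched": True,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["target", "wave", "observed", "predicted", "diff", "se",
                 "std_diff", "passed", "matched"],
    )
    return ValidationReport(table=table, tolerance=tolerance)


def external_validation(results, holdout_panel: pd.DataFrame, structure: ModelStructure,
                        tolerance: float = 3.0) -> ValidationReport:
    """Internal-validation comparison against a held-out panel."""
    return internal_validation(results, targets_from_panel(holdout_panel, structure), tolerance)
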
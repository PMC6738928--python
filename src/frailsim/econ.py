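"""Health-economic outputs: discounted QALYs and costs, incremental
cost-effectiveness results, and probabilistic sensitivity analysis.

Shipped default utility and cost values are illustrative fixtures for
testing and demonstration only; they are not estimates from any dataset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .frailty import FrailtyCategory

__all__ = [
    "CEResults",
    "CostModel",
    "DominanceLabel",
    "ParameterDistribution",
    "PSAResult",
    "UtilityModel",
    "accrue_costs",
    "accrue_qalys",
    "ceac",
    "discount_factor",
    "incremental_analysis",
    "run_psa",
]


def discount_factor(t: float, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** (-t)`` for time ``t`` in years."""
    if t < 0:
        raise InvalidInputError("time must be non-negative")
    if rate <= -1:
        raise InvalidInputError("discount rate must exceed -1")
    return float((1.0 + rate) ** (-t))


@dataclass(frozen=True)
class UtilityModel:
    """Baseline utility by frailty category with multiplicative decrements.

    Cycle utility = baseline(frailty) x product of multipliers for events
    occurring in the cycle x product of multipliers for active persistent
    states, floored at 0.  All inputs must lie in [0, 1] so the combined
    value cannot exceed 1.
    """

    by_frailty: Mapping[FrailtyCategory, float] = field(
        default_factory=lambda: {
            FrailtyCategory.NON_FRAIL: 0.86,
            FrailtyCategory.PRE_FRAIL: 0.77,
            FrailtyCategory.FRAIL: 0.65,
        }
    )
    event_multipliers: Mapping[str, float] = field(default_factory=dict)
    state_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in FrailtyCategory:
            u = self.by_frailty.get(cat)
            if u is None:
                raise ConfigurationError(f"utility missing for category {cat.label}")
            if not 0 <= u <= 1:
                raise ConfigurationError(f"utility for {cat.label} outside [0, 1]")
        for src in (self.event_multipliers, self.state_multipliers):
            for name, m in src.items():
                if not 0 <= m <= 1:
                    raise ConfigurationError(f"utility multiplier for {name!r} outside [0, 1]")

    def cycle_utility(self, frailty: FrailtyCategory, events=(), states=()) -> float:
        u = self.by_frailty[FrailtyCategory(frailty)]
        for ev in events:
            u *= self.event_multipliers.get(ev, 1.0)
        for st in states:
            u *= self.state_multipliers.get(st, 1.0)
        return max(u, 0.0)

    @property
    def frailty_vector(self) -> np.ndarray:
        return np.array([self.by_frailty[FrailtyCategory(i)] for i in range(3)])


@dataclass(frozen=True)
class CostModel:
    """One-off event costs plus annual persistent-state and frailty costs.

    ``perspective_tags`` optionally records a cost-perspective label per
    entry (e.g. government vs societal); it does not affect computation.
    """

    event_costs: Mapping[str, float] = field(default_factory=dict)
    annual_state_costs: Mapping[str, float] = field(default_factory=dict)
    annual_frailty_costs: Mapping[FrailtyCategory, float] = field(default_factory=dict)
    perspective_tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src in (self.event_costs, self.annual_state_costs, self.annual_frailty_costs):
            for name, c in src.items():
                if c < 0:
                    raise ConfigurationError(f"negative cost configured for {name!r}")

    def cycle_cost(self, frailty: FrailtyCategory, events=(), states=(), cycle_length: float = 1.0) -> float:
        c = sum(self.event_costs.get(ev, 0.0) for ev in events)
        c += cycle_length * sum(self.annual_state_costs.get(st, 0.0) for st in states)
        c += cycle_length * self.annual_frailty_costs.get(FrailtyCategory(frailty), 0.0)
        return c

    @property
    def frailty_vector(self) -> np.ndarray:
        return np.array(
            [self.annual_frailty_costs.get(FrailtyCategory(i), 0.0) for i in range(3)]
        )


def accrue_qalys(trajectory, utility_model: Optional[UtilityModel] = None, rate: float = 0.0) -> float:
    """Discounted QALYs for one trajectory.

    Sums cycle_length x cycle utility x discount factor at cycle start.
    With a utility model the per-cycle utility is recomputed from the
    recorded frailty, events and states; otherwise the stored accrual is used.
    """
    dt = trajectory.cycle_length
    total = 0.0
    for rec in trajectory.records:
        if utility_model is not None:
            occurred = [ev for ev, flag in rec.events.items() if flag]
            u = utility_model.cycle_utility(rec.frailty, occurred, rec.states)
        else:
            u = rec.utility
        if not 0 <= u <= 1:
            raise ConfigurationError(f"cycle {rec.cycle}: combined utility {u} outside [0, 1]")
        total += dt * u * discount_factor(rec.cycle * dt, rate)
    return total


def accrue_costs(
    trajectory,
    cost_model: Optional[CostModel] = None,
    scenario=None,
    rate: float = 0.0,
) -> float:
    """Discounted costs for one trajectory (events, states, intervention)."""
    dt = trajectory.cycle_length
    total = 0.0
    for rec in trajectory.records:
        if cost_model is not None:
            occurred = [ev for ev, flag in rec.events.items() if flag]
            c = cost_model.cycle_cost(rec.frailty, occurred, rec.states, dt)
            if scenario is not None:
                c += scenario.per_cycle_cost * dt
                if rec.cycle == 0:
                    c += scenario.one_off_cost
        else:
            c = rec.cost
        total += c * discount_factor(rec.cycle * dt, rate)
    return total


class DominanceLabel(str, enum.Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    TRADEOFF = "tradeoff"
    EQUAL_EFFECTIVENESS = "equal effectiveness"


@dataclass(frozen=True)
class CEResults:
    cost_a: float
    qalys_a: float
    cost_b: float
    qalys_b: float
    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    label: DominanceLabel


def _mean_cost_qalys(results) -> tuple:
    if hasattr(results, "mean_cost"):
        return float(results.mean_cost), float(results.mean_qalys)
    cost, qalys = results
    return float(cost), float(qalys)


def incremental_analysis(results_a, results_b) -> CEResults:
    """Incremental comparison of scenario B (intervention) against A.

    The ICER is reported only when incremental QALYs are non-zero; strict
    dominance quadrants get labels instead of a ratio.
    """
    cost_a, qalys_a = _mean_cost_qalys(results_a)
    cost_b, qalys_b = _mean_cost_qalys(results_b)
    dc = cost_b - cost_a
    dq = qalys_b - qalys_a
    if dq == 0:
        return CEResults(cost_a, qalys_a, cost_b, qalys_b, dc, dq, None,
                         DominanceLabel.EQUAL_EFFECTIVENESS)
    if dc < 0 and dq > 0:
        label = DominanceLabel.DOMINANT
    elif dc > 0 and dq < 0:
        label = DominanceLabel.DOMINATED
    else:
        label = DominanceLabel.TRADEOFF
    return CEResults(cost_a, qalys_a, cost_b, qalys_b, dc, dq, dc / dq, label)


def ceac(delta_costs, delta_qalys, thresholds) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay threshold, the fraction of draws whose net
    monetary benefit ``threshold * dQ - dC`` is positive.
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    lams = np.asarray(thresholds, dtype=float)
    return np.array([(lam * dq - dc > 0).mean() for lam in lams])


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one uncertain parameter.

    ``target`` addresses the parameter:
      ("coefficient", event, covariate)  -> normal draws on a risk coefficient
      ("utility", category_label)        -> beta (or degenerate normal) utility
      ("event_cost", event)              -> gamma cost
    """

    target: tuple
    dist: str  # normal | beta | gamma
    params: Mapping[str, float]

    def draw(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.dist == "normal":
            if p.get("sd", 0.0) < 0:
                raise ConfigurationError("normal sd must be non-negative")
            return float(p["mean"] + p.get("sd", 0.0) * rng.standard_normal()) if p.get("sd", 0.0) > 0 else float(p["mean"])
        if self.dist == "beta":
            if p["a"] <= 0 or p["b"] <= 0:
                raise ConfigurationError("beta parameters must be positive")
            return float(rng.beta(p["a"], p["b"]))
        if self.dist == "gamma":
            if p["shape"] <= 0 or p["scale"] < 0:
                raise ConfigurationError("gamma parameters must be positive")
            return float(rng.gamma(p["shape"], p["scale"]))
        raise ConfigurationError(f"unknown distribution {self.dist!r}")


@dataclass(frozen=True)
class PSAResult:
    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    thresholds: np.ndarray
    ceac: np.ndarray
    base: CEResults


def _apply_draws(params, utility_model, cost_model, values: Mapping):
    from .risks import RiskEquation, RiskParams

    equations = {name: dict(eq.coefficients) for name, eq in params.equations.items()}
    by_frailty = dict(utility_model.by_frailty)
    event_costs = dict(cost_model.event_costs)
    for target, value in values.items():
        kind = target[0]
        if kind == "coefficient":
            _, event, cov = target
            if event not in equations:
                raise ConfigurationError(f"no risk equation for event {event!r}")
            equations[event][cov] = value
        elif kind == "utility":
            _, label = target
            by_frailty[FrailtyCategory[label.upper()]] = min(max(value, 0.0), 1.0)
        elif kind == "event_cost":
            _, event = target
            event_costs[event] = max(value, 0.0)
        else:
            raise ConfigurationError(f"unknown PSA target kind {kind!r}")
    from .risks import FrailtyTransitionModel  # noqa: F401  (type re-export convenience)

    new_params = RiskParams(
        equations={
            name: RiskEquation(event=name, coefficients=c) for name, c in equations.items()
        },
        transitions=params.transitions,
    )
    new_util = replace(utility_model, by_frailty=by_frailty)
    new_cost = replace(cost_model, event_costs=event_costs)
    return new_params, new_util, new_cost


def run_psa(
    cohort,
    structure,
    base_params,
    scenario_a,
    scenario_b,
    distributions: Sequence[ParameterDistribution],
    n_draws: int,
    thresholds: Sequence[float],
    config,
    utility_model: UtilityModel,
    cost_model: CostModel,
    discount_rate: float = 0.0,
    seed: int = 0,
) -> PSAResult:
    """Probabilistic sensitivity analysis over declared parameter distributions.

    Monte-Carlo sampling noise is held fixed across draws (one shared
    common-random-number block), so zero-variance distributions reproduce
    the deterministic comparison exactly in every draw.
    """
    from .engine import build_uniform_block, max_cycle_count, run_comparison

    if n_draws <= 0:
        raise InvalidInputError("n_draws must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    cycles = max_cycle_count(config, cohort["age"].to_numpy(dtype=float).min())
    block = build_uniform_block(config.seed, len(cohort), cycles, structure)

    base = run_comparison(
        cohort, structure, base_params, scenario_a, scenario_b, config,
        utility_model=utility_model, cost_model=cost_model,
        discount_rate=discount_rate, uniforms=block,
    ).ce

    dcs = np.empty(n_draws)
    dqs = np.empty(n_draws)
    for i in range(n_draws):
        values = {d.target: d.draw(rng) for d in distributions}
        params_i, util_i, cost_i = _apply_draws(base_params, utility_model, cost_model, values)
        comp = run_comparison(
            cohort, structure, params_i, scenario_a, scenario_b, config,
            utility_model=util_i, cost_model=cost_i,
            discount_rate=discount_rate, uniforms=block,
        )
        dcs[i] = comp.ce.delta_cost
        dqs[i] = comp.ce.delta_qalys
    lams = np.asarray(thresholds, dtype=float)
    return PSAResult(
        delta_costs=dcs,
        delta_qalys=dqs,
        thresholds=lams,
        ceac=ceac(dcs, dqs, lams),
        base=base,
    )
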
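"""Individual-level discrete-time simulation of frailty progression.

Each cycle, in fixed order: (1) death is sampled from its risk equation —
on death the cycle is recorded and the trajectory ends; (2) each non-fatal
event is sampled independently given the linear predictors; (3) the frailty
category transitions; (4) history counters and persistent states update;
(5) utility and cost accrue for the cycle.  Death is treated as occurring
at the end of its cycle, so the death cycle accrues a full cycle of life.

Two implementations share these semantics: a scalar per-individual path
(:func:`simulate_individual`, the reference) and a vectorised cohort path
(:func:`simulate_cohort`).  Both can consume a pre-drawn block of uniforms
indexed by (cycle, draw slot); reusing one block across scenarios gives
common random numbers with one substream per individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .econ import CostModel, UtilityModel, incremental_analysis
from .errors import ConfigurationError, InvalidInputError
from .frailty import FrailtyCategory
from .risks import (
    RiskParams,
    cycle_probability,
    event_probabilities,
    frailty_transition_probs,
    linear_predictor,
    transition_matrix_for_scenario,
)
from .structure import EventKind, ModelStructure

__all__ = [
    "CohortResults",
    "ComparisonResults",
    "CycleRecord",
    "ScenarioConfig",
    "SimConfig",
    "Trajectory",
    "build_uniform_block",
    "max_cycle_count",
    "run_comparison",
    "simulate_cohort",
    "simulate_individual",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """An intervention (or comparator) scenario.

    Frailty multipliers rescale the worsening/improving transition mass;
    event hazard multipliers enter the linear predictors as log terms;
    intervention costs accrue per cycle and once at baseline.
    """

    name: str = "usual_care"
    intervention: bool = False
    frailty_worsening_multiplier: float = 1.0
    frailty_improvement_multiplier: float = 1.0
    event_hazard_multipliers: Mapping[str, float] = field(default_factory=dict)
    one_off_cost: float = 0.0
    per_cycle_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.frailty_worsening_multiplier < 0 or self.frailty_improvement_multiplier < 0:
            raise ConfigurationError("frailty transition multipliers must be non-negative")
        for ev, m in self.event_hazard_multipliers.items():
            if m <= 0:
                raise ConfigurationError(f"hazard multiplier for {ev!r} must be positive")
        if self.one_off_cost < 0 or self.per_cycle_cost < 0:
            raise ConfigurationError("intervention costs must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    cycle_length: float = 1.0
    max_age: float = 110.0
    horizon_cycles: Optional[int] = None
    seed: int = 0
    common_random_numbers: bool = False
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ConfigurationError("cycle_length must be positive")
        if not math.isfinite(self.max_age):
            raise ConfigurationError("max_age must be finite")


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    age: float
    frailty: FrailtyCategory
    events: Mapping[str, bool]
    states: frozenset
    attributes: Mapping[str, float]  # snapshot at cycle start
    utility: float
    cost: float


@dataclass(frozen=True)
class Trajectory:
    records: Sequence[CycleRecord]
    death_cycle: Optional[int]
    cycle_length: float
    baseline: Mapping[str, float]

    @property
    def life_years(self) -> float:
        return len(self.records) * self.cycle_length


def max_cycle_count(config: SimConfig, youngest_age: float) -> int:
    cycles = int(math.ceil((config.max_age - youngest_age) / config.cycle_length - 1e-9))
    cycles = max(cycles, 0)
    if config.horizon_cycles is not None:
        cycles = min(cycles, config.horizon_cycles)
    return cycles


def _draw_slots(structure: ModelStructure) -> int:
    # slot 0: death; slots 1..m: non-fatal events in structure order; last: frailty
    return len(structure.nonfatal_events) + 2


def build_uniform_block(
    seed: int, n: int, cycles: int, structure: ModelStructure
) -> np.ndarray:
    """Per-individual uniform draws, shape (n, cycles, slots).

    Each individual gets an independent substream spawned from the master
    seed, so the block is reproducible and reusable across scenarios.
    """
    k = _draw_slots(structure)
    out = np.empty((n, cycles, k))
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n)):
        out[i] = np.random.default_rng(child).random((cycles, k))
    return out


def _hazard_shift(scenario: ScenarioConfig, event: str) -> float:
    m = scenario.event_hazard_multipliers.get(event, 1.0)
    return math.log(m)


def simulate_individual(
    baseline: Mapping[str, float],
    structure: ModelStructure,
    params: RiskParams,
    scenario: ScenarioConfig,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    uniforms: Optional[np.ndarray] = None,
    utility_model: Optional[UtilityModel] = None,
    cost_model: Optional[CostModel] = None,
) -> Trajectory:
    """Simulate one individual; the scalar reference implementation.

    ``uniforms`` (cycles x slots) replaces ``rng`` when given; draws are
    then indexed by slot so the same block reproduces the vectorised path.
    """
    params.validate_against(structure)
    missing = [a for a in structure.attribute_names if a not in baseline]
    if missing:
        raise InvalidInputError(f"baseline missing attributes: {missing}")
    if rng is None and uniforms is None:
        rng = np.random.default_rng(config.seed)
    utility_model = utility_model or UtilityModel()
    cost_model = cost_model or CostModel()

    death = structure.death_event
    if death is None:
        raise ConfigurationError("structure has no absorbing death event")
    nonfatal = structure.nonfatal_events

    attrs = {a: float(baseline[a]) for a in structure.attribute_names}
    active_states: set = set()
    frailty = FrailtyCategory(int(attrs.get("frailty_status", 0)))
    cycles = max_cycle_count(config, attrs["age"])
    if uniforms is not None and uniforms.shape[0] < cycles:
        raise InvalidInputError("uniform block has fewer cycles than the horizon")

    def draw(c: int, slot: int) -> float:
        if uniforms is not None:
            return float(uniforms[c, slot])
        return float(rng.random())

    records: list[CycleRecord] = []
    death_cycle: Optional[int] = None
    dt = config.cycle_length
    for c in range(cycles):
        state = dict(attrs)
        state["frailty_status"] = float(frailty)
        for e in nonfatal:
            if e.persistent:
                state[e.name] = float(e.name in active_states)

        q = cycle_probability(
            linear_predictor(params.equations[death.name], state)
            + _hazard_shift(scenario, death.name)
        )
        died = draw(c, 0) < q
        occurred: dict[str, bool] = {death.name: died}
        if not died:
            for slot, e in enumerate(nonfatal, start=1):
                p = cycle_probability(
                    linear_predictor(params.equations[e.name], state)
                    + _hazard_shift(scenario, e.name)
                )
                u = draw(c, slot)
                occ = u < p
                if e.persistent and e.name in active_states:
                    occ = False
                occurred[e.name] = occ
        else:
            for e in nonfatal:
                occurred[e.name] = False

        events_now = [ev for ev, flag in occurred.items() if flag]
        util = utility_model.cycle_utility(frailty, events_now, active_states)
        if config.half_cycle_correction and (c == 0 or died):
            util *= 0.5 if not (c == 0 and died) else 0.25
        cost = cost_model.cycle_cost(frailty, events_now, active_states, dt)
        cost += scenario.per_cycle_cost * dt
        if c == 0:
            cost += scenario.one_off_cost
        records.append(
            CycleRecord(
                cycle=c,
                age=attrs["age"],
                frailty=frailty,
                events=dict(occurred),
                states=frozenset(active_states),
                attributes=dict(attrs),
                utility=util,
                cost=cost,
            )
        )
        if died:
            death_cycle = c
            break

        row = frailty_transition_probs(
            frailty,
            params.transitions,
            scenario.frailty_worsening_multiplier,
            scenario.frailty_improvement_multiplier,
        )
        u_f = draw(c, len(nonfatal) + 1)
        frailty = FrailtyCategory(int(min((u_f >= np.cumsum(row)).sum(), 2)))

        for e in nonfatal:
            if occurred[e.name]:
                if e.history_counter is not None and e.history_counter in attrs:
                    attrs[e.history_counter] += 1.0
                if e.persistent:
                    active_states.add(e.name)
        attrs["age"] += dt
        attrs["frailty_status"] = float(frailty)

    return Trajectory(
        records=tuple(records),
        death_cycle=death_cycle,
        cycle_length=dt,
        baseline=dict(baseline),
    )


@dataclass(frozen=True)
class CohortResults:
    """Per-individual outcomes plus per-cycle aggregates for a scenario run."""

    scenario: str
    n: int
    cycle_length: float
    discount_rate: float
    life_years: np.ndarray
    qalys: np.ndarray
    costs: np.ndarray
    qalys_undiscounted: np.ndarray
    costs_undiscounted: np.ndarray
    death_cycle: np.ndarray  # -1 when alive at end of follow-up
    event_counts: Mapping[str, np.ndarray]
    occupancy: np.ndarray  # (cycles+1, 4): non-frail, pre-frail, frail, dead
    cycle_alive: np.ndarray
    cycle_deaths: np.ndarray
    cycle_events: Mapping[str, np.ndarray]
    cycle_frailty: np.ndarray  # (cycles, 3) category counts among at-risk

    @staticmethod
    def _mean_se(x: np.ndarray) -> tuple:
        m = float(np.mean(x))
        se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
        return m, se

    @property
    def mean_life_years(self) -> float:
        return self._mean_se(self.life_years)[0]

    @property
    def se_life_years(self) -> float:
        return self._mean_se(self.life_years)[1]

    @property
    def mean_qalys(self) -> float:
        return self._mean_se(self.qalys)[0]

    @property
    def se_qalys(self) -> float:
        return self._mean_se(self.qalys)[1]

    @property
    def mean_cost(self) -> float:
        return self._mean_se(self.costs)[0]

    @property
    def se_cost(self) -> float:
        return self._mean_se(self.costs)[1]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": [self.scenario],
                "n": [self.n],
                "mean_life_years": [self.mean_life_years],
                "mean_qalys": [self.mean_qalys],
                "se_qalys": [self.se_qalys],
                "mean_cost": [self.mean_cost],
                "se_cost": [self.se_cost],
            }
        )


def simulate_cohort(
    cohort: pd.DataFrame,
    structure: ModelStructure,
    params: RiskParams,
    scenario: ScenarioConfig,
    config: SimConfig,
    utility_model: Optional[UtilityModel] = None,
    cost_model: Optional[CostModel] = None,
    discount_rate: float = 0.0,
    uniforms: Optional[np.ndarray] = None,
) -> CohortResults:
    """Vectorised cohort simulation; semantics match :func:`simulate_individual`.

    Randomness comes from a single master generator, or — when
    ``config.common_random_numbers`` is set or ``uniforms`` is supplied —
    from a per-individual uniform block indexed by (cycle, slot).
    """
    if len(cohort) == 0:
        raise InvalidInputError("cohort is empty")
    params.validate_against(structure)
    missing = [a for a in structure.attribute_names if a not in cohort.columns]
    if missing:
        raise InvalidInputError(f"cohort missing attributes: {missing}")
    utility_model = utility_model or UtilityModel()
    cost_model = cost_model or CostModel()
    death = structure.death_event
    if death is None:
        raise ConfigurationError("structure has no absorbing death event")
    nonfatal = structure.nonfatal_events
    dt = config.cycle_length
    n = len(cohort)

    attrs = {a: cohort[a].to_numpy(dtype=float).copy() for a in structure.attribute_names}
    frailty = attrs.get("frailty_status", np.zeros(n)).astype(int)
    persistent = {e.name: np.zeros(n, dtype=bool) for e in nonfatal if e.persistent}
    alive = np.ones(n, dtype=bool)

    cycles = max_cycle_count(config, float(attrs["age"].min()))
    if uniforms is None and config.common_random_numbers:
        uniforms = build_uniform_block(config.seed, n, cycles, structure)
    if uniforms is not None:
        if uniforms.shape[0] != n or uniforms.shape[1] < cycles:
            raise InvalidInputError("uniform block shape does not cover cohort and horizon")
        rng = None
    else:
        rng = np.random.default_rng(config.seed)

    Tm = transition_matrix_for_scenario(
        params.transitions,
        scenario.frailty_worsening_multiplier,
        scenario.frailty_improvement_multiplier,
    )
    u_frailty_vec = utility_model.frailty_vector
    c_frailty_vec = cost_model.frailty_vector

    life_cycles = np.zeros(n)
    qalys = np.zeros(n)
    costs = np.zeros(n)
    qalys_undisc = np.zeros(n)
    costs_undisc = np.zeros(n)
    death_cycle = np.full(n, -1)
    event_counts = {e.name: np.zeros(n, dtype=int) for e in structure.events}

    occupancy_rows: list[np.ndarray] = []
    cycle_alive: list[int] = []
    cycle_deaths: list[int] = []
    cycle_events: dict[str, list[int]] = {e.name: [] for e in nonfatal}
    cycle_frailty: list[np.ndarray] = []

    def occupancy_row() -> np.ndarray:
        row = np.zeros(4)
        for cat in range(3):
            row[cat] = np.count_nonzero(alive & (frailty == cat))
        row[3] = n - np.count_nonzero(alive)
        return row

    def draws(c: int, slot: int) -> np.ndarray:
        if uniforms is not None:
            return uniforms[:, c, slot]
        return rng.random(n)

    for c in range(cycles):
        active = alive & (attrs["age"] < config.max_age - 1e-9)
        if not active.any():
            break
        occupancy_rows.append(occupancy_row())
        cycle_alive.append(int(active.sum()))
        cycle_frailty.append(
            np.array([np.count_nonzero(active & (frailty == k)) for k in range(3)])
        )

        state = dict(attrs)
        state["frailty_status"] = frailty.astype(float)
        for name, act in persistent.items():
            state[name] = act.astype(float)

        q = np.asarray(
            event_probabilities(
                params.equations[death.name], state, _hazard_shift(scenario, death.name)
            )
        )
        died = active & (draws(c, 0) < q)
        cycle_deaths.append(int(died.sum()))

        occurred: dict[str, np.ndarray] = {}
        for slot, e in enumerate(nonfatal, start=1):
            p = np.asarray(
                event_probabilities(
                    params.equations[e.name], state, _hazard_shift(scenario, e.name)
                )
            )
            occ = active & ~died & (draws(c, slot) < p)
            if e.persistent:
                occ &= ~persistent[e.name]
            occurred[e.name] = occ
            cycle_events[e.name].append(int(occ.sum()))
            event_counts[e.name] += occ
        event_counts[death.name] += died

        u_f = draws(c, len(nonfatal) + 1)
        cdf = np.cumsum(Tm[frailty], axis=1)
        new_frailty = np.minimum((u_f[:, None] >= cdf).sum(axis=1), 2)

        # accrual at cycle-start frailty and states, with this cycle's events
        util = u_frailty_vec[frailty].copy()
        cost = np.full(n, scenario.per_cycle_cost * dt)
        cost += c_frailty_vec[frailty] * dt
        if c == 0:
            cost += scenario.one_off_cost
        for name, occ in occurred.items():
            m = utility_model.event_multipliers.get(name)
            if m is not None:
                util[occ] *= m
            ec = cost_model.event_costs.get(name, 0.0)
            if ec:
                cost[occ] += ec
        dc = cost_model.event_costs.get(death.name, 0.0)
        if dc:
            cost[died] += dc
        dm = utility_model.event_multipliers.get(death.name)
        if dm is not None:
            util[died] *= dm
        for name, act in persistent.items():
            m = utility_model.state_multipliers.get(name)
            if m is not None:
                util[act] *= m
            sc = cost_model.annual_state_costs.get(name, 0.0)
            if sc:
                cost[act] += sc * dt
        util = np.maximum(util, 0.0)
        if config.half_cycle_correction:
            w = np.ones(n)
            if c == 0:
                w *= 0.5
            w[died] *= 0.5
            util = util * w

        t = c * dt
        df = (1.0 + discount_rate) ** (-t)
        qalys[active] += dt * util[active] * df
        qalys_undisc[active] += dt * util[active]
        costs[active] += cost[active] * df
        costs_undisc[active] += cost[active]
        life_cycles[active] += 1

        # updates
        death_cycle[died] = c
        alive &= ~died
        survivors = active & ~died
        frailty = np.where(survivors, new_frailty, frailty)
        for e in nonfatal:
            occ = occurred[e.name]
            if e.history_counter is not None and e.history_counter in attrs:
                attrs[e.history_counter] = attrs[e.history_counter] + occ
            if e.persistent:
                persistent[e.name] |= occ
        attrs["age"] = np.where(active, attrs["age"] + dt, attrs["age"])
        attrs["frailty_status"] = frailty.astype(float)

    occupancy_rows.append(occupancy_row())
    n_recorded = len(cycle_alive)
    return CohortResults(
        scenario=scenario.name,
        n=n,
        cycle_length=dt,
        discount_rate=discount_rate,
        life_years=life_cycles * dt,
        qalys=qalys,
        costs=costs,
        qalys_undiscounted=qalys_undisc,
        costs_undiscounted=costs_undisc,
        death_cycle=death_cycle,
        event_counts={k: v for k, v in event_counts.items()},
        occupancy=np.vstack(occupancy_rows),
        cycle_alive=np.array(cycle_alive),
        cycle_deaths=np.array(cycle_deaths),
        cycle_events={k: np.array(v[:n_recorded]) for k, v in cycle_events.items()},
        cycle_frailty=np.vstack(cycle_frailty) if cycle_frailty else np.zeros((0, 3)),
    )


@dataclass(frozen=True)
class ComparisonResults:
    result_a: CohortResults
    result_b: CohortResults
    delta_costs: np.ndarray  # per-individual, B minus A
    delta_qalys: np.ndarray
    ce: "object"

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_costs.mean())

    @property
    def mean_delta_qalys(self) -> float:
        return float(self.delta_qalys.mean())

    @property
    def se_delta_cost(self) -> float:
        return float(np.std(self.delta_costs, ddof=1) / np.sqrt(len(self.delta_costs)))

    @property
    def se_delta_qalys(self) -> float:
        return float(np.std(self.delta_qalys, ddof=1) / np.sqrt(len(self.delta_qalys)))


def run_comparison(
    cohort: pd.DataFrame,
    structure: ModelStructure,
    params: RiskParams,
    scenario_a: ScenarioConfig,
    scenario_b: ScenarioConfig,
    config: SimConfig,
    utility_model: Optional[UtilityModel] = None,
    cost_model: Optional[CostModel] = None,
    discount_rate: float = 0.0,
    uniforms: Optional[np.ndarray] = None,
) -> ComparisonResults:
    """Paired comparison of two scenarios under common random numbers.

    The same per-individual uniform block drives both scenarios, so the
    per-individual differences are genuinely paired.
    """
    if len(cohort) == 0:
        raise InvalidInputError("cohort is empty")
    if uniforms is None:
        cycles = max_cycle_count(config, float(cohort["age"].min()))
        uniforms = build_uniform_block(config.seed, len(cohort), cycles, structure)
    kwargs = dict(
        utility_model=utility_model,
        cost_model=cost_model,
        discount_rate=discount_rate,
        uniforms=uniforms,
    )
    res_a = simulate_cohort(cohort, structure, params, scenario_a, config, **kwargs)
    res_b = simulate_cohort(cohort, structure, params, scenario_b, config, **kwargs)
    return ComparisonResults(
        result_a=res_a,
        result_b=res_b,
        delta_costs=res_b.costs - res_a.costs,
        delta_qalys=res_b.qalys - res_a.qalys,
        ce=incremental_analysis(res_a, res_b),
    )
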
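"""Per-event risk equations and the frailty state transition model.

Each health event has a logistic risk equation: a linear predictor over
patient attributes (including history counters and frailty-category
indicators) mapped through the logit link to a per-cycle probability.
Frailty progression is a per-cycle transition model over the three
categories; intervention scenarios act multiplicatively on the worsening
(and optionally improving) off-diagonal mass, with the remainder assigned
to the stay probability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigurationError, EstimationError, InvalidInputError
from .frailty import FrailtyCategory
from .structure import ModelStructure

__all__ = [
    "FrailtyTransitionModel",
    "RiskEquation",
    "RiskFit",
    "RiskParams",
    "cycle_probability",
    "default_risk_params",
    "derive_covariates",
    "event_probabilities",
    "fit_risk_equation",
    "frailty_transition_probs",
    "linear_predictor",
]

INTERCEPT = "intercept"

# Covariates derived from frailty_status; they never appear as raw columns.
DERIVED_COVARIATES = ("pre_frail", "frail")


@dataclass(frozen=True)
class RiskEquation:
    """Logistic risk equation for one event: coefficients keyed by covariate."""

    event: str
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.coefficients.items():
            if not math.isfinite(value):
                raise InvalidInputError(f"{self.event}: non-finite coefficient for {name!r}")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.coefficients if c != INTERCEPT]

    @property
    def intercept(self) -> float:
        return float(self.coefficients.get(INTERCEPT, 0.0))


def derive_covariates(state: Mapping) -> dict:
    """Augment a state mapping with frailty-category indicator covariates."""
    out = dict(state)
    if "frailty_status" in out and "frail" not in out:
        fs = out["frailty_status"]
        if isinstance(fs, (pd.Series, np.ndarray)):
            out["pre_frail"] = (np.asarray(fs) == FrailtyCategory.PRE_FRAIL).astype(float)
            out["frail"] = (np.asarray(fs) == FrailtyCategory.FRAIL).astype(float)
        else:
            out["pre_frail"] = float(int(fs) == FrailtyCategory.PRE_FRAIL)
            out["frail"] = float(int(fs) == FrailtyCategory.FRAIL)
    return out


def linear_predictor(eq: RiskEquation, state: Mapping) -> float:
    """Intercept plus the dot product of coefficients with covariate values."""
    full = derive_covariates(state)
    lp = eq.intercept
    for cov in eq.covariates:
        if cov not in full:
            raise InvalidInputError(f"{eq.event}: state missing covariate {cov!r}")
        lp += eq.coefficients[cov] * float(full[cov])
    return lp


def cycle_probability(lp: float) -> float:
    """Logistic link: per-cycle probability 1 / (1 + exp(-lp))."""
    return float(expit(lp))


def event_probabilities(eq: RiskEquation, state: Mapping, log_hazard_shift: float = 0.0):
    """Vectorised per-cycle probabilities for a column-mapping of arrays.

    ``log_hazard_shift`` adds a scenario log-multiplier to the linear predictor.
    """
    full = derive_covariates(state)
    lp = None
    for cov in eq.covariates:
        if cov not in full:
            raise InvalidInputError(f"{eq.event}: state missing covariate {cov!r}")
        term = eq.coefficients[cov] * np.asarray(full[cov], dtype=float)
        lp = term if lp is None else lp + term
    if lp is None:
        lp = 0.0
    lp = lp + eq.intercept + log_hazard_shift
    return expit(lp)


@dataclass(frozen=True)
class FrailtyTransitionModel:
    """Row-stochastic per-cycle transition matrix over the frailty categories."""

    matrix: np.ndarray

    def __init__(self, matrix) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ConfigurationError(f"transition matrix must be 3x3, got {m.shape}")
        if np.any(m < 0) or np.any(m > 1):
            raise ConfigurationError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("transition matrix rows must sum to 1")
        m = m.copy()
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    def __eq__(self, other) -> bool:
        return isinstance(other, FrailtyTransitionModel) and np.array_equal(
            self.matrix, other.matrix
        )


def frailty_transition_probs(
    current: FrailtyCategory,
    model: FrailtyTransitionModel,
    worsening_multiplier: float = 1.0,
    improvement_multiplier: float = 1.0,
) -> np.ndarray:
    """Transition distribution from ``current`` after scenario modification.

    Strictly-worse entries are scaled by ``worsening_multiplier`` and
    strictly-better entries by ``improvement_multiplier``; the stay
    probability absorbs the remaining mass so the row still sums to one.
    """
    if worsening_multiplier < 0 or improvement_multiplier < 0:
        raise ConfigurationError("transition multipliers must be non-negative")
    row = model.matrix[int(current)].copy()
    idx = np.arange(3)
    worse = idx > int(current)
    better = idx < int(current)
    row[worse] *= worsening_multiplier
    row[better] *= improvement_multiplier
    stay = 1.0 - row[worse].sum() - row[better].sum()
    if stay < -1e-12 or np.any(row < 0) or np.any(row > 1):
        raise ConfigurationError(
            "scenario modifiers drive transition probabilities outside [0, 1]"
        )
    row[int(current)] = max(stay, 0.0)
    return row


def transition_matrix_for_scenario(
    model: FrailtyTransitionModel,
    worsening_multiplier: float = 1.0,
    improvement_multiplier: float = 1.0,
) -> np.ndarray:
    """Full 3x3 matrix with the scenario modifiers applied to every row."""
    return np.stack(
        [
            frailty_transition_probs(
                FrailtyCategory(i), model, worsening_multiplier, improvement_multiplier
            )
            for i in range(3)
        ]
    )


@dataclass(frozen=True)
class RiskParams:
    """Complete parameterisation: one risk equation per event plus transitions."""

    equations: Mapping[str, RiskEquation]
    transitions: FrailtyTransitionModel

    def validate_against(self, structure: ModelStructure) -> None:
        missing = set(structure.event_names) - set(self.equations)
        if missing:
            raise ConfigurationError(f"risk equations missing for events: {sorted(missing)}")

    def to_dict(self) -> dict:
        return {
            "equations": {
                name: dict(eq.coefficients) for name, eq in self.equations.items()
            },
            "transitions": self.transitions.matrix.tolist(),
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RiskParams":
        return cls(
            equations={
                name: RiskEquation(event=name, coefficients=coeffs)
                for name, coeffs in d["equations"].items()
            },
            transitions=FrailtyTransitionModel(d["transitions"]),
        )

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "RiskParams":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def default_risk_params(structure: Optional[ModelStructure] = None) -> RiskParams:
    """Illustrative parameter set for the default structure.

    Coefficient values are plausible fixtures for testing and demos, not
    estimates from any dataset.  Death risk rises log-linearly with age.
    """
    coeffs = {
        "death": {INTERCEPT: -10.0, "age": 0.085, "pre_frail": 0.3, "frail": 0.8},
        "hip_fracture": {INTERCEPT: -6.5, "age": 0.04, "pre_frail": 0.4, "frail": 0.9,
                         "n_prev_fractures": 0.5},
        "falls": {INTERCEPT: -4.0, "age": 0.03, "pre_frail": 0.5, "frail": 1.0},
        "hospital_admission": {INTERCEPT: -5.0, "age": 0.04, "pre_frail": 0.3, "frail": 0.7,
                               "n_prev_hospital_admissions": 0.3},
        "residential_care_admission": {INTERCEPT: -9.0, "age": 0.07, "frail": 1.2},
        "physical_disability": {INTERCEPT: -7.0, "age": 0.05, "pre_frail": 0.5, "frail": 1.2},
        "delirium": {INTERCEPT: -5.5, "age": 0.03, "frail": 0.8},
    }
    if structure is not None:
        coeffs = {k: v for k, v in coeffs.items() if k in structure.event_names}
        for name in structure.event_names:
            coeffs.setdefault(name, {INTERCEPT: -5.0})
    equations = {name: RiskEquation(event=name, coefficients=c) for name, c in coeffs.items()}
    transitions = FrailtyTransitionModel(
        [[0.85, 0.12, 0.03],
         [0.06, 0.74, 0.20],
         [0.00, 0.05, 0.95]]
    )
    return RiskParams(equations=equations, transitions=transitions)


@dataclass(frozen=True)
class RiskFit:
    """Maximum-likelihood fit of one risk equation."""

    event: str
    params: Mapping[str, float]
    bse: Mapping[str, float]
    llf: float
    converged: bool
    nobs: int

    def to_equation(self) -> RiskEquation:
        return RiskEquation(event=self.event, coefficients=dict(self.params))


def fit_risk_equation(
    panel: pd.DataFrame,
    covariates: Sequence[str],
    event: str,
    death_event: str = "death",
) -> RiskFit:
    """Fit the logistic risk equation for ``event`` from a longitudinal panel.

    One row per individual-wave with start-of-wave covariates and event
    indicators.  Non-fatal events are defined conditional on surviving the
    wave, so rows where death occurred are dropped for those fits; the death
    equation itself uses every at-risk row.
    """
    import statsmodels.api as sm

    df = panel
    if event != death_event and death_event in df.columns:
        df = df[df[death_event] == 0]
    df = pd.DataFrame(derive_covariates(df))

    if event not in df.columns:
        raise InvalidInputError(f"panel has no outcome column {event!r}")
    y = df[event].to_numpy(dtype=float)
    if len(y) == 0 or y.min() == y.max():
        raise EstimationError(f"{event}: outcome is constant; cannot fit")
    for cov in covariates:
        if cov not in df.columns:
            raise InvalidInputError(f"panel missing covariate {cov!r}")
    X = df[list(covariates)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), X])

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise EstimationError(f"{event}: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 50:
        raise EstimationError(f"{event}: degenerate estimates suggest separation")

    names = [INTERCEPT, *covariates]
    return RiskFit(
        event=event,
        params=dict(zip(names, (float(v) for v in res.params))),
        bse=dict(zip(names, (float(v) for v in res.bse))),
        llf=float(res.llf),
        converged=bool(res.mle_retvals.get("converged", True)),
        nobs=int(res.nobs),
    )
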
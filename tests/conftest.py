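import numpy as np
import pandas as pd
import pytest

import frailsim as fs
from frailsim import risks as rk
from frailsim.structure import (
    EventKind,
    HealthEvent,
    ModelStructure,
    PatientAttribute,
    ValueType,
)


@pytest.fixture(scope="session")
def structure():
    return fs.default_structure()


@pytest.fixture(scope="session")
def params(structure):
    return fs.default_risk_params(structure)


@pytest.fixture(scope="session")
def small_cohort():
    return fs.generate_cohort(fs.synth.default_cohort_spec(n=300, seed=42))


@pytest.fixture(scope="session")
def mini_structure():
    """Three-event structure for fast estimation/validation loops."""
    events = [
        HealthEvent("death", EventKind.ABSORBING),
        HealthEvent("hip_fracture", history_counter="n_prev_fractures"),
        HealthEvent("falls"),
    ]
    attributes = [
        PatientAttribute("age", ValueType.CONTINUOUS, time_varying=True),
        PatientAttribute("frailty_status", ValueType.CATEGORICAL, time_varying=True),
        PatientAttribute("n_prev_fractures", ValueType.COUNT, time_varying=True),
    ]
    edges = [
        ("age", "death"), ("frailty_status", "death"),
        ("age", "hip_fracture"), ("n_prev_fractures", "hip_fracture"),
        ("age", "falls"), ("frailty_status", "falls"),
    ]
    return ModelStructure(events, attributes, edges)


@pytest.fixture(scope="session")
def mini_truth(mini_structure):
    return rk.RiskParams(
        equations={
            "death": rk.RiskEquation(
                "death", {"intercept": -8.0, "age": 0.07, "pre_frail": 0.3, "frail": 0.8}
            ),
            "hip_fracture": rk.RiskEquation(
                "hip_fracture",
                {"intercept": -4.5, "age": 0.02, "frail": 0.8, "n_prev_fractures": 0.5},
            ),
            "falls": rk.RiskEquation(
                "falls", {"intercept": -2.5, "age": 0.01, "pre_frail": 0.4, "frail": 0.9}
            ),
        },
        transitions=rk.FrailtyTransitionModel(
            [[0.85, 0.12, 0.03], [0.06, 0.74, 0.20], [0.00, 0.05, 0.95]]
        ),
    )


def mini_cohort_spec(n: int, seed: int) -> fs.CohortSpec:
    return fs.CohortSpec(
        n=n,
        marginals={
            "age": fs.MarginalSpec("uniform", {"low": 65.0, "high": 90.0}),
            "frailty_status": fs.MarginalSpec("categorical", {"probs": [0.5, 0.3, 0.2]}),
            "n_prev_fractures": fs.MarginalSpec("poisson", {"lam": 0.2}),
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def mini_cohort():
    return fs.generate_cohort(mini_cohort_spec(n=20_000, seed=7))
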
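"""Model structure: accepted health events, patient attributes, dependency edges.

The structure is the consensus outcome of the expert classification process
and is the single source of truth for the simulation state space.  It
serialises to a JSON config consumed by the synthesis, estimation and
simulation modules.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .delphi import ChoiceClassification, ChoiceKind, Decision
from .errors import InvalidInputError

__all__ = [
    "EventKind",
    "Finding",
    "HealthEvent",
    "ModelStructure",
    "PatientAttribute",
    "ValueType",
    "build_from_classifications",
    "default_structure",
    "validate_structure",
]

logger = logging.getLogger(__name__)

DEATH = "death"


class EventKind(str, enum.Enum):
    RECURRENT = "recurrent"
    ABSORBING = "absorbing"


class ValueType(str, enum.Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"
    COUNT = "count"
    CATEGORICAL = "categorical"


@dataclass(frozen=True)
class HealthEvent:
    name: str
    kind: EventKind = EventKind.RECURRENT
    # attribute incremented by one each time the event occurs
    history_counter: Optional[str] = None
    # once the event occurs the individual stays in that state (short of death)
    persistent: bool = False


@dataclass(frozen=True)
class PatientAttribute:
    name: str
    value_type: ValueType = ValueType.BINARY
    time_varying: bool = False


Edge = tuple  # (attribute_name, event_name)


@dataclass(frozen=True)
class ModelStructure:
    events: tuple
    attributes: tuple
    edges: frozenset

    def __init__(
        self,
        events: Iterable[HealthEvent],
        attributes: Iterable[PatientAttribute],
        edges: Iterable[Edge] = (),
    ) -> None:
        ev = tuple(sorted(events, key=lambda e: e.name))
        at = tuple(sorted(attributes, key=lambda a: a.name))
        names = [e.name for e in ev]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate event names")
        anames = [a.name for a in at]
        if len(set(anames)) != len(anames):
            raise InvalidInputError("duplicate attribute names")
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "attributes", at)
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in edges))

    # -- lookups ----------------------------------------------------------
    @property
    def event_names(self) -> list[str]:
        return [e.name for e in self.events]

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def event(self, name: str) -> HealthEvent:
        for e in self.events:
            if e.name == name:
                return e
        raise KeyError(name)

    def attribute(self, name: str) -> PatientAttribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def death_event(self) -> Optional[HealthEvent]:
        for e in self.events:
            if e.kind is EventKind.ABSORBING:
                return e
        return None

    @property
    def nonfatal_events(self) -> list[HealthEvent]:
        return [e for e in self.events if e.kind is not EventKind.ABSORBING]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "name": e.name,
                    "kind": e.kind.value,
                    "history_counter": e.history_counter,
                    "persistent": e.persistent,
                }
                for e in self.events
            ],
            "attributes": [
                {
                    "name": a.name,
                    "value_type": a.value_type.value,
                    "time_varying": a.time_varying,
                }
                for a in self.attributes
            ],
            "edges": sorted([list(e) for e in self.edges]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelStructure":
        return cls(
            events=[
                HealthEvent(
                    name=e["name"],
                    kind=EventKind(e["kind"]),
                    history_counter=e.get("history_counter"),
                    persistent=e.get("persistent", False),
                )
                for e in d["events"]
            ],
            attributes=[
                PatientAttribute(
                    name=a["name"],
                    value_type=ValueType(a["value_type"]),
                    time_varying=a.get("time_varying", False),
                )
                for a in d["attributes"]
            ],
            edges=[tuple(e) for e in d.get("edges", [])],
        )

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "ModelStructure":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


# Registry of known items so structures built from classification outcomes
# carry the same metadata as the shipped default.
KNOWN_EVENTS: dict = {
    "hip_fracture": dict(kind=EventKind.RECURRENT, history_counter="n_prev_fractures"),
    "falls": dict(kind=EventKind.RECURRENT),
    "residential_care_admission": dict(kind=EventKind.RECURRENT, persistent=True),
    "hospital_admission": dict(
        kind=EventKind.RECURRENT, history_counter="n_prev_hospital_admissions"
    ),
    "physical_disability": dict(kind=EventKind.RECURRENT, persistent=True),
    "delirium": dict(kind=EventKind.RECURRENT),
    DEATH: dict(kind=EventKind.ABSORBING),
}

KNOWN_ATTRIBUTES: dict = {
    "age": dict(value_type=ValueType.CONTINUOUS, time_varying=True),
    "gender": dict(value_type=ValueType.BINARY),
    "education": dict(value_type=ValueType.CATEGORICAL),
    "frailty_status": dict(value_type=ValueType.CATEGORICAL, time_varying=True),
    "n_prev_hospital_admissions": dict(value_type=ValueType.COUNT, time_varying=True),
    "n_prev_fractures": dict(value_type=ValueType.COUNT, time_varying=True),
    "polypharmacy": dict(value_type=ValueType.BINARY),
    "stroke": dict(value_type=ValueType.BINARY),
    "diabetes": dict(value_type=ValueType.BINARY),
    "physical_activity": dict(value_type=ValueType.CATEGORICAL),
    "depression": dict(value_type=ValueType.BINARY, time_varying=True),
}


def _default_edges(event_names: Sequence[str], attribute_names: Sequence[str]) -> list[Edge]:
    """Baseline dependency wiring: demographics and frailty drive every event;
    history counters feed back into their own event."""
    edges: list[Edge] = []
    core = [a for a in ("age", "gender", "frailty_status") if a in attribute_names]
    for ev in event_names:
        for a in core:
            edges.append((a, ev))
    counter_edges = {
        "n_prev_fractures": "hip_fracture",
        "n_prev_hospital_admissions": "hospital_admission",
    }
    for attr, ev in counter_edges.items():
        if attr in attribute_names and ev in event_names:
            edges.append((attr, ev))
    return edges


def default_structure() -> ModelStructure:
    """The consensus structure: seven health events and eleven attributes."""
    events = [HealthEvent(name=n, **kw) for n, kw in KNOWN_EVENTS.items()]
    attributes = [PatientAttribute(name=n, **kw) for n, kw in KNOWN_ATTRIBUTES.items()]
    edges = _default_edges([e.name for e in events], [a.name for a in attributes])
    return ModelStructure(events=events, attributes=attributes, edges=edges)


def build_from_classifications(
    classifications: Sequence[ChoiceClassification],
) -> ModelStructure:
    """Assemble a structure from finalised classification outcomes.

    Items whose final decision is *included* enter the structure; a death
    event is appended (with a warning) if the classification outcomes did
    not include one.
    """
    event_names: list[str] = []
    attribute_names: list[str] = []
    for c in classifications:
        if c.final_decision is not Decision.INCLUDED:
            continue
        target = event_names if c.choice_kind is ChoiceKind.HEALTH_EVENT else attribute_names
        if c.choice_name in target:
            raise InvalidInputError(f"duplicate classification for {c.choice_name}")
        target.append(c.choice_name)

    if DEATH not in event_names:
        logger.warning("classifications lack an absorbing death event; adding %r", DEATH)
        event_names.append(DEATH)

    events = []
    for n in event_names:
        kw = dict(KNOWN_EVENTS.get(n, {}))
        counter = kw.get("history_counter")
        if counter is not None and n != DEATH and counter not in attribute_names:
            kw["history_counter"] = None  # counter attribute not part of this structure
        events.append(HealthEvent(name=n, **kw))
    attributes = [
        PatientAttribute(name=n, **KNOWN_ATTRIBUTES.get(n, {})) for n in attribute_names
    ]
    edges = _default_edges(event_names, attribute_names)
    return ModelStructure(events=events, attributes=attributes, edges=edges)


@dataclass(frozen=True)
class Finding:
    code: str
    message: str


def validate_structure(structure: ModelStructure) -> list[Finding]:
    """Diagnostic checks; returns findings instead of raising."""
    findings: list[Finding] = []
    absorbing = [e for e in structure.events if e.kind is EventKind.ABSORBING]
    if not absorbing:
        findings.append(Finding("no_absorbing_state", "no absorbing (death) event present"))
    elif len(absorbing) > 1:
        findings.append(
            Finding("multiple_absorbing_states",
                    f"expected one absorbing event, found {len(absorbing)}")
        )
    attr_names = set(structure.attribute_names)
    event_names = set(structure.event_names)
    events_with_edge = {ev for (_, ev) in structure.edges}
    for e in structure.events:
        if e.name not in events_with_edge:
            findings.append(Finding("orphan_event", f"event {e.name!r} has no predictors"))
        if e.history_counter is not None and e.history_counter not in attr_names:
            findings.append(
                Finding("missing_counter",
                        f"event {e.name!r} references unknown counter {e.history_counter!r}")
            )
    for (a, ev) in sorted(structure.edges):
        if a not in attr_names or ev not in event_names:
            findings.append(Finding("dangling_edge", f"edge ({a!r} -> {ev!r}) has unknown endpoint"))
    return findings
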
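"""Multi-round expert-panel (Delphi) consensus classification.

Candidate health states/events and patient attributes are scored by a panel
on 1-5 Likert scales.  Scores are summarised per aspect, banded into
acceptable / moderate / unacceptable agreement, and mapped to an
include / feed-back / reject decision.  Items fed back receive a final
round of scoring after which they are either included or rejected.

Agreement bands (defaults, configurable via :class:`AgreementThresholds`):

* acceptable — mean score >= 4 and at least 80% of panellists scoring 4-5;
* moderate   — mean score >= 3 and at least 60% scoring >= 4, evaluated only
  when the acceptable test fails;
* unacceptable — everything else.

The acceptable band is always tested first, so the bands are exhaustive and
mutually exclusive even though the raw mean intervals overlap at 4.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import InvalidInputError, StateError

__all__ = [
    "AgreementLevel",
    "AgreementThresholds",
    "AspectSummary",
    "ChoiceClassification",
    "ChoiceKind",
    "Decision",
    "DEFAULT_THRESHOLDS",
    "apply_round3",
    "classify_aspect",
    "classify_attribute",
    "classify_health_event",
    "classify_responses",
    "classifications_to_frame",
    "summarize_scores",
]

DEFAULT_PANEL_SIZE = 9


class AgreementLevel(str, enum.Enum):
    ACCEPTABLE = "acceptable"
    MODERATE = "moderate"
    UNACCEPTABLE = "unacceptable"


class Decision(str, enum.Enum):
    INCLUDED = "included"
    ROUND3 = "round3"
    REJECTED = "rejected"


class ChoiceKind(str, enum.Enum):
    HEALTH_EVENT = "health_event"
    PATIENT_ATTRIBUTE = "patient_attribute"


@dataclass(frozen=True)
class AspectSummary:
    """Panel summary for one aspect of one candidate item."""

    mean_score: float
    frac_high: float  # fraction of panellists scoring 4 or 5
    n: int


@dataclass(frozen=True)
class AgreementThresholds:
    acceptable_mean: float = 4.0
    acceptable_frac: float = 0.8
    moderate_mean: float = 3.0
    moderate_frac: float = 0.6


DEFAULT_THRESHOLDS = AgreementThresholds()


@dataclass(frozen=True)
class ChoiceClassification:
    """Outcome of the classification for one candidate structural choice."""

    choice_name: str
    choice_kind: ChoiceKind
    strength_level: AgreementLevel
    impact_level: Optional[AgreementLevel]  # health events only
    decision: Decision
    round3_final: Optional[Decision] = None

    def __post_init__(self) -> None:
        if self.choice_kind is ChoiceKind.HEALTH_EVENT and self.impact_level is None:
            raise InvalidInputError(
                f"{self.choice_name}: health events require an impact level"
            )
        if self.choice_kind is ChoiceKind.PATIENT_ATTRIBUTE and self.impact_level is not None:
            raise InvalidInputError(
                f"{self.choice_name}: patient attributes carry no impact level"
            )
        if self.round3_final is not None and self.decision is not Decision.ROUND3:
            raise InvalidInputError(
                f"{self.choice_name}: round3_final only applies to fed-back items"
            )

    @property
    def final_decision(self) -> Decision:
        """Decision after all rounds; round-3 items must have been resolved."""
        if self.decision is Decision.ROUND3:
            if self.round3_final is None:
                raise StateError(f"{self.choice_name}: round-3 outcome pending")
            return self.round3_final
        return self.decision


def summarize_scores(scores: Sequence[int]) -> AspectSummary:
    """Summarise a vector of 1-5 Likert scores into mean and high-score fraction."""
    if len(scores) == 0:
        raise InvalidInputError("empty score vector")
    for s in scores:
        if int(s) != s or not 1 <= s <= 5:
            raise InvalidInputError(f"score {s!r} outside Likert range 1-5")
    n = len(scores)
    high = sum(1 for s in scores if s >= 4)
    return AspectSummary(mean_score=sum(scores) / n, frac_high=high / n, n=n)


def classify_aspect(
    summary: AspectSummary,
    thresholds: AgreementThresholds = DEFAULT_THRESHOLDS,
) -> AgreementLevel:
    """Band an aspect summary; the acceptable test is always evaluated first."""
    if summary.mean_score >= thresholds.acceptable_mean and summary.frac_high >= thresholds.acceptable_frac:
        return AgreementLevel.ACCEPTABLE
    if summary.mean_score >= thresholds.moderate_mean and summary.frac_high >= thresholds.moderate_frac:
        return AgreementLevel.MODERATE
    return AgreementLevel.UNACCEPTABLE


def classify_scores(
    scores: Sequence[int],
    thresholds: AgreementThresholds = DEFAULT_THRESHOLDS,
) -> AgreementLevel:
    return classify_aspect(summarize_scores(scores), thresholds)


def classify_health_event(strength: AgreementLevel, impact: AgreementLevel) -> Decision:
    """Decision for a health event given agreement on both aspects.

    Both acceptable -> included; any unacceptable -> rejected; remaining
    combinations (moderate with moderate or acceptable) are fed back.
    """
    if strength is None or impact is None:
        raise InvalidInputError("both strength and impact levels are required")
    levels = {strength, impact}
    if AgreementLevel.UNACCEPTABLE in levels:
        return Decision.REJECTED
    if levels == {AgreementLevel.ACCEPTABLE}:
        return Decision.INCLUDED
    return Decision.ROUND3


def classify_attribute(level: AgreementLevel) -> Decision:
    if level is AgreementLevel.ACCEPTABLE:
        return Decision.INCLUDED
    if level is AgreementLevel.MODERATE:
        return Decision.ROUND3
    return Decision.REJECTED


def apply_round3(
    prior: ChoiceClassification,
    strength_scores: Sequence[int],
    impact_scores: Optional[Sequence[int]] = None,
    thresholds: AgreementThresholds = DEFAULT_THRESHOLDS,
) -> ChoiceClassification:
    """Resolve a fed-back item with the final-round scores.

    The updated scores are re-summarised and re-banded; the item is included
    only if the result is fully acceptable (both aspects for a health event),
    otherwise rejected.
    """
    if prior.decision is not Decision.ROUND3:
        raise StateError(f"{prior.choice_name} was not fed back to round 3")
    strength = classify_scores(strength_scores, thresholds)
    if prior.choice_kind is ChoiceKind.HEALTH_EVENT:
        if impact_scores is None:
            raise InvalidInputError("health events require updated impact scores")
        impact = classify_scores(impact_scores, thresholds)
        final = (
            Decision.INCLUDED
            if classify_health_event(strength, impact) is Decision.INCLUDED
            else Decision.REJECTED
        )
        return replace(prior, strength_level=strength, impact_level=impact, round3_final=final)
    final = (
        Decision.INCLUDED if strength is AgreementLevel.ACCEPTABLE else Decision.REJECTED
    )
    return replace(prior, strength_level=strength, round3_final=final)


# --- tabular interface -----------------------------------------------------

RESPONSE_COLUMNS = ("choice_name", "choice_kind", "aspect", "panellist_id", "round", "score")


def _aspect_scores(group: pd.DataFrame, aspect: str, rounds: Iterable[int]) -> Optional[list]:
    sub = group[(group["aspect"] == aspect) & (group["round"].isin(list(rounds)))]
    if sub.empty:
        return None
    return sub["score"].astype(int).tolist()


def classify_responses(
    responses: pd.DataFrame,
    thresholds: AgreementThresholds = DEFAULT_THRESHOLDS,
) -> list[ChoiceClassification]:
    """Classify a long table of panel responses.

    Expected columns: choice_name, choice_kind, aspect (strength|impact),
    panellist_id, round, score.  Rounds 1-2 drive the initial banding;
    round-3 rows, when present, resolve fed-back items.
    """
    missing = set(RESPONSE_COLUMNS) - set(responses.columns)
    if missing:
        raise InvalidInputError(f"response table missing columns: {sorted(missing)}")

    out: list[ChoiceClassification] = []
    for (name, kind_str), group in responses.groupby(["choice_name", "choice_kind"], sort=True):
        kind = ChoiceKind(kind_str)
        strength_scores = _aspect_scores(group, "strength", (1, 2))
        if strength_scores is None:
            raise InvalidInputError(f"{name}: no strength scores in rounds 1-2")
        strength = classify_scores(strength_scores, thresholds)
        if kind is ChoiceKind.HEALTH_EVENT:
            impact_scores = _aspect_scores(group, "impact", (1, 2))
            if impact_scores is None:
                raise InvalidInputError(f"{name}: no impact scores in rounds 1-2")
            impact = classify_scores(impact_scores, thresholds)
            item = ChoiceClassification(
                choice_name=name,
                choice_kind=kind,
                strength_level=strength,
                impact_level=impact,
                decision=classify_health_event(strength, impact),
            )
        else:
            item = ChoiceClassification(
                choice_name=name,
                choice_kind=kind,
                strength_level=strength,
                impact_level=None,
                decision=classify_attribute(strength),
            )
        if item.decision is Decision.ROUND3:
            r3_strength = _aspect_scores(group, "strength", (3,))
            if r3_strength is not None:
                r3_impact = (
                    _aspect_scores(group, "impact", (3,))
                    if kind is ChoiceKind.HEALTH_EVENT
                    else None
                )
                item = apply_round3(item, r3_strength, r3_impact, thresholds)
        out.append(item)
    return out


def classifications_to_frame(classifications: Iterable[ChoiceClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append(
            {
                "choice_name": c.choice_name,
                "choice_kind": c.choice_kind.value,
                "strength_level": c.strength_level.value,
                "impact_level": c.impact_level.value if c.impact_level else "",
                "decision": c.decision.value,
                "round3_final": c.round3_final.value if c.round3_final else "",
            }
        )
    return pd.DataFrame(rows, columns=[
        "choice_name", "choice_kind", "strength_level", "impact_level",
        "decision", "round3_final",
    ])
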
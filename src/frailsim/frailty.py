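"""Frailty measurement: deficit-accumulation index and the five-criterion phenotype."""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "DeficitProfile",
    "FrailtyCategory",
    "PhenotypeProfile",
    "fi_to_category",
    "frailty_index",
    "phenotype_category",
]


class FrailtyCategory(enum.IntEnum):
    """Ordered frailty categories; the integer code is the severity rank."""

    NON_FRAIL = 0
    PRE_FRAIL = 1
    FRAIL = 2

    @property
    def label(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class DeficitProfile:
    deficits_present: int
    deficits_total: int

    def __post_init__(self) -> None:
        if self.deficits_total <= 0:
            raise InvalidInputError("deficits_total must be positive")
        if not 0 <= self.deficits_present <= self.deficits_total:
            raise InvalidInputError(
                f"deficits_present must lie in [0, {self.deficits_total}]"
            )


@dataclass(frozen=True)
class PhenotypeProfile:
    """The five physical-frailty indicators."""

    weight_loss: bool = False
    exhaustion: bool = False
    weak_grip: bool = False
    slow_walk: bool = False
    sedentary: bool = False

    @property
    def criteria_count(self) -> int:
        return sum(
            (self.weight_loss, self.exhaustion, self.weak_grip, self.slow_walk, self.sedentary)
        )


def frailty_index(profile: DeficitProfile) -> float:
    """Proportion of measured deficits present, in [0, 1]."""
    return profile.deficits_present / profile.deficits_total


def phenotype_category(profile: PhenotypeProfile) -> FrailtyCategory:
    """Frail with >= 3 criteria, pre-frail with 1-2, otherwise non-frail."""
    k = profile.criteria_count
    if k >= 3:
        return FrailtyCategory.FRAIL
    if k >= 1:
        return FrailtyCategory.PRE_FRAIL
    return FrailtyCategory.NON_FRAIL


def fi_to_category(fi: float, cutpoints: Tuple[float, float]) -> FrailtyCategory:
    """Map a frailty-index score to a category using half-open bands.

    ``fi < c1`` -> non-frail, ``c1 <= fi < c2`` -> pre-frail, ``fi >= c2`` -> frail.
    There is no baked-in default for the cutpoints; callers must configure them.
    """
    if cutpoints is None:
        raise ConfigurationError("frailty-index cutpoints must be configured")
    c1, c2 = cutpoints
    if not 0 < c1 < c2 < 1:
        raise ConfigurationError(f"cutpoints must satisfy 0 < c1 < c2 < 1, got {cutpoints}")
    if not 0 <= fi <= 1:
        raise InvalidInputError(f"frailty index {fi} outside [0, 1]")
    if fi < c1:
        return FrailtyCategory.NON_FRAIL
    if fi < c2:
        return FrailtyCategory.PRE_FRAIL
    return FrailtyCategory.FRAIL
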
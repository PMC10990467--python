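"""Instrument scoring: CES-D, PSQI and the exposure Likert item.

CES-D: 20 items scored 0-3, four reverse-keyed items, caseness at total >= 16.
PSQI: 7 component scores 0-3 summed to a global 0-21, poor sleep at >= 6.
Exposure: five-point frequency scale dichotomized at "never" vs anything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

CESD_N_ITEMS = 20
CESD_ITEM_MAX = 3
#: Standard reverse-keyed CES-D item positions (1-based: items 4, 8, 12, 16).
CESD_REVERSE_ITEMS_1BASED = frozenset({4, 8, 12, 16})
CESD_CUTOFF = 16

PSQI_N_COMPONENTS = 7
PSQI_COMPONENT_MAX = 3
PSQI_CUTOFF = 6

LIKERT_LEVELS = {
    1: "never",
    2: "once or less in a month",
    3: "a few times a month",
    4: "one to few times a week",
    5: "mostly every day",
}


class ScoringError(ValueError):
    """Raised for out-of-range or malformed instrument responses."""


@dataclass(frozen=True)
class InstrumentScore:
    total: int
    case: bool


def score_cesd(
    items: Sequence[int],
    reverse_items_1based: frozenset[int] = CESD_REVERSE_ITEMS_1BASED,
    cutoff: int = CESD_CUTOFF,
) -> InstrumentScore:
    """Total CES-D score (reverse items mapped v -> 3 - v) and caseness."""
    if len(items) != CESD_N_ITEMS:
        raise ScoringError(f"CES-D needs {CESD_N_ITEMS} items, got {len(items)}")
    total = 0
    for i, value in enumerate(items, start=1):
        if not (0 <= value <= CESD_ITEM_MAX):
            raise ScoringError(f"CES-D item {i} out of range 0..{CESD_ITEM_MAX}: {value}")
        total += CESD_ITEM_MAX - value if i in reverse_items_1based else value
    return InstrumentScore(total=total, case=total >= cutoff)


def score_psqi(components: Sequence[int], cutoff: int = PSQI_CUTOFF) -> InstrumentScore:
    """PSQI global score (sum of 7 components) and poor-sleep caseness."""
    if len(components) != PSQI_N_COMPONENTS:
        raise ScoringError(f"PSQI needs {PSQI_N_COMPONENTS} components, got {len(components)}")
    for i, value in enumerate(components, start=1):
        if not (0 <= value <= PSQI_COMPONENT_MAX):
            raise ScoringError(f"PSQI component {i} out of range 0..{PSQI_COMPONENT_MAX}: {value}")
    total = sum(components)
    return InstrumentScore(total=total, case=total >= cutoff)


def caseness(total: int | float, cutoff: int) -> bool:
    """Threshold rule shared by both instruments: case iff total >= cutoff."""
    return total >= cutoff


def dichotomize_exposure(likert: int) -> bool:
    """False iff the frequency response is "never" (level 1); True otherwise."""
    if likert not in LIKERT_LEVELS:
        raise ScoringError(f"exposure Likert value out of range 1..5: {likert}")
    return likert != 1
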
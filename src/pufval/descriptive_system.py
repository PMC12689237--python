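"""The EQ-5D-5L descriptive system: five dimensions, five severity levels.

A health state is a 5-digit code, one digit per dimension in the canonical
order mobility (MO), self-care (SC), usual activities (UA), pain/discomfort
(PD), anxiety/depression (AD). Level 1 is "no problems", level 5 "extreme
problems"; ``"11111"`` is full health and ``"55555"`` the worst ("pits")
state. There are 5**5 = 3125 states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache


class Dimension(str, Enum):
    """One of the five EQ-5D-5L dimensions, in canonical order."""

    MO = "MO"
    SC = "SC"
    UA = "UA"
    PD = "PD"
    AD = "AD"

    @property
    def label(self) -> str:
        return _LABELS[self]


#: Canonical storage/output order; all arrays and I/O headers follow it.
DIMENSIONS: tuple[Dimension, ...] = tuple(Dimension)

_DIM_INDEX = {d: i for i, d in enumerate(DIMENSIONS)}

_LABELS = {
    Dimension.MO: "mobility",
    Dimension.SC: "self-care",
    Dimension.UA: "usual activities",
    Dimension.PD: "pain/discomfort",
    Dimension.AD: "anxiety/depression",
}

#: Severity levels of the instrument, 1-based.
LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

N_STATES = 5 ** 5


class StateCodeError(ValueError):
    """Raised for a malformed 5-digit health-state code."""


@dataclass(frozen=True, order=True)
class HealthState:
    """An EQ-5D-5L health state; ``levels`` holds one severity per dimension
    in canonical order."""

    levels: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 5:
            raise StateCodeError(
                f"expected 5 levels, got {len(self.levels)}"
            )
        for i, lev in enumerate(self.levels):
            if not (isinstance(lev, int) and 1 <= lev <= 5):
                raise StateCodeError(
                    f"level at position {i + 1} ({DIMENSIONS[i].value}) must "
                    f"be an integer in 1..5, got {lev!r}"
                )

    @property
    def code(self) -> str:
        """5-character digit string, canonical dimension order."""
        return "".join(str(lev) for lev in self.levels)

    def level(self, dim: Dimension) -> int:
        return self.levels[_DIM_INDEX[dim]]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


FULL_HEALTH = HealthState((1, 1, 1, 1, 1))
PITS = HealthState((5, 5, 5, 5, 5))


def parse_state(code: str) -> HealthState:
    """Parse a 5-character digit string into a :class:`HealthState`.

    Raises :class:`StateCodeError` naming the offending position for codes
    of the wrong length or containing characters outside '1'..'5'.
    """
    if not isinstance(code, str):
        raise StateCodeError(f"state code must be text, got {type(code).__name__}")
    if len(code) != 5:
        raise StateCodeError(
            f"state code must have exactly 5 characters, got {len(code)} ({code!r})"
        )
    levels = []
    for i, ch in enumerate(code):
        if ch not in "12345":
            raise StateCodeError(
                f"state code {code!r}: character {ch!r} at position {i + 1} "
                f"({DIMENSIONS[i].value}) is not a digit in 1..5"
            )
        levels.append(int(ch))
    return HealthState(tuple(levels))


@lru_cache(maxsize=1)
def _all_states() -> tuple[HealthState, ...]:
    return tuple(
        HealthState(combo) for combo in itertools.product(LEVELS, repeat=5)
    )


def enumerate_states() -> list[HealthState]:
    """All 3125 states in lexicographic code order ("11111" first)."""
    return list(_all_states())
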
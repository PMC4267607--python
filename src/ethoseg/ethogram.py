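"""The behavioural class vocabulary (ethogram).

Eight classes form a closed set: attack, body_care, fly, handle, inactive,
peck, search, walk. They cover a shorebird foraging repertoire — dominant
inactive/walk states, intermediate search/handle/body_care, and rare brief
attack/fly/peck events.
"""

from __future__ import annotations

import enum


class Behavior(str, enum.Enum):
    """One of the eight behavioural classes. Values are the CSV spellings."""

    ATTACK = "attack"
    BODY_CARE = "body_care"
    FLY = "fly"
    HANDLE = "handle"
    INACTIVE = "inactive"
    PECK = "peck"
    SEARCH = "search"
    WALK = "walk"

    def __str__(self) -> str:  # so f"{b}" gives the CSV spelling
        return self.value


#: Canonical ordering used for tables and reports.
BEHAVIORS: tuple[str, ...] = tuple(b.value for b in Behavior)


def validate_behavior(name: str) -> str:
    """Return ``name`` if it is a known behaviour, else raise ValueError."""
    if name not in _BEHAVIOR_SET:
        raise ValueError(
            f"unknown behaviour {name!r}; valid classes: {', '.join(BEHAVIORS)}"
        )
    return name


_BEHAVIOR_SET = frozenset(BEHAVIORS)
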
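"""ASCOT SCT4 domains and states.

The ASCOT SCT4 instrument describes social care-related quality of life
(SCRQoL) on eight domains, each at one of four levels (1 = the ideal state,
4 = high-level needs).  A *state* is one combination of levels across the
eight domains and is written as an 8-digit string in questionnaire order,
e.g. ``"24313222"``.

Two orderings coexist and are both carried on :class:`AscotDomain`:

* ``p_index`` — the coding-scheme index used in the utility model
  (1 accommodation, 2 safety, 3 food, 4 cleanliness, 5 control,
  6 participation, 7 dignity, 8 occupation); control is the reference
  domain.
* ``position`` — the position of the domain's digit in the state string
  (control first, then personal cleanliness, food, safety, participation,
  occupation, accommodation, dignity).

The instrument's questionnaire has a ninth item (a first dignity item about
needing care at all); it is not part of the scoring and has no domain here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "AscotDomain",
    "AscotState",
    "DOMAINS",
    "DOMAIN_BY_NAME",
    "DOMAINS_IN_POSITION_ORDER",
    "N_LEVELS",
    "parse_state",
    "enumerate_states",
    "state_level_matrix",
]

N_LEVELS = 4


@dataclass(frozen=True)
class AscotDomain:
    """One ASCOT scoring domain."""

    p_index: int  # model-coding index, 1..8 (control = 5, the reference)
    name: str  # short canonical key
    label: str  # full instrument wording
    position: int  # digit position in the 8-character state string, 1..8


DOMAINS: tuple[AscotDomain, ...] = (
    AscotDomain(1, "accommodation", "Accommodation cleanliness and comfort", 7),
    AscotDomain(2, "safety", "Personal safety", 4),
    AscotDomain(3, "food", "Food and drink", 3),
    AscotDomain(4, "cleanliness", "Personal cleanliness and comfort", 2),
    AscotDomain(5, "control", "Control over daily life", 1),
    AscotDomain(6, "participation", "Social participation and involvement", 5),
    AscotDomain(7, "dignity", "Dignity", 8),
    AscotDomain(8, "occupation", "Occupation", 6),
)

DOMAIN_BY_NAME: dict[str, AscotDomain] = {d.name: d for d in DOMAINS}
DOMAINS_IN_POSITION_ORDER: tuple[AscotDomain, ...] = tuple(
    sorted(DOMAINS, key=lambda d: d.position)
)

# internal consistency of the two orderings
assert sorted(d.p_index for d in DOMAINS) == list(range(1, 9))
assert sorted(d.position for d in DOMAINS) == list(range(1, 9))
assert DOMAIN_BY_NAME["control"].p_index == 5
assert DOMAIN_BY_NAME["control"].position == 1


@dataclass(frozen=True)
class AscotState:
    """One SCRQoL state: a level in {1,2,3,4} for each of the 8 domains.

    ``levels_by_position`` stores levels in state-string (questionnaire)
    order so that ``str(state)`` round-trips with :func:`parse_state`.
    """

    levels_by_position: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels_by_position) != 8:
            raise ValueError(
                f"an ASCOT state needs 8 levels, got {len(self.levels_by_position)}"
            )
        for pos, level in enumerate(self.levels_by_position, start=1):
            if level not in (1, 2, 3, 4):
                raise ValueError(
                    f"level at position {pos} is {level!r}; must be in 1..4"
                )

    @classmethod
    def from_levels(cls, levels: Mapping[str, int]) -> "AscotState":
        """Build a state from a domain-name -> level mapping."""
        missing = set(DOMAIN_BY_NAME) - set(levels)
        if missing:
            raise ValueError(f"missing domains: {sorted(missing)}")
        return cls(tuple(levels[d.name] for d in DOMAINS_IN_POSITION_ORDER))

    @property
    def levels(self) -> dict[str, int]:
        """Domain-name -> level mapping."""
        return {
            d.name: self.levels_by_position[d.position - 1]
            for d in DOMAINS
        }

    def level(self, domain: str | AscotDomain) -> int:
        dom = DOMAIN_BY_NAME[domain] if isinstance(domain, str) else domain
        return self.levels_by_position[dom.position - 1]

    def __str__(self) -> str:
        return "".join(str(q) for q in self.levels_by_position)

    def with_level(self, domain: str, level: int) -> "AscotState":
        """Copy of this state with one domain's level replaced."""
        pos = DOMAIN_BY_NAME[domain].position - 1
        levels = list(self.levels_by_position)
        levels[pos] = level
        return AscotState(tuple(levels))


BEST_STATE = AscotState((1,) * 8)
WORST_STATE = AscotState((4,) * 8)


def parse_state(text: str) -> AscotState:
    """Parse an 8-digit state string (questionnaire order, control first).

    Raises ``ValueError`` naming the offending position for malformed input.
    """
    if not isinstance(text, str):
        raise ValueError(f"state must be a string, got {type(text).__name__}")
    if len(text) != 8:
        raise ValueError(f"state string must have 8 digits, got {len(text)}")
    levels = []
    for pos, ch in enumerate(text, start=1):
        if not ch.isdigit():
            raise ValueError(f"non-digit {ch!r} at position {pos}")
        q = int(ch)
        if q not in (1, 2, 3, 4):
            raise ValueError(f"level {q} at position {pos} outside 1..4")
        levels.append(q)
    return AscotState(tuple(levels))


def enumerate_states() -> Iterator[AscotState]:
    """All 4^8 = 65,536 states, lexicographic on the state string."""
    for combo in itertools.product((1, 2, 3, 4), repeat=8):
        yield AscotState(combo)


def state_level_matrix() -> np.ndarray:
    """Levels of all 65,536 states as a (65536, 8) int array.

    Rows follow :func:`enumerate_states` order; columns follow state-string
    position order.  This is the vectorised counterpart of the enumeration
    and is what full-state-space scoring uses.
    """
    grids = np.meshgrid(*([np.arange(1, 5)] * 8), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)
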
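"""Core data types for classroom sociometric studies.

A study consists of a roster of actors (with gender, age, classroom and
rural/urban setting), one ordinal contact matrix per classroom (directed
ratings 1 = "we never coincided" … 5 = "we are always together"), one binary
co-drinking nomination network per classroom, and a 10-item AUDIT response
per actor.

Directionality convention (fixed here because triad frequencies depend on
it): **rows are raters** — entry ``[i, j]`` is actor *i*'s rating of, or tie
to, actor *j* (an out-tie of *i*).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ShapeError, ValidationError

#: Sentinel for a missing sociometric rating (absent respondent).  By default
#: it dichotomizes like 1 ("we never coincided") at every intensity level.
MISSING = 0

GENDERS = ("female", "male")
SETTINGS = ("rural", "urban")

#: AUDIT item score ranges: items 1-8 take 0-4, items 9-10 take 0/2/4.
AUDIT_ITEM_SETS = tuple([frozenset(range(5))] * 8 + [frozenset({0, 2, 4})] * 2)

_GENDER_ALIASES = {
    "f": "female", "female": "female", "w": "female",
    "m": "male", "male": "male",
}


def normalize_gender(value: str) -> str:
    key = str(value).strip().lower()
    try:
        return _GENDER_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unrecognized gender value {value!r}") from None


@dataclass(frozen=True)
class Actor:
    """One student: identity plus the attributes the analysis composes on."""

    id: str
    gender: str
    age: int
    classroom: str
    setting: str

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(
                f"actor {self.id!r}: gender must be one of {GENDERS}, got {self.gender!r}"
            )
        if self.setting not in SETTINGS:
            raise ValidationError(
                f"actor {self.id!r}: setting must be one of {SETTINGS}, got {self.setting!r}"
            )


@dataclass(frozen=True)
class AuditResponse:
    """A 10-item AUDIT questionnaire response (total 0-40)."""

    actor_id: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValidationError(
                f"actor {self.actor_id!r}: AUDIT needs exactly 10 items, got {len(self.items)}"
            )
        for k, (value, allowed) in enumerate(zip(self.items, AUDIT_ITEM_SETS), start=1):
            if value not in allowed:
                raise ValidationError(
                    f"actor {self.actor_id!r}: AUDIT item {k} = {value} outside "
                    f"allowed set {sorted(allowed)}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.items))


def validate_age(age: int, actor_id: str, window: tuple[int, int] = (10, 25)) -> int:
    """Check an age against the plausibility window (default 10-25 years)."""
    age = int(age)
    lo, hi = window
    if not lo <= age <= hi:
        raise ValidationError(
            f"actor {actor_id!r}: age {age} outside plausibility window [{lo}, {hi}]"
        )
    return age


def _check_square(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError(f"{what} must be square, got shape {values.shape}")
    return values


@dataclass
class ContactMatrix:
    """Square ordinal (1-5) directed rating matrix for one classroom.

    The diagonal is ignored (self-rating undefined); off-diagonal entries are
    1-5 or :data:`MISSING`.
    """

    classroom: str
    actor_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_square(self.values, "contact matrix").astype(int)
        n = len(self.actor_order)
        if self.values.shape[0] != n:
            raise ShapeError(
                f"contact matrix for {self.classroom!r}: {n} actors but "
                f"{self.values.shape[0]}x{self.values.shape[1]} values"
            )
        off = ~np.eye(n, dtype=bool)
        bad = off & ~np.isin(self.values, [MISSING, 1, 2, 3, 4, 5])
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"contact matrix for {self.classroom!r}: entry "
                f"({self.actor_order[i]!r} -> {self.actor_order[j]!r}) = "
                f"{self.values[i, j]} outside {{1..5}}"
            )

    @property
    def n_actors(self) -> int:
        return len(self.actor_order)


@dataclass
class BinaryNetwork:
    """Directed 0/1 adjacency for one analysis layer of one classroom."""

    classroom: str
    actor_order: list[str]
    adjacency: np.ndarray
    layer: str = "unknown"

    def __post_init__(self) -> None:
        self.adjacency = _check_square(self.adjacency, "adjacency").astype(int)
        n = len(self.actor_order)
        if self.adjacency.shape[0] != n:
            raise ShapeError(
                f"network for {self.classroom!r}: {n} actors but "
                f"{self.adjacency.shape[0]}x{self.adjacency.shape[1]} adjacency"
            )
        if not np.isin(self.adjacency, [0, 1]).all():
            raise ValidationError(
                f"network for {self.classroom!r}: adjacency entries must be 0/1"
            )
        np.fill_diagonal(self.adjacency, 0)

    @property
    def n_actors(self) -> int:
        return len(self.actor_order)

    @property
    def n_ties(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Directed ties as (source, target) label pairs, sorted."""
        return sorted(
            (self.actor_order[i], self.actor_order[j])
            for i, j in zip(*np.nonzero(self.adjacency))
        )

    def with_layer(self, layer: str) -> "BinaryNetwork":
        return replace(self, layer=layer)


def align_orders(a: Sequence[str], b: Sequence[str], what: str = "networks") -> None:
    """Raise :class:`AlignmentError` unless two actor orders are identical."""
    from .errors import AlignmentError

    if list(a) != list(b):
        raise AlignmentError(f"{what} have different actor orders: {list(a)[:5]}... vs {list(b)[:5]}...")
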
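"""MAN triad census of directed networks and its transitive/intransitive partition.

Every unordered triple of actors in a directed network falls into one of 16
isomorphism classes, labelled by the Holland–Leinhardt MAN code: the counts
of Mutual, Asymmetric and Null dyads among its three dyads, plus a letter
(D/U/C/T) disambiguating arc orientation (e.g. 030T = three asymmetric arcs
forming the transitive pattern X→Y, Y→Z, X→Z).

The analysis partitions the 16 types into *transitive* (balance-exhibiting)
and *intransitive*.  The default partition counts as transitive exactly the
types that contain at least one transitive triple and no intransitive one —
{030T, 120D, 120U, 300} — and reports everything else, including the
vacuous types (003, 012, 102), as intransitive.  A three-way scheme that
separates the vacuous types is available for sensitivity analysis.

Classification uses dyad-pattern logic (M, A, N counts plus orientation
rules); a precomputed 64-entry lookup over the off-diagonal bit patterns
drives the O(n³) census, which is ample for classroom-sized networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ShapeError, UsageError, ValidationError
from .model import BinaryNetwork

#: The 16 MAN triad type codes in canonical order.
TRIAD_TYPES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

_TYPE_INDEX = {code: k for k, code in enumerate(TRIAD_TYPES)}

#: MAN digits (mutual, asymmetric, null dyad counts) per type code.
MAN_DIGITS = {code: (int(code[0]), int(code[1]), int(code[2])) for code in TRIAD_TYPES}

#: Types reported as transitive under the default binary partition.
TRANSITIVE_TYPES = frozenset({"030T", "120D", "120U", "300"})

#: Types with no directed two-path through distinct actors at all.
VACUOUS_TYPES = frozenset({"003", "012", "102"})


def classify_triad(sub: np.ndarray) -> str:
    """MAN type code of a 3-node directed adjacency matrix.

    Dyad-level logic: count mutual/asymmetric/null dyads, then disambiguate
    orientation (shared source → D, shared target → U, chain/cycle → C,
    transitive 3-arc pattern → T).
    """
    sub = np.asarray(sub)
    if sub.shape != (3, 3):
        raise ShapeError(f"triad must be a 3x3 matrix, got shape {sub.shape}")
    if np.diag(sub).any() or not np.isin(sub, [0, 1]).all():
        raise ShapeError("triad matrix must be 0/1 with a zero diagonal")

    mutual, arcs, nulls = [], [], 0
    for i, j in ((0, 1), (0, 2), (1, 2)):
        fwd, back = sub[i, j], sub[j, i]
        if fwd and back:
            mutual.append((i, j))
        elif fwd:
            arcs.append((i, j))
        elif back:
            arcs.append((j, i))
        else:
            nulls += 1
    m, a = len(mutual), len(arcs)

    base = f"{m}{a}{nulls}"
    if base == "021":
        (s1, t1), (s2, t2) = arcs
        if s1 == s2:
            return "021D"
        if t1 == t2:
            return "021U"
        return "021C"
    if base == "111":
        pair = set(mutual[0])
        (s, t) = arcs[0]
        return "111D" if t in pair else "111U"
    if base == "030":
        outdeg = sub.sum(axis=1)
        return "030C" if (outdeg == 1).all() else "030T"
    if base == "120":
        pair = set(mutual[0])
        (z,) = set(range(3)) - pair
        sources = {s for s, _ in arcs}
        targets = {t for _, t in arcs}
        if sources == {z}:
            return "120D"
        if targets == {z}:
            return "120U"
        return "120C"
    code = {"003": "003", "012": "012", "102": "102", "201": "201", "210": "210",
            "300": "300"}.get(base)
    if code is None:  # unreachable: every (m, a, n) with m+a+n=3 is covered
        raise ValueError(f"unclassifiable dyad pattern {base}")
    return code


def _build_lookup() -> np.ndarray:
    """Type index for each of the 64 off-diagonal bit patterns.

    Bit order for a triple (i, j, k): a[i,j], a[j,i], a[i,k], a[k,i],
    a[j,k], a[k,j].
    """
    table = np.empty(64, dtype=np.int64)
    for bits in range(64):
        sub = np.zeros((3, 3), dtype=int)
        sub[0, 1] = bits & 1
        sub[1, 0] = (bits >> 1) & 1
        sub[0, 2] = (bits >> 2) & 1
        sub[2, 0] = (bits >> 3) & 1
        sub[1, 2] = (bits >> 4) & 1
        sub[2, 1] = (bits >> 5) & 1
        table[bits] = _TYPE_INDEX[classify_triad(sub)]
    return table


_LOOKUP = _build_lookup()


@dataclass(frozen=True)
class TransitivityScheme:
    """Partition of the 16 triad types into transitive / intransitive
    (/ optionally vacuous) classes.

    Invariants: 300 is always transitive; 012, 102 and 111U are never
    transitive; the transitive and vacuous sets are disjoint.
    """

    transitive: frozenset = TRANSITIVE_TYPES
    vacuous: frozenset = frozenset()

    def __post_init__(self) -> None:
        for code in self.transitive | self.vacuous:
            if code not in _TYPE_INDEX:
                raise ValidationError(f"unknown triad type code {code!r}")
        if "300" not in self.transitive:
            raise ValidationError("type 300 must be classed as transitive")
        clash = {"012", "102", "111U"} & set(self.transitive)
        if clash:
            raise ValidationError(f"types {sorted(clash)} cannot be classed as transitive")
        if self.transitive & self.vacuous:
            raise ValidationError("transitive and vacuous sets must be disjoint")

    def partition(self, code: str) -> str:
        if code in self.transitive:
            return "transitive"
        if code in self.vacuous:
            return "vacuous"
        return "intransitive"

    def transitive_mask(self) -> np.ndarray:
        return np.array([c in self.transitive for c in TRIAD_TYPES])

    def vacuous_mask(self) -> np.ndarray:
        return np.array([c in self.vacuous for c in TRIAD_TYPES])


DEFAULT_SCHEME = TransitivityScheme()


def three_way_scheme() -> TransitivityScheme:
    """Sensitivity-analysis scheme separating the vacuous types (003, 012, 102)."""
    return TransitivityScheme(vacuous=VACUOUS_TYPES)


@dataclass
class TriadCensus:
    """Counts of the 16 triad types over all C(n, 3) actor triples.

    ``n_actors`` is an int for a single classroom and a tuple of classroom
    sizes for an aggregate.  ``is_empty`` flags a census over fewer than 3
    actors (zero triples).
    """

    counts: dict[str, int]
    n_actors: int | tuple[int, ...]
    scheme: TransitivityScheme = DEFAULT_SCHEME
    classroom: str | None = None
    layer: str | None = None

    def __post_init__(self) -> None:
        self.counts = {code: int(self.counts.get(code, 0)) for code in TRIAD_TYPES}
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("triad counts must be nonnegative")

    @property
    def sizes(self) -> tuple[int, ...]:
        return (self.n_actors,) if isinstance(self.n_actors, int) else tuple(self.n_actors)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        return self.total == 0

    @property
    def transitive_total(self) -> int:
        return sum(self.counts[c] for c in self.scheme.transitive)

    @property
    def vacuous_total(self) -> int:
        return sum(self.counts[c] for c in self.scheme.vacuous)

    @property
    def intransitive_total(self) -> int:
        return self.total - self.transitive_total - self.vacuous_total

    @property
    def transitive_share(self) -> float:
        return self.transitive_total / self.total if self.total else 0.0

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, name="count")


def _triple_codes(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(index triples, 6-bit codes) for every unordered triple i<j<k."""
    n = adjacency.shape[0]
    idx = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
    a = adjacency
    i, j, k = idx.T
    codes = (
        a[i, j] | (a[j, i] << 1) | (a[i, k] << 2)
        | (a[k, i] << 3) | (a[j, k] << 4) | (a[k, j] << 5)
    )
    return idx, codes


def census(net: BinaryNetwork, scheme: TransitivityScheme = DEFAULT_SCHEME) -> TriadCensus:
    """Full 16-type triad census of one network.

    Networks with fewer than 3 actors yield an empty census (``is_empty``).
    """
    n = net.n_actors
    if n < 3:
        return TriadCensus(
            counts={}, n_actors=n, scheme=scheme,
            classroom=net.classroom, layer=net.layer,
        )
    _, codes = _triple_codes(net.adjacency)
    tallies = np.bincount(_LOOKUP[codes], minlength=16)
    counts = {code: int(tallies[_TYPE_INDEX[code]]) for code in TRIAD_TYPES}
    assert sum(counts.values()) == comb(n, 3)
    return TriadCensus(
        counts=counts, n_actors=n, scheme=scheme,
        classroom=net.classroom, layer=net.layer,
    )


def census_proportions(c: TriadCensus) -> dict[str, float]:
    """Percentage of triples per type; raises on a zero-triad census."""
    if c.total == 0:
        raise DegenerateInputError("census has zero triads; proportions undefined")
    return {code: 100.0 * count / c.total for code, count in c.counts.items()}


def node_triad_profile(
    net: BinaryNetwork, scheme: TransitivityScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Per-actor counts of transitive and intransitive triads containing the actor.

    Each of the C(n-1, 2) triples through an actor contributes to exactly one
    of that actor's counters, so summing any column over actors gives 3x the
    corresponding census total.
    """
    n = net.n_actors
    frame = pd.DataFrame(
        0, index=list(net.actor_order),
        columns=["transitive", "intransitive", "vacuous"], dtype=int,
    )
    if n < 3:
        return frame
    idx, codes = _triple_codes(net.adjacency)
    type_idx = _LOOKUP[codes]
    for column, mask in (
        ("transitive", scheme.transitive_mask()),
        ("vacuous", scheme.vacuous_mask()),
    ):
        hit = mask[type_idx]
        col = np.zeros(n, dtype=int)
        for member in range(3):
            np.add.at(col, idx[:, member], hit)
        frame[column] = col
    per_node_total = comb(n - 1, 2)
    frame["intransitive"] = per_node_total - frame["transitive"] - frame["vacuous"]
    return frame


def aggregate_censuses(censuses: list[TriadCensus]) -> TriadCensus:
    """Componentwise sum of censuses (e.g. all classrooms of one setting)."""
    if not censuses:
        raise UsageError("cannot aggregate an empty list of censuses")
    scheme = censuses[0].scheme
    if any(c.scheme != scheme for c in censuses):
        raise UsageError("cannot aggregate censuses computed under different schemes")
    counts: dict[str, int] = {code: 0 for code in TRIAD_TYPES}
    sizes: tuple[int, ...] = ()
    for c in censuses:
        for code in TRIAD_TYPES:
            counts[code] += c.counts[code]
        sizes += c.sizes
    layers = {c.layer for c in censuses}
    return TriadCensus(
        counts=counts, n_actors=sizes, scheme=scheme,
        layer=layers.pop() if len(layers) == 1 else None,
    )
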
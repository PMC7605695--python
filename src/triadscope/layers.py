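"""Attribute-composition layers: same-attribute subnetworks, attribute-
stratified censuses, and the co-drinking consumption layer.

Homophily — the tendency to tie with similar others — motivates two readings
of "composition by gender": (a) the same-gender subnetwork of a contact
layer, and (b) a census stratified by the gender make-up of each triple
(FFF/FFM/FMM/MMM).  Both are provided; the pipeline's default is (a).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ValidationError
from .model import Actor, BinaryNetwork, align_orders
from .triads import (
    DEFAULT_SCHEME,
    TRIAD_TYPES,
    TransitivityScheme,
    TriadCensus,
    _LOOKUP,
    _TYPE_INDEX,
    _triple_codes,
)


def _attribute_map(
    roster: Iterable[Actor] | Mapping[str, object], attribute: str
) -> Mapping[str, object]:
    if isinstance(roster, Mapping):
        return roster
    return {actor.id: getattr(actor, attribute) for actor in roster}


def _attribute_vector(
    net: BinaryNetwork, roster, attribute: str
) -> list:
    values = _attribute_map(roster, attribute)
    out = []
    for actor_id in net.actor_order:
        if actor_id not in values or values[actor_id] in (None, ""):
            raise ValidationError(
                f"actor {actor_id!r} has no value for attribute {attribute!r}"
            )
        out.append(values[actor_id])
    return out


def homophilous_subnetwork(
    net: BinaryNetwork,
    roster: Iterable[Actor] | Mapping[str, object],
    attribute: str = "gender",
) -> BinaryNetwork:
    """Keep tie i→j iff i and j share the attribute value.

    Idempotent and never adds ties.  ``roster`` may be a list of actors or a
    precomputed id → value mapping.
    """
    attrs = np.asarray(_attribute_vector(net, roster, attribute), dtype=object)
    same = attrs[:, None] == attrs[None, :]
    return BinaryNetwork(
        classroom=net.classroom,
        actor_order=list(net.actor_order),
        adjacency=net.adjacency * same.astype(int),
        layer=f"{attribute}_homophilous",
    )


@dataclass
class StratifiedCensus:
    """Triad censuses keyed by the attribute multiset of each triple.

    Keys are tuples of sorted attribute values, e.g. ``("female", "female",
    "male")``.  Summed over strata, every type's count equals its count in
    the unstratified census.
    """

    strata: dict[tuple, TriadCensus]
    attribute: str

    def total_census(self) -> TriadCensus:
        from .triads import aggregate_censuses

        return aggregate_censuses(list(self.strata.values()))


def stratified_census(
    net: BinaryNetwork,
    roster: Iterable[Actor] | Mapping[str, object],
    attribute: str = "gender",
    scheme: TransitivityScheme = DEFAULT_SCHEME,
) -> StratifiedCensus:
    """Census partitioned by the attribute composition of each actor triple."""
    attrs = _attribute_vector(net, roster, attribute)
    n = net.n_actors
    strata: dict[tuple, np.ndarray] = {}
    if n >= 3:
        idx, codes = _triple_codes(net.adjacency)
        type_idx = _LOOKUP[codes]
        keys = [tuple(sorted((attrs[i], attrs[j], attrs[k]))) for i, j, k in idx]
        for key, t in zip(keys, type_idx):
            strata.setdefault(key, np.zeros(16, dtype=int))[t] += 1
    return StratifiedCensus(
        strata={
            key: TriadCensus(
                counts={code: int(v[_TYPE_INDEX[code]]) for code in TRIAD_TYPES},
                n_actors=n, scheme=scheme,
                classroom=net.classroom, layer=net.layer,
            )
            for key, v in sorted(strata.items())
        },
        attribute=attribute,
    )


def consumption_layer(
    nominations: BinaryNetwork,
    contact: BinaryNetwork | None = None,
    restrict_to_contact: bool = False,
    symmetrize: bool = False,
) -> BinaryNetwork:
    """Co-drinking layer from directed nominations.

    With ``restrict_to_contact`` the nominations are intersected with the
    contact layer's ties (requires aligned actor orders).  ``symmetrize``
    applies union symmetrization (i~j if either nominated the other) for
    sensitivity checks; default keeps directed nominations.
    """
    adjacency = nominations.adjacency.copy()
    if restrict_to_contact:
        if contact is None:
            raise ValidationError("restrict_to_contact requires a contact network")
        align_orders(nominations.actor_order, contact.actor_order, "nomination/contact layers")
        adjacency &= contact.adjacency
    if symmetrize:
        adjacency = (adjacency | adjacency.T).astype(int)
    return BinaryNetwork(
        classroom=nominations.classroom,
        actor_order=list(nominations.actor_order),
        adjacency=adjacency,
        layer="consumption",
    )
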
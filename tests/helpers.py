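"""Shared test utilities: an isomorphism-matching triad oracle independent of
the package's dyad-pattern classifier, plus random-network builders."""

from __future__ import annotations

import itertools

import numpy as np

from triadscope.model import BinaryNetwork

# Canonical representative of each MAN triad type, as directed edge pairs on
# nodes {0, 1, 2} (a=0, b=1, c=2).  Written down independently of the
# implementation, following the standard Holland-Leinhardt pictures.
CANONICAL_TRIADS = {
    "003": [],
    "012": [(0, 1)],
    "102": [(0, 1), (1, 0)],
    "021D": [(1, 0), (1, 2)],
    "021U": [(0, 1), (2, 1)],
    "021C": [(0, 1), (1, 2)],
    "111D": [(0, 2), (2, 0), (1, 2)],
    "111U": [(0, 2), (2, 0), (2, 1)],
    "030T": [(0, 1), (2, 1), (0, 2)],
    "030C": [(1, 0), (2, 1), (0, 2)],
    "201": [(0, 1), (1, 0), (0, 2), (2, 0)],
    "120D": [(1, 2), (1, 0), (0, 2), (2, 0)],
    "120U": [(0, 1), (2, 1), (0, 2), (2, 0)],
    "120C": [(0, 1), (1, 2), (0, 2), (2, 0)],
    "210": [(0, 1), (1, 2), (2, 1), (0, 2), (2, 0)],
    "300": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)],
}


def triad_matrix(edges) -> np.ndarray:
    m = np.zeros((3, 3), dtype=int)
    for i, j in edges:
        m[i, j] = 1
    return m


_CANONICAL_MATRICES = {code: triad_matrix(e) for code, e in CANONICAL_TRIADS.items()}


def oracle_classify(sub: np.ndarray) -> str:
    """Type of a 3-node digraph by exhaustive isomorphism matching."""
    sub = np.asarray(sub)
    for code, canon in _CANONICAL_MATRICES.items():
        for perm in itertools.permutations(range(3)):
            p = np.asarray(perm)
            if np.array_equal(sub[np.ix_(p, p)], canon):
                return code
    raise AssertionError("unclassifiable triad — canonical table is broken")


def oracle_census(adjacency: np.ndarray) -> dict[str, int]:
    """Brute-force per-triple census using the isomorphism oracle."""
    n = adjacency.shape[0]
    counts = {code: 0 for code in CANONICAL_TRIADS}
    for triple in itertools.combinations(range(n), 3):
        p = np.asarray(triple)
        counts[oracle_classify(adjacency[np.ix_(p, p)])] += 1
    return counts


def bits_to_matrix(bits: int) -> np.ndarray:
    """One of the 64 labeled 3-node digraphs, from its off-diagonal bit code."""
    sub = np.zeros((3, 3), dtype=int)
    for k, (i, j) in enumerate([(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]):
        sub[i, j] = (bits >> k) & 1
    return sub


def random_network(
    rng: np.random.Generator, n: int, density: float = 0.3, classroom: str = "X"
) -> BinaryNetwork:
    adj = (rng.random((n, n)) < density).astype(int)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(
        classroom=classroom, actor_order=[f"a{k}" for k in range(n)],
        adjacency=adj, layer="minimum",
    )
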
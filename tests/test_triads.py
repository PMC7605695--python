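"""Triad classification, census identities, partitions and aggregation."""

from math import comb

import networkx as nx
import numpy as np
import pytest

from triadscope import (
    TRIAD_TYPES,
    BinaryNetwork,
    TransitivityScheme,
    aggregate_censuses,
    census,
    census_proportions,
    classify_triad,
    node_triad_profile,
    three_way_scheme,
)
from triadscope.errors import DegenerateInputError, ShapeError, UsageError, ValidationError
from triadscope.triads import MAN_DIGITS, TriadCensus

from helpers import bits_to_matrix, oracle_census, oracle_classify, random_network, triad_matrix


class TestClassify:
    def test_transitive_path_closure_is_030T(self):
        # X→Y, Y→Z, X→Z: the defining transitive pattern
        assert classify_triad(triad_matrix([(0, 1), (1, 2), (0, 2)])) == "030T"

    def test_empty_and_single_mutual(self):
        assert classify_triad(np.zeros((3, 3), dtype=int)) == "003"
        assert classify_triad(triad_matrix([(0, 1), (1, 0)])) == "102"

    def test_all_64_labeled_digraphs_match_isomorphism_oracle(self):
        for bits in range(64):
            sub = bits_to_matrix(bits)
            assert classify_triad(sub) == oracle_classify(sub), f"bit pattern {bits}"

    def test_man_digits_consistent_with_code(self):
        for bits in range(64):
            sub = bits_to_matrix(bits)
            code = classify_triad(sub)
            mutual = int((sub * sub.T).sum() / 2)
            asym = int((sub | sub.T).sum() / 2) - mutual
            assert MAN_DIGITS[code] == (mutual, asym, 3 - mutual - asym)

    def test_malformed_input_rejected(self):
        with pytest.raises(ShapeError):
            classify_triad(np.zeros((4, 4), dtype=int))
        with pytest.raises(ShapeError):
            classify_triad(np.eye(3, dtype=int))


class TestCensus:
    def test_empty_network(self):
        net = BinaryNetwork("c", list("abcde"), np.zeros((5, 5), dtype=int))
        c = census(net)
        assert c.counts["003"] == 10 and c.total == 10
        assert c.transitive_share == 0.0

    def test_complete_mutual_network(self):
        net = BinaryNetwork("c", list("abcd"), 1 - np.eye(4, dtype=int))
        c = census(net)
        assert c.counts["300"] == 4 and c.transitive_share == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        net = random_network(rng, int(rng.integers(4, 13)), density=float(rng.uniform(0.1, 0.7)))
        assert census(net).counts == oracle_census(net.adjacency)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_triadic_census(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, 15, density=0.3)
        g = nx.from_numpy_array(net.adjacency, create_using=nx.DiGraph)
        assert census(net).counts == nx.triadic_census(g)

    def test_census_sum_identity(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 20))
            net = random_network(rng, n, density=float(rng.uniform(0, 1)))
            assert census(net).total == comb(n, 3)

    def test_reversal_symmetry(self, rng):
        """Transposing the adjacency swaps D↔U types and fixes the rest."""
        swap = {"021D": "021U", "021U": "021D", "111D": "111U", "111U": "111D",
                "120D": "120U", "120U": "120D"}
        for _ in range(10):
            net = random_network(rng, 12, density=0.35)
            rev = BinaryNetwork("c", net.actor_order, net.adjacency.T.copy())
            fwd_counts, rev_counts = census(net).counts, census(rev).counts
            for code in TRIAD_TYPES:
                assert fwd_counts[code] == rev_counts[swap.get(code, code)]

    def test_small_network_yields_empty_census(self):
        net = BinaryNetwork("c", ["a", "b"], np.zeros((2, 2), dtype=int))
        c = census(net)
        assert c.is_empty and c.total == 0

    def test_closing_a_pure_two_path_creates_a_transitive_triad(self, rng):
        """An 021C triple (X→Y→Z only) becomes 030T when X→Z is added; in a
        network where that is the only triple touching the new arc, the
        transitive total rises by exactly one."""
        from helpers import triad_matrix

        two_path = triad_matrix([(0, 1), (1, 2)])
        assert classify_triad(two_path) == "021C"
        closed = two_path.copy()
        closed[0, 2] = 1
        assert classify_triad(closed) == "030T"

        # embed the isolated two-path in a larger otherwise-empty classroom
        n = 8
        adj = np.zeros((n, n), dtype=int)
        adj[0, 1] = adj[1, 2] = 1
        before = census(BinaryNetwork("c", [f"a{k}" for k in range(n)], adj))
        adj2 = adj.copy()
        adj2[0, 2] = 1
        after = census(BinaryNetwork("c", [f"a{k}" for k in range(n)], adj2))
        assert after.transitive_total == before.transitive_total + 1


class TestProportionsAndProfiles:
    def test_single_type_is_100_percent(self):
        net = BinaryNetwork("c", list("abcde"), np.zeros((5, 5), dtype=int))
        assert census_proportions(census(net))["003"] == 100.0

    def test_proportions_sum_to_100(self, rng):
        net = random_network(rng, 14, density=0.4)
        assert sum(census_proportions(census(net)).values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_triads_proportions_undefined(self):
        c = TriadCensus(counts={}, n_actors=2)
        with pytest.raises(DegenerateInputError):
            census_proportions(c)

    def test_empty_network_profile_all_zero(self):
        net = BinaryNetwork("c", list("abcd"), np.zeros((4, 4), dtype=int))
        assert (node_triad_profile(net)["transitive"] == 0).all()

    def test_complete_mutual_profile(self):
        net = BinaryNetwork("c", list("abcd"), 1 - np.eye(4, dtype=int))
        prof = node_triad_profile(net)
        assert (prof["transitive"] == 3).all()  # C(3,2) triples per actor

    def test_double_counting_identity(self, rng):
        """Each triad contains 3 actors, so node counts sum to 3x census totals."""
        for _ in range(10):
            net = random_network(rng, 11, density=0.3)
            c = census(net)
            prof = node_triad_profile(net)
            assert prof["transitive"].sum() == 3 * c.transitive_total
            assert prof["intransitive"].sum() == 3 * c.intransitive_total


class TestSchemes:
    def test_default_partition_matches_representative_labels(self):
        scheme = TransitivityScheme()
        assert scheme.partition("300") == "transitive"
        for code in ("012", "102", "111U"):
            assert scheme.partition(code) == "intransitive"
        assert scheme.transitive == {"030T", "120D", "120U", "300"}

    def test_three_way_scheme_separates_vacuous(self):
        scheme = three_way_scheme()
        assert scheme.partition("003") == "vacuous"
        assert scheme.partition("021C") == "intransitive"
        assert scheme.partition("030T") == "transitive"

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValidationError):
            TransitivityScheme(transitive=frozenset({"030T"}))  # missing 300
        with pytest.raises(ValidationError):
            TransitivityScheme(transitive=frozenset({"300", "102"}))
        with pytest.raises(ValidationError):
            TransitivityScheme(transitive=frozenset({"300", "banana"}))

    def test_three_way_totals_partition_census(self, rng):
        net = random_network(rng, 12, density=0.3)
        c = census(net, three_way_scheme())
        assert c.transitive_total + c.intransitive_total + c.vacuous_total == c.total


class TestAggregation:
    def test_self_aggregation_doubles(self, rng):
        c = census(random_network(rng, 8))
        agg = aggregate_censuses([c, c])
        assert all(agg.counts[t] == 2 * c.counts[t] for t in TRIAD_TYPES)

    def test_sizes_recorded_and_totals_add(self, rng):
        c4 = census(random_network(rng, 4))
        c5 = census(random_network(rng, 5))
        agg = aggregate_censuses([c4, c5])
        assert agg.total == comb(4, 3) + comb(5, 3) == 14
        assert sorted(agg.sizes) == [4, 5]

    def test_order_independence(self, rng):
        censuses = [census(random_network(rng, int(rng.integers(4, 10)))) for _ in range(6)]
        a = aggregate_censuses(censuses[:3] + censuses[3:])
        b = aggregate_censuses(censuses[::-1])
        assert a.counts == b.counts and a.total == b.total

    def test_empty_list_rejected(self):
        with pytest.raises(UsageError):
            aggregate_censuses([])
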
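"""AUDIT scoring, chi-square, cross-layer correlation and power."""

import numpy as np
import pytest

from triadscope import (
    AuditResponse,
    BinaryNetwork,
    chi_square,
    node_triad_profile,
    power_for_r,
    risk_proportions,
    score_audit,
    transitive_profile_correlation,
)
from triadscope.errors import DegenerateInputError, UsageError, ValidationError

from helpers import random_network

#: Monte-Carlo reference: power of the two-sided t test of rho=0 at alpha=.05
#: with true rho 0.8 and n=10, from 1e5 bivariate-normal replicates (fixed
#: before the power implementation was written).
MC_POWER_R08_N10 = 0.8684


def resp(items):
    return AuditResponse(actor_id="a", items=tuple(items))


class TestAudit:
    def test_all_zero_not_at_risk(self):
        c = score_audit(resp([0] * 10))
        assert c.audit_total == 0 and not c.at_risk

    def test_maximum_total_at_risk(self):
        c = score_audit(resp([4] * 10), threshold=40)
        assert c.audit_total == 40 and c.at_risk

    def test_boundary_total_at_default_threshold(self):
        c = score_audit(resp([1] * 8 + [0, 0]))
        assert c.audit_total == 8 and c.at_risk and c.threshold == 8

    def test_invalid_items_rejected(self):
        with pytest.raises(ValidationError):
            resp([5] + [0] * 9)
        with pytest.raises(ValidationError):
            resp([0] * 8 + [1, 0])

    def test_risk_proportions_single_actor(self):
        table = risk_proportions([score_audit(resp([4] * 10))])
        assert table.loc[0, "pct_at_risk"] == 100.0

    def test_risk_proportions_stratified_sums(self):
        from triadscope import Actor

        actors = [
            Actor(id=f"s{k}", gender="female" if k < 3 else "male",
                  age=17, classroom="c", setting="rural")
            for k in range(5)
        ]
        risks = [
            score_audit(AuditResponse(actor_id=f"s{k}", items=(4,) * 8 + (0, 0) if k % 2 else (0,) * 10))
            for k in range(5)
        ]
        table = risk_proportions(risks, actors=actors, by="gender")
        assert set(table["gender"]) == {"female", "male"}
        assert np.allclose(table["pct_at_risk"] + table["pct_no_risk"], 100.0)
        assert table["n"].sum() == 5

    def test_empty_list_rejected(self):
        with pytest.raises(UsageError):
            risk_proportions([])


class TestChiSquare:
    def test_independent_table_zero_statistic(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        # N(ad-bc)^2 / (row and column margins) = 60*(400-100)^2/30^4 = 20/3
        res = chi_square([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert res.df == 1

    def test_df_of_2x3_table(self):
        assert chi_square([[5, 6, 7], [8, 9, 10]]).df == 2

    def test_permutation_and_transposition_invariance(self, rng):
        table = rng.integers(1, 30, size=(3, 4))
        base = chi_square(table).statistic
        assert chi_square(table[::-1]).statistic == pytest.approx(base)
        assert chi_square(table[:, ::-1]).statistic == pytest.approx(base)
        assert chi_square(table.T).statistic == pytest.approx(base)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateInputError):
            chi_square([[0, 0], [5, 6]])

    def test_continuity_correction_reduces_statistic(self):
        plain = chi_square([[20, 10], [10, 20]], continuity=False)
        corrected = chi_square([[20, 10], [10, 20]], continuity=True)
        assert corrected.statistic < plain.statistic


class TestPower:
    @pytest.mark.parametrize("method", ["exact", "fisher_z"])
    def test_null_power_equals_alpha(self, method):
        for alpha in (0.01, 0.05, 0.2):
            assert power_for_r(0.0, 30, alpha, method=method) == pytest.approx(alpha, abs=1e-6)

    def test_monotone_in_n(self):
        assert power_for_r(0.5, 60) > power_for_r(0.5, 20)

    def test_monotone_in_r(self):
        powers = [power_for_r(r, 25) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_power_tends_to_one(self):
        assert power_for_r(0.3, 500) > 0.999

    def test_matches_monte_carlo_oracle(self):
        assert power_for_r(0.8, 10, 0.05) == pytest.approx(MC_POWER_R08_N10, abs=0.01)

    def test_usage_errors(self):
        with pytest.raises(UsageError):
            power_for_r(0.5, 3)
        with pytest.raises(UsageError):
            power_for_r(1.0, 10)
        with pytest.raises(UsageError):
            power_for_r(0.5, 10, alpha=0)


class TestLayerCorrelation:
    def test_identical_networks_r_one(self, rng):
        net = random_network(rng, 10, density=0.4)
        prof = node_triad_profile(net)["transitive"]
        assert prof.nunique() > 1  # guard: nondegenerate example
        lc = transitive_profile_correlation(net, net)
        assert lc.r == pytest.approx(1.0)

    def test_exact_antiordering_r_minus_one(self, rng):
        # tie_level mode on complementary off-diagonal patterns
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = adj[1, 2] = adj[2, 3] = 1
        comp = 1 - adj - np.eye(4, dtype=int)
        a = BinaryNetwork("c", list("abcd"), adj)
        b = BinaryNetwork("c", list("abcd"), comp.astype(int))
        lc = transitive_profile_correlation(a, b, mode="tie_level")
        assert lc.r == pytest.approx(-1.0)

    def test_r_matches_covariance_oracle(self, rng):
        a, b = random_network(rng, 10, 0.45), random_network(rng, 10, 0.45)
        b.actor_order = list(a.actor_order)
        lc = transitive_profile_correlation(a, b)
        x = node_triad_profile(a)["transitive"].to_numpy(float)
        y = node_triad_profile(b)["transitive"].to_numpy(float)
        direct = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert lc.r == pytest.approx(direct, abs=1e-12)

    def test_symmetry_in_networks(self, rng):
        a, b = random_network(rng, 9, 0.4), random_network(rng, 9, 0.4)
        b.actor_order = list(a.actor_order)
        assert transitive_profile_correlation(a, b).r == pytest.approx(
            transitive_profile_correlation(b, a).r
        )

    def test_invariance_to_common_reordering(self, rng):
        a, b = random_network(rng, 9, 0.4), random_network(rng, 9, 0.4)
        b.actor_order = list(a.actor_order)
        perm = rng.permutation(9)
        order = [a.actor_order[p] for p in perm]
        a2 = BinaryNetwork("X", order, a.adjacency[np.ix_(perm, perm)], layer=a.layer)
        b2 = BinaryNetwork("X", order, b.adjacency[np.ix_(perm, perm)], layer=b.layer)
        assert transitive_profile_correlation(a2, b2).r == pytest.approx(
            transitive_profile_correlation(a, b).r
        )

    def test_zero_variance_raises_not_nan(self):
        empty = BinaryNetwork("c", list("abcde"), np.zeros((5, 5), dtype=int))
        with pytest.raises(DegenerateInputError):
            transitive_profile_correlation(empty, empty)

    def test_census_vector_mode_n_is_16(self, rng):
        a, b = random_network(rng, 10, 0.4), random_network(rng, 10, 0.5)
        b.actor_order = list(a.actor_order)
        assert transitive_profile_correlation(a, b, mode="census_vector").n == 16

    def test_power_attached_at_observed_r(self, rng):
        a, b = random_network(rng, 12, 0.4), random_network(rng, 12, 0.4)
        b.actor_order = list(a.actor_order)
        lc = transitive_profile_correlation(a, b)
        assert lc.power == pytest.approx(power_for_r(abs(lc.r), lc.n, lc.alpha))
        assert lc.alpha <= lc.power <= 1.0
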
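"""Degradation, replicability, metabolic activity, claims and the lottery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcrs.engine import Grid
from mcrs.fitness import (
    KineticParams,
    claim,
    degradation_prob,
    empty_claim,
    metabolic_activity,
    replicability,
    replication_lottery,
)
from mcrs.replicator import Replicator

P = KineticParams()


def make_rep(alphas, p_fold=1.0, length=35, energy=-10.0):
    eff = tuple(p_fold * a / max(sum(x > 0 for x in alphas), 1) ** P.sigma
                for a in alphas)
    return Replicator(
        sequence="A" * length,
        structure="." * length,
        energy=energy,
        alphas=alphas,
        effective=eff,
        m=sum(a > 0 for a in alphas),
        p_fold=p_fold,
        p_deg=degradation_prob(energy, P),
        replicability=replicability(length, p_fold, P),
    )


class TestDegradation:
    @pytest.mark.parametrize(
        "energy,expected", [(0.0, 0.9), (-25.0, 0.1), (-12.5, 0.5)]
    )
    def test_linear_anchors(self, energy, expected):
        assert degradation_prob(energy, P) == pytest.approx(expected)

    def test_clamped_below_e_min(self):
        assert degradation_prob(-40.0, P) == pytest.approx(0.1)

    @given(st.floats(min_value=-50.0, max_value=0.0))
    @settings(deadline=None)
    def test_bounded_and_monotone(self, e):
        p = degradation_prob(e, P)
        assert 0.1 - 1e-12 <= p <= 0.9 + 1e-12
        assert degradation_prob(e, P) <= degradation_prob(min(e + 1.0, 0.0), P)


class TestReplicability:
    def test_reference_value(self):
        # fully folded 35-mer at defaults: 10 * 1 / (1 + 0.05*35)
        assert replicability(35, 1.0, P) == pytest.approx(3.6364, abs=1e-4)

    def test_unfolded_replicates_twice_as_fast(self):
        assert replicability(35, 0.0, P) == pytest.approx(
            2 * replicability(35, 1.0, P)
        )

    def test_length_independent_when_elongation_free(self):
        params = KineticParams(b2=1e-12)
        assert replicability(10, 0.5, params) == pytest.approx(
            replicability(70, 0.5, params), rel=1e-6
        )

    @given(st.integers(min_value=1, max_value=69),
           st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None)
    def test_monotone_decreasing_in_length_and_pfold(self, L, pf):
        assert replicability(L, pf, P) > replicability(L + 1, pf, P) > 0
        assert replicability(L, pf, P) >= replicability(L, min(pf + 0.1, 1.0), P)


class TestMetabolicActivity:
    def grid_with(self, reps):
        g = Grid(5)
        for (x, y), rep in reps.items():
            g.set(x, y, rep)
        return g

    def test_geometric_mean_identity(self):
        g = self.grid_with(
            {
                (2, 2): make_rep((1.0, 0, 0)),
                (2, 3): make_rep((0, 1.0, 0)),
                (3, 2): make_rep((0, 0, 1.0)),
            }
        )
        assert metabolic_activity(g, 2, 2, 3) == pytest.approx(1.0)

    def test_optimal_8_neighbour_configuration(self):
        """3/3/2 optimal mono-active neighbours give M = cbrt(18) * 1.1."""
        g = Grid(5)
        types = [(1.1, 0, 0)] * 3 + [(0, 1.1, 0)] * 3 + [(0, 0, 1.1)] * 2
        cells = [(x, y) for x in (1, 2, 3) for y in (1, 2, 3) if (x, y) != (2, 2)]
        for pos, alphas in zip(cells, types):
            g.set(*pos, make_rep(alphas))
        m = metabolic_activity(g, 2, 2, 3)
        assert m == pytest.approx(18 ** (1 / 3) * 1.1, abs=1e-9)
        assert m == pytest.approx(2.8828, abs=2e-4)

    def test_missing_type_zeroes_activity(self):
        g = self.grid_with(
            {(2, 2): make_rep((5.0, 0, 0)), (2, 3): make_rep((0, 5.0, 0))}
        )
        assert metabolic_activity(g, 2, 2, 3) == 0.0

    def test_toroidal_wraparound(self):
        g = self.grid_with(
            {
                (0, 0): make_rep((1.0, 0, 0)),
                (4, 4): make_rep((0, 1.0, 0)),  # wraps into (0,0)'s Moore hood
                (0, 4): make_rep((0, 0, 1.0)),
            }
        )
        assert metabolic_activity(g, 0, 0, 3) > 0

    def test_mean_field_uses_whole_lattice(self):
        g = self.grid_with(
            {
                (0, 0): make_rep((1.0, 0, 0)),
                (2, 2): make_rep((0, 1.0, 0)),
                (4, 0): make_rep((0, 0, 1.0)),
            }
        )
        assert metabolic_activity(g, 0, 0, 3) == 0.0
        assert metabolic_activity(g, 0, 0, 5) > 0.0


class TestClaims:
    def test_claim_is_bilinear(self):
        assert claim(0.0, 5.0) == 0.0
        assert claim(2.8828, 3.6364) == pytest.approx(10.483, abs=2e-3)
        assert claim(1.5, 4.0) == 2 * claim(1.5, 2.0)

    def test_empty_claim_default(self):
        assert empty_claim(P) == pytest.approx(1.048, abs=1e-3)

    def test_max_claim_default(self):
        assert empty_claim(P) / P.epsilon == pytest.approx(10.48, abs=5e-3)

    def test_empty_claim_scales_with_epsilon(self):
        assert empty_claim(KineticParams(epsilon=1e-12)) == pytest.approx(0.0, abs=1e-9)
        assert empty_claim(KineticParams(epsilon=1.0)) == pytest.approx(
            10.48, abs=5e-3
        )


class TestLottery:
    def cluster_grid(self):
        """Empty focal site (3,3) with exactly one von Neumann claimant.

        The claimant at (2,3) carries type 1; its Moore neighbourhood is
        completed by types 2 and 3 placed outside the replication
        neighbourhood of (3,3), so only one competitor enters the lottery.
        """
        g = Grid(7)
        g.set(2, 3, make_rep((1.0, 0, 0)))
        g.set(1, 3, make_rep((0, 1.0, 0)))
        g.set(1, 2, make_rep((0, 0, 1.0)))
        return g

    def two_claimant_grid(self):
        """As cluster_grid plus a second complete claimant at (3,2)."""
        g = self.cluster_grid()
        g.set(3, 2, make_rep((0, 1.0, 0)))
        g.set(4, 2, make_rep((0, 0, 1.0)))
        return g

    def test_no_neighbours_stays_empty(self):
        g = Grid(7)
        rng = np.random.default_rng(0)
        assert replication_lottery(g, 3, 3, 1.048, rng) is None

    def test_zero_metabolism_never_wins(self):
        g = Grid(7)
        g.set(2, 3, make_rep((1.0, 0, 0)))  # alone: incomplete metabolism
        rng = np.random.default_rng(0)
        for _ in range(200):
            assert replication_lottery(g, 3, 3, 1.048, rng) is None

    def test_single_claimant_matching_empty_claim_is_fair_coin(self):
        """A claimant with C == C_e wins exactly half the lotteries."""
        g = self.cluster_grid()
        m = metabolic_activity(g, 2, 3, 3)
        assert m > 0
        c = claim(m, g.get(2, 3).replicability)
        rng = np.random.default_rng(42)
        n, wins = 40000, 0
        for _ in range(n):
            wins += replication_lottery(g, 3, 3, c, rng) is not None
        se = (0.25 / n) ** 0.5
        assert wins / n == pytest.approx(0.5, abs=3 * se)

    def test_empirical_frequencies_match_claim_ratios(self):
        """Long-run win frequencies equal C_s / (C_e + sum C) per competitor."""
        g = self.two_claimant_grid()
        c_e = 1.048
        claims = {}
        for pos in [(2, 3), (3, 2)]:  # von Neumann neighbours of (3,3) occupied
            m = metabolic_activity(g, *pos, 3)
            assert m > 0
            claims[pos] = claim(m, g.get(*pos).replicability)
        total = sum(claims.values())
        expected = {pos: c / (c_e + total) for pos, c in claims.items()}
        p_empty = 1.0 - sum(expected.values())
        assert p_empty >= 0
        assert sum(expected.values()) + p_empty == pytest.approx(1.0, abs=1e-12)

        rng = np.random.default_rng(7)
        n = 60000
        counts = {pos: 0 for pos in claims}
        empties = 0
        for _ in range(n):
            w = replication_lottery(g, 3, 3, c_e, rng)
            if w is None:
                empties += 1
            else:
                counts[w] += 1
        for pos, p in expected.items():
            se = (p * (1 - p) / n) ** 0.5
            assert counts[pos] / n == pytest.approx(p, abs=3 * se + 1e-4)
        se = (p_empty * (1 - p_empty) / n) ** 0.5
        assert empties / n == pytest.approx(p_empty, abs=3 * se + 1e-4)

    def test_four_optimal_claimants_reference_probabilities(self):
        """Four competitors at the maximum claim: P_s ~ 0.2439 each."""
        c_hat, c_e = 10.48, 1.048
        p_s = c_hat / (c_e + 4 * c_hat)
        assert p_s == pytest.approx(0.2439, abs=2e-4)
        assert 1 - 4 * p_s == pytest.approx(0.0244, abs=2e-4)
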
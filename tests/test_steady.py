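"""Product-form weights, conditioned distributions, connecting states,
and rank analysis."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import catnet as cn
from catnet.steady import (
    _ordered_partition,
    extract_product_families,
    lambda_residual,
)


class TestPairMatrix:
    def test_three_species_structure(self, triangle_a):
        # row/column layout over pairs (1,2),(1,3),(2,3)
        A, pairs = cn.lambda_pair_matrix(triangle_a.network)
        assert pairs == [(1, 2), (1, 3), (2, 3)]
        R = triangle_a.network.rate
        expected = [
            [-R(1, 2, 3) - R(2, 1, 3), R(3, 1, 2), R(3, 2, 1)],
            [R(2, 1, 3), -R(1, 3, 2) - R(3, 1, 2), R(2, 3, 1)],
            [R(1, 2, 3), R(1, 3, 2), -R(2, 3, 1) - R(3, 2, 1)],
        ]
        assert A == expected

    def test_singular_for_any_three_species_network(self, triangle_a,
                                                    triangle_b, triangle_c):
        for fx in (triangle_a, triangle_b, triangle_c):
            A, _ = cn.lambda_pair_matrix(fx.network)
            det = (
                A[0][0] * (A[1][1] * A[2][2] - A[1][2] * A[2][1])
                - A[0][1] * (A[1][0] * A[2][2] - A[1][2] * A[2][0])
                + A[0][2] * (A[1][0] * A[2][1] - A[1][1] * A[2][0])
            )
            assert det == 0

    def test_five_component_matrix_size(self, five_component):
        fx, _ = five_component
        A, pairs = cn.lambda_pair_matrix(fx.network)
        assert len(A) == len(pairs) == 10


class TestLambdaClosedForm:
    def test_exact_fractions(self, triangle_a, triangle_c):
        sol = cn.solve_lambda_M3(triangle_a.network)
        assert sol.lambdas == (
            Fraction(2, 11), Fraction(3, 11), Fraction(6, 11)
        )
        assert sol.classification == "nontrivial"
        assert sol.residual == 0.0
        sol_c = cn.solve_lambda_M3(triangle_c.network)
        assert sol_c.lambdas == (
            Fraction(1, 1000), Fraction(1, 3), Fraction(1997, 3000)
        )

    def test_one_vanishing_invariant_is_trivial(self, triangle_b):
        sol = cn.solve_lambda_M3(triangle_b.network)
        assert sol.Lambdas == (0, 2, 4)
        assert sol.classification == "trivial_WTA"
        assert sol.lambdas == (1, 0, 0)

    def test_two_vanishing_invariants_indefinite(self):
        # single reaction: two of the three invariants vanish
        net = cn.validate_network({(1, 2, 3): 1}, 3)
        sol = cn.solve_lambda_M3(net)
        assert sol.classification == "indefinite"
        assert sol.lambdas is None

    def test_general_path_agrees(self, triangle_a, triangle_c):
        for fx in (triangle_a, triangle_c):
            closed = cn.solve_lambda_M3(fx.network)
            general = cn.solve_lambda_general(fx.network)
            assert isinstance(general, cn.LambdaSolution)
            assert general.lambdas == closed.lambdas

    @pytest.mark.parametrize("seed", range(25))
    def test_random_networks_residual(self, seed):
        net = cn.random_network(3, 1.0, seed)
        sol = cn.solve_lambda_M3(net)
        if sol.classification == "nontrivial":
            assert lambda_residual(net, sol.lambdas) < 1e-10
            assert sum(sol.lambdas) == 1
            assert all(0 < v < 1 for v in sol.lambdas)


class TestLambdaFamily:
    def test_five_component_nullspace_and_branches(self, five_component):
        fx, _ = five_component
        fam = cn.solve_lambda_general(fx.network)
        assert isinstance(fam, cn.LambdaFamily)
        assert fam.dimension == 6
        supports = {f.support for f in fam.families}
        assert supports == {
            (1, 2), (1, 3), (2, 4), (3, 4), (1, 3, 5), (2, 4, 5),
        }
        # the three-species branches carry the equal-split constraint
        b = fam.find((2, 4, 5))
        lam = b.sample(Fraction(1, 3))  # lam5 = 1/3
        assert lam == (0, Fraction(1, 3), 0, Fraction(1, 3), Fraction(1, 3))
        assert lambda_residual(fx.network, lam) == 0

    def test_four_component_branches(self):
        fx, _ = cn.convert_2tk("four_component_a")
        fam = cn.solve_lambda_general(fx.network)
        assert isinstance(fam, cn.LambdaFamily)
        supports = {f.support for f in fam.families}
        assert {(3, 4), (2, 4), (1, 3)} <= supports
        for support in ((3, 4), (2, 4), (1, 3)):
            lam = fam.find(support).sample(Fraction(2, 5))
            assert lambda_residual(fx.network, lam) == 0

    def test_family_samples_satisfy_condition(self, five_component):
        fx, _ = five_component
        for branch in extract_product_families(fx.network):
            for c in (Fraction(1, 8), Fraction(1, 4), Fraction(2, 5)):
                lam = branch.sample(c)
                assert sum(lam) == 1
                assert lambda_residual(fx.network, lam) == 0


class TestConditionedProductForm:
    def test_hand_computed_probability(self):
        lam = (Fraction(2, 11), Fraction(3, 11), Fraction(6, 11))
        d = cn.pgfwowtas_distribution(lam, 2)
        assert d.prob((1, 1, 0)) == pytest.approx(1 / 6)

    def test_zero_on_wta_and_normalised(self, triangle_a):
        lam = cn.solve_lambda_M3(triangle_a.network).lambdas
        for N in (2, 5, 9):
            d = cn.pgfwowtas_distribution(lam, N)
            for idx in d.space.wta_indices():
                assert d.p[idx] == 0.0
            assert d.p.sum() == pytest.approx(1.0)

    def test_uniform_weights_proportional_to_multinomial(self):
        lam = (Fraction(1, 3),) * 3
        d = cn.pgfwowtas_distribution(lam, 3)
        assert d.prob((1, 1, 1)) / d.prob((2, 1, 0)) == pytest.approx(2.0)

    def test_trivial_weight_rejected(self):
        with pytest.raises(ValueError, match="winner-takes-all"):
            cn.pgfwowtas_distribution((1, 0, 0), 4)

    def test_marginal_hand_value_and_top_zero(self):
        lam = (Fraction(2, 11), Fraction(3, 11), Fraction(6, 11))
        m = cn.pgfwowtas_marginal(lam, 3, 2)
        assert m[1] == pytest.approx(5 / 6)
        assert m[2] == 0.0
        assert m.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [2, 3, 6])
    def test_marginal_consistent_with_distribution(self, triangle_a, N):
        lam = cn.solve_lambda_M3(triangle_a.network).lambdas
        d = cn.pgfwowtas_distribution(lam, N)
        for i in (1, 2, 3):
            from_dist = cn.marginal_from_distribution(d, i)
            direct = cn.pgfwowtas_marginal(lam, i, N)
            assert np.abs(from_dist - direct).max() < 1e-12

    @pytest.mark.parametrize("N", [2, 4, 7])
    def test_moments_consistent_with_distribution(self, triangle_a, N):
        lam = cn.solve_lambda_M3(triangle_a.network).lambdas
        params = cn.SystemParams(N=N, rho=1.0, epsilon=0)
        d = cn.pgfwowtas_distribution(lam, N)
        direct = cn.pgfwowtas_moments(lam, N, 1)
        summed = cn.moments_from_distribution(d, params)
        for i in (1, 2, 3):
            assert float(direct.first[i]) == pytest.approx(
                summed.first[i], abs=1e-12
            )
            assert float(direct.var(i)) == pytest.approx(
                summed.var(i), abs=1e-12
            )
        for p in summed.second_cross:
            assert float(direct.second_cross[p]) == pytest.approx(
                summed.second_cross[p], abs=1e-12
            )

    def test_large_N_limit(self):
        lam = (0.2, 0.3, 0.5)
        mom = cn.pgfwowtas_moments(lam, 400, 1.0)
        for i, li in enumerate(lam, start=1):
            assert mom.first[i] == pytest.approx(li, abs=1e-12)
            assert mom.var(i) == pytest.approx(0.0, abs=1e-2)


class TestConnectingState:
    def test_kappa_exact(self, triangle_b):
        kap = cn.kappa_solve(triangle_b.network, 1)
        assert kap.kappa == {2: Fraction(2, 3), 3: Fraction(1, 3)}
        assert kap.residual <= 1e-12
        assert kap.lambda_definite

    def test_substrate_dominant_rejected(self, triangle_a):
        with pytest.raises(ValueError, match="substrate"):
            cn.kappa_solve(triangle_a.network, 1)

    def test_connecting_state_statistics(self, triangle_b):
        kap = cn.kappa_solve(triangle_b.network, 1)
        dist, marginals, mom = cn.cstowtas(kap, 10, 1)
        assert float(dist.p.sum()) == pytest.approx(1.0)
        assert mom.first[1] == Fraction(9, 10)
        assert mom.first[2] == Fraction(2, 30)
        assert mom.first[3] == Fraction(1, 30)
        assert mom.var(1) == 0
        assert mom.var(2) == Fraction(2, 3) * Fraction(1, 3) / 100
        assert marginals[1][9] == 1.0
        assert marginals[2][1] == pytest.approx(2 / 3)

    @pytest.mark.parametrize("lam1", [0.9, 0.99, 0.999])
    def test_product_form_limit_approaches_connecting_state(
        self, triangle_b, lam1
    ):
        # push the dominant weight toward one along the fixed-ratio path
        kap = cn.kappa_solve(triangle_b.network, 1)
        k2, k3 = float(kap.kappa[2]), float(kap.kappa[3])
        lam = (lam1, k2 * (1 - lam1), k3 * (1 - lam1))
        N = 10
        mom = cn.pgfwowtas_moments(lam, N, 1.0)
        _, _, limit = cn.cstowtas(kap, N, 1)
        for i in (1, 2, 3):
            assert float(mom.first[i]) == pytest.approx(
                float(limit.first[i]), abs=(1 - lam1) * 2
            )


class TestRankAnalysis:
    def test_ordering_helper_groups_ties(self):
        part = _ordered_partition({1: 1, 2: 2, 3: 1})
        assert part == ((1, 3), (2,))

    def test_concentration_rank_conserved(self, triangle_c):
        lam = cn.solve_lambda_M3(triangle_c.network).lambdas
        rep = cn.rank_analysis(lam, Fraction(1), range(2, 21))
        assert rep.conc_rank_conserved

    def test_variance_exchanges(self, triangle_c):
        lam = cn.solve_lambda_M3(triangle_c.network).lambdas
        rep = cn.rank_analysis(lam, Fraction(1), range(2, 21))
        assert rep.variance_exchanges == [3, 7]

    def test_equal_weights_tie_everywhere(self):
        lam = (Fraction(1, 3),) * 3
        rep = cn.rank_analysis(lam, Fraction(1), range(2, 10))
        for N in rep.N_values:
            assert rep.conc_orderings[N] == ((1, 2, 3),)
        assert rep.variance_exchanges == []


@given(
    a=st.integers(min_value=1, max_value=50),
    b=st.integers(min_value=1, max_value=50),
    c=st.integers(min_value=1, max_value=50),
    N=st.integers(min_value=2, max_value=40),
)
@settings(max_examples=60, deadline=None)
def test_rank_conservation_property(a, b, c, N):
    """Concentration ordering equals the weight ordering at every N."""
    total = a + b + c
    lam = (Fraction(a, total), Fraction(b, total), Fraction(c, total))
    mom = cn.pgfwowtas_moments(lam, N, Fraction(1))
    for i in range(3):
        for j in range(3):
            if lam[i] < lam[j]:
                assert mom.first[i + 1] < mom.first[j + 1]
            elif lam[i] == lam[j]:
                assert mom.first[i + 1] == mom.first[j + 1]


@given(
    a=st.integers(min_value=1, max_value=30),
    b=st.integers(min_value=1, max_value=30),
    c=st.integers(min_value=1, max_value=30),
    N=st.integers(min_value=2, max_value=30),
)
@settings(max_examples=40, deadline=None)
def test_marginal_normalisation_and_nonnegative_variance(a, b, c, N):
    total = a + b + c
    lam = (Fraction(a, total), Fraction(b, total), Fraction(c, total))
    if any(v == 1 for v in lam):
        return
    m = cn.pgfwowtas_marginal(lam, 1, N)
    assert m.sum() == pytest.approx(1.0)
    mom = cn.pgfwowtas_moments(lam, N, Fraction(1))
    assert all(mom.var(i) >= 0 for i in (1, 2, 3))
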
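"""Tests for the weak-selection favourability analysis."""

import numpy as np
import pytest

from reciprocity.game import ALLC, ALLD, PARADOX, TFT, WSLS, GameParams
from reciprocity.moran import MoranParams
from reciprocity.rare_mutation import equilibrium
from reciprocity.spaces import appendix_refined_grid, build_space
from reciprocity.weak_selection import (
    L_continuous,
    L_finite,
    classify_archetype,
    fixation_slope,
    memory_one_stage1_candidates,
    most_favoured,
    pair_slope_difference,
    quadrature_gap,
    slope_from_payoffs,
)
from reciprocity._kernels import fixation_batch, pair_stats_batch

N = 100
GAME = GameParams(c=0.2, epsilon=0.01)


class TestFixationSlope:
    def test_self_invasion_has_zero_slope(self):
        assert fixation_slope(WSLS, WSLS, GAME, N) == pytest.approx(0.0, abs=1e-14)

    def test_payoff_neutral_pair_has_zero_slope(self):
        assert slope_from_payoffs(0.7, 0.7, 0.7, 0.7, N) == pytest.approx(0.0, abs=1e-15)

    def test_analytic_matches_finite_difference(self, rng):
        fixation_slope(TFT, ALLD, GAME, N, cross_validate=True)
        for _ in range(5):
            p, q = rng.random(4), rng.random(4)
            fixation_slope(p, q, GAME, N, cross_validate=True)

    def test_pairwise_reduction_identity(self, rng):
        # slope(p->q) - slope(q->p) collapses to a single expression in the
        # four pairwise payoffs; check against the two slopes evaluated
        # separately
        for _ in range(5):
            p, q = rng.random(4), rng.random(4)
            direct = fixation_slope(p, q, GAME, N) - fixation_slope(q, p, GAME, N)
            pi_pq, pi_qp, _, _ = pair_stats_batch(p[None], q[None], GAME.c, GAME.epsilon)
            pi_pp = pair_stats_batch(p[None], p[None], GAME.c, GAME.epsilon)[0]
            pi_qq = pair_stats_batch(q[None], q[None], GAME.c, GAME.epsilon)[0]
            reduced = pair_slope_difference(pi_pq[0], pi_qp[0], pi_pp[0], pi_qq[0], N)
            assert reduced == pytest.approx(direct, rel=1e-10, abs=1e-15)


class TestFiniteSpaceCoefficients:
    def test_coefficients_sum_to_zero(self):
        for kind in ("deterministic-reactive", "deterministic-memory-one"):
            L = L_finite(build_space(kind), GAME, N)
            assert L.sum() == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("c", np.round(np.arange(0.1, 0.91, 0.1), 10))
    def test_alld_always_on_top_among_deterministic_reactive(self, c):
        space = build_space("deterministic-reactive")
        L = L_finite(space, GameParams(c=float(c), epsilon=0.01), N)
        assert int(np.argmax(L)) == space.index_of(ALLD)

    @pytest.mark.parametrize("c", np.round(np.arange(0.1, 0.91, 0.1), 10))
    def test_alld_and_wsls_favoured_for_all_costs(self, c):
        space = build_space("deterministic-memory-one")
        L = L_finite(space, GameParams(c=float(c), epsilon=0.01), N)
        assert L[space.index_of(ALLD)] > 0
        assert L[space.index_of(WSLS)] > 0

    @pytest.mark.parametrize("c", [0.2, 0.6])
    @pytest.mark.parametrize("kind", ["deterministic-reactive", "deterministic-memory-one"])
    def test_sign_and_ranking_match_equilibrium_deviation(self, kind, c):
        # at small w the equilibrium deviates from uniform proportionally to
        # L; signs and rankings must agree wherever the first-order term is
        # not degenerate (strategies with L = 0 are decided at second order)
        space = build_space(kind)
        game = GameParams(c=c, epsilon=0.01)
        L = L_finite(space, game, N)
        eq = equilibrium(space, game, MoranParams(N, 1e-4))
        dev = space.n * eq.xi - 1.0
        keep = np.abs(L) > 1e-10 * np.abs(L).max()
        assert np.all(np.sign(L[keep]) == np.sign(dev[keep]))
        order_L = np.argsort(L[keep])
        order_dev = np.argsort(dev[keep])
        np.testing.assert_array_equal(order_L, order_dev)


class TestContinuousCoefficients:
    def test_quadrature_refinement_stability(self, rng):
        for kind, n_random in (("reactive", 10), ("memory-one", 10)):
            for _ in range(n_random):
                p = rng.random(4)
                if kind == "reactive":
                    p = p[[0, 1, 0, 1]]
                _, _, gap = quadrature_gap(p, kind, GAME, N, order=16)
                assert gap < 1e-4

    def test_paradox_beats_allc_at_intermediate_cost(self):
        game = GameParams(c=0.5, epsilon=0.01)
        assert L_continuous(PARADOX, "memory-one", game, N, order=16) > \
            L_continuous(ALLC, "memory-one", game, N, order=16)

    def test_grid_and_integral_agree_on_reactive_space(self):
        # evaluating L via the continuous mutant integral at the points of a
        # fine reactive grid must reproduce the finite-space coefficients up
        # to discretisation error (the finite sum is a Riemann approximation
        # of the integral, modulo the boundary weights)
        space = build_space("reactive-grid", m=20)
        Lf = L_finite(space, GAME, N) / space.n
        Lc = np.array([
            L_continuous(p, "reactive", GAME, N, order=24) for p in space.strategies[::21]
        ])
        # compare on the subsample: same signs for clearly non-zero entries
        sub = Lf[::21]
        strong = np.abs(Lc) > 0.02
        assert np.all(np.sign(sub[strong]) == np.sign(Lc[strong]))


class TestMostFavoured:
    def test_reactive_low_cost_is_generous(self):
        res = most_favoured("reactive", GameParams(c=0.1, epsilon=0.01), N,
                            order=24, max_iter=100)
        assert res.strategy[0] > 0.95  # full reciprocation of cooperation
        assert res.strategy[1] > 0.02  # positive forgiveness after defection
        assert classify_archetype(res.strategy) == "cooperative"

    def test_reactive_high_cost_is_alld(self):
        res = most_favoured("reactive", GameParams(c=0.5, epsilon=0.01), N,
                            order=24, max_iter=100)
        np.testing.assert_allclose(res.strategy, 0.0, atol=0.005)
        assert classify_archetype(res.strategy) == "defective"

    def test_memory_one_low_cost_is_wsls_variant(self):
        res = most_favoured("memory-one", GameParams(c=0.2, epsilon=0.01), N,
                            order=16, stage1=memory_one_stage1_candidates(),
                            max_iter=60)
        p = res.strategy
        assert p[0] > 0.9 and p[1] < 0.1 and p[2] < 0.1  # (≈1, ≈0, ≈0, x)

    def test_unconditional_space_favours_defection(self):
        for c in (0.1, 0.5, 0.9):
            res = most_favoured("unconditional", GameParams(c=c, epsilon=0.01),
                                N, order=24, max_iter=50)
            assert classify_archetype(res.strategy) == "defective"

    def test_stage_two_never_worse_than_stage_one(self):
        res = most_favoured("reactive", GAME, N, order=24, max_iter=50)
        assert res.L >= res.stage1_L - 1e-15

    def test_stage1_mesh_refinement(self):
        # where the optimum sits on a wide basin (c = 0.2, WSLS face) the
        # 11- and 17-value stage-1 meshes give the same final optimum; where
        # the landscape varies on the error scale (c = 0.5, paradoxical
        # corner with p_dd ~ 2 epsilon) the error-scale mesh is *necessary*:
        # the coarse mesh starts the ascent in the wrong basin and the
        # refined mesh finds a strictly better maximiser
        coarse = build_space("memory-one-grid", m=10)
        fine = appendix_refined_grid("memory-one")

        def pair(c):
            game = GameParams(c=c, epsilon=0.01)
            return (
                most_favoured("memory-one", game, N, order=8, stage1=coarse,
                              max_iter=200),
                most_favoured("memory-one", game, N, order=8, stage1=fine,
                              max_iter=200),
            )

        r_coarse, r_fine = pair(0.2)
        np.testing.assert_allclose(r_coarse.strategy, r_fine.strategy, atol=1e-3)

        r_coarse, r_fine = pair(0.5)
        assert r_fine.L > r_coarse.L + 1e-3
        p = r_fine.strategy
        assert p[0] < 0.1 and p[1] > 0.9 and p[3] < 0.1  # (0, 1, 0, ~0) form


class TestArchetypeClassifier:
    @pytest.mark.parametrize(
        "p, label",
        [
            ((1.0, 0.1, 1.0, 0.1), "cooperative"),
            ((1.0, 0.0, 0.0, 0.3), "cooperative"),
            ((0.0, 0.0, 0.0, 0.0), "defective"),
            ((0.003, 0.0, 0.001, 0.0), "defective"),
            ((0.0, 1.0, 0.0, 0.0), "intermediate"),
            ((0.0, 0.15, 0.0, 0.15), "intermediate"),
        ],
    )
    def test_labels(self, p, label):
        assert classify_archetype(p) == label
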
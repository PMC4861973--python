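"""Selection-mutation equilibrium over a finite strategy space.

When mutations are sufficiently rare the population is almost always
homogeneous, and evolution reduces to a Markov chain over monomorphic
states: from a resident ``p^j`` the next mutant is one of the other
``n - 1`` strategies uniformly at random, and it replaces the resident with
its fixation probability.  The chain's invariant distribution ``xi`` gives
the long-run fraction of time each strategy is resident; population
averages (payoff, cooperation) weight each strategy's *self-play* values by
``xi`` because the population is homogeneous almost always.

The overall mutation rate only rescales every off-diagonal entry by a
common factor, which leaves ``xi`` unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import fixation_batch, pair_stats_batch
from .game import GameParams
from .moran import MoranParams
from .spaces import StrategySpace

__all__ = [
    "EquilibriumSummary",
    "pairwise_tables",
    "fixation_matrix",
    "embedded_chain",
    "stationary_of_chain",
    "equilibrium",
]

_DENSE_LIMIT = 5000


@dataclass(frozen=True)
class EquilibriumSummary:
    """Invariant distribution over a strategy space with population averages."""

    space: StrategySpace
    xi: np.ndarray
    self_payoffs: np.ndarray
    self_cooperation: np.ndarray
    mean_payoff: float
    mean_cooperation: float


def pairwise_tables(space: StrategySpace, game: GameParams) -> tuple[np.ndarray, np.ndarray]:
    """Payoff and cooperation tables ``pi[i, j] = pi(p_i, p_j)`` for a space.

    Both directions of every unordered pair come from a single stationary
    solve, so only ``n (n - 1) / 2`` chains are solved (plus the diagonal).
    """
    S = space.strategies
    n = len(S)
    iu, ju = np.triu_indices(n, k=1)
    pi = np.empty((n, n))
    gamma = np.empty((n, n))
    p1, p2, g1, g2 = pair_stats_batch(S[iu], S[ju], game.c, game.epsilon)
    pi[iu, ju] = p1
    pi[ju, iu] = p2
    gamma[iu, ju] = g1
    gamma[ju, iu] = g2
    d1, _, dg, _ = pair_stats_batch(S, S, game.c, game.epsilon)
    pi[np.diag_indices(n)] = d1
    gamma[np.diag_indices(n)] = dg
    return pi, gamma


def fixation_matrix(space: StrategySpace, game: GameParams, moran: MoranParams) -> np.ndarray:
    """Matrix ``rho[j, k]``: fixation probability of mutant ``k`` in resident ``j``."""
    pi, _ = pairwise_tables(space, game)
    n = len(pi)
    diag = np.diag(pi)
    # mutant k invading resident j: pi_mm = pi[k,k], pi_mr = pi[k,j],
    # pi_rm = pi[j,k], pi_rr = pi[j,j]
    pi_mm = np.broadcast_to(diag[None, :], (n, n))
    pi_rr = np.broadcast_to(diag[:, None], (n, n))
    rho = fixation_batch(pi_mm, pi.T, pi, pi_rr, moran.N, moran.w)
    return rho


def embedded_chain(
    space: StrategySpace,
    game: GameParams,
    moran: MoranParams,
    mu: float = 1.0,
) -> np.ndarray:
    """Transition matrix of the rare-mutation chain over monomorphic states.

    Off-diagonal entry ``(j, k)`` is ``mu * rho(p_k into p_j) / (n - 1)``;
    the diagonal absorbs the rest of the row.  ``mu`` rescales all
    off-diagonal entries uniformly and does not affect the invariant
    distribution.
    """
    if space.n < 2:
        raise ValueError("the embedded chain needs at least two strategies")
    if not (0.0 < mu <= 1.0):
        raise ValueError("mutation factor mu must lie in (0, 1]")
    rho = fixation_matrix(space, game, moran)
    n = len(rho)
    M = mu * rho / (n - 1)
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    if np.any(np.diag(M) < 0):
        raise ArithmeticError("negative diagonal in embedded chain")
    return M


def stationary_of_chain(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Invariant distribution of an irreducible row-stochastic matrix.

    Dense null-space solve with a normalisation constraint for chains up to
    ~5000 states; iterative eigensolver above that.
    """
    M = np.asarray(M, dtype=float)
    n = len(M)
    if n == 1:
        return np.ones(1)
    if n <= _DENSE_LIMIT:
        A = M.T - np.eye(n)
        A[-1, :] = 1.0
        b = np.zeros(n)
        b[-1] = 1.0
        xi = np.linalg.solve(A, b)
    else:  # pragma: no cover - very large grids only
        from scipy.sparse.linalg import eigs

        vals, vecs = eigs(M.T, k=1, sigma=1.0 + 1e-9, which="LM")
        xi = np.real(vecs[:, 0])
        xi = xi / xi.sum()
    xi = np.where(np.abs(xi) < tol, np.maximum(xi, 0.0), xi)
    if np.any(xi < -tol):
        raise ArithmeticError("invariant distribution has negative entries")
    return xi / xi.sum()


def equilibrium(
    space: StrategySpace, game: GameParams, moran: MoranParams
) -> EquilibriumSummary:
    """Selection-mutation equilibrium and its population averages."""
    if space.n == 1:
        _, _, g, _ = pair_stats_batch(space.strategies, space.strategies, game.c, game.epsilon)
        p, _, _, _ = pair_stats_batch(space.strategies, space.strategies, game.c, game.epsilon)
        return EquilibriumSummary(
            space=space,
            xi=np.ones(1),
            self_payoffs=p,
            self_cooperation=g,
            mean_payoff=float(p[0]),
            mean_cooperation=float(g[0]),
        )
    M = embedded_chain(space, game, moran)
    xi = stationary_of_chain(M)
    self_pi, _, self_g, _ = pair_stats_batch(
        space.strategies, space.strategies, game.c, game.epsilon
    )
    return EquilibriumSummary(
        space=space,
        xi=xi,
        self_payoffs=self_pi,
        self_cooperation=self_g,
        mean_payoff=float(xi @ self_pi),
        mean_cooperation=float(xi @ self_g),
    )
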
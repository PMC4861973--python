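"""Frequency-dependent Moran process: fixation probabilities and invasions.

A finite population of ``N`` players contains ``i`` mutants with strategy
``p`` and ``N - i`` residents with strategy ``q``.  Everybody plays the
repeated game against everybody else (no self-interaction); fitness is the
linear map ``1 + w * payoff`` with selection strength ``w >= 0``, which is
positive for every admissible payoff.  Reproduction is fitness-proportional,
death is uniform (birth-death updating).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import game as _game
from ._kernels import fixation_batch, pair_stats_batch
from .game import GameParams, StrategyLike, as_strategy_array

__all__ = [
    "MoranParams",
    "InvasionVerdict",
    "group_payoffs",
    "fixation_probability",
    "classify_invasion",
    "is_evolutionary_robust",
    "birth_death_rates",
]


@dataclass(frozen=True)
class MoranParams:
    """Population size ``N >= 2`` and selection strength ``w >= 0``."""

    N: int
    w: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"population size N={self.N!r} must be an integer >= 2")
        if self.w < 0:
            raise ValueError(f"selection strength w={self.w!r} must be >= 0")


@dataclass(frozen=True)
class InvasionVerdict:
    """Fixation probability of a single mutant and its comparison with 1/N."""

    rho: float
    classification: str  # "advantageous" | "neutral" | "disadvantageous"


def _pairwise_payoffs(p: StrategyLike, q: StrategyLike, game: GameParams):
    """The four payoffs pi(p,p), pi(p,q), pi(q,p), pi(q,q)."""
    pa, qa = as_strategy_array(p), as_strategy_array(q)
    pi_pq, pi_qp, _, _ = pair_stats_batch(pa[None, :], qa[None, :], game.c, game.epsilon)
    pi_pp = _game.self_play(pa, game).payoff_focal
    pi_qq = _game.self_play(qa, game).payoff_focal
    return pi_pp, float(pi_pq[0]), float(pi_qp[0]), pi_qq


def group_payoffs(
    p: StrategyLike,
    q: StrategyLike,
    i: int,
    game: GameParams,
    N: int,
) -> tuple[float, float]:
    """Average payoffs of the two groups when ``i`` players use ``p``.

    Each player interacts with the other ``N - 1`` players but not with
    itself::

        pi_p(i) = [(i-1) pi(p,p) + (N-i) pi(p,q)] / (N-1)
        pi_q(i) = [i pi(q,p) + (N-i-1) pi(q,q)] / (N-1)
    """
    if not (1 <= i <= N - 1):
        raise ValueError(f"mutant count i={i} must lie in 1..N-1")
    pi_pp, pi_pq, pi_qp, pi_qq = _pairwise_payoffs(p, q, game)
    pi_p = ((i - 1) * pi_pp + (N - i) * pi_pq) / (N - 1)
    pi_q = (i * pi_qp + (N - i - 1) * pi_qq) / (N - 1)
    return pi_p, pi_q


def fixation_probability(
    mutant: StrategyLike,
    resident: StrategyLike,
    game: GameParams,
    moran: MoranParams,
) -> float:
    """Probability that a single mutant takes over the whole population.

    ``rho = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} g_j / f_j)`` where
    ``f_j`` and ``g_j`` are the mutant and resident group fitnesses at
    mutant count ``j``.  At ``w = 0`` this is exactly ``1/N``.
    """
    if moran.w == 0.0:
        return 1.0 / moran.N
    pi_mm, pi_mr, pi_rm, pi_rr = _pairwise_payoffs(mutant, resident, game)
    rho = fixation_batch(pi_mm, pi_mr, pi_rm, pi_rr, moran.N, moran.w)
    rho = float(rho[0])
    if not (0.0 < rho < 1.0):
        raise ArithmeticError(f"fixation probability {rho} outside (0, 1)")
    return rho


def classify_invasion(
    mutant: StrategyLike,
    resident: StrategyLike,
    game: GameParams,
    moran: MoranParams,
    rtol: float = 1e-12,
) -> InvasionVerdict:
    """Compare the mutant's fixation probability with the neutral value 1/N."""
    rho = fixation_probability(mutant, resident, game, moran)
    neutral = 1.0 / moran.N
    if rho > neutral * (1.0 + rtol):
        label = "advantageous"
    elif rho < neutral * (1.0 - rtol):
        label = "disadvantageous"
    else:
        label = "neutral"
    return InvasionVerdict(rho=rho, classification=label)


def is_evolutionary_robust(
    resident: StrategyLike,
    mutants: Iterable[Sequence[float]],
    game: GameParams,
    moran: MoranParams,
) -> tuple[bool, list[np.ndarray]]:
    """A resident is evolutionary robust if no mutant is advantageous.

    ``mutants`` may be a :class:`~reciprocity.spaces.StrategySpace` or any
    iterable of strategies; the resident itself (neutral by definition) is
    ignored.  Returns the verdict and the list of advantageous mutants.
    """
    res = as_strategy_array(resident)
    M = np.array([as_strategy_array(m) for m in mutants], dtype=float)
    mask = ~np.all(M == res, axis=1)
    M = M[mask]
    if len(M) == 0:
        return True, []
    c, eps = game.c, game.epsilon
    pi_mr, pi_rm, _, _ = pair_stats_batch(M, res, c, eps)
    pi_mm = pair_stats_batch(M, M, c, eps)[0]
    pi_rr = _game.self_play(res, game).payoff_focal
    rho = fixation_batch(pi_mm, pi_mr, pi_rm, np.full(len(M), pi_rr), moran.N, moran.w)
    adv = rho > (1.0 / moran.N) * (1.0 + 1e-12)
    return not bool(adv.any()), [m for m in M[adv]]


def birth_death_rates(
    mutant: StrategyLike,
    resident: StrategyLike,
    game: GameParams,
    moran: MoranParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state transition probabilities ``(T+, T-)`` of the birth-death chain.

    ``T+_i`` is the probability that the mutant count goes from ``i`` to
    ``i + 1`` in one step (a mutant is chosen to reproduce and a resident
    dies), ``T-_i`` the reverse.  Indexed ``i = 1..N-1``.  Only their ratio
    enters the fixation probability; the full rates exist for the small-N
    absorption oracle.
    """
    N, w = moran.N, moran.w
    i = np.arange(1, N)
    pi_m = np.empty(N - 1)
    pi_r = np.empty(N - 1)
    for k, ii in enumerate(i):
        pi_m[k], pi_r[k] = group_payoffs(mutant, resident, int(ii), game, N)
    f = 1.0 + w * pi_m
    g = 1.0 + w * pi_r
    t_plus = (i * f / (i * f + (N - i) * g)) * (N - i) / N
    t_minus = ((N - i) * g / (i * f + (N - i) * g)) * i / N
    return t_plus, t_minus
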
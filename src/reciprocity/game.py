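"""Exact analysis of one infinitely repeated prisoner's dilemma.

Two players with memory-one strategies and implementation errors play the
(shifted) donation game for infinitely many rounds.  The per-round play forms
a Markov chain over the four outcomes ``CC, CD, DC, DD`` (focal player's
action first).  With a positive error rate the chain is primitive, so it has
a unique invariant distribution ``v`` from which long-run payoffs and
cooperation rates follow exactly.

Payoff convention: the benefit of cooperation is fixed to ``b = 1``, the cost
is ``0 < c < 1``, and all payoffs are shifted by ``+c`` so that they are
non-negative.  The focal player's per-state payoff vector is
``h1 = (1, 0, 1+c, c)`` and the co-player's is ``h2 = (1, 1+c, 0, c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "STATES",
    "Strategy",
    "GameParams",
    "PairOutcome",
    "ALLC",
    "ALLD",
    "TFT",
    "ATFT",
    "WSLS",
    "GRIM",
    "PARADOX",
    "gtft",
    "as_strategy_array",
    "effective_strategy",
    "pair_transition_matrix",
    "stationary_distribution",
    "pair_outcome",
    "self_play",
    "limit_payoff",
    "classify_self_play",
]

#: Global state order: focal player's previous action first.
STATES = ("CC", "CD", "DC", "DD")

#: Column permutation mapping the focal state (i, j) to the co-player's
#: view (j, i): CC->CC, CD->DC, DC->CD, DD->DD.
_TRANSPOSE = np.array([0, 2, 1, 3])

StrategyLike = Union["Strategy", Sequence[float], np.ndarray]


@dataclass(frozen=True)
class Strategy:
    """A memory-one strategy: four conditional cooperation probabilities.

    ``p_ij`` is the probability to cooperate in the next round given that the
    focal player's previous action was ``i`` and the co-player's was ``j``.
    """

    p_cc: float
    p_cd: float
    p_dc: float
    p_dd: float

    def __post_init__(self) -> None:
        for name in ("p_cc", "p_cd", "p_dc", "p_dd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "Strategy":
        a = np.asarray(list(arr), dtype=float)
        if a.shape != (4,):
            raise ValueError("a memory-one strategy needs exactly 4 entries")
        return cls(*a)

    def as_array(self) -> np.ndarray:
        return np.array([self.p_cc, self.p_cd, self.p_dc, self.p_dd])

    @property
    def is_reactive(self) -> bool:
        """True when the strategy conditions only on the co-player's move."""
        return self.p_cc == self.p_dc and self.p_cd == self.p_dd

    @property
    def is_deterministic(self) -> bool:
        return all(v in (0.0, 1.0) for v in self.as_array())

    @property
    def is_unconditional(self) -> bool:
        return self.p_cc == self.p_cd == self.p_dc == self.p_dd

    def __iter__(self):
        return iter(self.as_array())


ALLC = Strategy(1, 1, 1, 1)
ALLD = Strategy(0, 0, 0, 0)
TFT = Strategy(1, 0, 1, 0)
ATFT = Strategy(0, 1, 0, 1)  # cooperates iff the co-player defected
WSLS = Strategy(1, 0, 0, 1)  # win-stay lose-shift
GRIM = Strategy(1, 0, 0, 0)  # grim trigger
PARADOX = Strategy(0, 1, 0, 0)  # cooperates only after being exploited


def gtft(c: float, b: float = 1.0) -> Strategy:
    """Generous tit-for-tat: reciprocate cooperation, forgive with 1 - c/b."""
    g = 1.0 - c / b
    return Strategy(1.0, g, 1.0, g)


def as_strategy_array(p: StrategyLike) -> np.ndarray:
    """Coerce a :class:`Strategy` or 4-sequence to a validated float array."""
    if isinstance(p, Strategy):
        return p.as_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (4,):
        raise ValueError(f"expected 4 cooperation probabilities, got shape {a.shape}")
    if np.any(a < 0.0) or np.any(a > 1.0):
        raise ValueError("cooperation probabilities must lie in [0, 1]")
    return a


@dataclass(frozen=True)
class GameParams:
    """Parameters of the shifted donation game.

    Attributes
    ----------
    c:
        Cost of cooperation, ``0 < c < 1`` (the benefit is fixed to 1).
    epsilon:
        Implementation-error probability: each round, a player executes the
        opposite of the intended action with this probability.  Must satisfy
        ``0 <= epsilon < 1/2``; the pair chain is primitive only for
        ``epsilon > 0``.
    """

    c: float
    epsilon: float

    b: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.c < 1.0):
            raise ValueError(f"cost c={self.c!r} must lie in (0, 1)")
        if not (0.0 <= self.epsilon < 0.5):
            raise ValueError(f"error rate epsilon={self.epsilon!r} must lie in [0, 1/2)")

    def payoff_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-state payoff vectors ``(h1, h2)`` over (CC, CD, DC, DD)."""
        c = self.c
        h1 = np.array([1.0, 0.0, 1.0 + c, c])
        h2 = np.array([1.0, 1.0 + c, 0.0, c])
        return h1, h2


@dataclass(frozen=True)
class PairOutcome:
    """Long-run outcome of one repeated game between two strategies."""

    v: np.ndarray  # invariant distribution over (CC, CD, DC, DD)
    payoff_focal: float
    payoff_other: float
    coop_focal: float
    coop_other: float


def effective_strategy(p: StrategyLike, epsilon: float) -> np.ndarray:
    """Apply the implementation error: ``p' = (1 - eps) p + eps (1 - p)``.

    Each entry is mapped into ``[eps, 1 - eps]``; ``eps = 0`` is the identity
    and ``(1/2, 1/2, 1/2, 1/2)`` is a fixed point for every ``eps``.
    """
    if not (0.0 <= epsilon < 0.5):
        raise ValueError(f"error rate epsilon={epsilon!r} must lie in [0, 1/2)")
    a = as_strategy_array(p)
    return (1.0 - 2.0 * epsilon) * a + epsilon


def pair_transition_matrix(p: StrategyLike, q: StrategyLike, epsilon: float) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix of the pair chain.

    From state ``(i, j)`` the focal player cooperates with probability
    ``p'_ij`` while the co-player — who sees the transposed state ``(j, i)``
    — cooperates with probability ``q'_ji``; the two decisions are
    independent, so each row is the outer product of the two Bernoulli
    distributions.  All entries are positive when ``epsilon > 0``.
    """
    pe = effective_strategy(p, epsilon)
    qe = effective_strategy(q, epsilon)[_TRANSPOSE]
    M = np.empty((4, 4))
    M[:, 0] = pe * qe
    M[:, 1] = pe * (1.0 - qe)
    M[:, 2] = (1.0 - pe) * qe
    M[:, 3] = (1.0 - pe) * (1.0 - qe)
    return M


def stationary_distribution(M: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unique invariant distribution of a row-stochastic 4x4 matrix.

    Solved exactly as the left null-space of ``M - I`` with a normalisation
    row.  If the chain is reducible (possible at ``epsilon = 0``) the
    invariant distribution is not unique and a :class:`ValueError` is raised
    rather than silently picking one ergodic component.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError("expected a 4x4 transition matrix")
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows of the transition matrix must sum to 1")
    # uniqueness <=> eigenvalue 1 of M is simple
    eigvals = np.linalg.eigvals(M)
    if np.sum(np.abs(eigvals - 1.0) < 1e-9) > 1:
        raise ValueError(
            "transition matrix is reducible: the invariant distribution is "
            "not unique (this occurs only at epsilon = 0)"
        )
    A = np.vstack([M.T - np.eye(4), np.ones((1, 4))])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    v, *_ = np.linalg.lstsq(A, b, rcond=None)
    v = np.where(np.abs(v) < tol, np.maximum(v, 0.0), v)
    if np.any(v < -tol):
        raise ValueError("invariant distribution has negative entries")
    return v / v.sum()


def pair_outcome(p: StrategyLike, q: StrategyLike, params: GameParams) -> PairOutcome:
    """Exact long-run payoffs and cooperation rates for a strategy pair.

    The focal player's payoff is ``v . h1`` and the co-player's is
    ``v . h2``; the cooperation rates are ``v_CC + v_CD`` (focal) and
    ``v_CC + v_DC`` (co-player).
    """
    M = pair_transition_matrix(p, q, params.epsilon)
    v = stationary_distribution(M)
    h1, h2 = params.payoff_vectors()
    return PairOutcome(
        v=v,
        payoff_focal=float(v @ h1),
        payoff_other=float(v @ h2),
        coop_focal=float(v[0] + v[1]),
        coop_other=float(v[0] + v[2]),
    )


def self_play(p: StrategyLike, params: GameParams) -> PairOutcome:
    """Outcome of a strategy against itself."""
    return pair_outcome(p, p, params)


_EPS_SEQUENCE = (1e-2, 1e-3, 1e-4, 1e-5)


def limit_payoff(
    p: StrategyLike,
    q: StrategyLike,
    c: float,
    eps_pair: tuple[float, float] = (1e-3, 1e-4),
) -> float:
    """Focal payoff in the vanishing-error limit, by linear extrapolation.

    Payoffs are analytic in the error rate, so evaluating at two small error
    rates and extrapolating the linear trend to zero removes the leading
    O(eps) bias.
    """
    e1, e2 = eps_pair
    f1 = pair_outcome(p, q, GameParams(c=c, epsilon=e1)).payoff_focal
    f2 = pair_outcome(p, q, GameParams(c=c, epsilon=e2)).payoff_focal
    return (e1 * f2 - e2 * f1) / (e1 - e2)


def classify_self_play(
    p: StrategyLike,
    c: float,
    eps_sequence: Sequence[float] = _EPS_SEQUENCE,
) -> str:
    """Classify a strategy by its self-play cooperation rate as errors vanish.

    A *self-cooperator* has ``gamma(p, p) -> 1`` and a *self-defector* has
    ``gamma(p, p) -> 0`` as the error rate goes to zero.  The limit is probed
    numerically along a decreasing error sequence: the strategy is classified
    as a self-cooperator when the rate exceeds ``1 - 10 eps`` at the two
    smallest error rates and is increasing along the tail (symmetrically for
    self-defectors); otherwise the limit is interior and the result is
    ``"neither"``.
    """
    eps = sorted(eps_sequence, reverse=True)
    if len(eps) < 2:
        raise ValueError("need at least two error rates to probe the limit")
    gammas = [self_play(p, GameParams(c=c, epsilon=e)).coop_focal for e in eps]
    g1, g2 = gammas[-2], gammas[-1]
    e1, e2 = eps[-2], eps[-1]
    if g1 >= 1.0 - 10.0 * e1 and g2 >= 1.0 - 10.0 * e2 and g2 >= g1 - 1e-12:
        return "self-cooperator"
    if g1 <= 10.0 * e1 and g2 <= 10.0 * e2 and g2 <= g1 + 1e-12:
        return "self-defector"
    return "neither"
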
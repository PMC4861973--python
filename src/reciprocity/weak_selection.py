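"""Weak-selection favourability analysis.

Under weak selection (``w -> 0``) the rare-mutation equilibrium is uniform
to zeroth order, and each strategy's abundance deviates from ``1/n`` by a
term proportional to a linear coefficient ``L``.  The coefficient is the
first-order perturbation of the embedded chain's stationary distribution::

    L_i = sum_{j != i} [ d rho(i into j)/dw - d rho(j into i)/dw ]  at w = 0

and a strategy is *favoured by selection* when ``L_i > 0``.  For continuous
strategy spaces the sum becomes an integral over mutants drawn uniformly
from the space (two-dimensional for reactive strategies, four-dimensional
for memory-one), evaluated by tensor-product Gauss-Legendre quadrature; the
implementation error smooths the integrand, so polynomial quadrature
converges quickly.

The fixation-probability slope has a closed form.  Writing ``pi_m(j)`` and
``pi_r(j)`` for the mutant/resident group payoffs at mutant count ``j``,

    d rho/dw |_0 = (1/N^2) sum_{j=1}^{N-1} (N - j) (pi_m(j) - pi_r(j)),

and the antisymmetric combination entering ``L`` collapses to

    slope(p->q) - slope(q->p)
        = (1/2N) [ N (pi(p,q) - pi(q,p)) + (N-2) (pi(p,p) - pi(q,q)) ],

so each mutant costs a single stationary-distribution solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from ._kernels import fixation_batch, pair_stats_batch
from .game import GameParams, StrategyLike, as_strategy_array
from .rare_mutation import pairwise_tables
from .spaces import StrategySpace, appendix_refined_grid

__all__ = [
    "fixation_slope",
    "pair_slope_difference",
    "L_finite",
    "L_continuous",
    "L_continuous_batch",
    "quadrature_gap",
    "most_favoured",
    "FavouredResult",
    "classify_archetype",
    "regime_boundaries",
    "RegimeScan",
]

_FREE_COORDS = {"memory-one": [0, 1, 2, 3], "reactive": [0, 1], "unconditional": [0]}
_EXPAND = {
    "memory-one": lambda f: f,
    "reactive": lambda f: f[..., [0, 1, 0, 1]],
    "unconditional": lambda f: np.repeat(f, 4, axis=-1),
}


def _slope_weights(N: int) -> tuple[float, float, float, float]:
    j = np.arange(1, N)
    nj = N - j
    return (float(nj @ (j - 1)), float(nj @ nj), float(nj @ j), float(nj @ (nj - 1)))


def slope_from_payoffs(pi_mm, pi_mr, pi_rm, pi_rr, N: int):
    """Closed-form ``d rho/dw`` at ``w = 0`` from the four pairwise payoffs."""
    s1, s2, s3, s4 = _slope_weights(N)
    return (s1 * pi_mm + s2 * pi_mr - s3 * pi_rm - s4 * pi_rr) / (N * N * (N - 1))


def fixation_slope(
    mutant: StrategyLike,
    resident: StrategyLike,
    game: GameParams,
    N: int,
    cross_validate: bool = False,
    fd_step: float = 1e-6,
    fd_rtol: float = 1e-6,
) -> float:
    """Derivative of the fixation probability in ``w`` at ``w = 0``.

    With ``cross_validate=True`` the analytic value is checked against a
    central finite difference of the exact fixation probability at
    ``w = +-fd_step``; a relative disagreement beyond ``fd_rtol`` raises
    :class:`ArithmeticError`.
    """
    m = as_strategy_array(mutant)
    r = as_strategy_array(resident)
    pi_mr, pi_rm, _, _ = pair_stats_batch(m[None, :], r[None, :], game.c, game.epsilon)
    pi_mm = pair_stats_batch(m[None, :], m[None, :], game.c, game.epsilon)[0]
    pi_rr = pair_stats_batch(r[None, :], r[None, :], game.c, game.epsilon)[0]
    slope = float(slope_from_payoffs(pi_mm[0], pi_mr[0], pi_rm[0], pi_rr[0], N))
    if cross_validate:
        rp = fixation_batch(pi_mm, pi_mr, pi_rm, pi_rr, N, +fd_step)[0]
        rm_ = fixation_batch(pi_mm, pi_mr, pi_rm, pi_rr, N, -fd_step)[0]
        fd = (rp - rm_) / (2.0 * fd_step)
        scale = max(abs(fd), abs(slope), 1e-300)
        if abs(fd - slope) / scale > fd_rtol:
            raise ArithmeticError(
                f"analytic slope {slope} disagrees with finite difference {fd}"
            )
    return slope


def pair_slope_difference(pi_pq, pi_qp, pi_pp, pi_qq, N: int):
    """Antisymmetric slope combination ``slope(p->q) - slope(q->p)``."""
    return (N * (pi_pq - pi_qp) + (N - 2) * (pi_pp - pi_qq)) / (2.0 * N)


def L_finite(space: StrategySpace, game: GameParams, N: int) -> np.ndarray:
    """Weak-selection abundance coefficients for every strategy in a space.

    The vector sums to zero (the coefficients are deviations from the
    uniform distribution) and is defined up to a common positive scale;
    only signs and rankings are meaningful.
    """
    pi, _ = pairwise_tables(space, game)
    diag = np.diag(pi)
    D = pair_slope_difference(pi, pi.T, diag[:, None], diag[None, :], N)
    np.fill_diagonal(D, 0.0)
    return D.sum(axis=1)


# Gauss-Legendre tensor rules and mutant self-play integrals, cached per
# (kind, order) and (kind, order, c, epsilon) respectively.
_NODE_CACHE: dict = {}
_SELF_CACHE: dict = {}


def _quad_rule(kind: str, order: int) -> tuple[np.ndarray, np.ndarray]:
    key = (kind, order)
    if key not in _NODE_CACHE:
        x, w = np.polynomial.legendre.leggauss(order)
        x = 0.5 * (x + 1.0)
        w = 0.5 * w
        d = len(_FREE_COORDS[kind])
        grids = np.meshgrid(*([x] * d), indexing="ij")
        free = np.stack([g.ravel() for g in grids], axis=1)
        wgrids = np.meshgrid(*([w] * d), indexing="ij")
        W = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
        Q = np.ascontiguousarray(_EXPAND[kind](free))
        _NODE_CACHE[key] = (Q, W)
    return _NODE_CACHE[key]


def _mutant_self_mean(kind: str, order: int, game: GameParams) -> float:
    key = (kind, order, game.c, game.epsilon)
    if key not in _SELF_CACHE:
        Q, W = _quad_rule(kind, order)
        pi_qq = pair_stats_batch(Q, Q, game.c, game.epsilon)[0]
        _SELF_CACHE[key] = float(W @ pi_qq)
    return _SELF_CACHE[key]


def L_continuous_batch(
    P: np.ndarray,
    kind: str,
    game: GameParams,
    N: int,
    order: int = 24,
    pair_budget: int = 1 << 19,
) -> np.ndarray:
    """Continuous-space weak-selection coefficient for a batch of strategies.

    ``L(p)`` integrates the antisymmetric slope difference over mutants
    drawn uniformly from the strategy class of the given ``kind`` (the
    mutant integral has the class's own dimension).
    """
    if kind not in _FREE_COORDS:
        raise ValueError(f"unknown continuous kind {kind!r}")
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q, W = _quad_rule(kind, order)
    Eqq = _mutant_self_mean(kind, order, game)
    pi_pp = pair_stats_batch(P, P, game.c, game.epsilon)[0]
    nq = len(Q)
    group = max(1, pair_budget // nq)
    L = np.empty(len(P))
    for i0 in range(0, len(P), group):
        Pb = P[i0 : i0 + group]
        nb = len(Pb)
        PP = np.repeat(Pb, nq, axis=0)
        QQ = np.tile(Q, (nb, 1))
        pi_pq, pi_qp, _, _ = pair_stats_batch(PP, QQ, game.c, game.epsilon)
        a = pi_pq.reshape(nb, nq) @ W
        b = pi_qp.reshape(nb, nq) @ W
        L[i0 : i0 + nb] = pair_slope_difference(a, b, pi_pp[i0 : i0 + nb], Eqq, N)
    return L


def L_continuous(
    p: StrategyLike, kind: str, game: GameParams, N: int, order: int = 24
) -> float:
    """Weak-selection coefficient of a single strategy in a continuous space."""
    return float(L_continuous_batch(as_strategy_array(p)[None, :], kind, game, N, order)[0])


def quadrature_gap(
    p: StrategyLike, kind: str, game: GameParams, N: int, order: int = 16
) -> tuple[float, float, float]:
    """``L`` at two quadrature orders and their relative gap.

    Doubling the order should move ``L`` by less than ~1e-4 relative for a
    smooth (error-regularised) integrand; a larger shift signals
    non-convergence of the quadrature.
    """
    l1 = L_continuous(p, kind, game, N, order)
    l2 = L_continuous(p, kind, game, N, 2 * order)
    gap = abs(l1 - l2) / max(abs(l2), 1e-300)
    return l1, l2, gap


@dataclass(frozen=True)
class FavouredResult:
    """Outcome of the two-stage most-favoured-strategy search."""

    strategy: np.ndarray
    L: float
    stage1_strategy: np.ndarray
    stage1_L: float
    converged: bool
    n_iterations: int


def _project(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def _ascend(
    f: Callable[[np.ndarray], float],
    x0: np.ndarray,
    h: float = 1e-4,
    gtol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[np.ndarray, float, bool, int]:
    """Projected gradient ascent on the unit box with backtracking steps."""
    x = np.array(x0, dtype=float)
    fx = f(x)
    it = 0
    for it in range(1, max_iter + 1):
        g = np.zeros_like(x)
        for i in range(len(x)):
            xp = x.copy(); xm = x.copy()
            xp[i] = min(1.0, x[i] + h)
            xm[i] = max(0.0, x[i] - h)
            g[i] = (f(xp) - f(xm)) / (xp[i] - xm[i])
        gnorm = float(np.linalg.norm(g))
        if gnorm < gtol:
            return x, fx, True, it
        step = 0.1
        moved = False
        while step > 1e-12:
            xn = _project(x + step * g / gnorm)
            fn = f(xn)
            if fn > fx + 1e-15:
                x, fx, moved = xn, fn, True
                break
            step *= 0.5
        if not moved:
            # boundary optimum: the projected gradient vanishes even though
            # the raw finite-difference gradient does not
            return x, fx, True, it
    return x, fx, False, it


def most_favoured(
    kind: str,
    game: GameParams,
    N: int,
    order: int = 24,
    stage1: Optional[StrategySpace | np.ndarray] = None,
    max_iter: int = 500,
) -> FavouredResult:
    """Globally search for the strategy most favoured by weak selection.

    Stage 1 evaluates ``L`` on a refined grid (default: 17 values per free
    coordinate, error-scale spacing near the boundary); stage 2 runs
    projected gradient ascent in the kind's free coordinates from the best
    grid point.  Stage-1 ties break lexicographically (the grid is stored
    in lexicographic order and ``argmax`` returns the first maximiser).
    """
    if stage1 is None:
        stage1 = appendix_refined_grid(kind)
    cand = stage1.strategies if isinstance(stage1, StrategySpace) else np.atleast_2d(stage1)
    Lvals = L_continuous_batch(cand, kind, game, N, order)
    best = int(np.argmax(Lvals))
    x0_full = cand[best]
    free_idx = _FREE_COORDS[kind]
    expand = _EXPAND[kind]

    def f(free: np.ndarray) -> float:
        return L_continuous(expand(free), kind, game, N, order)

    x, fx, converged, n_it = _ascend(f, x0_full[free_idx], max_iter=max_iter)
    strategy = expand(x)
    if fx < Lvals[best]:  # never return a worse point than stage 1
        strategy, fx = x0_full, float(Lvals[best])
    return FavouredResult(
        strategy=np.asarray(strategy, dtype=float),
        L=float(fx),
        stage1_strategy=x0_full,
        stage1_L=float(Lvals[best]),
        converged=converged,
        n_iterations=n_it,
    )


def classify_archetype(p: StrategyLike, alld_tol: float = 0.005, coop_min: float = 0.9) -> str:
    """Label a most-favoured strategy as cooperative, defective or intermediate.

    The regimes are identified by the optimum's response to cooperation:
    *cooperative* optima keep cooperating after mutual cooperation
    (``p_cc >= 0.9`` — generous reactive strategies and win-stay-lose-shift
    variants ``(1, 0, 0, x)`` alike); *defective* optima are unconditional
    defection up to below-error-floor probabilities (every coordinate
    ``<= 0.005``); everything else — notably the paradoxical
    ``(0, 1, 0, 0)``-like optima and low-forgiveness reactive strategies —
    is *intermediate*.
    """
    a = as_strategy_array(p)
    if a[0] >= coop_min:
        return "cooperative"
    if np.max(a) <= alld_tol:
        return "defective"
    return "intermediate"


def memory_one_stage1_candidates() -> np.ndarray:
    """Reduced stage-1 grid for memory-one cost scans near the regime boundaries.

    The full refined grid has 83,521 points; for locating the boundary of
    the cooperative regime it suffices to sample the neighbourhoods where
    the optimum can live — the win-stay-lose-shift face ``(~1, ~0, ~0, x)``
    with the full 17-value range in the last coordinate, the paradoxical
    corner ``(~0, ~1, ~0, ~0)``, the unconditional-defection corner — plus
    a coarse global safety net.
    """
    import itertools

    lo = [0.0, 0.005, 0.01, 0.02]
    hi = [0.98, 0.99, 0.995, 1.0]
    from .spaces import refined_values

    full = refined_values()
    wsls_face = np.array(list(itertools.product(hi, lo, lo, full)))
    paradox = np.array(list(itertools.product(lo, hi, lo, lo)))
    alld = np.array(list(itertools.product(lo, lo, lo, lo)))
    coarse = np.array(list(itertools.product(*([[0.0, 0.2, 0.4, 0.6, 0.8, 1.0]] * 4))))
    cand = np.vstack([wsls_face, paradox, alld, coarse])
    return np.unique(cand, axis=0)


@dataclass(frozen=True)
class RegimeScan:
    """Result of a cost scan of the most-favoured strategy."""

    kind: str
    costs: np.ndarray
    optima: np.ndarray  # (len(costs), 4)
    L_values: np.ndarray
    labels: list[str]
    boundaries: list[dict]  # refined switch points
    monotone: bool


def regime_boundaries(
    kind: str,
    costs: Sequence[float],
    epsilon: float,
    N: int,
    order: int = 24,
    stage1: Optional[StrategySpace | np.ndarray] = None,
    max_iter: int = 100,
    refine_tol: float = 0.01,
) -> RegimeScan:
    """Scan the cost axis, classify the optimum, and refine regime switches.

    Each switch between adjacent labels is refined by bisection on the cost
    until the bracket is narrower than ``refine_tol``; the reported boundary
    is the bracket midpoint.  A non-monotone label sequence (a regime
    reappearing after it was left) is flagged rather than rejected.
    """
    costs = np.sort(np.asarray(costs, dtype=float))
    if len(costs) >= 2 and np.max(np.diff(costs)) > 0.05 + 1e-12:
        raise ValueError("cost grid spacing must be <= 0.05 to bracket regimes")

    def optimum_at(c: float) -> FavouredResult:
        return most_favoured(
            kind, GameParams(c=float(c), epsilon=epsilon), N,
            order=order, stage1=stage1, max_iter=max_iter,
        )

    results = [optimum_at(c) for c in costs]
    labels = [classify_archetype(r.strategy) for r in results]
    boundaries: list[dict] = []
    for i in range(len(costs) - 1):
        if labels[i] == labels[i + 1]:
            continue
        lo, hi = float(costs[i]), float(costs[i + 1])
        lab_lo, lab_hi = labels[i], labels[i + 1]
        while hi - lo > 2.0 * refine_tol:
            mid = 0.5 * (lo + hi)
            lab_mid = classify_archetype(optimum_at(mid).strategy)
            if lab_mid == lab_lo:
                lo = mid
            else:
                hi, lab_hi = mid, lab_mid
        boundaries.append(
            {"cost": 0.5 * (lo + hi), "from": lab_lo, "to": lab_hi,
             "bracket": (lo, hi)}
        )
    seen: list[str] = []
    monotone = True
    for lab in labels:
        if lab in seen and seen[-1] != lab:
            monotone = False
        if not seen or seen[-1] != lab:
            seen.append(lab)
    return RegimeScan(
        kind=kind,
        costs=costs,
        optima=np.array([r.strategy for r in results]),
        L_values=np.array([r.L for r in results]),
        labels=labels,
        boundaries=boundaries,
        monotone=monotone,
    )
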
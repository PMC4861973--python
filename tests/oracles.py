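"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's analytic machinery: the repeated
game is simulated round by round, the Moran process run by run, and small
stationary distributions are obtained symbolically.  They are slow-but-sure
references, not alternative implementations.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=False)
def _simulate_game_counts(pe, qe, n_rounds, u):  # pragma: no cover - jitted
    """Count visits to (CC, CD, DC, DD) over a simulated repeated game.

    ``u`` is a pre-drawn (n_rounds, 2) uniform array; play starts from
    mutual cooperation in round 0 (the start state does not affect the
    long-run frequencies).
    """
    counts = np.zeros(4, np.int64)
    a, b = 1, 1  # 1 = cooperate
    for t in range(n_rounds):
        s = (1 - a) * 2 + (1 - b)
        sq = (1 - b) * 2 + (1 - a)
        a = 1 if u[t, 0] < pe[s] else 0
        b = 1 if u[t, 1] < qe[sq] else 0
        s_next = (1 - a) * 2 + (1 - b)
        counts[s_next] += 1
    return counts


def simulate_pair_game(p, q, c, epsilon, n_rounds, rng, n_blocks=10):
    """Monte-Carlo estimate of payoffs/cooperation rates with standard errors.

    The game is simulated in ``n_blocks`` independent blocks (each restarted
    from mutual cooperation); the estimate is the mean of the per-block
    values and the standard error is the empirical one across blocks, which
    correctly accounts for the chain's autocorrelation within a block.

    Returns ``(payoff_focal, payoff_other, coop_focal, coop_other, ses)``
    with ``ses`` the four standard errors in the same order.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pe = (1 - 2 * epsilon) * p + epsilon
    qe = (1 - 2 * epsilon) * q + epsilon
    h1 = np.array([1.0, 0.0, 1 + c, c])
    h2 = np.array([1.0, 1 + c, 0.0, c])
    per_block = n_rounds // n_blocks
    stats = np.empty((n_blocks, 4))
    for b in range(n_blocks):
        u = rng.random((per_block, 2))
        v = _simulate_game_counts(pe, qe, per_block, u) / per_block
        stats[b] = (v @ h1, v @ h2, v[0] + v[1], v[0] + v[2])
    mean = stats.mean(axis=0)
    ses = stats.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return mean[0], mean[1], mean[2], mean[3], ses


@njit(cache=False)
def _moran_runs(t_plus, t_minus, n_runs, N, seed):  # pragma: no cover - jitted
    """Count fixations of a lineage starting from a single mutant.

    Simulates the embedded jump chain (holding steps where the mutant count
    does not change are skipped; they cannot affect which boundary absorbs).
    ``t_plus[i-1]`` / ``t_minus[i-1]`` are the up/down probabilities at
    mutant count ``i``.
    """
    np.random.seed(seed)
    fixed = 0
    for _ in range(n_runs):
        i = 1
        while 0 < i < N:
            up = t_plus[i - 1]
            down = t_minus[i - 1]
            if np.random.random() < up / (up + down):
                i += 1
            else:
                i -= 1
        if i == N:
            fixed += 1
    return fixed


def simulate_fixation(t_plus, t_minus, N, n_runs, seed):
    """Empirical fixation frequency of a single mutant with standard error."""
    fixed = _moran_runs(np.asarray(t_plus, float), np.asarray(t_minus, float),
                        n_runs, N, seed)
    phat = fixed / n_runs
    se = np.sqrt(max(phat * (1 - phat), 1.0 / n_runs) / n_runs)
    return phat, se


def absorption_probability(t_plus, t_minus, N):
    """Fixation probability from the birth-death absorption linear system.

    Solves ``x_i = T+_i x_{i+1} + T-_i x_{i-1} + (1 - T+_i - T-_i) x_i``
    with ``x_0 = 0`` and ``x_N = 1`` as a dense linear system.
    """
    A = np.zeros((N - 1, N - 1))
    b = np.zeros(N - 1)
    for i in range(1, N):
        r = i - 1
        A[r, r] = t_plus[i - 1] + t_minus[i - 1]
        if i + 1 <= N - 1:
            A[r, r + 1] = -t_plus[i - 1]
        else:
            b[r] = t_plus[i - 1]
        if i - 1 >= 1:
            A[r, r - 1] = -t_minus[i - 1]
    x = np.linalg.solve(A, b)
    return float(x[0])


def stationary_3state_symbolic(M):
    """Closed-form stationary distribution of a 3-state chain via sympy.

    Uses the Markov-chain tree theorem expressions in exact rational
    arithmetic after rationalising the entries.
    """
    import sympy as sp

    Msym = sp.Matrix([[sp.Rational(x).limit_denominator(10**12) for x in row] for row in M])
    A = Msym.T - sp.eye(3)
    A = A.row_insert(3, sp.Matrix([[1, 1, 1]]))
    b = sp.Matrix([0, 0, 0, 1])
    sol = (A.T * A).solve(A.T * b)
    return np.array([float(s) for s in sol])
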
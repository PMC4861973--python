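"""Sequential mutant-invasion dynamics over continuous strategy spaces.

For infinite (stochastic) strategy spaces the rare-mutation chain cannot be
enumerated.  The sequential-invasion approximation starts from a resident
strategy, repeatedly draws a single mutant from a mutation kernel, and lets
it either fixate (with its Moran fixation probability) or go extinct,
producing a sequence of successive resident populations.  Time averages over
the resident sequence approximate the selection-mutation equilibrium.

The simulation is driven by one NumPy generator stream: each chunk of steps
draws its mutant coordinates first and its acceptance uniforms second, so a
given seed yields a bitwise-identical trajectory on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import fixation_batch, pair_stats_batch
from .game import GameParams, StrategyLike, as_strategy_array
from .moran import MoranParams
from .spaces import MutationKernel, sample_mutants

__all__ = ["InvasionTrajectory", "run_invasions", "survivor_filter", "trajectory_summary"]


@dataclass(frozen=True)
class InvasionTrajectory:
    """Record of a sequential-invasion run.

    Attributes
    ----------
    residents:
        ``(t + 1, 4)`` array; ``residents[k]`` is the resident after step
        ``k`` (``residents[0]`` is the initial strategy).
    accepted:
        ``(t,)`` boolean; whether step ``k + 1``'s mutant fixated.
    survival_count:
        ``(t,)`` integer; number of consecutive failed invasion attempts the
        current resident has survived after each step (reset to 0 when a
        mutant takes over).
    step_payoff, step_cooperation:
        ``(t,)`` self-play payoff and cooperation rate of the resident at
        steps ``1..t``.
    seed:
        Seed used for the generator stream (``None`` if a generator was
        supplied directly).
    """

    residents: np.ndarray
    accepted: np.ndarray
    survival_count: np.ndarray
    step_payoff: np.ndarray
    step_cooperation: np.ndarray
    game: GameParams
    moran: MoranParams
    seed: int | None = None

    @property
    def t(self) -> int:
        return len(self.accepted)

    def running_means(self) -> tuple[np.ndarray, np.ndarray]:
        """Running averages of payoff and cooperation over steps ``1..t``."""
        k = np.arange(1, self.t + 1)
        return np.cumsum(self.step_payoff) / k, np.cumsum(self.step_cooperation) / k


def _rho_against(mutants: np.ndarray, resident: np.ndarray, pi_rr: float,
                 game: GameParams, moran: MoranParams) -> np.ndarray:
    pi_mr, pi_rm, _, _ = pair_stats_batch(mutants, resident, game.c, game.epsilon)
    pi_mm = pair_stats_batch(mutants, mutants, game.c, game.epsilon)[0]
    return fixation_batch(pi_mm, pi_mr, pi_rm, np.full(len(mutants), pi_rr),
                          moran.N, moran.w)


def run_invasions(
    p0: StrategyLike,
    t: int,
    kernel: MutationKernel,
    game: GameParams,
    moran: MoranParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    chunk: int = 256,
) -> InvasionTrajectory:
    """Simulate ``t`` sequential mutant invasions starting from ``p0``.

    Each step draws one mutant from the kernel and accepts it as the new
    resident with probability equal to its fixation probability.  Fixation
    probabilities are evaluated in batches against the current resident;
    batching does not change the trajectory because mutant draws are
    independent of the resident.
    """
    if t < 1:
        raise ValueError("need at least one invasion step")
    if rng is None:
        rng = np.random.default_rng(seed)
    cur = as_strategy_array(p0)
    residents = np.empty((t + 1, 4))
    residents[0] = cur
    accepted = np.zeros(t, dtype=bool)
    survival = np.zeros(t, dtype=np.int64)
    step_pi = np.empty(t)
    step_g = np.empty(t)

    def self_stats(s: np.ndarray) -> tuple[float, float]:
        p, _, g, _ = pair_stats_batch(s[None, :], s[None, :], game.c, game.epsilon)
        return float(p[0]), float(g[0])

    cur_pi, cur_g = self_stats(cur)
    surv = 0
    step = 0
    while step < t:
        k = min(chunk, t - step)
        mutants = sample_mutants(kernel, k, rng)
        u = rng.random(k)
        rho = _rho_against(mutants, cur, cur_pi, game, moran)
        i = 0
        while i < k:
            hits = np.nonzero(u[i:] < rho[i:])[0]
            j = k if len(hits) == 0 else i + int(hits[0])
            # steps i..j-1 fail; the resident survives each attempt
            for s in range(i, min(j, k)):
                surv += 1
                residents[step + s + 1] = cur
                survival[step + s] = surv
                step_pi[step + s] = cur_pi
                step_g[step + s] = cur_g
            if j >= k:
                break
            # step j succeeds: the mutant becomes the new resident
            cur = mutants[j]
            cur_pi, cur_g = self_stats(cur)
            accepted[step + j] = True
            surv = 0
            residents[step + j + 1] = cur
            survival[step + j] = 0
            step_pi[step + j] = cur_pi
            step_g[step + j] = cur_g
            i = j + 1
            if i < k:
                rho = rho.copy()
                rho[i:] = _rho_against(mutants[i:], cur, cur_pi, game, moran)
        step += k
    return InvasionTrajectory(
        residents=residents,
        accepted=accepted,
        survival_count=survival,
        step_payoff=step_pi,
        step_cooperation=step_g,
        game=game,
        moran=moran,
        seed=seed,
    )


def survivor_filter(traj: InvasionTrajectory, k: int) -> list[tuple[np.ndarray, int]]:
    """Residency episodes that survived at least ``k`` consecutive invasions.

    A residency episode runs from a mutant's fixation (or the initial state)
    until the next fixation; its survival count is the number of failed
    invasion attempts it endured.  Episodes are returned in order with
    multiplicity, as ``(strategy, survival_count)`` pairs.
    """
    if k < 1:
        raise ValueError("survival threshold must be >= 1")
    out: list[tuple[np.ndarray, int]] = []
    starts = [0] + [int(i) + 1 for i in np.nonzero(traj.accepted)[0]]
    bounds = starts + [traj.t + 1]
    for a, b in zip(bounds[:-1], bounds[1:]):
        # episode resident occupies steps a..b-1; failures = attempts before
        # the one (if any) that deposed it
        n_attempts = (b - 1) - a if b <= traj.t else traj.t - a
        if n_attempts >= k:
            out.append((traj.residents[a].copy(), int(n_attempts)))
    return out


def trajectory_summary(traj: InvasionTrajectory) -> tuple[float, float]:
    """Time-averaged self-play payoff and cooperation over steps ``1..t``."""
    return float(traj.step_payoff.mean()), float(traj.step_cooperation.mean())
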
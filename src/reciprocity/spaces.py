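"""Strategy spaces and mutation kernels.

The four strategy classes compared in this package arise from crossing two
axes of strategic complexity: the *input* a strategy conditions on (nothing,
the co-player's previous move, or the full previous round) and whether the
response is *deterministic* or *stochastic*.  Finite spaces enumerate the
deterministic strategies exactly; stochastic spaces are approximated by
restricting each free cooperation probability to a regular grid
``{0, 1/m, ..., 1}``.

A refined grid is also provided for the weak-selection search: the favoured-
strategy landscape varies on the scale of the error rate near the boundary
of the cube, so the 11-point regular mesh is augmented with the six values
``0.005, 0.01, 0.02, 0.98, 0.99, 0.995`` (17 values per coordinate, hence
``17**4 = 83,521`` memory-one grid points).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .game import Strategy

__all__ = [
    "StrategySpace",
    "MutationKernel",
    "build_space",
    "appendix_refined_grid",
    "refined_values",
    "sample_mutant",
    "sample_mutants",
    "SPACE_KINDS",
]

#: Canonical kind names (CLI aliases in parentheses are accepted too).
SPACE_KINDS = (
    "deterministic-reactive",
    "deterministic-memory-one",
    "reactive-grid",
    "memory-one-grid",
    "unconditional",
)

_ALIASES = {
    "det-reactive": "deterministic-reactive",
    "det-mem1": "deterministic-memory-one",
    "mem1-grid": "memory-one-grid",
    "reactive": "reactive-grid",
    "memory-one": "memory-one-grid",
}


@dataclass(frozen=True)
class StrategySpace:
    """A finite, ordered, duplicate-free set of memory-one strategies.

    Strategies are stored as an ``(n, 4)`` array in lexicographic order on
    ``(p_cc, p_cd, p_dc, p_dd)``; all reported distributions index strategies
    in this order.
    """

    kind: str
    strategies: np.ndarray
    m: Optional[int] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.strategies, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4:
            raise ValueError("strategies must form an (n, 4) array")
        if len(np.unique(s, axis=0)) != len(s):
            raise ValueError("strategy space contains duplicates")
        object.__setattr__(self, "strategies", s)

    @property
    def n(self) -> int:
        return len(self.strategies)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.strategies)

    def index_of(self, strategy) -> int:
        """Row index of a strategy (exact match), or raise ``KeyError``."""
        target = np.asarray(
            strategy.as_array() if isinstance(strategy, Strategy) else strategy,
            dtype=float,
        )
        hits = np.where(np.all(self.strategies == target, axis=1))[0]
        if len(hits) == 0:
            raise KeyError(f"strategy {target} not in space")
        return int(hits[0])


def _lexsorted(rows: np.ndarray) -> np.ndarray:
    order = np.lexsort((rows[:, 3], rows[:, 2], rows[:, 1], rows[:, 0]))
    return rows[order]


def _grid_values(m: int) -> np.ndarray:
    if m < 1:
        raise ValueError(f"grid resolution m={m} must be >= 1")
    return np.arange(m + 1) / m


def build_space(kind: str, m: Optional[int] = None) -> StrategySpace:
    """Enumerate one of the strategy spaces.

    Parameters
    ----------
    kind:
        One of :data:`SPACE_KINDS` (or a CLI alias such as ``det-mem1``).
    m:
        Grid resolution for the grid kinds: probabilities take values
        ``{0, 1/m, ..., 1}``.  ``m = 1`` recovers the deterministic space
        of the same input class.

    The deterministic reactive space contains exactly AllD, AllC, TFT and
    ATFT; the deterministic memory-one space contains all 16 binary
    4-tuples.  Grid spaces respect the defining equality constraints
    (reactive: ``p_cc = p_dc`` and ``p_cd = p_dd``; unconditional: all four
    entries equal).
    """
    kind = _ALIASES.get(kind, kind)
    if kind == "deterministic-reactive":
        base = build_space("reactive-grid", m=1)
        return StrategySpace(kind=kind, strategies=base.strategies, m=1)
    if kind == "deterministic-memory-one":
        base = build_space("memory-one-grid", m=1)
        return StrategySpace(kind=kind, strategies=base.strategies, m=1)
    if kind == "reactive-grid":
        if m is None:
            raise ValueError("reactive-grid requires a grid resolution m")
        vals = _grid_values(m)
        rows = np.array([(rc, rd, rc, rd) for rc, rd in itertools.product(vals, vals)])
        return StrategySpace(kind=kind, strategies=_lexsorted(rows), m=m)
    if kind == "memory-one-grid":
        if m is None:
            raise ValueError("memory-one-grid requires a grid resolution m")
        vals = _grid_values(m)
        rows = np.array(list(itertools.product(vals, repeat=4)))
        return StrategySpace(kind=kind, strategies=_lexsorted(rows), m=m)
    if kind == "unconditional":
        m_eff = 1 if m is None else m
        vals = _grid_values(m_eff)
        rows = np.stack([vals] * 4, axis=1)
        return StrategySpace(kind=kind, strategies=_lexsorted(rows), m=m_eff)
    raise ValueError(f"unknown strategy-space kind {kind!r}")


def refined_values() -> np.ndarray:
    """The 17 per-coordinate values of the refined search grid."""
    regular = np.arange(11) / 10
    extra = np.array([0.005, 0.01, 0.02, 0.98, 0.99, 0.995])
    return np.sort(np.concatenate([regular, extra]))


def appendix_refined_grid(kind: str = "memory-one") -> StrategySpace:
    """The refined search grid: 17 values per free coordinate.

    For ``kind="memory-one"`` this is the full 4-dimensional product with
    ``17**4 = 83,521`` points; for ``kind="reactive"`` the two equality
    constraints leave ``17**2 = 289`` points.
    """
    vals = refined_values()
    if kind in ("memory-one", "memory-one-grid", "mem1"):
        rows = np.array(list(itertools.product(vals, repeat=4)))
        return StrategySpace(kind="refined-memory-one", strategies=_lexsorted(rows))
    if kind in ("reactive", "reactive-grid"):
        rows = np.array([(rc, rd, rc, rd) for rc, rd in itertools.product(vals, vals)])
        return StrategySpace(kind="refined-reactive", strategies=_lexsorted(rows))
    if kind == "unconditional":
        rows = np.stack([vals] * 4, axis=1)
        return StrategySpace(kind="refined-unconditional", strategies=_lexsorted(rows))
    raise ValueError(f"unknown refined-grid kind {kind!r}")


@dataclass(frozen=True)
class MutationKernel:
    """Product distribution over a strategy class's free coordinates.

    Each free coordinate of a new mutant is drawn independently from a beta
    distribution with shape ``(alpha, beta)``; ``alpha = beta = 1`` is the
    uniform kernel, while ``alpha = beta = 0.1`` is strongly U-shaped,
    concentrating mutants near deterministic corners.  Constrained
    coordinates (reactive, unconditional) are copied, not redrawn.
    """

    kind: str = "memory-one"  # "memory-one" | "reactive" | "unconditional"
    family: str = "uniform"  # "uniform" | "beta"
    alpha: float = 1.0
    beta: float = 1.0

    _DIMS = {"memory-one": 4, "reactive": 2, "unconditional": 1}

    def __post_init__(self) -> None:
        if self.kind not in self._DIMS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.family not in ("uniform", "beta"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def dimension(self) -> int:
        return self._DIMS[self.kind]

    @property
    def is_uniform(self) -> bool:
        return self.family == "uniform" or (self.alpha == 1.0 and self.beta == 1.0)


def sample_mutants(
    kernel: MutationKernel, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` mutant strategies as an ``(size, 4)`` array.

    The uniform kernel and ``beta(1, 1)`` consume the same generator stream,
    so they produce identical samples under the same seed.
    """
    d = kernel.dimension
    if kernel.is_uniform:
        free = rng.random((size, d))
    else:
        free = rng.beta(kernel.alpha, kernel.beta, size=(size, d))
    if kernel.kind == "memory-one":
        return free
    if kernel.kind == "reactive":
        return free[:, [0, 1, 0, 1]]
    return np.repeat(free, 4, axis=1)


def sample_mutant(kernel: MutationKernel, rng: np.random.Generator) -> np.ndarray:
    """Draw a single mutant strategy as a length-4 array."""
    return sample_mutants(kernel, 1, rng)[0]
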
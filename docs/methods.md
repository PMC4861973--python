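# Methods

This note documents the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Pair game

The repeated donation game between memory-one strategies `p` and `q` with
implementation error `ε` is a Markov chain over the states
`(CC, CD, DC, DD)`, ordered with the focal player's move first. The row
for state `(i, j)` is the outer product of two independent Bernoulli
decisions: the focal player cooperates with probability `p'_{ij}`, the
co-player — who sees the transposed state — with probability `q'_{ji}`,
where `p' = (1−ε)p + ε(1−p)`. For `ε > 0` every entry is positive, the
chain is primitive, and the invariant distribution `v` is unique. Payoff
vectors are `h₁ = (1, 0, 1+c, c)` and `h₂ = (1, 1+c, 0, c)` (benefit fixed
to 1, all payoffs shifted by `+c` to be non-negative, `0 < c < 1`).

Two solvers coexist deliberately:

* the public single-pair API solves `v(M − I) = 0` with a normalisation
  row by dense least squares (tolerance 1e-12) and *checks uniqueness* via
  the multiplicity of eigenvalue 1 — at `ε = 0` a reducible chain raises
  instead of silently picking an ergodic component;
* the batched kernels used by the population layers evaluate the
  stationary vector in closed form as the diagonal cofactors of `I − M`
  (matrix-tree theorem for a 4-state chain), JIT-compiled with numba.
  Tests assert both paths agree to 1e-12 over random pairs, and a
  pure-numpy implementation of the identical arithmetic is used when
  numba is not importable.

Limits as `ε → 0` (self-cooperator/self-defector classification, the
exact-payoff identities of the paradoxical strategy `(0,1,0,0)`) are taken
numerically: payoffs are analytic in `ε`, so we evaluate along the
decreasing sequence `10⁻² … 10⁻⁵` and, where a limit value is asserted,
linearly extrapolate the two smallest values to `ε = 0`. A strategy is a
self-cooperator when its self-play cooperation rate exceeds `1 − 10ε` at
the two smallest error rates and increases along the tail (symmetrically
for self-defectors); interior limits are reported as "neither".

## Moran process

Group payoffs exclude self-interaction (`/(N−1)` normalisation). Fitness
is `1 + w·π`, which is strictly positive for every admissible payoff and
selection strength — including `w = 10` — because payoffs are shifted
non-negative. Fixation probabilities use the standard birth–death formula;
the cumulative products `Π g_j/f_j` are accumulated in log space so that
`N = 100` at `w = 10` is exact to machine precision. At `w = 0` the code
returns `1/N` identically. The birth–death rates `T±` are exposed only for
the small-population oracle, which solves the absorption linear system
directly and cross-checks a simulated fixation frequency (the simulation
uses the embedded jump chain: holding steps cannot change which boundary
absorbs).

## Rare-mutation equilibrium

The embedded chain over monomorphic states has off-diagonal entries
`ρ(p_k into p_j)/(n−1)`. Both payoff directions of each unordered pair
come from one stationary solve (`n(n−1)/2` solves per space), and the
invariant distribution `ξ` is obtained by a dense null-space solve with a
normalisation constraint up to `n = 5000` states (iterative eigensolver
above). Population averages weight *self-play* payoff and cooperation by
`ξ`, because in the rare-mutation limit the population is homogeneous
almost always. A uniform rescaling of all off-diagonal entries (the
mutation rate) provably cancels from `ξ`; tests assert this numerically.

## Sequential mutant invasions

The continuous-space approximation draws one mutant per step from a
product kernel (uniform, or beta(α, β) per free coordinate; reactive and
unconditional kernels copy the constrained coordinates) and accepts it
with its fixation probability. One generator stream drives the run: each
chunk of 256 steps draws its mutant coordinates first, then its acceptance
uniforms, so a seed reproduces the trajectory bitwise; batching is
possible because mutant draws are independent of the current resident.
Survival counts reset on replacement — "survived k invasions" means k
consecutive failed invasion attempts against that resident. Time averages
run over steps `1..t` (excluding the initial resident; negligible for the
`t ≥ 10⁴` runs used anywhere in the package).

Publication-scale runs of these dynamics typically use several million
mutants; this package's tests use 2·10⁵–5·10⁵ steps with the first 20%
discarded, which is where the time averages stabilise to ±0.02 for the
reactive space. Single runs at strong selection remain noisy at the
±0.02–0.05 level because residencies near the generous edge are long.

## Weak selection

The abundance coefficient `L` is defined operationally as the first-order
perturbation in `w` of the embedded chain's stationary distribution, which
is uniform at `w = 0`:

    L_i = Σ_{j≠i} [ dρ(i→j)/dw − dρ(j→i)/dw ]  at w = 0.

The slope has the closed form
`dρ/dw|₀ = (1/N²) Σ_{j=1}^{N−1} (N−j)(π_m(j) − π_r(j))`, cross-validated
against central finite differences of the exact `ρ(w)` at `w = ±10⁻⁶`.
The antisymmetric combination entering `L` collapses to
`(1/2N)[N(π_pq − π_qp) + (N−2)(π_pp − π_qq)]`, so each mutant costs one
stationary solve. Numerically, the equilibrium deviation satisfies
`nξ_i − 1 ≈ (N/n)·w·L_i` at `w = 10⁻⁴`, and sign/ranking agreement with
the exact equilibrium holds wherever `L_i` is not itself zero (strategies
with exchange-symmetric payoff profiles, e.g. tit-for-tat, have `L_i = 0`
and their tiny deviations are decided at second order).

For continuous spaces `L(p)` integrates the same combination over mutants
drawn uniformly from the *same strategy class* (2-dimensional for
reactive, 4-dimensional for memory-one, 1-dimensional for unconditional),
by tensor-product Gauss–Legendre quadrature. The implementation error
smooths the integrand; `L` is stable to better than 1e-4 relative under
order doubling already at 16 nodes per dimension, so the default order 24
is conservative.

### Global search

The maximiser of `L(p)` is found in two stages. Stage 1 evaluates `L` on
a refined grid: the regular mesh `{0, 0.1, …, 1}` augmented with
`{0.005, 0.01, 0.02, 0.98, 0.99, 0.995}` — 17 values per coordinate
(83,521 memory-one points) — because the landscape varies on the scale of
`ε` near the boundary of the cube. Stage 2 runs projected gradient ascent
(central differences with step 1e-4, backtracking line search, stop at
gradient norm 1e-6 or the iteration cap) from the best grid point, in the
class's free coordinates, and never returns a point worse than stage 1.

The error-scale mesh values are not optional: at `c = 0.5` the memory-one
optimum is `(0, 1, 0, ~0.02)` with `L = 0.3025`, while the best point of a
plain 11-value mesh in that basin, `(0,1,0,0)`, scores below the local
win-stay-lose-shift maximum `(1,0,0,0.22)` at `L = 0.2935` — a coarse
stage 1 starts the ascent in the wrong basin. On wide basins (the WSLS
face at `c = 0.2`) the 11- and 17-value meshes give identical optima to
1e-3 per coordinate.

For cost scans near a regime boundary, the stage-1 grid is restricted to
the regions that can host the optimum — the WSLS face `(~1, ~0, ~0, x)`
with the full 17-value range in the last coordinate, the paradoxical and
defection corners, plus a coarse global net of 6⁴ points (≈2,900
candidates in total). This reproduces the full-grid optimum at every cost
we checked while keeping a two-boundary scan under two minutes.

### Regime classification

The three regimes of the most favoured strategy are identified by the
optimum's *form*, not by a cooperation-rate threshold: *cooperative* if it
keeps cooperating after mutual cooperation (`p_CC ≥ 0.9`; this covers
both generous reactive optima and WSLS variants `(1, 0, 0, x)`),
*defective* if every coordinate is at most 0.005 (unconditional defection
up to below-error-floor probabilities), *intermediate* otherwise. A
rate-based rule was rejected because the intermediate reactive optimum
`(0, δ)` has self-cooperation below 0.1 long before the optimum actually
collapses to AllD — the form-based rule places the reactive boundaries at
≈0.235 and ≈0.395 (theory: 1/4 and 2/5 for vanishing error) and the
memory-one cooperative boundary at ≈0.456 (≈0.45). Regime switches are
refined by bisection on the cost to a ±0.01 bracket.

## What the synthetic dynamics do and do not show

All inputs are generated by the model itself; there is no external data.
The default study conditions are `N = 100`,
`ε = 0.01` (also `10⁻⁴` for the mutation-kernel comparison), `c ∈ (0,1)`,
`w ∈ {0.1, 10}` for equilibria and `w → 0` for the favourability
analysis; uniform and beta(0.1, 0.1) mutation kernels. Passing tests show
internal consistency of the exact machinery (Monte-Carlo, linear-system
and symbolic oracles agree with the closed forms) and reproduction of the
qualitative and threshold findings under these conditions. They do not
show robustness to asymmetric error rates, discounted games, longer
memory, or non-product mutation kernels — all outside the model class.

Two known quantitative caveats. First, the discretised reactive
equilibrium carries an O(1/m) grid bias in its mean cooperation (the grid
gives exact-boundary strategies finite probability mass that the
continuous kernel assigns measure zero); comparisons against the invasion
simulation therefore use the Richardson extrapolation of the m = 25 and
m = 50 grids, which agrees with a converged simulation to better than
0.03. Second, evolutionary *robustness* of win-stay-lose-shift is lost at
c ≈ 0.33 (to the mutant `(0,0,0,1)`) even though the AllD deviant's
payoff only overtakes mutual cooperation at c = 1/2 — fixation
probabilities weigh the whole invasion path, not just the lone-deviant
payoff, so the two thresholds differ.
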
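"""Vectorised numeric kernels shared by the population-level modules.

The pair chain is only 4x4, so its invariant distribution has a closed form:
for ``A = I - M`` the vector of diagonal cofactors of ``A`` is proportional
to the stationary distribution (matrix-tree theorem for a 4-state chain).
The kernels below evaluate that closed form per pair, which is what makes
grid equilibria, quadrature integrals and invasion simulations over many
thousands of strategy pairs affordable.

When numba is importable the per-pair loops are JIT-compiled; otherwise a
chunked pure-numpy implementation of the identical arithmetic is used.  Both
paths are deterministic and agree to machine precision (asserted in tests
against the dense linear solve in :mod:`reciprocity.game`).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    numba = None
    HAVE_NUMBA = False

__all__ = ["pair_stats_batch", "fixation_batch", "HAVE_NUMBA"]

_CHUNK = 1 << 16  # keep numpy temporaries ~ tens of MB


def _effective(P: np.ndarray, epsilon: float) -> np.ndarray:
    return (1.0 - 2.0 * epsilon) * P + epsilon


def _pair_stats_numpy(Pe: np.ndarray, Qe: np.ndarray, c: float, out) -> None:
    pi1, pi2, g1, g2 = out
    n = len(Pe)
    for i0 in range(0, n, _CHUNK):
        sl = slice(i0, min(i0 + _CHUNK, n))
        x = Pe[sl]
        y = Qe[sl][:, [0, 2, 1, 3]]  # co-player sees the transposed state
        xy = x * y
        # A = I - M, built column-wise; M row s = (xy, x-xy, y-xy, 1-x-y+xy)
        A = np.empty(x.shape[:-1] + (4, 4))
        A[..., :, 0] = -xy
        A[..., :, 1] = xy - x
        A[..., :, 2] = xy - y
        A[..., :, 3] = x + y - xy - 1.0
        for s in range(4):
            A[..., s, s] += 1.0

        def det3(r):
            a, b, cc = A[..., r[0], r[0]], A[..., r[0], r[1]], A[..., r[0], r[2]]
            d, e, f = A[..., r[1], r[0]], A[..., r[1], r[1]], A[..., r[1], r[2]]
            g, h, i = A[..., r[2], r[0]], A[..., r[2], r[1]], A[..., r[2], r[2]]
            return a * (e * i - f * h) - b * (d * i - f * g) + cc * (d * h - e * g)

        v0 = det3((1, 2, 3))
        v1 = det3((0, 2, 3))
        v2 = det3((0, 1, 3))
        v3 = det3((0, 1, 2))
        s_ = v0 + v1 + v2 + v3
        pi1[sl] = (v0 + (1.0 + c) * v2 + c * v3) / s_
        pi2[sl] = (v0 + (1.0 + c) * v1 + c * v3) / s_
        g1[sl] = (v0 + v1) / s_
        g2[sl] = (v0 + v2) / s_


if HAVE_NUMBA:

    @numba.njit(cache=False)
    def _pair_stats_numba(Pe, Qe, c, pi1, pi2, g1, g2):  # pragma: no cover - jitted
        n = Pe.shape[0]
        for k in range(n):
            p0 = Pe[k, 0]; p1 = Pe[k, 1]; p2 = Pe[k, 2]; p3 = Pe[k, 3]
            # the co-player conditions on the transposed state
            q0 = Qe[k, 0]; q1 = Qe[k, 2]; q2 = Qe[k, 1]; q3 = Qe[k, 3]
            a00 = 1.0 - p0 * q0; a01 = -(p0 * (1.0 - q0))
            a02 = -((1.0 - p0) * q0); a03 = -((1.0 - p0) * (1.0 - q0))
            a10 = -(p1 * q1); a11 = 1.0 - p1 * (1.0 - q1)
            a12 = -((1.0 - p1) * q1); a13 = -((1.0 - p1) * (1.0 - q1))
            a20 = -(p2 * q2); a21 = -(p2 * (1.0 - q2))
            a22 = 1.0 - (1.0 - p2) * q2; a23 = -((1.0 - p2) * (1.0 - q2))
            a30 = -(p3 * q3); a31 = -(p3 * (1.0 - q3))
            a32 = -((1.0 - p3) * q3); a33 = 1.0 - (1.0 - p3) * (1.0 - q3)
            v0 = a11 * (a22 * a33 - a23 * a32) - a12 * (a21 * a33 - a23 * a31) \
                + a13 * (a21 * a32 - a22 * a31)
            v1 = a00 * (a22 * a33 - a23 * a32) - a02 * (a20 * a33 - a23 * a30) \
                + a03 * (a20 * a32 - a22 * a30)
            v2 = a00 * (a11 * a33 - a13 * a31) - a01 * (a10 * a33 - a13 * a30) \
                + a03 * (a10 * a31 - a11 * a30)
            v3 = a00 * (a11 * a22 - a12 * a21) - a01 * (a10 * a22 - a12 * a20) \
                + a02 * (a10 * a21 - a11 * a20)
            s = v0 + v1 + v2 + v3
            pi1[k] = (v0 + (1.0 + c) * v2 + c * v3) / s
            pi2[k] = (v0 + (1.0 + c) * v1 + c * v3) / s
            g1[k] = (v0 + v1) / s
            g2[k] = (v0 + v2) / s


def pair_stats_batch(P, Q, c: float, epsilon: float):
    """Long-run payoffs and cooperation rates for batches of strategy pairs.

    Parameters
    ----------
    P, Q:
        Arrays of shape ``(n, 4)`` (either may be a single ``(4,)`` strategy,
        broadcast against the other).
    c, epsilon:
        Cost and implementation-error rate.

    Returns
    -------
    ``(pi1, pi2, gamma1, gamma2)`` — focal/co-player payoffs and cooperation
    rates, each of shape ``(n,)``.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.ndim == 1:
        P = np.broadcast_to(P, Q.shape)
    if Q.ndim == 1:
        Q = np.broadcast_to(Q, P.shape)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 4:
        raise ValueError("P and Q must broadcast to a common (n, 4) shape")
    Pe = np.ascontiguousarray(_effective(P, epsilon))
    Qe = np.ascontiguousarray(_effective(Q, epsilon))
    n = len(Pe)
    pi1 = np.empty(n); pi2 = np.empty(n); g1 = np.empty(n); g2 = np.empty(n)
    if HAVE_NUMBA:
        _pair_stats_numba(Pe, Qe, float(c), pi1, pi2, g1, g2)
    else:
        _pair_stats_numpy(Pe, Qe, float(c), (pi1, pi2, g1, g2))
    return pi1, pi2, g1, g2


def _fixation_numpy(pi_mm, pi_mr, pi_rm, pi_rr, N, w):
    j = np.arange(1, N)[None, :]
    f = 1.0 + w * (((j - 1) * pi_mm[:, None] + (N - j) * pi_mr[:, None]) / (N - 1))
    g = 1.0 + w * ((j * pi_rm[:, None] + (N - j - 1) * pi_rr[:, None]) / (N - 1))
    cs = np.cumsum(np.log(g) - np.log(f), axis=1)
    m = np.maximum(np.max(cs, axis=1), 0.0)
    denom = np.exp(-m) + np.sum(np.exp(cs - m[:, None]), axis=1)
    return np.exp(-m) / denom


if HAVE_NUMBA:

    @numba.njit(cache=False)
    def _fixation_numba(pi_mm, pi_mr, pi_rm, pi_rr, N, w, out):  # pragma: no cover
        n = pi_mm.shape[0]
        cs = np.empty(N - 1)
        for k in range(n):
            acc = 0.0
            m = 0.0
            for j in range(1, N):
                f = 1.0 + w * (((j - 1) * pi_mm[k] + (N - j) * pi_mr[k]) / (N - 1))
                g = 1.0 + w * ((j * pi_rm[k] + (N - j - 1) * pi_rr[k]) / (N - 1))
                acc += np.log(g) - np.log(f)
                cs[j - 1] = acc
                if acc > m:
                    m = acc
            denom = np.exp(-m)
            for j in range(N - 1):
                denom += np.exp(cs[j] - m)
            out[k] = np.exp(-m) / denom


def fixation_batch(pi_mm, pi_mr, pi_rm, pi_rr, N: int, w: float) -> np.ndarray:
    """Moran fixation probabilities from the four pairwise payoffs, batched.

    Evaluates ``rho = 1 / (1 + sum_k prod_{j<=k} g_j / f_j)`` with
    ``f_j = 1 + w pi_m(j)`` and ``g_j = 1 + w pi_r(j)`` in log space, which
    keeps the running products stable even at strong selection.
    """
    pi_mm, pi_mr, pi_rm, pi_rr = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (pi_mm, pi_mr, pi_rm, pi_rr))
    )
    shape = pi_mm.shape
    flat = [np.ascontiguousarray(a.ravel()) for a in (pi_mm, pi_mr, pi_rm, pi_rr)]
    if w == 0.0:
        return np.full(shape, 1.0 / N)
    if HAVE_NUMBA:
        out = np.empty(flat[0].shape)
        _fixation_numba(*flat, N, float(w), out)
    else:
        out = _fixation_numpy(*flat, N, float(w))
    return out.reshape(shape)
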
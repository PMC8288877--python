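"""Lempel–Ziv match-length fields and entropy-rate estimation.

The entropy rate of a temporal network is estimated from the recurrence
structure of its link-by-time matrix.  For every cell ``v`` of a square
matrix, the match length ``Λ_v`` is the smallest block side ``k`` such that
the ``k × k`` block whose lower-right corner is ``v`` does not occur (with
the same anchoring) at any earlier position inside the rectangle spanned by
the origin and ``v``.  Large match lengths mean the local pattern has been
seen before — a regular, and hence predictable, matrix.  The entropy rate
in bits per symbol is then

    H = n^2 * log2(n^2) / sum_v Λ_v^2

which converges to the true entropy rate of a stationary random field as
the matrix grows.  A one-dimensional analogue (substring match lengths,
``H = T log2 T / sum_t Λ_t``) scores individual link time series; the
match length enters linearly there because a length-k substring covers k
symbols, whereas a side-k block covers k^2.

Saturation convention
---------------------
A size ``k`` only "distinguishes" ``v`` if at least one earlier anchor
position exists where a ``k × k`` block fits entirely inside the matrix.
Cells for which every admissible size is matched somewhere earlier — or for
which no admissible candidate exists at all, e.g. the origin cell — are
assigned the saturated value ``k_max(v) + 1``, where ``k_max(v)`` is the
largest block side that fits at ``v``.  Saturation extends the estimator
monotonically: more regularity always means larger match lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


__all__ = [
    "MatchLengthField",
    "EntropyEstimate",
    "match_length_field",
    "match_lengths_1d",
    "match_lengths_1d_rows",
    "entropy_rate_2d",
    "entropy_rate_1d",
]


@dataclass(frozen=True)
class MatchLengthField:
    """Grid of 2D match lengths for one square matrix.

    Attributes
    ----------
    lambdas : (n, n) int array
        Match length at every cell; always >= 1.
    side : int
        Side length n of the source matrix.
    saturated : (n, n) bool array
        True where no admissible distinguishing block size exists in-bounds
        and the cell carries the capped value ``k_max + 1``.
    """

    lambdas: np.ndarray
    side: int
    saturated: np.ndarray


@dataclass(frozen=True)
class EntropyEstimate:
    """Entropy rate in bits per symbol, with the problem size it came from."""

    H: float
    n: int
    N: int


# --- hashing constants (odd => invertible modulo 2**64) ---------------------
_B1 = np.uint64(0x9E3779B97F4A7C15)
_B2 = np.uint64(0xC2B2AE3D27D4EB4F)
_V1 = np.uint64(0xD6E8FEB86659FD93)
_V2 = np.uint64(0xA24BAED4963EE407)
_MASK = (1 << 64) - 1


def _modinv64(b: int) -> int:
    """Inverse of an odd integer modulo 2**64 (Newton iteration)."""
    x = b
    for _ in range(6):
        x = (x * (2 - b * x)) & _MASK
    return x


@_njit(cache=True)
def _segment_prefix_match(starts, cvals, out):  # pragma: no cover - jitted
    """out[i] = True iff some earlier cell in the same hash group has c <= c_i."""
    big = np.int64(1 << 60)
    run_min = big
    for i in range(cvals.shape[0]):
        if starts[i]:
            run_min = big
        out[i] = run_min <= cvals[i]
        if cvals[i] < run_min:
            run_min = cvals[i]


def _match_lengths_2d(codes: np.ndarray) -> np.ndarray:
    """Exact match lengths for a square integer matrix.

    Level-wise algorithm: at each block side k, all cells where a k-block
    fits are grouped by a rolling polynomial hash of their block (two
    independent 64-bit hashes); within a group, a single sweep in (row, col)
    order decides for every cell whether an earlier anchor with both
    coordinates <= its own exists.  Cells whose block is unmatched at the
    smallest admissible k get Λ = k; the rest saturate at k_max + 1.
    """
    n = codes.shape[0]
    rows = np.arange(n)[:, None] * np.ones(n, dtype=np.int64)[None, :]
    cols = rows.T
    mins = np.minimum(rows, cols)
    k_max = mins + 1
    # Largest k for which an admissible candidate anchor exists.
    adm = np.where(rows != cols, mins + 1, rows)

    lam = np.zeros((n, n), dtype=np.int64)
    active = np.ones((n, n), dtype=bool)

    M = codes.astype(np.uint64) + np.uint64(1)
    r1 = M.copy()
    r2 = M * np.uint64(3)  # distinct starting mix for the second hash

    def _pows(base: int) -> np.ndarray:
        out, acc = np.empty(n + 1, dtype=np.uint64), 1
        for j in range(n + 1):
            out[j] = acc
            acc = (acc * base) & _MASK
        return out

    b1pows = _pows(int(_B1))
    b2pows = _pows(int(_B2))
    v1pow = _pows(int(_V1))
    v2pow = _pows(int(_V2))
    iv1pow = _pows(_modinv64(int(_V1)))
    iv2pow = _pows(_modinv64(int(_V2)))

    for k in range(1, n + 1):
        vac = active & (adm < k)
        if vac.any():
            lam[vac] = k_max[vac] + 1
            active &= ~vac
        if not active.any():
            break

        if k > 1:
            r1[:, k - 1 :] += M[:, : n - k + 1] * b1pows[k - 1]
            r2[:, k - 1 :] += M[:, : n - k + 1] * b2pows[k - 1]

        # Vertical combination over the k-row window via invertible prefix sums.
        p1 = np.cumsum(r1 * v1pow[:n, None], axis=0, dtype=np.uint64)
        p2 = np.cumsum(r2 * v2pow[:n, None], axis=0, dtype=np.uint64)
        sub1 = p1[k - 1 :, k - 1 :].copy()
        sub2 = p2[k - 1 :, k - 1 :].copy()
        if k < n:
            sub1[1:] -= p1[: n - k, k - 1 :]
            sub2[1:] -= p2[: n - k, k - 1 :]
        h1 = sub1 * iv1pow[1 : n - k + 2][:, None]
        h2 = sub2 * iv2pow[1 : n - k + 2][:, None]

        rr = rows[k - 1 :, k - 1 :].ravel()
        cc = cols[k - 1 :, k - 1 :].ravel()
        f1 = h1.ravel()
        f2 = h2.ravel()
        order = np.lexsort((cc, rr, f2, f1))
        f1s, f2s = f1[order], f2[order]
        starts = np.empty(f1s.shape[0], dtype=bool)
        starts[0] = True
        starts[1:] = (f1s[1:] != f1s[:-1]) | (f2s[1:] != f2s[:-1])
        matched_sorted = np.empty(f1s.shape[0], dtype=bool)
        _segment_prefix_match(starts, cc[order].astype(np.int64), matched_sorted)
        matched = np.empty(f1s.shape[0], dtype=bool)
        matched[order] = matched_sorted

        matched_grid = np.zeros((n, n), dtype=bool)
        matched_grid[rr, cc] = matched
        done = active & ~matched_grid & (adm >= k)
        if done.any():
            lam[done] = k
            active &= ~done

    return lam


def match_length_field(S) -> MatchLengthField:
    """Compute the 2D match-length field of a square matrix.

    Parameters
    ----------
    S : array-like, shape (n, n)
        Square matrix over a finite value alphabet (any hashable numeric
        values; they are recoded internally).

    Returns
    -------
    MatchLengthField
    """
    S = np.asarray(S)
    if S.size == 0:
        raise ValueError("empty matrix")
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"matrix must be square, got shape {S.shape}")
    n = S.shape[0]
    _, inv = np.unique(S, return_inverse=True)
    codes = inv.reshape(n, n).astype(np.int64)
    lam = _match_lengths_2d(codes)
    k_max = np.minimum(np.arange(n)[:, None], np.arange(n)[None, :]) + 1
    return MatchLengthField(lambdas=lam, side=n, saturated=lam > k_max)


def match_lengths_1d(x) -> np.ndarray:
    """1D substring match lengths Λ_t for a value sequence.

    Λ_t is the smallest length k such that the k-substring ending at t does
    not end at any earlier position; cells with no admissible distinguishing
    length saturate to t + 1 (1-based), mirroring the 2D convention.
    """
    x = np.asarray(x).ravel()
    T = x.shape[0]
    if T < 2:
        raise ValueError("sequence must have length >= 2")
    _, codes = np.unique(x, return_inverse=True)
    best = np.zeros(T, dtype=np.int64)
    for d in range(1, T):
        eq = codes[d:] == codes[:-d]
        if not eq.any():
            continue
        idx = np.arange(T - d)
        last_fail = np.maximum.accumulate(np.where(~eq, idx, -1))
        run = np.where(eq, idx - last_fail, 0)
        np.maximum(best[d:], run, out=best[d:])
    i = np.arange(T)
    return np.where(best + 1 <= i, best + 1, i + 2)


@_njit(cache=True)
def _best_runs_rows(codes):  # pragma: no cover - jitted
    m, T = codes.shape
    best = np.zeros((m, T), dtype=np.int64)
    for i in range(m):
        for d in range(1, T):
            run = 0
            for t in range(d, T):
                if codes[i, t] == codes[i, t - d]:
                    run += 1
                    if run > best[i, t]:
                        best[i, t] = run
                else:
                    run = 0
    return best


def match_lengths_1d_rows(X) -> np.ndarray:
    """1D match lengths for every row of a matrix at once.

    Equivalent to stacking :func:`match_lengths_1d` over rows, but batched
    for speed (per-link predictability touches every row of the filtered
    matrix and all its shuffles).
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D matrix with at least two columns")
    _, inv = np.unique(X, return_inverse=True)
    codes = inv.reshape(X.shape).astype(np.int64)
    if _HAVE_NUMBA:
        best = _best_runs_rows(codes)
    else:
        T = X.shape[1]
        best = np.zeros(codes.shape, dtype=np.int64)
        idx = np.arange(T)
        for d in range(1, T):
            eq = codes[:, d:] == codes[:, :-d]
            last_fail = np.maximum.accumulate(
                np.where(~eq, idx[: T - d], -1), axis=1
            )
            run = np.where(eq, idx[: T - d] - last_fail, 0)
            np.maximum(best[:, d:], run, out=best[:, d:])
    i = np.arange(X.shape[1])
    return np.where(best + 1 <= i, best + 1, i + 2)


def entropy_rate_2d(field: MatchLengthField) -> EntropyEstimate:
    """Entropy rate (bits/symbol) of a square matrix from its match lengths.

    ``H = n^2 log2(n^2) / sum_v Λ_v^2``.  On small or pathological inputs H
    may exceed log2 of the alphabet size; callers clamp at the Fano step.
    """
    lam = np.asarray(field.lambdas, dtype=np.float64)
    n = field.side
    if n == 1:
        return EntropyEstimate(H=0.0, n=1, N=1)
    H = (n * n) * np.log2(n * n) / float(np.sum(lam * lam))
    return EntropyEstimate(H=float(H), n=n, N=0)


def entropy_rate_1d(x) -> EntropyEstimate:
    """Entropy rate (bits/symbol) of a single value sequence.

    ``H = T log2(T) / sum_t Λ_t`` with 1D substring match lengths (the
    sequence match-length estimator; the recurrence time of a length-k
    substring scales as 2^(kH), so Λ enters linearly).
    """
    x = np.asarray(x).ravel()
    T = x.shape[0]
    if T < 2:
        raise ValueError("sequence must have length >= 2")
    lam = match_lengths_1d(x).astype(np.float64)
    H = T * np.log2(T) / float(np.sum(lam))
    return EntropyEstimate(H=float(H), n=T, N=int(np.unique(x).size))
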
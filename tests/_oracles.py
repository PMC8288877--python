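"""Independent brute-force oracles for match-length computations.

These transcribe the match-length definitions literally — explicit loops
over every candidate anchor and every block size — and exist solely to
cross-check the optimized implementations on small inputs.
"""

from __future__ import annotations

import numpy as np


def brute_match_lengths_2d(S) -> np.ndarray:
    """Direct enumeration of 2D match lengths.

    For each cell v (0-based (r, c)), try block sides k = 1, 2, ...:
    a size k is admissible if at least one anchor u != v exists with
    u <= v componentwise whose k x k block (lower-right anchored) lies
    inside the matrix.  Λ_v is the smallest admissible k whose block at v
    matches no such anchor; if none exists, Λ_v = k_max(v) + 1 where
    k_max(v) = min(r, c) + 1.
    """
    S = np.asarray(S)
    n = S.shape[0]
    lam = np.zeros((n, n), dtype=int)
    for r in range(n):
        for c in range(n):
            k_cap = min(r, c) + 1
            found = 0
            for k in range(1, k_cap + 1):
                block_v = S[r - k + 1 : r + 1, c - k + 1 : c + 1]
                anchors = [
                    (ur, uc)
                    for ur in range(k - 1, r + 1)
                    for uc in range(k - 1, c + 1)
                    if (ur, uc) != (r, c)
                ]
                if not anchors:
                    continue
                occurs = any(
                    np.array_equal(
                        S[ur - k + 1 : ur + 1, uc - k + 1 : uc + 1], block_v
                    )
                    for ur, uc in anchors
                )
                if not occurs:
                    found = k
                    break
            lam[r, c] = found if found else k_cap + 1
    return lam


def brute_match_lengths_1d(x) -> np.ndarray:
    """Direct enumeration of 1D substring match lengths."""
    x = np.asarray(x).ravel()
    T = x.shape[0]
    lam = np.zeros(T, dtype=int)
    for t in range(T):
        found = 0
        for k in range(1, t + 2):
            sub = tuple(x[t - k + 1 : t + 1])
            earlier = [
                tuple(x[u - k + 1 : u + 1]) for u in range(k - 1, t)
            ]
            if not earlier:
                continue
            if sub not in earlier:
                found = k
                break
        lam[t] = found if found else t + 2
    return lam
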
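"""Predictive congruency: predictability of non-square matrices.

The 2D entropy estimator applies to square matrices only.  A non-square
link-by-time matrix is tiled exactly into squares (greedy Euclidean
tiling: repeatedly carve the largest square off the longer axis) plus
1x1 leftovers ("units").  Atomizing the squares one by one, smallest
first, produces a sequence of stages: at stage i the weighted-average
predictability p_i mixes the surviving squares' predictabilities with the
chance level 1/|A| assigned to every unit, and N_i counts the pieces.
Empirically p_i is linear in N_i with negative slope — longer intact
history means higher predictability — so extrapolating the fitted line to
a single piece (N = 1) scores the whole matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SquareDecomposition",
    "CongruencyFit",
    "decompose",
    "staged_points",
    "fit_extrapolate",
]


@dataclass(frozen=True)
class SquareDecomposition:
    """Exact tiling of an m x T rectangle into squares plus unit cells.

    ``squares`` holds (origin_row, origin_col, side) with side >= 2, sorted
    by side descending; 1x1 pieces are only counted, in ``u``.  The tiling
    covers the rectangle exactly: sum of side^2 plus u equals D = m * T.
    """

    squares: tuple
    Q: int
    u: int
    D: int


@dataclass(frozen=True)
class CongruencyFit:
    """Staged points, fitted line and extrapolated predictability."""

    stages: tuple          # ((N_i, p_i), ...)
    slope: float           # k; NaN when no line could be fitted
    intercept: float       # b; NaN when no line could be fitted
    p: float               # extrapolated predictability k + b (clamped)


def decompose(m: int, T: int) -> SquareDecomposition:
    """Greedy Euclidean tiling of an m-by-T rectangle.

    From an a x b rectangle (a <= b) carve floor(b / a) squares of side a
    along the longer axis and recurse on the a x (b mod a) remainder;
    1-wide strips dissolve into units.
    """
    if m < 1 or T < 1:
        raise ValueError("matrix dimensions must be positive")
    squares = []
    units = 0
    r0, c0, h, w = 0, 0, m, T
    while h > 0 and w > 0:
        a = min(h, w)
        if a == 1:
            units += h * w
            break
        if h <= w:
            for i in range(w // a):
                squares.append((r0, c0 + i * a, a))
            c0 += (w // a) * a
            w = w % a
        else:
            for i in range(h // a):
                squares.append((r0 + i * a, c0, a))
            r0 += (h // a) * a
            h = h % a
    squares.sort(key=lambda s: -s[2])
    return SquareDecomposition(
        squares=tuple(squares), Q=len(squares), u=units, D=m * T
    )


def staged_points(
    dec: SquareDecomposition, square_pis, alphabet_size: int
) -> list:
    """Weighted-average predictability and piece count for each stage.

    ``square_pis`` must align with ``dec.squares`` (sides descending).  At
    stage i the i - 1 smallest squares have been atomized into units; every
    unit contributes the chance level 1 / alphabet_size with weight 1,
    every surviving square its predictability with weight side^2.  Stages
    run i = 1 .. Q-1 (a single stage when Q == 1); N_1 = Q + u.
    """
    square_pis = list(square_pis)
    if len(square_pis) != dec.Q:
        raise ValueError("square_pis must match the number of squares")
    if dec.Q < 1:
        return []
    sides = np.array([s[2] for s in dec.squares], dtype=float)
    areas = sides**2
    pis = np.asarray(square_pis, dtype=float)
    chance = 1.0 / alphabet_size
    stages = []
    n_stages = max(1, dec.Q - 1)
    for i in range(1, n_stages + 1):
        keep = dec.Q - i + 1  # surviving squares, largest first
        atom_area = float(areas[keep:].sum())
        p_i = (
            float((areas[:keep] * pis[:keep]).sum())
            + (atom_area + dec.u) * chance
        ) / dec.D
        N_i = keep + atom_area + dec.u
        stages.append((float(N_i), float(p_i)))
    return stages


def fit_extrapolate(stages, alphabet_size: int) -> CongruencyFit:
    """Fit p_i = k * N_i + b and extrapolate to a single piece (N = 1).

    The extrapolated predictability ``p = k + b`` is clamped to
    ``[1/alphabet_size, 1]``.  With fewer than two distinct stages no line
    exists; the fallback returns the coarsest stage's weighted average.
    """
    stages = list(stages)
    chance = 1.0 / alphabet_size
    if not stages:
        return CongruencyFit(stages=(), slope=np.nan, intercept=np.nan, p=chance)
    Ns = np.array([s[0] for s in stages], dtype=float)
    ps = np.array([s[1] for s in stages], dtype=float)
    if len(stages) < 2 or np.allclose(Ns, Ns[0]):
        if len(stages) >= 2:
            warnings.warn("degenerate stages: all N_i equal; no extrapolation")
        p = float(np.clip(ps[0], chance, 1.0))
        return CongruencyFit(
            stages=tuple(stages), slope=np.nan, intercept=np.nan, p=p
        )
    k, b = np.polyfit(Ns, ps, 1)
    p = float(np.clip(k + b, chance, 1.0))
    return CongruencyFit(stages=tuple(stages), slope=float(k), intercept=float(b), p=p)
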
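"""Link-by-time matrices for temporal networks.

A temporal network on ``n`` nodes is an ordered sequence of weighted
snapshots.  Its *expanded matrix* ``M`` has one row per ordered node pair
(``n^2`` rows, row index = source * n + target) and one column per
snapshot; entry ``(row, t)`` is the weight of that link at time ``t`` (0 if
absent).  Because real snapshots are sparse, most rows are almost all
zeros, which by itself inflates predictability; the *filtered matrix*
``M~`` keeps only the most active links, sorted by activation rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TemporalNetwork",
    "ExpandedMatrix",
    "FilteredMatrix",
    "build_expanded_matrix",
    "filter_matrix",
    "shuffle_matrix",
    "read_temporal_edgelist",
    "quantize_weights",
]


@dataclass
class TemporalNetwork:
    """Node set plus an ordered sequence of weighted edge lists.

    Parameters
    ----------
    n : int
        Number of nodes; node ids must lie in ``[0, n)``.
    snapshots : list of list of (source, target, weight)
        One edge list per time step.  An absent link has weight 0 by
        convention and is simply not listed.
    directed : bool
        If False, each stored edge stands for both ordered pairs.
    weighted : bool
        If False, all weights are expected to be 1.
    """

    n: int
    snapshots: list
    directed: bool = True
    weighted: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one node")
        if len(self.snapshots) < 1:
            raise ValueError("need at least one snapshot")
        for t, snap in enumerate(self.snapshots):
            for (u, v, w) in snap:
                if not (0 <= u < self.n and 0 <= v < self.n):
                    raise ValueError(
                        f"node id out of range in snapshot {t}: ({u}, {v})"
                    )

    @property
    def T(self) -> int:
        return len(self.snapshots)


@dataclass
class ExpandedMatrix:
    """The n^2-by-T link-by-time matrix over a finite value alphabet."""

    values: np.ndarray
    row_links: np.ndarray  # (L, 2) array of (source, target) per row
    n_nodes: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.row_links = np.asarray(self.row_links)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    @property
    def alphabet(self) -> np.ndarray:
        """Distinct values present in the stored grid (zeros included)."""
        return np.unique(self.values)

    @property
    def N(self) -> int:
        return int(self.alphabet.size)

    def to_snapshots(self) -> list:
        """Reconstruct the per-snapshot edge lists (round-trip of build)."""
        out = []
        for t in range(self.T):
            col = self.values[:, t]
            nz = np.flatnonzero(col)
            out.append(
                [
                    (int(self.row_links[i, 0]), int(self.row_links[i, 1]), col[i].item())
                    for i in nz
                ]
            )
        return out

    def to_csv(self, path) -> None:
        """Write the grid as CSV with rows labeled ``src>dst``, columns t0.."""
        labels = [f"{s}>{d}" for s, d in self.row_links]
        df = pd.DataFrame(
            self.values, index=labels, columns=[f"t{t}" for t in range(self.T)]
        )
        df.to_csv(path, index_label="link")


@dataclass
class FilteredMatrix(ExpandedMatrix):
    """Sorted/filtered submatrix of an expanded matrix.

    Rows are ordered by activation rate (fraction of non-zero entries)
    descending, ties broken by original row index; only rows surviving the
    activity filter are kept.
    """

    activation_rates: np.ndarray = field(default_factory=lambda: np.array([]))
    m_theta: int = 1000

    @property
    def m(self) -> int:
        return self.values.shape[0]


def quantize_weights(values: np.ndarray, bins: int) -> np.ndarray:
    """Uniformly bin positive weights into ``bins`` integer levels 1..bins.

    Zeros (absent links) are preserved as 0, keeping the alphabet finite
    while distinguishing absence from the weakest weight class.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros(values.shape, dtype=np.int64)
    nz = values != 0
    if not nz.any():
        return out
    lo, hi = values[nz].min(), values[nz].max()
    if hi == lo:
        out[nz] = 1
        return out
    codes = np.floor((values[nz] - lo) / (hi - lo) * bins).astype(np.int64)
    out[nz] = np.clip(codes, 0, bins - 1) + 1
    return out


def build_expanded_matrix(net: TemporalNetwork, bins: int | None = None) -> ExpandedMatrix:
    """Build the n^2-by-T expanded matrix of a temporal network.

    Rows enumerate all ordered node pairs in fixed order
    ``row = source * n + target`` (self-pairs included; they stay all-zero
    for loop-free networks and are dropped later by filtering).  Undirected
    networks populate both ordered pairs of every edge.

    Parameters
    ----------
    net : TemporalNetwork
    bins : int, optional
        Quantize continuous weights uniformly into this many levels.
        Required when weights are not drawn from a finite integer alphabet.
    """
    n, T = net.n, net.T
    grid = np.zeros((n * n, T), dtype=float)
    for t, snap in enumerate(net.snapshots):
        for (u, v, w) in snap:
            grid[u * n + v, t] += w
            if not net.directed and u != v:
                grid[v * n + u, t] += w
    if bins is not None:
        grid = quantize_weights(grid, bins)
    else:
        rounded = np.rint(grid)
        if not np.allclose(grid, rounded, atol=1e-9):
            raise ValueError(
                "weights are not from a finite integer alphabet; pass "
                "bins=<B> to quantize continuous weights"
            )
        grid = rounded.astype(np.int64)
    links = np.array(
        [(s, d) for s in range(n) for d in range(n)], dtype=np.int64
    )
    return ExpandedMatrix(values=grid, row_links=links, n_nodes=n)


def filter_matrix(M: ExpandedMatrix, m_theta: int = 1000) -> FilteredMatrix:
    """Sort rows by activation rate and keep only the most active links.

    Let ``a_i`` be the sorted (descending) activation rates.  With
    ``m60`` the smallest m whose cumulative activation reaches 60% of the
    total and ``m10`` the number of rows with ``a_i >= 0.1``:

    * if ``m60 < m_theta`` keep ``m60`` rows (the 60% rule);
    * otherwise keep ``max(m_theta, m10)`` rows — at least the ``m_theta``
      most active links — capped at the number of non-zero rows.

    All-zero rows are never retained.
    """
    counts = (M.values != 0).sum(axis=1)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no active links: matrix is all zero")
    L, T = M.values.shape
    order = np.lexsort((np.arange(L), -counts))
    counts_sorted = counts[order]
    n_nonzero = int((counts_sorted > 0).sum())
    cum = np.cumsum(counts_sorted)
    m60 = int(np.searchsorted(cum, 0.6 * total, side="left")) + 1
    if m60 < m_theta:
        m = m60
    else:
        m10 = int((counts_sorted * 10 >= T).sum())
        m = min(max(m_theta, m10), n_nonzero)
    m = min(m, n_nonzero)
    keep = order[:m]
    return FilteredMatrix(
        values=M.values[keep].copy(),
        row_links=M.row_links[keep].copy(),
        n_nodes=M.n_nodes,
        activation_rates=counts[keep] / T,
        m_theta=m_theta,
    )


def shuffle_matrix(Mf: FilteredMatrix, mode: str = "global", seed: int = 0) -> FilteredMatrix:
    """Return a value-shuffled copy of a filtered matrix.

    ``global`` applies one uniform permutation to all entries of the grid —
    the baseline capturing only the link-weight (sparsity) distribution.
    ``per_row`` permutes independently within each row, preserving every
    activation rate exactly — the baseline for per-link predictability.
    """
    rng = np.random.default_rng(seed)
    vals = Mf.values
    if mode == "global":
        flat = vals.ravel().copy()
        rng.shuffle(flat)
        new = flat.reshape(vals.shape)
    elif mode == "per_row":
        new = rng.permuted(vals, axis=1)
    else:
        raise ValueError(f"unknown shuffle mode: {mode!r}")
    return FilteredMatrix(
        values=new,
        row_links=Mf.row_links.copy(),
        n_nodes=Mf.n_nodes,
        activation_rates=(new != 0).mean(axis=1),
        m_theta=Mf.m_theta,
    )


def read_temporal_edgelist(
    path,
    window: float,
    weighted: bool = True,
    directed: bool = True,
) -> TemporalNetwork:
    """Read a timestamped edge list and bin events into snapshots.

    Expects TSV lines ``source<TAB>target<TAB>time[<TAB>weight]``; lines
    starting with ``#`` are comments.  Event times are binned into
    consecutive snapshots of the given window; repeated records of a link
    within one window are aggregated by summing weights (presence for
    unweighted networks).  Node labels are mapped to 0..n-1 in sorted
    order.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                t = float(parts[2])
                w = float(parts[3]) if len(parts) == 4 and weighted else 1.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number") from exc
            events.append((parts[0], parts[1], t, w))
    if not events:
        raise ValueError("no events in input file")

    labels = sorted({e[0] for e in events} | {e[1] for e in events})
    try:  # prefer numeric ordering when every label parses as a number
        labels = sorted(labels, key=float)
    except ValueError:
        pass
    index = {lab: i for i, lab in enumerate(labels)}
    t_min = min(e[2] for e in events)
    T = int(np.floor((max(e[2] for e in events) - t_min) / window)) + 1

    agg: list[dict] = [dict() for _ in range(T)]
    for (a, b, t, w) in events:
        s = int(np.floor((t - t_min) / window))
        key = (index[a], index[b])
        agg[s][key] = agg[s].get(key, 0.0) + w
    snapshots = []
    for s in range(T):
        if weighted:
            snapshots.append([(u, v, w) for (u, v), w in sorted(agg[s].items())])
        else:
            snapshots.append([(u, v, 1.0) for (u, v) in sorted(agg[s])])
    return TemporalNetwork(
        n=len(labels), snapshots=snapshots, directed=directed, weighted=weighted
    )
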
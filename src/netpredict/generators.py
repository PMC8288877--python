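"""Synthetic temporal networks for validating predictability measures.

Three families probe different kinds of regularity:

* **Temporal stochastic block model** — a community-structured graph whose
  topology is frozen after the first snapshot while link weights evolve
  with tunable nearest-neighbour memory: with probability ``p_beta * beta``
  a link copies the weight just written for the adjacent (previous) link
  in the same snapshot (topological memory), with probability
  ``p_gamma * gamma`` it keeps its own previous weight (temporal memory),
  otherwise it draws a fresh uniform weight.
* **2D fractional Gaussian noise** — a Gaussian random field with
  anisotropic power-law correlations ``C(r, phi) = r^-gx cos^2(phi) +
  r^-gy sin^2(phi)``, quantized to a finite alphabet; long-range memory
  with separate temporal (x) and topological (y) decay exponents.
* **Evolving small world** — a ring whose links are randomly rewired by a
  fraction ``p`` at every snapshot; ``p`` interpolates between a frozen,
  perfectly regular network and a fully randomized one.

An IID uniform matrix generator provides the structureless null.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_matrix import TemporalNetwork

__all__ = [
    "TemporalSBMConfig",
    "FGNConfig",
    "SmallWorldConfig",
    "temporal_sbm",
    "sbm_weight_matrix",
    "fgn2d",
    "evolving_small_world",
    "iid_null",
]


@dataclass
class TemporalSBMConfig:
    """Temporal stochastic block model parameters.

    Defaults follow the standard validation setting: 100 nodes in four
    communities, per-node degree 3, 300 snapshots, equal chance of
    activating the structural or the temporal channel, and integer weights
    1..10.
    """

    n: int = 100
    communities: int = 4
    degree: int = 3
    T: int = 300
    beta: float = 0.5
    gamma: float = 0.5
    p_beta: float = 0.5
    p_gamma: float = 0.5
    n_weights: int = 10
    intra_frac: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.beta <= 1 and 0 <= self.gamma <= 1):
            raise ValueError("beta and gamma must lie in [0, 1]")
        if abs(self.p_beta + self.p_gamma - 1.0) > 1e-9:
            raise ValueError("p_beta + p_gamma must equal 1")


@dataclass
class FGNConfig:
    """2D fractional-Gaussian-noise field parameters."""

    size: int = 128
    gx: float = 1.0
    gy: float = 1.0
    bins: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.gx <= 0 or self.gy <= 0:
            raise ValueError("decay exponents must be positive")


@dataclass
class SmallWorldConfig:
    """Evolving small-world (rewired ring) parameters."""

    n: int = 50
    T: int = 300
    p: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("rewiring probability must lie in [0, 1]")


def _sbm_topology(n, communities, degree, intra_frac, rng):
    """Near-regular community graph via biased stub matching.

    Roughly ``intra_frac`` of each node's stubs pair within its community;
    the rest pair across.  Self-loops and duplicate edges are rejected with
    bounded retries, so a handful of nodes may end one short of ``degree``
    when parity forbids an exact match.
    """
    sizes = [n // communities] * communities
    for i in range(n % communities):
        sizes[i] += 1
    if degree >= min(sizes):
        raise ValueError(
            f"degree {degree} infeasible for community size {min(sizes)}"
        )
    membership = np.repeat(np.arange(communities), sizes)
    edges: set = set()

    def try_pair(stubs, same_community_ok):
        stubs = list(stubs)
        leftovers = []
        for _ in range(200):
            if len(stubs) < 2:
                break
            rng.shuffle(stubs)
            next_round = []
            for a, b in zip(stubs[::2], stubs[1::2]):
                key = (min(a, b), max(a, b))
                if (
                    a == b
                    or key in edges
                    or (not same_community_ok and membership[a] == membership[b])
                ):
                    next_round.extend([a, b])
                else:
                    edges.add(key)
            if len(stubs) % 2:
                next_round.append(stubs[-1])
            if len(next_round) == len(stubs):
                break
            stubs = next_round
        leftovers.extend(stubs)
        return leftovers

    leftovers = []
    inter_pool = []
    for c in range(communities):
        nodes = np.flatnonzero(membership == c)
        stubs = np.repeat(nodes, degree).tolist()
        n_intra = int(intra_frac * len(stubs))
        n_intra -= n_intra % 2
        rng.shuffle(stubs)
        leftovers += try_pair(stubs[:n_intra], same_community_ok=True)
        inter_pool += stubs[n_intra:]
    leftovers += try_pair(inter_pool, same_community_ok=False)
    # final relaxed pass: pair whatever is left regardless of community
    try_pair(leftovers, same_community_ok=True)
    return sorted(edges), membership


def sbm_weight_matrix(cfg: TemporalSBMConfig):
    """Generate the SBM topology and its link-by-time weight matrix.

    Returns ``(edges, W)`` where ``edges`` is the fixed undirected edge
    list and ``W`` is the (links x T) integer weight matrix generated
    column by column, top to bottom, with the copy dynamics described in
    the module docstring.  The first link of a column has no previous link
    and falls back to a fresh draw when the structural channel fires.
    """
    rng = np.random.default_rng(cfg.seed)
    edges, _ = _sbm_topology(
        cfg.n, cfg.communities, cfg.degree, cfg.intra_frac, rng
    )
    m = len(edges)
    K = cfg.n_weights
    W = np.zeros((m, cfg.T), dtype=np.int64)
    W[:, 0] = rng.integers(1, K + 1, m)
    p_b, p_g = cfg.p_beta * cfg.beta, cfg.p_gamma * cfg.gamma
    u = rng.random((m, cfg.T))
    fresh = rng.integers(1, K + 1, (m, cfg.T))
    for t in range(1, cfg.T):
        for i in range(m):
            r = u[i, t]
            if r < p_b and i > 0:
                W[i, t] = W[i - 1, t]
            elif r < p_b + p_g:
                W[i, t] = W[i, t - 1]
            else:
                W[i, t] = fresh[i, t]
    return edges, W


def temporal_sbm(cfg: TemporalSBMConfig) -> TemporalNetwork:
    """Temporal SBM as a TemporalNetwork (fixed topology, evolving weights)."""
    edges, W = sbm_weight_matrix(cfg)
    snapshots = [
        [(a, b, int(W[i, t])) for i, (a, b) in enumerate(edges)]
        for t in range(cfg.T)
    ]
    return TemporalNetwork(
        n=cfg.n, snapshots=snapshots, directed=False, weighted=True
    )


def fgn2d(cfg: FGNConfig) -> np.ndarray:
    """Quantized Gaussian random field with power-law correlations.

    The target correlogram ``C(r, phi)`` is evaluated on the periodic
    (minimum-image) grid, turned into a spectral density by FFT (negative
    spectral weight from the non-PSD target is clipped), and filtered white
    noise is transformed back.  The standardized field is quantized into
    ``cfg.bins`` uniform levels, giving a finite-alphabet matrix whose
    correlation structure approximates the target for r >= 1.
    """
    n = cfg.size
    rng = np.random.default_rng(cfg.seed)
    idx = np.arange(n)
    d = np.minimum(idx, n - idx).astype(float)
    dx = d[None, :]  # column offsets = temporal axis
    dy = d[:, None]
    r = np.hypot(dx, dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2 = np.where(r > 0, (dx / np.where(r > 0, r, 1.0)) ** 2, 0.0)
        sin2 = np.where(r > 0, (dy / np.where(r > 0, r, 1.0)) ** 2, 0.0)
        C = np.where(
            r >= 1.0, r**-cfg.gx * cos2 + r**-cfg.gy * sin2, 1.0
        )
    S = np.fft.fft2(C).real
    S = np.clip(S, 0.0, None)
    noise = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    fld = np.fft.ifft2(np.sqrt(S) * np.fft.fft2(noise.real)).real
    fld = (fld - fld.mean()) / fld.std()
    lo, hi = fld.min(), fld.max()
    codes = np.floor((fld - lo) / (hi - lo) * cfg.bins).astype(np.int64)
    return np.clip(codes, 0, cfg.bins - 1)


def evolving_small_world(cfg: SmallWorldConfig) -> TemporalNetwork:
    """Ring network rewired by a fraction p of links at every snapshot.

    Each rewired link keeps one (randomly chosen) endpoint and redraws the
    other uniformly, avoiding self-loops and duplicates; the link count
    stays exactly n throughout.  Unweighted, undirected.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    current = {(i, (i + 1) % n) if i < (i + 1) % n else ((i + 1) % n, i) for i in range(n)}
    current = {(min(a, b), max(a, b)) for a, b in current}
    snapshots = [sorted(current)]
    n_rewire = int(np.floor(cfg.p * len(current)))
    for _ in range(1, cfg.T):
        edges = sorted(current)
        pick = rng.choice(len(edges), size=n_rewire, replace=False)
        for j in pick:
            old = edges[j]
            if old not in current:
                continue
            keep = old[int(rng.integers(2))]
            for _attempt in range(100):
                new_other = int(rng.integers(n))
                cand = (min(keep, new_other), max(keep, new_other))
                if new_other != keep and cand not in current:
                    current.discard(old)
                    current.add(cand)
                    break
        snapshots.append(sorted(current))
    return TemporalNetwork(
        n=n,
        snapshots=[[(a, b, 1) for a, b in snap] for snap in snapshots],
        directed=False,
        weighted=False,
    )


def iid_null(rows: int, cols: int, N: int, seed: int = 0) -> np.ndarray:
    """IID uniform matrix over N symbols (0..N-1); the structureless null."""
    if N < 1:
        raise ValueError("alphabet size must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, N, size=(rows, cols))
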
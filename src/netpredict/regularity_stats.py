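"""Topological regularity from pairwise Hamming distances between links.

For two link rows of the filtered matrix, the normalized Hamming distance
h is the fraction of snapshots in which their entries differ.  The summary
statistic mean(e^(1 - h)) over link pairs is large when many links move in
step (h near 0) and approaches 1 for uncorrelated links.  Comparing it
with the gap between the combined (NTTP) and the per-link (NPIL)
predictability across networks shows where predictability comes from:
temporal and topological regularity rather than their interdependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RegularitySummary", "hamming_regularity", "profile_correlation"]


@dataclass(frozen=True)
class RegularitySummary:
    """Pairwise Hamming statistics for one network."""

    h_pairs: np.ndarray    # normalized distances in [0, 1], one per sampled pair
    mean_e1mh: float       # mean of e^(1 - h); lies in [1, e]
    n_pairs: int


def hamming_regularity(
    Mf, max_pairs: int = 50_000, seed: int = 0
) -> RegularitySummary:
    """Mean e^(1 - h) over (sampled) unordered row pairs of a matrix.

    All pairs are used when their number is at most ``max_pairs``;
    otherwise pairs are sampled uniformly without replacement.
    """
    vals = np.asarray(getattr(Mf, "values", Mf))
    m, T = vals.shape
    if m < 2:
        raise ValueError("need at least two rows for pairwise distances")
    total = m * (m - 1) // 2
    if total <= max_pairs:
        ii, jj = np.triu_indices(m, k=1)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=max_pairs, replace=False)
        # decode the upper-triangular linear index (row-major, k = 1)
        ii = (
            m - 2
            - np.floor(
                (np.sqrt(4 * m * (m - 1) - 8 * flat.astype(float) - 7) - 1) / 2
            )
        ).astype(np.int64)
        jj = (flat + ii * (ii + 1) // 2 - m * ii + ii + 1).astype(np.int64)
    h = (vals[ii] != vals[jj]).mean(axis=1)
    return RegularitySummary(
        h_pairs=h, mean_e1mh=float(np.mean(np.exp(1.0 - h))), n_pairs=len(h)
    )


def profile_correlation(summaries, profiles) -> float:
    """Pearson correlation of mean e^(1 - h) with NTTP - mean(NPIL).

    One point per network.  Returns NaN (with a warning) when either
    statistic has zero variance across the networks.
    """
    if len(summaries) != len(profiles):
        raise ValueError("need one summary per profile")
    if len(summaries) < 3:
        raise ValueError("need at least three networks")
    x = np.array([s.mean_e1mh for s in summaries])
    y = np.array([p.NTTP - np.nanmean(p.NPIL) for p in profiles])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance across networks; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)
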
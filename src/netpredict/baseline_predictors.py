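"""Markov baseline predictor for temporal network matrices.

Treats the network as a set of uncorrelated link time series: each row of
the filtered matrix gets its own add-alpha-smoothed first-order Markov
chain, fitted on the leading training fraction of snapshots.  Held-out
snapshots are predicted by the most likely transition from the previously
observed symbol (training-set mode for states never seen in training, the
smaller symbol on ties).  The resulting accuracy is a concrete algorithm's
performance to hold against the information-theoretic predictability
bounds, which no algorithm can exceed.
"""

from __future__ import annotations

from math import ceil

import numpy as np

__all__ = ["markov_accuracy"]


def markov_accuracy(Mf, train_frac: float = 0.8, alpha: float = 1.0) -> float:
    """Prediction accuracy of per-row first-order Markov chains.

    Parameters
    ----------
    Mf : FilteredMatrix or 2D array
        Link-by-time matrix of symbols.
    train_frac : float
        Leading fraction of columns used for fitting (ceil'd); the rest
        are evaluated.
    alpha : float
        Add-alpha smoothing constant for the transition counts.

    Returns
    -------
    float
        Fraction of correctly predicted held-out entries over all rows.
    """
    vals = np.asarray(getattr(Mf, "values", Mf))
    m, T = vals.shape
    if T < 5:
        raise ValueError("need at least 5 snapshots for a train/test split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    T_train = ceil(train_frac * T)
    if T_train >= T:
        T_train = T - 1
    correct = 0
    total = 0
    for row in vals:
        train = row[:T_train]
        syms, inv = np.unique(train, return_inverse=True)
        K = syms.size
        counts = np.zeros((K, K))
        np.add.at(counts, (inv[:-1], inv[1:]), 1.0)
        counts += alpha
        # argmax returns the first maximum; syms is sorted, so ties break
        # toward the smaller symbol
        best_next = syms[np.argmax(counts, axis=1)]
        mode = syms[np.argmax(np.bincount(inv, minlength=K))]
        lookup = {s: best_next[k] for k, s in enumerate(syms)}
        for t in range(T_train, T):
            prev = row[t - 1]
            pred = lookup.get(prev, mode)
            correct += int(pred == row[t])
            total += 1
    return correct / total
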
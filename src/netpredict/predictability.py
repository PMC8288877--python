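"""Predictability bounds from entropy rates via the Fano inequality.

Given the entropy rate H of a process over an alphabet of N values, the
maximum achievable prediction accuracy Π solves

    H = -(Π log2 Π + (1 - Π) log2(1 - Π)) + (1 - Π) log2(N - 1)

whose right-hand side decreases strictly from log2 N at Π = 1/N to 0 at
Π = 1, so the solution is unique.  Applied to the 2D entropy of the
link-by-time matrix this yields the topological-temporal predictability
(TTP); applied per link time series it yields the predictability of
individual links (PIL), whose network average is the temporal
predictability (TeP).  Sparsity alone makes networks look predictable, so
every quantity is also normalized against its value-shuffled baseline:
NTTP = (TTP - TTP_bl) / (1 - TTP_bl), and likewise NPIL / NTeP per link.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .congruency import CongruencyFit, decompose, fit_extrapolate, staged_points
from .core_matrix import FilteredMatrix, shuffle_matrix
from .lz_entropy import (
    entropy_rate_1d,
    entropy_rate_2d,
    match_length_field,
    match_lengths_1d_rows,
)

__all__ = [
    "PredictabilityProfile",
    "solve_fano",
    "ttp",
    "congruency_fit",
    "pil",
    "pil_rows",
    "normalize",
    "profile",
]


def solve_fano(H: float, N: int) -> float:
    """Invert the Fano-type bound: maximum accuracy for entropy H, alphabet N.

    Closed-form limits: H = 0 gives Π = 1 (a deterministic process is
    perfectly predictable); H >= log2 N gives Π = 1/N (chance level); a
    single-value alphabet is always perfectly predictable.  Otherwise the
    unique root in (1/N, 1) is found by bracketed root solving to 1e-9.
    """
    if N < 1:
        raise ValueError("alphabet size must be >= 1")
    if H < 0:
        raise ValueError("entropy rate must be non-negative")
    if N == 1 or H == 0.0:
        return 1.0
    log2N = np.log2(N)
    if H >= log2N:
        return 1.0 / N
    logNm1 = np.log2(N - 1)

    def fano_gap(p: float) -> float:
        ent = 0.0
        if 0.0 < p < 1.0:
            ent = -(p * np.log2(p) + (1.0 - p) * np.log2(1.0 - p))
        return ent + (1.0 - p) * logNm1 - H

    return float(brentq(fano_gap, 1.0 / N, 1.0, xtol=1e-9))


def _square_pi(vals: np.ndarray, N: int) -> float:
    H = entropy_rate_2d(match_length_field(vals)).H
    return solve_fano(H, N)


def congruency_fit(Mf: FilteredMatrix) -> CongruencyFit:
    """Square-decomposition fit of a (possibly non-square) filtered matrix.

    Each tile's predictability comes from the 2D entropy estimator with the
    global alphabet of the matrix; units score the chance level.  An m = T
    matrix yields a single full-size square (degenerate fit whose value is
    the direct estimate).
    """
    vals = Mf.values
    N = int(np.unique(vals).size)
    dec = decompose(vals.shape[0], vals.shape[1])
    pis = [
        _square_pi(vals[r0 : r0 + e, c0 : c0 + e], N)
        for (r0, c0, e) in dec.squares
    ]
    stages = staged_points(dec, pis, N)
    return fit_extrapolate(stages, N)


def ttp(Mf: FilteredMatrix) -> float:
    """Topological-temporal predictability of a filtered matrix.

    Square matrices are scored directly via the 2D entropy estimator and
    the Fano bound; non-square matrices via predictive congruency.
    """
    vals = Mf.values
    m, T = vals.shape
    N = int(np.unique(vals).size)
    if m == T:
        return _square_pi(vals, N)
    return congruency_fit(Mf).p


def pil(row) -> float:
    """Predictability of an individual link from its time series alone.

    Uses the row's own alphabet: a link that never changes is perfectly
    predictable in isolation (Π = 1).
    """
    row = np.asarray(row).ravel()
    N_row = int(np.unique(row).size)
    if N_row == 1:
        return 1.0
    return solve_fano(entropy_rate_1d(row).H, N_row)


def pil_rows(X) -> np.ndarray:
    """Per-link predictability for every row of a matrix (batched PIL)."""
    X = np.asarray(X)
    T = X.shape[1]
    lam = match_lengths_1d_rows(X).astype(np.float64)
    H = T * np.log2(T) / lam.sum(axis=1)
    srt = np.sort(X, axis=1)
    n_row = (np.diff(srt, axis=1) != 0).sum(axis=1) + 1
    return np.array(
        [
            1.0 if nr == 1 else solve_fano(h, int(nr))
            for h, nr in zip(H, n_row)
        ]
    )


def normalize(p: float, b: float) -> float:
    """Normalize a predictability over its shuffled baseline.

    Returns 1 when both saturate (b = p = 1), otherwise
    (p - b)/(1 - b) clamped to [0, 1].  b = 1 with p < 1 is undefined and
    yields NaN with a warning.
    """
    if b >= 1.0 - 1e-12:
        if p >= 1.0 - 1e-12:
            return 1.0
        warnings.warn("baseline is 1 but predictability is below 1; undefined")
        return float("nan")
    return float(np.clip((p - b) / (1.0 - b), 0.0, 1.0))


@dataclass
class PredictabilityProfile:
    """Full predictability profile of one temporal network matrix."""

    TTP: float
    TTP_bl: float
    NTTP: float
    PIL: np.ndarray
    PIL_bl: np.ndarray
    NPIL: np.ndarray
    TeP: float
    NTeP: float
    N: int
    m: int
    T: int
    n_shuffles: int
    seed: int
    congruency: CongruencyFit | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "TTP": self.TTP,
            "TTP_bl": self.TTP_bl,
            "NTTP": self.NTTP,
            "TeP": self.TeP,
            "NTeP": self.NTeP,
            "N": self.N,
            "m": self.m,
            "T": self.T,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_frame(self, name: str = "network") -> pd.DataFrame:
        d = self.to_dict()
        d["network"] = name
        return pd.DataFrame(
            [d],
            columns=["network", "TTP", "TTP_bl", "NTTP", "TeP", "NTeP", "N", "m", "T"],
        )


def profile(
    Mf: FilteredMatrix, n_shuffles: int = 10, seed: int = 0
) -> PredictabilityProfile:
    """Compute TTP, TeP, per-link PIL and all shuffle-normalized variants.

    Baselines average over ``n_shuffles`` independent shuffles (global for
    TTP, within-row for PIL); all randomness derives from ``seed``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_shuffles)
    vals = Mf.values
    m, T = vals.shape
    N = int(np.unique(vals).size)

    fit = congruency_fit(Mf) if m != T else None
    p_ttp = fit.p if fit is not None else _square_pi(vals, N)
    bl_vals = [
        ttp(shuffle_matrix(Mf, "global", int(s))) for s in seeds[:n_shuffles]
    ]
    ttp_bl = float(np.mean(bl_vals))
    nttp = normalize(p_ttp, ttp_bl)

    pil_vals = pil_rows(vals)
    per_row_bl = np.zeros((n_shuffles, m))
    for j, s in enumerate(seeds[n_shuffles:]):
        shuffled = shuffle_matrix(Mf, "per_row", int(s)).values
        per_row_bl[j] = pil_rows(shuffled)
    pil_bl = per_row_bl.mean(axis=0)
    npil = np.array([normalize(p, b) for p, b in zip(pil_vals, pil_bl)])

    return PredictabilityProfile(
        TTP=p_ttp,
        TTP_bl=ttp_bl,
        NTTP=nttp,
        PIL=pil_vals,
        PIL_bl=pil_bl,
        NPIL=npil,
        TeP=float(np.mean(pil_vals)),
        NTeP=float(np.nanmean(npil)),
        N=N,
        m=m,
        T=T,
        n_shuffles=n_shuffles,
        seed=seed,
        congruency=fit,
    )
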
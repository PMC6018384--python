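"""Cosine similarity between spectra and replicate-reproducibility summaries.

Cosine similarity (CS) is the normalised inner product of two non-negative
intensity vectors, so it lies in [0, 1]; 1 - CS serves as the clustering
distance. The vectors compared are rows of the back-filled feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleRecord

__all__ = [
    "cosine_similarity",
    "pairwise_cs",
    "average_cs",
    "interval_statistics",
    "IntervalStats",
]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """CS = <u, v> / (||u|| ||v||) for non-negative vectors of equal length."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("intensities must be non-negative")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def pairwise_cs(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample-by-sample cosine-similarity matrix with unit diagonal."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        zero = list(matrix.index[norms == 0])
        raise ValueError(f"zero intensity row(s): {zero}")
    S = (X @ X.T) / np.outer(norms, norms)
    S = np.clip(S, 0.0, 1.0)
    S = 0.5 * (S + S.T)  # exact symmetry
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=matrix.index, columns=matrix.index)


def average_cs(sim: pd.DataFrame, group: list[str] | set[str]) -> float:
    """Mean of the off-diagonal pairwise CS values within a replicate group."""
    ids = sorted(group)
    if len(ids) < 2:
        raise ValueError("ACS needs a group of at least 2 samples")
    sub = sim.loc[ids, ids].to_numpy()
    iu = np.triu_indices(len(ids), k=1)
    return float(sub[iu].mean())


@dataclass
class IntervalStats:
    """Per-1-kDa-interval diagnostics over the 2-20 kDa range."""

    low: float
    high: float
    n_signals: int
    summed_intensity: float
    mean_acs: float  # NaN when the interval holds no bins
    n_discriminative: int


def interval_statistics(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    discriminative_bins: set[str] | None = None,
    low: float = 2000.0,
    high: float = 20000.0,
    width: float = 1000.0,
) -> pd.DataFrame:
    """Split the mass range into 1-kDa intervals and summarise each.

    Per interval: the number of mass bins, the summed intensity over all
    matrix cells, the mean over cultures of the ACS computed on the
    columns restricted to the interval, and the count of discriminative
    bins. Cultures whose restricted vectors are all-zero (and intervals
    with no bins at all) are excluded from the ACS mean, reported as NaN
    rather than zero. Max-normalised copies of each variable are appended
    (columns suffixed ``_norm``).
    """
    from .features import bin_masses_of

    bin_masses = bin_masses_of(matrix)
    by_culture: dict[str, list[str]] = {}
    for rec in samples:
        by_culture.setdefault(rec.culture_id, []).append(rec.sample_id)
    edges = np.arange(low, high + width / 2, width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_iv = (bin_masses >= lo) & (bin_masses < hi)
        cols = matrix.columns[in_iv]
        n_signals = int(in_iv.sum())
        summed = float(matrix.loc[:, cols].to_numpy().sum()) if n_signals else 0.0
        n_disc = (
            len([c for c in cols if c in discriminative_bins])
            if discriminative_bins is not None
            else 0
        )
        acs_vals = []
        if n_signals:
            for culture, sids in sorted(by_culture.items()):
                sids = [s for s in sids if s in matrix.index]
                if len(sids) < 2:
                    continue
                sub = matrix.loc[sids, cols].to_numpy(dtype=float)
                norms = np.linalg.norm(sub, axis=1)
                if np.any(norms == 0):
                    continue
                S = (sub @ sub.T) / np.outer(norms, norms)
                iu = np.triu_indices(len(sids), k=1)
                acs_vals.append(float(np.clip(S[iu], 0, 1).mean()))
        mean_acs = float(np.mean(acs_vals)) if acs_vals else np.nan
        rows.append(
            {
                "low": lo,
                "high": hi,
                "n_signals": n_signals,
                "summed_intensity": summed,
                "mean_acs": mean_acs,
                "n_discriminative": n_disc,
            }
        )
    df = pd.DataFrame(rows)
    for col in ["n_signals", "summed_intensity", "mean_acs", "n_discriminative"]:
        mx = df[col].max(skipna=True)
        df[col + "_norm"] = df[col] / mx if mx and mx > 0 else 0.0
    return df
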
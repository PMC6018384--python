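"""Peak alignment across spectra and feature-matrix construction.

Peaks from all spectra are pooled and divisively binned: a candidate group
is split at its largest internal mass gap until every member lies within a
relative tolerance (default 0.002) of the group mean and no spectrum
contributes two peaks to the same bin. Each bin becomes one column of the
feature matrix; spectra lacking a peak in a bin are back-filled with the
intensity of their preprocessed trace at the bin mass, so the matrix has
no missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleRecord
from .preprocess import PeakList, PreprocessedSpectrum

__all__ = ["MassBin", "bin_peaks", "build_feature_matrix", "qc_filter_technical"]


@dataclass
class MassBin:
    """One aligned mass signal: mean mass plus (sample_id, peak index) members."""

    bin_mass: float
    members: list[tuple[str, int]]


def _group_ok(masses: np.ndarray, sample_ids: list[str], tolerance: float) -> bool:
    mean = masses.mean()
    if np.any(np.abs(masses - mean) / mean > tolerance):
        return False
    return len(set(sample_ids)) == len(sample_ids)


def bin_peaks(peaklists: list[PeakList], tolerance: float = 0.002) -> list[MassBin]:
    """Align peaks into shared mass bins by divisive largest-gap splitting.

    Deterministic and invariant to the order of the input peak lists:
    the pooled peaks are sorted by mass (ties broken by sample id and
    peak index) before splitting, and every input peak ends up in exactly
    one bin.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    pooled = []
    for pl in peaklists:
        for j in range(len(pl)):
            pooled.append((float(pl.peak_masses[j]), pl.sample_id, j))
    if not pooled:
        return []
    pooled.sort()
    masses = np.array([p[0] for p in pooled])
    bins: list[MassBin] = []
    stack: list[tuple[int, int]] = [(0, len(pooled))]  # half-open index ranges
    accepted: list[tuple[int, int]] = []
    while stack:
        lo, hi = stack.pop()
        seg = masses[lo:hi]
        sids = [pooled[k][1] for k in range(lo, hi)]
        if hi - lo == 1 or _group_ok(seg, sids, tolerance):
            accepted.append((lo, hi))
            continue
        gaps = np.diff(seg)
        split = int(np.argmax(gaps)) + 1  # ties -> lowest index
        stack.append((lo + split, hi))
        stack.append((lo, lo + split))
    for lo, hi in sorted(accepted):
        seg = masses[lo:hi]
        members = [(pooled[k][1], pooled[k][2]) for k in range(lo, hi)]
        bins.append(MassBin(bin_mass=float(seg.mean()), members=members))
    return bins


def build_feature_matrix(
    bins: list[MassBin],
    peaklists: dict[str, PeakList],
    preprocessed: dict[str, PreprocessedSpectrum],
) -> pd.DataFrame:
    """Samples x bins intensity matrix with trace back-fill.

    Cell (s, b) is the detected peak intensity when sample s has a member
    peak in bin b, else the linearly interpolated intensity of s's
    preprocessed trace at the bin mass. Columns are sorted by mass and
    labelled ``mass_<Da>``.
    """
    sample_ids = list(preprocessed.keys())
    order = np.argsort([b.bin_mass for b in bins], kind="stable")
    bins_sorted = [bins[i] for i in order]
    bin_masses = np.array([b.bin_mass for b in bins_sorted])
    mat = np.empty((len(sample_ids), len(bins_sorted)))
    for i, sid in enumerate(sample_ids):
        mat[i] = preprocessed[sid].interpolate(bin_masses)
    col_of = {}
    for j, b in enumerate(bins_sorted):
        for sid, pk_idx in b.members:
            if sid not in preprocessed:
                continue
            # same-sample duplicates that survived splitting: keep the stronger
            val = float(peaklists[sid].peak_intensities[pk_idx])
            key = (sid, j)
            if key in col_of:
                val = max(val, col_of[key])
            col_of[key] = val
    row_index = {sid: i for i, sid in enumerate(sample_ids)}
    for (sid, j), val in col_of.items():
        mat[row_index[sid], j] = val
    columns = [f"mass_{m:.4f}" for m in bin_masses]
    df = pd.DataFrame(mat, index=sample_ids, columns=columns)
    df.attrs["bin_masses"] = bin_masses
    return df


def bin_masses_of(matrix: pd.DataFrame) -> np.ndarray:
    """Recover the numeric bin masses from a feature matrix's column labels."""
    if "bin_masses" in matrix.attrs:
        return np.asarray(matrix.attrs["bin_masses"], dtype=float)
    return np.array([float(c.removeprefix("mass_")) for c in matrix.columns])


def qc_filter_technical(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    acs_cutoff: float = 0.9,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Flag technical outliers by average cosine similarity (ACS).

    For each spectrum the ACS to the other technical replicates of its
    (culture, biological replicate) group is computed on the feature-matrix
    rows. Outliers are removed iteratively: while the group's worst
    spectrum falls below the cutoff it is discarded and the remaining
    ACS recomputed, so a single aberrant replicate does not drag its
    well-behaved partners below the cutoff with it. Spectra without
    technical partners are kept and flagged (NaN ACS) in the report.

    Returns (kept sample_ids, discarded sample_ids, report) where the
    report has columns sample_id, acs, kept.
    """
    from .similarity import cosine_similarity

    by_group: dict[tuple[str, int], list[str]] = {}
    for rec in samples:
        by_group.setdefault((rec.culture_id, rec.biological_replicate), []).append(
            rec.sample_id
        )

    def acs_of(sid: str, others: list[str]) -> float:
        return float(
            np.mean(
                [
                    cosine_similarity(matrix.loc[sid].to_numpy(), matrix.loc[o].to_numpy())
                    for o in others
                ]
            )
        )

    rows = []
    kept, discarded = [], []
    for (_, _), sids in sorted(by_group.items()):
        if len(sids) == 1:
            rows.append({"sample_id": sids[0], "acs": np.nan, "kept": True})
            kept.append(sids[0])
            continue
        active = list(sids)
        final_acs: dict[str, float] = {}
        while len(active) >= 2:
            acs = {s: acs_of(s, [o for o in active if o != s]) for s in active}
            worst = min(sorted(active), key=lambda s: acs[s])
            if acs[worst] >= acs_cutoff:
                final_acs.update(acs)
                break
            final_acs[worst] = acs[worst]
            active.remove(worst)
            discarded.append(worst)
        if len(active) == 1:
            final_acs.setdefault(active[0], np.nan)
        kept.extend(active)
        for sid in sids:
            rows.append(
                {"sample_id": sid, "acs": final_acs.get(sid, np.nan), "kept": sid in active}
            )
    report = pd.DataFrame(rows)
    return kept, discarded, report
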
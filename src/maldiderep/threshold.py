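"""F1-optimal cosine-similarity threshold against a 16S reference.

Every unordered sample pair is labelled *intra* (same species-level
reference bin) or *inter* (different bins); a CS threshold t classifies a
pair positive when CS >= t. Scanning t over 0..1 in 0.01 steps gives
precision = TP/(TP+FP), recall = TP/(TP+FN) and F1 = 2PR/(P+R) per
threshold. The operating threshold T_CS is chosen by 2-fold cross
validation: pairs are split 50/50 at random, each half is used once for
training (pick the best-F1 grid threshold, ties resolved by averaging the
tied grid points) and once for testing (precision/recall at the threshold
picked on the other half); T_CS is the mean of the two training picks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqsim import SPECIES_IDENTITY_CUTOFF

__all__ = [
    "label_pairs",
    "confusion_at",
    "threshold_curve",
    "optimize_threshold",
    "ThresholdResult",
    "GRID",
]

#: CS threshold grid: 0 to 1 in 0.01 steps.
GRID = np.round(np.arange(0, 101) / 100.0, 2)

INTRA, INTER = "intra", "inter"


def label_pairs(
    sim: pd.DataFrame,
    reference,
    identity_cutoff: float = SPECIES_IDENTITY_CUTOFF,
    culture_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the table of all unordered sample pairs with CS and relation.

    ``reference`` is either a mapping sample/culture -> phylotype label
    (phylotype mode) or a percent-identity DataFrame (sequence mode, pairs
    with identity >= ``identity_cutoff`` are intra). With ``culture_of``
    given, culture-level references are broadcast to samples.

    Returns a DataFrame with columns sample_a, sample_b (a < b), cs,
    relation.
    """
    ids = list(sim.index)

    def ref_key(sid: str) -> str:
        if culture_of is not None and sid not in _ref_ids:
            return culture_of[sid]
        return sid

    if isinstance(reference, pd.DataFrame):
        _ref_ids = set(reference.index)
        missing = [s for s in ids if ref_key(s) not in _ref_ids]
        if missing:
            raise ValueError(f"no reference sequence for sample(s): {missing}")

        def relation(a: str, b: str) -> str:
            ident = float(reference.loc[ref_key(a), ref_key(b)])
            return INTRA if ident >= identity_cutoff else INTER

    else:
        _ref_ids = set(reference)
        missing = [s for s in ids if ref_key(s) not in _ref_ids]
        if missing:
            raise ValueError(f"no reference label for sample(s): {missing}")

        def relation(a: str, b: str) -> str:
            return INTRA if reference[ref_key(a)] == reference[ref_key(b)] else INTER

    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            rows.append(
                {
                    "sample_a": min(a, b),
                    "sample_b": max(a, b),
                    "cs": float(sim.loc[a, b]),
                    "relation": relation(a, b),
                }
            )
    return pd.DataFrame(rows)


def confusion_at(pairs: pd.DataFrame, t: float) -> dict:
    """Confusion counts and scores at one threshold (CS >= t is positive).

    precision/recall/F1 are NaN when their denominator is zero.
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    cs = pairs["cs"].to_numpy()
    intra = (pairs["relation"] == INTRA).to_numpy()
    pos = cs >= t
    tp = int(np.sum(pos & intra))
    fp = int(np.sum(pos & ~intra))
    tn = int(np.sum(~pos & ~intra))
    fn = int(np.sum(~pos & intra))
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    recall = tp / (tp + fn) if (tp + fn) else np.nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if (tp + fp) and (tp + fn) and (precision + recall) > 0
        else np.nan
    )
    return {
        "t": t,
        "TP": tp,
        "FP": fp,
        "TN": tn,
        "FN": fn,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def threshold_curve(pairs: pd.DataFrame, grid: np.ndarray = GRID) -> pd.DataFrame:
    """Confusion table and scores at every grid threshold."""
    return pd.DataFrame([confusion_at(pairs, float(t)) for t in grid])


def _best_threshold(pairs: pd.DataFrame, grid: np.ndarray = GRID) -> float:
    """Grid threshold with the highest F1; ties -> mean of tied grid points."""
    curve = threshold_curve(pairs, grid)
    f1 = curve["f1"].to_numpy()
    if np.all(np.isnan(f1)):
        raise ValueError("F1 undefined at every threshold (single-relation input?)")
    best = np.nanmax(f1)
    tied = curve["t"].to_numpy()[np.isclose(f1, best)]
    return float(np.mean(tied))


@dataclass
class ThresholdResult:
    """Outcome of the 2-fold cross-validated threshold search."""

    t_cs: float
    precision_test: float
    recall_test: float
    fold_thresholds: list[float]
    fold_precisions: list[float]
    fold_recalls: list[float]
    seed: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def optimize_threshold(
    pairs: pd.DataFrame,
    seed: int,
    grid: np.ndarray = GRID,
    split: bool = True,
) -> ThresholdResult:
    """2-fold cross-validated F1-optimal CS threshold.

    With ``split=False`` the whole pair table is used as a single
    training set and the global best-F1 grid threshold is returned (test
    precision/recall then refer to the same data).
    """
    relations = set(pairs["relation"])
    if relations != {INTRA, INTER}:
        raise ValueError("pair table must contain both intra and inter pairs")
    if not split:
        t = _best_threshold(pairs, grid)
        c = confusion_at(pairs, min(t, 1.0))
        return ThresholdResult(t, c["precision"], c["recall"], [t], [c["precision"]], [c["recall"]], seed)
    if len(pairs) < 4:
        raise ValueError("need at least 4 pairs for 2-fold cross validation")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    half = len(pairs) // 2
    folds = [pairs.iloc[perm[:half]], pairs.iloc[perm[half:]]]
    ts, ps, rs = [], [], []
    for k in (0, 1):
        train, test = folds[k], folds[1 - k]
        if set(train["relation"]) != {INTRA, INTER}:
            raise ValueError("a fold lost one relation class; use more pairs")
        t = _best_threshold(train, grid)
        ts.append(t)
        c = confusion_at(test, min(t, 1.0))
        ps.append(c["precision"])
        rs.append(c["recall"])
    return ThresholdResult(
        t_cs=float(np.mean(ts)),
        precision_test=float(np.nanmean(ps)),
        recall_test=float(np.nanmean(rs)),
        fold_thresholds=ts,
        fold_precisions=ps,
        fold_recalls=rs,
        seed=seed,
    )
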
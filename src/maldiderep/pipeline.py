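"""End-to-end workflows: dereplicate a collection, benchmark against 16S.

These functions are the library behind the command-line interface: they
chain preprocessing, peak binning, the feature matrix, cosine similarity,
UPGMA clustering and (for the benchmark) the reference comparison and
threshold optimisation, under one reproducible configuration object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import (
    Dendrogram,
    OTUPartition,
    PartitionComparison,
    compare_partitions,
    cut,
    upgma,
)
from .features import bin_peaks, build_feature_matrix, qc_filter_technical
from .io import SampleRecord, SequenceRecord, Spectrum
from .preprocess import PreprocessParams, preprocess_pipeline
from .seqsim import SPECIES_IDENTITY_CUTOFF, identity_matrix, identity_to_distance
from .similarity import average_cs, pairwise_cs
from .threshold import ThresholdResult, label_pairs, optimize_threshold

__all__ = [
    "RunConfig",
    "build_features",
    "acs_summary",
    "run_dereplicate",
    "run_benchmark",
]


@dataclass
class RunConfig:
    """All pipeline parameters with their conventional defaults.

    ``t_cs`` defaults to 0.92, the threshold that mimics closest-type-
    strain phylotype delineation; 0.79 mimics the 98.65% sequence rule.
    """

    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    bin_tolerance: float = 0.002
    acs_cutoff: float = 0.9
    t_cs: float = 0.92
    identity_cutoff: float = SPECIES_IDENTITY_CUTOFF
    grid_step: float = 0.01
    lfdr_cutoff: float = 0.2
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def build_features(
    spectra: list[Spectrum],
    samples: list[SampleRecord],
    config: RunConfig = RunConfig(),
    qc: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess, bin and assemble the QC-filtered feature matrix.

    Returns (feature matrix, QC report); discarded technical outliers are
    dropped from the matrix.
    """
    traces, peaklists = {}, {}
    for spec in spectra:
        trace, peaks = preprocess_pipeline(spec, config.preprocess)
        traces[spec.sample_id] = trace
        peaklists[spec.sample_id] = peaks
    bins = bin_peaks(list(peaklists.values()), tolerance=config.bin_tolerance)
    if not bins:
        raise ValueError("no peaks detected in any spectrum")
    matrix = build_feature_matrix(bins, peaklists, traces)
    if not qc:
        return matrix, pd.DataFrame()
    kept, _discarded, report = qc_filter_technical(
        matrix, samples, acs_cutoff=config.acs_cutoff
    )
    return matrix.loc[kept], report


def acs_summary(sim: pd.DataFrame, samples: list[SampleRecord]) -> dict:
    """Mean technical vs biological reproducibility.

    Technical ACS averages CS over pairs from the same (culture,
    biological replicate); biological ACS over pairs from the same culture
    but different biological replicates.
    """
    tech_pairs, bio_pairs = [], []
    recs = [r for r in samples if r.sample_id in sim.index]
    for i, a in enumerate(recs):
        for b in recs[i + 1 :]:
            if a.culture_id != b.culture_id:
                continue
            v = float(sim.loc[a.sample_id, b.sample_id])
            if a.biological_replicate == b.biological_replicate:
                tech_pairs.append(v)
            else:
                bio_pairs.append(v)
    return {
        "technical_acs": float(np.mean(tech_pairs)) if tech_pairs else np.nan,
        "biological_acs": float(np.mean(bio_pairs)) if bio_pairs else np.nan,
    }


@dataclass
class DereplicationResult:
    partition: OTUPartition
    representatives: dict[int, str]  # cluster label -> representative sample
    dendrogram: Dendrogram
    similarity: pd.DataFrame
    matrix: pd.DataFrame
    qc_report: pd.DataFrame
    config: RunConfig


def run_dereplicate(
    spectra: list[Spectrum],
    samples: list[SampleRecord],
    config: RunConfig = RunConfig(),
) -> DereplicationResult:
    """Cluster a spectrum collection into OTUs at the configured T_CS.

    The representative of each OTU is the member with the highest mean CS
    to its co-members (singletons represent themselves).
    """
    matrix, qc_report = build_features(spectra, samples, config)
    if matrix.shape[0] == 1:
        part = OTUPartition({matrix.index[0]: 1}, cut_height=1 - config.t_cs)
        return DereplicationResult(
            part, {1: matrix.index[0]}, Dendrogram([matrix.index[0]], np.empty((0, 4))),
            pd.DataFrame([[1.0]], index=matrix.index, columns=matrix.index),
            matrix, qc_report, config,
        )
    sim = pairwise_cs(matrix)
    dend = upgma(1.0 - sim)
    part = cut(dend, height=1.0 - config.t_cs)
    reps: dict[int, str] = {}
    for lab, members in part.clusters().items():
        if len(members) == 1:
            reps[lab] = members[0]
            continue
        best = max(
            members,
            key=lambda s: (
                float(np.mean([sim.loc[s, o] for o in members if o != s])),
                s,
            ),
        )
        reps[lab] = best
    return DereplicationResult(part, reps, dend, sim, matrix, qc_report, config)


@dataclass
class BenchmarkResult:
    threshold: ThresholdResult
    ms_partition: OTUPartition
    ref_partition: OTUPartition
    comparison: PartitionComparison
    acs: dict
    similarity: pd.DataFrame
    pairs: pd.DataFrame
    config: RunConfig


def run_benchmark(
    spectra: list[Spectrum],
    samples: list[SampleRecord],
    reference,
    config: RunConfig = RunConfig(),
) -> BenchmarkResult:
    """Full comparison of MS clustering against a 16S-style reference.

    ``reference`` is a culture -> phylotype mapping (phylotype mode) or a
    list of one SequenceRecord per culture (sequence mode; pairs at
    identity >= 98.65% count as intra-related). Computes the pair table,
    the 2-fold cross-validated optimal T_CS, MS OTUs at that threshold,
    the reference partition and the dereplication comparison.
    """
    matrix, _ = build_features(spectra, samples, config)
    kept_samples = [r for r in samples if r.sample_id in matrix.index]
    culture_of = {r.sample_id: r.culture_id for r in kept_samples}
    missing = [
        r.culture_id
        for r in kept_samples
        if r.culture_id
        not in (
            {s.seq_id for s in reference}
            if isinstance(reference, list)
            else set(reference)
        )
    ]
    if missing:
        raise ValueError(f"missing reference for culture(s): {sorted(set(missing))}")
    sim = pairwise_cs(matrix)

    if isinstance(reference, list):
        ident = identity_matrix(reference)
        pairs = label_pairs(
            sim, ident, identity_cutoff=config.identity_cutoff, culture_of=culture_of
        )
        ref_dend = upgma(identity_to_distance(ident))
        ref_part = cut(ref_dend, height=1.0 - config.identity_cutoff / 100.0)
    else:
        pairs = label_pairs(sim, reference, culture_of=culture_of)
        cultures = sorted(set(culture_of.values()))
        labels = sorted(set(reference[c] for c in cultures))
        ref_part = OTUPartition(
            {c: labels.index(reference[c]) + 1 for c in cultures}, cut_height=np.nan
        )
    result = optimize_threshold(pairs, seed=config.seed)
    dend = upgma(1.0 - sim)
    ms_part = cut(dend, height=1.0 - result.t_cs)
    comparison = compare_partitions(ms_part, ref_part, kept_samples)
    return BenchmarkResult(
        threshold=result,
        ms_partition=ms_part,
        ref_partition=ref_part,
        comparison=comparison,
        acs=acs_summary(sim, kept_samples),
        similarity=sim,
        pairs=pairs,
        config=config,
    )
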
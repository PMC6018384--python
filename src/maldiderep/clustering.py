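"""UPGMA clustering of spectra or sequences into OTUs and partition comparison.

Mass-spectral OTUs come from cutting the average-linkage (UPGMA) tree of
pairwise 1 - CS distances at 1 - T_CS; sequence OTUs from cutting the
1 - identity/100 tree at 1 - 0.9865. A cut applies exactly the merges
whose height is strictly below the cutoff, so cutting at a merge height
separates that merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "OTUPartition",
    "PartitionComparison",
    "upgma",
    "cut",
    "compare_partitions",
]


@dataclass
class Dendrogram:
    """Average-linkage merge tree over ``leaf_ids``.

    ``merges`` follows the SciPy linkage convention: row k merges nodes
    ``merges[k, 0]`` and ``merges[k, 1]`` (leaves are 0..n-1, internal
    nodes n+k) at height ``merges[k, 2]`` into node n+k.
    """

    leaf_ids: list[str]
    merges: np.ndarray  # (n-1, 4) linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = len(self.leaf_ids)
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        for k in range(self.merges.shape[0]):
            a, b, h = int(self.merges[k, 0]), int(self.merges[k, 1]), self.merges[k, 2]
            la = height[a]
            lb = height[b]
            node[n + k] = f"({node[a]}:{h - la:.6g},{node[b]}:{h - lb:.6g})"
            height[n + k] = h
        return node[n + len(self.leaf_ids) - 2] + ";" if n > 1 else node[0] + ";"


@dataclass
class OTUPartition:
    """Assignment of samples (or sequences) to clusters from a tree cut."""

    assignments: dict[str, int]
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, lab in self.assignments.items():
            out.setdefault(lab, []).append(sid)
        return out


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomeration of a symmetric distance matrix."""
    D = dist.to_numpy(dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 2:
        raise ValueError("need a square distance matrix with >= 2 items")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("negative distances are not allowed")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(leaf_ids=list(dist.index), merges=Z)


def cut(dendrogram: Dendrogram, height: float) -> OTUPartition:
    """Cut the tree: apply exactly the merges with height < cutoff.

    Cluster labels are consecutive integers starting at 1, ordered by each
    cluster's lowest leaf index.
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    n = len(dendrogram.leaf_ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k in range(dendrogram.merges.shape[0]):
        a, b, h = (
            int(dendrogram.merges[k, 0]),
            int(dendrogram.merges[k, 1]),
            dendrogram.merges[k, 2],
        )
        members = node_members[a] + node_members[b]
        node_members[n + k] = members
        if h < height:
            ra, rb = find(members[0]), find(members[-1])
            # union all members (a and b may themselves be unapplied merges,
            # but linkage trees are nested so member-wise union is safe)
            roots = {find(m) for m in members}
            target = min(roots)
            for m in members:
                parent[find(m)] = target
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    labels: dict[str, int] = {}
    for lab, root in enumerate(sorted(groups, key=lambda r: min(groups[r])), start=1):
        for i in groups[root]:
            labels[dendrogram.leaf_ids[i]] = lab
    return OTUPartition(assignments=labels, cut_height=height)


@dataclass
class PartitionComparison:
    """Side-by-side summary of an MS partition against a reference partition."""

    n_samples: int
    n_cultures: int
    n_clusters_ms: int
    n_clusters_ref: int
    derep_rate_ms: float  # 100 * clusters / samples
    derep_rate_ref: float
    redundant_ms: int
    redundant_ms_pct: float
    cultures_same: int
    cultures_more_ref: int
    cultures_more_ms: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _primary_clusters(
    partition: OTUPartition, culture_of: dict[str, str]
) -> dict[str, int]:
    """Plurality cluster per culture (ties broken by the lower label)."""
    counts: dict[str, dict[int, int]] = {}
    for sid, lab in partition.assignments.items():
        c = culture_of[sid]
        counts.setdefault(c, {}).setdefault(lab, 0)
        counts[c][lab] += 1
    primary = {}
    for c, labcounts in counts.items():
        best = max(labcounts.items(), key=lambda kv: (kv[1], -kv[0]))
        primary[c] = best[0]
    return primary


def compare_partitions(
    ms: OTUPartition, ref: OTUPartition, samples: list
) -> PartitionComparison:
    """Dereplication-rate, redundancy and culture-agreement summary.

    ``ref`` may be defined at culture level; labels are then broadcast to
    all samples of the culture. Redundant MS clusters are clusters that
    are the plurality ("primary") cluster of no culture — the extra
    clusters created by biological variability of the spectra. For the
    agreement counts each culture's MS grouping is collapsed to primary
    clusters: a culture agrees ("same") when its primary-cluster
    companions and its reference companions split into equally many
    groups, else whichever method splits them further is counted.
    """
    culture_of = {r.sample_id: r.culture_id for r in samples}
    ms_ids = set(ms.assignments)
    if ms_ids != set(culture_of):
        raise ValueError("MS partition and sample list cover different samples")
    ref_assign = dict(ref.assignments)
    if set(ref_assign) != ms_ids:
        # culture-level reference: broadcast to samples
        cultures = {r.culture_id for r in samples}
        if set(ref_assign) != cultures:
            raise ValueError("reference partition covers neither samples nor cultures")
        ref_assign = {sid: ref_assign[culture_of[sid]] for sid in ms_ids}
    n_samples = len(ms_ids)
    cultures = sorted({r.culture_id for r in samples})
    n_clusters_ms = len(set(ms.assignments.values()))
    n_clusters_ref = len(set(ref_assign.values()))

    primary_ms = _primary_clusters(ms, culture_of)
    ref_part = OTUPartition(assignments=ref_assign, cut_height=ref.cut_height)
    primary_ref = _primary_clusters(ref_part, culture_of)
    redundant = n_clusters_ms - len(set(primary_ms.values()))

    same = more_ref = more_ms = 0
    for c in cultures:
        ms_companions = [d for d in cultures if primary_ms[d] == primary_ms[c]]
        ref_companions = [d for d in cultures if primary_ref[d] == primary_ref[c]]
        # how many reference groups the MS cluster lumps together, and
        # how many (primary) MS clusters the reference group splits into
        n_ref_groups = len({primary_ref[d] for d in ms_companions})
        n_ms_groups = len({primary_ms[d] for d in ref_companions})
        if n_ref_groups == n_ms_groups:
            same += 1
        elif n_ref_groups > n_ms_groups:
            more_ref += 1
        else:
            more_ms += 1

    return PartitionComparison(
        n_samples=n_samples,
        n_cultures=len(cultures),
        n_clusters_ms=n_clusters_ms,
        n_clusters_ref=n_clusters_ref,
        derep_rate_ms=100.0 * n_clusters_ms / n_samples,
        derep_rate_ref=100.0 * n_clusters_ref / n_samples,
        redundant_ms=redundant,
        redundant_ms_pct=100.0 * redundant / n_clusters_ms,
        cultures_same=same,
        cultures_more_ref=more_ref,
        cultures_more_ms=more_ms,
    )
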
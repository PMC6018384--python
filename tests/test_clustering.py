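import itertools

import numpy as np
import pandas as pd
import pytest

from maldiderep.clustering import (
    OTUPartition,
    compare_partitions,
    cut,
    upgma,
)
from maldiderep.io import SampleRecord


def dist_df(D, ids):
    return pd.DataFrame(D, index=ids, columns=ids, dtype=float)


def naive_upgma(D):
    """Brute-force average linkage: at each step merge the pair of clusters
    with the smallest mean of original inter-cluster distances."""
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [
            clusters[a] + clusters[b]
        ]
    return merges


def naive_cut(D, height):
    """Partition by applying naive-UPGMA merges with height < cutoff."""
    n = D.shape[0]
    label = list(range(n))
    for members, h in naive_upgma(D):
        if h < height:
            target = min(label[i] for i in members)
            for i in members:
                old = label[i]
                label = [target if l == old else l for l in label]
    return label


class TestUpgma:
    def test_hand_checked_three_leaves(self):
        D = [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]
        dend = upgma(dist_df(D, list("ABC")))
        assert np.allclose(dend.heights, [0.2, 0.6])
        # first merge joins leaves A and B
        assert sorted(dend.merges[0, :2]) == [0, 1]

    def test_two_items(self):
        dend = upgma(dist_df([[0, 0.4], [0.4, 0]], list("AB")))
        assert dend.merges.shape[0] == 1
        assert dend.heights[0] == pytest.approx(0.4)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = rng.uniform(0.1, 1, (7, 7))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            dend = upgma(dist_df(D, [f"l{i}" for i in range(7)]))
            assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        ids = [f"l{i}" for i in range(6)]
        for _ in range(20):
            A = rng.uniform(0.1, 1, (6, 6))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0)
            dend = upgma(dist_df(D, ids))
            oracle = naive_upgma(D)
            assert np.allclose(sorted(dend.heights), sorted(h for _, h in oracle))
            # cuts agree at every inter-merge midpoint
            hs = sorted(h for _, h in oracle)
            probes = [hs[0] / 2] + [
                (a + b) / 2 for a, b in zip(hs[:-1], hs[1:])
            ] + [hs[-1] * 1.1]
            for h in probes:
                mine = cut(dend, h)
                ref = naive_cut(D, h)
                mine_sets = {
                    frozenset(s for s in mine.clusters()[lab])
                    for lab in mine.clusters()
                }
                ref_sets = {
                    frozenset(ids[i] for i in range(6) if ref[i] == l)
                    for l in set(ref)
                }
                assert mine_sets == ref_sets

    def test_asymmetric_rejected(self):
        D = [[0, 0.1], [0.9, 0]]
        with pytest.raises(ValueError):
            upgma(dist_df(D, list("AB")))

    def test_newick_contains_all_leaves(self):
        D = [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]
        nwk = upgma(dist_df(D, list("ABC"))).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABC":
            assert leaf in nwk


class TestCut:
    @pytest.fixture()
    def dend(self):
        D = [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]]
        return upgma(dist_df(D, list("ABC")))

    def test_above_max_height_single_cluster(self, dend):
        assert cut(dend, 0.7).n_clusters == 1

    def test_zero_height_all_singletons(self, dend):
        assert cut(dend, 0.0).n_clusters == 3

    def test_mid_cut(self, dend):
        part = cut(dend, 0.3)
        assert part.assignments["A"] == part.assignments["B"]
        assert part.assignments["A"] != part.assignments["C"]

    def test_cut_at_merge_height_separates(self, dend):
        part = cut(dend, 0.2)  # strict: the 0.2 merge is NOT applied
        assert part.n_clusters == 3

    def test_refinement_and_monotone_cluster_count(self):
        rng = np.random.default_rng(2)
        A = rng.uniform(0.1, 1, (8, 8))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0)
        dend = upgma(dist_df(D, [f"l{i}" for i in range(8)]))
        prev = None
        prev_n = 9
        for h in np.linspace(0, 1.1, 12):
            part = cut(dend, h)
            assert part.n_clusters <= prev_n
            if prev is not None:
                for lab, members in prev.clusters().items():
                    assert len({part.assignments[m] for m in members}) == 1
            prev, prev_n = part, part.n_clusters


def samples_for(cultures):
    recs = []
    for c, n in cultures.items():
        for i in range(n):
            recs.append(SampleRecord(f"{c}_{i}", c, 1 + i, 1))
    return recs


class TestComparePartitions:
    def test_dereplication_rate_arithmetic(self):
        # 196 samples in 76 MS clusters -> 38.8%; 43 reference clusters -> 21.9%
        samples = samples_for({f"c{i}": 4 for i in range(49)})
        ms = {}
        for k, r in enumerate(samples):
            ms[r.sample_id] = k % 76 + 1
        ref = {f"c{i}": i % 43 + 1 for i in range(49)}
        cmp = compare_partitions(
            OTUPartition(ms, 0.08), OTUPartition(ref, np.nan), samples
        )
        assert cmp.n_samples == 196
        assert cmp.n_clusters_ms == 76
        assert cmp.derep_rate_ms == pytest.approx(100 * 76 / 196)
        assert round(cmp.derep_rate_ms) == 39
        assert round(cmp.derep_rate_ref) == 22

    def test_redundant_fraction_arithmetic(self):
        # 32 redundant of 76 clusters -> 42%
        assert round(100 * 32 / 76) == 42

    def test_perfect_clustering(self):
        samples = samples_for({"a": 3, "b": 3, "c": 3})
        ms = {r.sample_id: {"a": 1, "b": 2, "c": 3}[r.culture_id] for r in samples}
        ref = {"a": "p1", "b": "p2", "c": "p3"}
        labels = {"p1": 1, "p2": 2, "p3": 3}
        cmp = compare_partitions(
            OTUPartition(ms, 0.1),
            OTUPartition({c: labels[p] for c, p in ref.items()}, np.nan),
            samples,
        )
        assert cmp.redundant_ms == 0
        assert cmp.cultures_same == 3
        assert cmp.cultures_more_ms == 0 and cmp.cultures_more_ref == 0

    def test_biological_split_counts_redundant(self):
        # culture a splits into 2 MS clusters; cluster 2 is primary for no culture
        samples = samples_for({"a": 4, "b": 3})
        ms = {}
        for r in samples:
            if r.culture_id == "a":
                ms[r.sample_id] = 1 if r.biological_replicate <= 3 else 2
            else:
                ms[r.sample_id] = 3
        cmp = compare_partitions(
            OTUPartition(ms, 0.1),
            OTUPartition({"a": 1, "b": 2}, np.nan),
            samples,
        )
        assert cmp.n_clusters_ms == 3
        assert cmp.redundant_ms == 1
        assert cmp.cultures_same == 2  # redundancy collapsed before comparing

    def test_agreement_sums_to_n_cultures(self):
        rng = np.random.default_rng(3)
        samples = samples_for({f"c{i}": 3 for i in range(8)})
        ms = {r.sample_id: int(rng.integers(1, 6)) for r in samples}
        ref = {f"c{i}": int(rng.integers(1, 4)) for i in range(8)}
        cmp = compare_partitions(
            OTUPartition(ms, 0.1), OTUPartition(ref, np.nan), samples
        )
        assert cmp.cultures_same + cmp.cultures_more_ref + cmp.cultures_more_ms == 8

    def test_relabeling_invariance(self):
        samples = samples_for({"a": 2, "b": 2, "c": 2})
        ms1 = {r.sample_id: {"a": 1, "b": 1, "c": 2}[r.culture_id] for r in samples}
        ms2 = {r.sample_id: {"a": 9, "b": 9, "c": 4}[r.culture_id] for r in samples}
        ref = OTUPartition({"a": 1, "b": 2, "c": 3}, np.nan)
        c1 = compare_partitions(OTUPartition(ms1, 0.1), ref, samples)
        c2 = compare_partitions(OTUPartition(ms2, 0.1), ref, samples)
        assert c1.as_dict() == c2.as_dict()

    def test_sample_set_mismatch_rejected(self):
        samples = samples_for({"a": 2})
        ms = OTUPartition({"a_0": 1}, 0.1)
        with pytest.raises(ValueError):
            compare_partitions(ms, OTUPartition({"a": 1}, np.nan), samples)
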
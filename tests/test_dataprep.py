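import numpy as np
import pytest

from ablm.dataprep import (
    Cluster,
    build_test_set,
    cluster_cdr3,
    cluster_identity,
    extract_cdr3,
    filter_min_count,
    pairwise_identity,
    split,
)
from ablm.sequences import AntibodySequence
from ablm.synthetic_data import truth_numberer


def _seq(id, residues, numbering=None, chain="heavy"):
    return AntibodySequence(id, chain, residues, numbering)


class TestFilterMinCount:
    def test_threshold_inclusive(self):
        records = [(_seq(str(c), "EVQ"), c) for c in (1, 2, 3, 4)]
        kept = filter_min_count(records)
        assert [s.id for s in kept] == ["3", "4"]

    def test_all_at_boundary_survive(self):
        records = [(_seq(str(i), "EVQ"), 3) for i in range(4)]
        assert len(filter_min_count(records)) == 4

    def test_empty_input(self):
        assert filter_min_count([]) == []

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            filter_min_count([(_seq("a", "EVQ"), 0)])


class TestClusterCdr3:
    def test_same_cdr3_different_framework_one_cluster(self, repertoire):
        seqs, gt = repertoire
        nb = truth_numberer(gt)
        clusters, rejects = cluster_cdr3(seqs, nb)
        # every member of a cluster shares the cluster's CDR3 string
        for c in clusters:
            by_id = {s.id: s for s in seqs}
            for m in c.members:
                assert extract_cdr3(by_id[m], nb) == c.key

    def test_cluster_count_matches_ground_truth(self, repertoire):
        """Generator bookkeeping oracle: distinct true CDR3s among accepted
        sequences equals the number of clusters."""
        seqs, gt = repertoire
        nb = truth_numberer(gt)
        clusters, rejects = cluster_cdr3(seqs, nb)
        accepted = {m for c in clusters for m in c.members}
        assert accepted | set(rejects) == {s.id for s in seqs}
        expected = {gt.cdr3_of(sid) for sid in accepted}
        assert len(clusters) == len(expected)

    def test_distinct_cdr3s_give_singletons(self):
        numbering = tuple((str(p), i) for i, p in enumerate(range(105, 114)))
        seqs = [
            _seq("a", "ARDYSGGMD", numbering),
            _seq("b", "ARDYSGGMY", numbering),
        ]
        clusters, rejects = cluster_cdr3(seqs)
        assert len(clusters) == 2 and not rejects

    def test_missing_numbering_routed_to_rejects(self):
        clusters, rejects = cluster_cdr3([_seq("a", "EVQLV")])
        assert clusters == [] and rejects == ["a"]

    def test_mixed_chains_rejected(self):
        with pytest.raises(ValueError):
            cluster_cdr3([_seq("a", "EVQ"), _seq("b", "DIQ", chain="light")])


def brute_force_greedy(seqs, threshold):
    """Independent small-instance reference: explicit all-pairs identity
    table, then the documented centroid semantics by hand."""
    table = {
        (a.id, b.id): pairwise_identity(a.residues, b.residues)
        for a in seqs
        for b in seqs
    }
    order = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    assignment = {}
    centroids = []
    for s in order:
        placed = False
        for c in centroids:
            if table[(s.id, c.id)] >= threshold:
                assignment[s.id] = c.id
                placed = True
                break
        if not placed:
            centroids.append(s)
            assignment[s.id] = s.id
    return assignment


class TestClusterIdentity:
    def test_identical_sequences_merge(self):
        clusters = cluster_identity([_seq("a", "EVQLVE"), _seq("b", "EVQLVE")])
        assert len(clusters) == 1
        assert clusters[0].members == ("a", "b")

    def test_threshold_one_all_distinct_singletons(self):
        seqs = [_seq("a", "EVQLVE"), _seq("b", "EVQLVK"), _seq("c", "KVQLVE")]
        assert len(cluster_identity(seqs, threshold=1.0)) == 3

    def test_matches_brute_force_on_small_instance(self, repertoire):
        seqs, _ = repertoire
        sample = seqs[:15]
        clusters = cluster_identity(sample, threshold=0.70)
        expected = brute_force_greedy(sample, 0.70)
        got = {m: c.representative.id for c in clusters for m in c.members}
        assert got == expected

    def test_partition_property(self, repertoire):
        seqs, _ = repertoire
        sample = seqs[:40]
        clusters = cluster_identity(sample)
        ids = [m for c in clusters for m in c.members]
        assert sorted(ids) == sorted(s.id for s in sample)

    def test_order_invariance(self, repertoire):
        seqs, _ = repertoire
        sample = seqs[:20]
        a = cluster_identity(sample)
        b = cluster_identity(sample[::-1])
        assert [(c.representative.id, c.members) for c in a] == [
            (c.representative.id, c.members) for c in b
        ]

    def test_representative_is_longest_then_lexicographic(self):
        seqs = [_seq("b", "EVQLVE"), _seq("a", "EVQLVE"), _seq("c", "EVQLV")]
        clusters = cluster_identity(seqs, threshold=0.5)
        assert clusters[0].representative.id == "a"


class TestSplit:
    def test_sizes_and_disjointness(self, repertoire):
        seqs, _ = repertoire
        train, evals = split(seqs[:100], n_eval=10, seed=0)
        assert len(train) == 90 and len(evals) == 10
        assert not ({s.id for s in train} & {s.id for s in evals})

    def test_same_seed_same_split(self, repertoire):
        seqs, _ = repertoire
        a = split(seqs[:50], 7, seed=4)
        b = split(seqs[:50], 7, seed=4)
        assert [s.id for s in a[1]] == [s.id for s in b[1]]

    def test_zero_eval(self, repertoire):
        seqs, _ = repertoire
        train, evals = split(seqs[:10], 0, seed=0)
        assert evals == [] and len(train) == 10

    def test_oversized_eval_rejected(self, repertoire):
        seqs, _ = repertoire
        with pytest.raises(ValueError):
            split(seqs[:10], 10, seed=0)


class TestBuildTestSet:
    def _eligible(self, repertoire):
        seqs, gt = repertoire
        complete = [s for s in seqs if "*" not in s.residues and gt[s.id].truncation == 0]
        alleles = {s.id: gt[s.id].allele for s in complete}
        return complete, alleles

    def test_per_allele_sampling(self, repertoire):
        complete, alleles = self._eligible(repertoire)
        per = 5
        out = build_test_set(complete, alleles, per_allele=per, seed=0)
        counts = {}
        for s in out:
            counts[alleles[s.id]] = counts.get(alleles[s.id], 0) + 1
        assert all(v == per for v in counts.values())

    def test_small_alleles_skipped_or_included(self, repertoire):
        complete, alleles = self._eligible(repertoire)
        out_skip = build_test_set(complete, alleles, per_allele=10_000, seed=0)
        assert out_skip == []
        out_all = build_test_set(
            complete, alleles, per_allele=10_000, seed=0, include_small=True
        )
        assert len(out_all) == len(complete)

    def test_reproducible_under_seed(self, repertoire):
        complete, alleles = self._eligible(repertoire)
        a = build_test_set(complete, alleles, per_allele=5, seed=3)
        b = build_test_set(complete, alleles, per_allele=5, seed=3)
        assert [s.id for s in a] == [s.id for s in b]
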
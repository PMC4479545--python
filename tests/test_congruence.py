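"""Partition agreement, contiguity, diffuse-cluster merging, delimitation."""

import numpy as np
import pytest

from delimix import errors
from delimix.congruence import (
    _pruned_delaunay_edges,
    adjusted_rand,
    congruence_report,
    contiguity,
    delimit,
    merge_diffuse_clusters,
)
from delimix.mixtures import Partition


def brute_force_ari(a, b):
    """Pair-counting Hubert-Arabie ARI, straight from the definition."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a, same_b = a[i] == a[j], b[i] == b[j]
            ss += same_a and same_b
            sd += same_a and not same_b
            ds += same_b and not same_a
            dd += not same_a and not same_b
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    maximum = ((ss + sd) + (ss + ds)) / 2
    if maximum == expected:
        return 1.0
    return (ss - expected) / (maximum - expected)


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        p = {f"s{i}": i % 3 for i in range(9)}
        assert adjusted_rand(p, dict(p)) == 1.0

    def test_one_cluster_vs_singletons_scores_zero(self):
        p = {f"s{i}": 1 for i in range(10)}
        q = {f"s{i}": i for i in range(10)}
        assert adjusted_rand(p, q) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pair_counting_oracle(self, rng):
        ids = [f"s{i}" for i in range(12)]
        a = rng.integers(1, 4, 12)
        b = rng.integers(1, 5, 12)
        p = dict(zip(ids, a.tolist()))
        q = dict(zip(ids, b.tolist()))
        assert adjusted_rand(p, q) == pytest.approx(brute_force_ari(a, b), abs=1e-12)

    def test_symmetry_and_label_permutation_invariance(self, rng):
        ids = [f"s{i}" for i in range(15)]
        a = rng.integers(1, 4, 15)
        p = dict(zip(ids, a.tolist()))
        q = dict(zip(ids, rng.integers(1, 4, 15).tolist()))
        assert adjusted_rand(p, q) == adjusted_rand(q, p)
        relabeled = {k: {1: 7, 2: 5, 3: 9}[v] for k, v in p.items()}
        assert adjusted_rand(p, q) == pytest.approx(adjusted_rand(relabeled, q))

    def test_disjoint_specimen_sets_rejected(self):
        with pytest.raises(errors.IdError):
            adjusted_rand({"a": 1}, {"b": 1})


def union_find_components(n_nodes, edges):
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(i) for i in range(n_nodes)})


class TestContiguity:
    def test_tight_patch_is_contiguous(self, rng):
        locs = {f"s{i}": (rng.normal(0, 0.01), rng.normal(0, 0.01)) for i in range(12)}
        flag, score = contiguity(list(locs), locs)
        assert flag and score == 1.0

    def test_isolated_corners_pruned_apart(self, rng):
        locs = {f"s{i}": (rng.uniform(0, 1), rng.uniform(0, 1)) for i in range(100)}
        locs["far1"] = (50.0, 50.0)
        locs["far2"] = (-50.0, -50.0)
        flag, score = contiguity(["far1", "far2"], locs)
        assert not flag and score == 0.0

    def test_components_match_union_find_oracle(self, rng):
        ids = [f"s{i}" for i in range(40)]
        coords = rng.uniform(0, 1, size=(40, 2))
        locs = dict(zip(ids, map(tuple, coords)))
        members = ids[::2]
        _, score = contiguity(members, locs)
        edges = _pruned_delaunay_edges(coords, 0.95)
        member_idx = {int(i) for i in range(0, 40, 2)}
        remap = {node: k for k, node in enumerate(sorted(member_idx))}
        sub = [(remap[i], remap[j]) for i, j in edges
               if i in member_idx and j in member_idx]
        n_comp = union_find_components(len(member_idx), sub)
        expected = 1.0 - (n_comp - 1) / (len(member_idx) - 1)
        assert score == pytest.approx(expected)

    def test_two_point_fallback_complete_graph(self):
        locs = {"a": (0.0, 0.0), "b": (1.0, 1.0)}
        flag, score = contiguity(["a", "b"], locs)
        assert flag and score == 1.0


def make_partition(labels, uncertainty):
    labels = np.asarray(labels)
    K = labels.max()
    post = np.zeros((len(labels), K))
    for i, (lab, unc) in enumerate(zip(labels, uncertainty)):
        post[i, lab - 1] = 1.0 - unc
        if K > 1:
            others = [k for k in range(K) if k != lab - 1]
            post[i, others] = unc / len(others)
    return Partition(labels=labels, posterior=post,
                     uncertainty=np.asarray(uncertainty, dtype=float))


class TestMergeDiffuseClusters:
    def test_separated_confident_clusters_unchanged(self, rng):
        ids = [f"s{i}" for i in range(20)]
        labels = [1] * 10 + [2] * 10
        locs = {ids[i]: (0 + 0.01 * rng.normal(), 0) if i < 10 else (10, 10)
                for i in range(20)}
        part = make_partition(labels, [0.01] * 20)
        merged, audit = merge_diffuse_clusters(part, ids, locs)
        assert audit == []
        np.testing.assert_array_equal(merged.labels, labels)

    def test_interleaved_uncertain_split_is_merged(self, rng):
        # one cloud artificially split in two, posteriors near 0.5
        ids = [f"s{i}" for i in range(30)]
        coords = rng.uniform(0, 1, size=(30, 2))
        locs = dict(zip(ids, map(tuple, coords)))
        labels = [1, 2] * 15
        part = make_partition(labels, [0.45] * 30)
        merged, audit = merge_diffuse_clusters(part, ids, locs)
        assert len(audit) == 1
        assert merged.labels.max() == 1

    def test_idempotent(self, rng):
        ids = [f"s{i}" for i in range(30)]
        coords = rng.uniform(0, 1, size=(30, 2))
        locs = dict(zip(ids, map(tuple, coords)))
        part = make_partition([1, 2] * 15, [0.45] * 30)
        once, _ = merge_diffuse_clusters(part, ids, locs)
        twice, audit = merge_diffuse_clusters(once, ids, locs)
        assert audit == []
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_uncertain_but_allopatric_not_merged(self):
        ids = [f"s{i}" for i in range(20)]
        locs = {ids[i]: (i * 0.01, 0) if i < 10 else (10 + i * 0.01, 0)
                for i in range(20)}
        part = make_partition([1] * 10 + [2] * 10, [0.45] * 20)
        merged, audit = merge_diffuse_clusters(part, ids, locs)
        assert audit == []
        assert merged.labels.max() == 2


def grid_localities(ids, rng):
    return {s: (rng.uniform(0, 1), rng.uniform(0, 1)) for s in ids}


class TestDelimit:
    def test_identical_partitions_reproduce_clusters(self, rng):
        ids = [f"s{i}" for i in range(12)]
        labels = dict(zip(ids, [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3]))
        hyp = delimit({"mtdna": labels, "snp": dict(labels)}, grid_localities(ids, rng))
        assert len(hyp.groups) == 3
        assert all(s == 2 for s in hyp.support)
        assert sorted(map(len, hyp.groups)) == [4, 4, 4]

    def test_nested_partition_with_min_support_one_gives_inclusive_groups(self, rng):
        ids = [f"s{i}" for i in range(9)]
        p = dict(zip(ids, [1, 1, 1, 2, 2, 2, 2, 2, 2]))           # A | B
        q = dict(zip(ids, [1, 1, 1, 2, 2, 2, 3, 3, 3]))           # A | B1 | B2
        hyp = delimit({"p": p, "q": q}, grid_localities(ids, rng), min_support=1)
        assert sorted(map(len, hyp.groups)) == [3, 6]              # A and B
        # default rule keeps only pairs co-clustered in >= 2 datasets
        strict = delimit({"p": p, "q": q}, grid_localities(ids, rng))
        assert sorted(map(len, strict.groups)) == [3, 3, 3]        # A, B1, B2

    def test_invariant_to_partition_order_and_covers_join(self, rng):
        ids = [f"s{i}" for i in range(10)]
        locs = grid_localities(ids, rng)
        p = dict(zip(ids, [1, 1, 1, 1, 1, 2, 2, 2, 2, 2]))
        q = dict(zip(ids, [1, 1, 1, 2, 2, 2, 2, 1, 1, 1]))
        r = dict(zip(ids, [1, 1, 1, 1, 2, 2, 2, 2, 2, 2]))
        h1 = delimit({"a": p, "b": q, "c": r}, locs)
        h2 = delimit({"c": r, "a": p, "b": q}, locs)
        assert [sorted(g) for g in h1.groups] == [sorted(g) for g in h2.groups]
        covered = sorted(s for g in h1.groups for s in g)
        assert covered == sorted(ids)  # groups partition the joined set

    def test_fewer_than_two_partitions_rejected(self, rng):
        with pytest.raises(ValueError):
            delimit({"only": {"a": 1}}, {})


def test_congruence_report_matrix_properties():
    ids = [f"s{i}" for i in range(8)]
    parts = {
        "mtdna": dict(zip(ids, [1, 1, 1, 1, 2, 2, 2, 2])),
        "snp": dict(zip(ids, [1, 1, 2, 2, 1, 1, 2, 2])),
        "phenotype": dict(zip(ids, [1, 1, 1, 1, 2, 2, 2, 2])),
    }
    rep = congruence_report(parts)
    assert np.allclose(np.diag(rep.ari_matrix), 1.0)
    assert np.allclose(rep.ari_matrix, rep.ari_matrix.T)
    assert rep.ari_matrix[0, 2] == pytest.approx(1.0)
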
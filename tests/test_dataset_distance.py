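"""Bit-score Jaccard distances, matrices, and neighbor-joining trees."""

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM, TreeNode
from skbio.tree import nj as skbio_nj

from metacomp import synthetic_data as syn
from metacomp.aligner import Hit, HitTable
from metacomp.dataset_distance import (
    DistanceMatrix, distance_matrix, filter_distance_hits, jaccard_distance,
    neighbor_joining, total_bit_score, write_newick,
)
from metacomp.sequence_io import ReadSet


def _hit(q, s, ident, length, bits):
    return Hit(q, s, ident, length, 0, 0, 1, length, 1, length, 1e-10, bits)


class TestHitFilter:
    def test_thresholds_are_strict(self):
        ht = HitTable("a", "b", [
            _hit("q1", "s1", 70.0, 150, 50),   # identity not > 70
            _hit("q2", "s1", 71.0, 100, 50),   # length not > 100
            _hit("q3", "s1", 75.0, 150, 50),   # passes
        ])
        kept = filter_distance_hits(ht)
        assert [h.query_id for h in kept.hits] == ["q3"]

    def test_matches_brute_force_on_random_tables(self, rng):
        hits = [_hit(f"q{i}", "s", float(rng.uniform(50, 100)),
                     int(rng.integers(50, 400)), 50.0) for i in range(200)]
        ht = HitTable("a", "b", hits)
        kept = filter_distance_hits(ht, 70, 100)
        expected = [h for h in hits if h.percent_identity > 70 and h.align_length > 100]
        assert kept.hits == expected


class TestTotalBitScore:
    def test_policies(self):
        ht = HitTable("a", "b", [
            _hit("q1", "s1", 99, 200, 50.0),
            _hit("q1", "s2", 99, 200, 40.0),
            _hit("q2", "s1", 99, 200, 60.0),
            _hit("q3", "s1", 99, 200, 70.0),
        ])
        assert total_bit_score(HitTable("a", "b", [])) == 0.0
        assert total_bit_score(ht, "best-per-query") == 180.0
        assert total_bit_score(ht, "best-per-pair") == 220.0
        assert total_bit_score(ht, "all-hsps") == 220.0
        with pytest.raises(ValueError, match="policy"):
            total_bit_score(ht, "bogus")


class TestJaccardDistance:
    def test_worked_values(self):
        assert jaccard_distance(100.0, 100.0, 100.0) == 0.0
        assert jaccard_distance(0.0, 100.0, 100.0) == 1.0
        assert jaccard_distance(50.0, 100.0, 100.0) == pytest.approx(2.0 / 3.0)

    def test_scale_invariance(self):
        d1 = jaccard_distance(50.0, 100.0, 120.0)
        d2 = jaccard_distance(500.0, 1000.0, 1200.0)
        assert d1 == pytest.approx(d2, abs=1e-15)

    def test_dice_form(self):
        assert jaccard_distance(50.0, 100.0, 100.0, form="dice") == pytest.approx(0.5)

    def test_inconsistent_inputs_raise(self):
        with pytest.raises(ValueError):
            jaccard_distance(120.0, 100.0, 100.0)
        with pytest.raises(ValueError):
            jaccard_distance(10.0, 0.0, 100.0)


def test_duplicate_dataset_has_near_zero_distance(genome_50pct):
    reads, _ = syn.simulate_community([genome_50pct], [1.0], n_reads=80,
                                      error_rate=0.0, seed=30)
    twin = ReadSet("twin", list(reads.reads))
    dm = distance_matrix([reads, twin])
    assert dm[("community", "twin")] <= 0.01


def test_distance_decreases_with_planted_overlap():
    means = []
    for sf in (0.0, 0.5, 1.0):
        vals = []
        for seed in range(3):
            a, b, _, _ = syn.simulate_paired_communities(
                sf, 4, n_reads=120, seed=seed, genome_length=10_000)
            vals.append(distance_matrix([a, b])[("A", "B")])
        means.append(np.mean(vals))
    assert means[0] == 1.0  # disjoint communities share no filtered hits
    assert means[0] > means[1] > means[2]
    assert all(0.0 <= m <= 1.0 for m in means)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # distances generated by the tree ((A:1,B:2):1,(C:3,D:4))
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        # topology: A and B are siblings apart from C and D
        ab = tree.lca([tree.find("A"), tree.find("B")])
        assert {t.name for t in ab.tips()} == {"A", "B"}
        # tree distances reproduce the input matrix exactly
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    got = tree.find(x).distance(tree.find(y))
                    assert got == pytest.approx(d[i, j], abs=1e-12)

    def test_agrees_with_skbio_on_random_matrices(self, rng):
        for _ in range(5):
            n = 6
            pts = rng.random((n, 3))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            labels = [f"L{i}" for i in range(n)]
            ours = neighbor_joining(DistanceMatrix(labels, d))
            ref = skbio_nj(SkbioDM(d, labels))
            assert ours.compare_rfd(ref) == 0.0

    def test_two_labels_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(dm)

    def test_negative_branches_clamped(self):
        d = np.array([[0, 0.1, 0.9, 0.9],
                      [0.1, 0, 0.9, 0.9],
                      [0.9, 0.9, 0, 0.02],
                      [0.9, 0.9, 0.02, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        assert all((n.length or 0) >= 0 for n in tree.traverse())


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(dm)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = TreeNode.read(str(p))
        assert {t.name for t in back.tips()} == {"A", "B", "C"}
        for name in "ABC":
            assert back.find(name).length == pytest.approx(
                tree.find(name).length, abs=1e-9)

    def test_outgroup_rooting(self, tmp_path):
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        p = tmp_path / "rooted.nwk"
        write_newick(tree, p, outgroup="D")
        back = TreeNode.read(str(p))
        root_children = {c.name for c in back.children}
        assert "D" in root_children
        with pytest.raises(ValueError, match="outgroup"):
            write_newick(tree, p, outgroup="Z")


def test_distance_matrix_container_validation(tmp_path):
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["A", "B"], np.array([[0.1, 1], [1, 0]], float))
    dm = DistanceMatrix(["A", "B"], np.array([[0, 0.25], [0.25, 0]], float))
    p = tmp_path / "dm.tsv"
    dm.to_tsv(p)
    back = DistanceMatrix.from_tsv(p)
    assert back.labels == dm.labels
    assert np.array_equal(back.values, dm.values)
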
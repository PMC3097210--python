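import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from chitfam.phylogeny import (
    Alignment,
    _bipartitions,
    assign_groups,
    bootstrap_support,
    build_msa,
    distance_matrix,
    neighbor_joining,
    pairwise_global_align,
    read_newick,
    write_newick,
)
from chitfam.seqio import ProteinRecord

from oracles import best_ls_topology, gotoh_score, random_additive_matrix

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _blosum(a, b):
    return float(BLOSUM62[a, b])


def _score_of(aln: Alignment, gap_open=-10.0, gap_extend=-1.0) -> float:
    """Score an alignment under BLOSUM62 + affine gaps, independently."""
    a, b = aln.rows
    score = 0.0
    in_gap = None
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            which = "a" if x == "-" else "b"
            score += gap_extend if in_gap == which else gap_open
            in_gap = which
        else:
            score += _blosum(x, y)
            in_gap = None
    return score


class TestPairwiseAlignment:
    def test_identical_sequences_align_without_gaps(self):
        rec = ProteinRecord("a", "MKTWYEE")
        aln = pairwise_global_align(rec, ProteinRecord("b", "MKTWYEE"))
        assert aln.rows[0] == aln.rows[1] == "MKTWYEE"
        assert _score_of(aln) == sum(_blosum(c, c) for c in "MKTWYEE")

    def test_classic_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aln = pairwise_global_align(ProteinRecord("a", a), ProteinRecord("b", b))
        assert _score_of(aln) == gotoh_score(a, b, _blosum)

    def test_fuzzed_scores_match_dp_oracle(self):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            a = "".join(rng.choice(letters, size=int(rng.integers(5, 40))))
            b = "".join(rng.choice(letters, size=int(rng.integers(5, 40))))
            aln = pairwise_global_align(ProteinRecord("a", a), ProteinRecord("b", b))
            assert _score_of(aln) == pytest.approx(gotoh_score(a, b, _blosum))

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            ProteinRecord("a", "")


class TestMultipleAlignment:
    def test_identical_records_align_gap_free(self):
        records = [ProteinRecord(f"s{i}", "MKTWYEEGH") for i in range(4)]
        aln = build_msa(records)
        assert all(row == "MKTWYEEGH" for row in aln.rows)

    def test_prefix_records_get_terminal_gaps(self):
        records = [
            ProteinRecord("long", "MKTWYEEGHKL"),
            ProteinRecord("short", "MKTWYEE"),
        ]
        aln = build_msa(records)
        assert aln.row("short").replace("-", "") == "MKTWYEE"
        assert aln.row("short").endswith("----")

    def test_planted_indel_is_recovered_as_a_gap_block(self):
        base = "MKTAYEDWQRGHILVNSTPF"
        deleted = base[:8] + base[11:]  # drop WQR
        records = [ProteinRecord(f"s{i}", base) for i in range(4)]
        records.append(ProteinRecord("del", deleted))
        aln = build_msa(records)
        row = aln.row("del")
        assert row.replace("-", "") == deleted
        assert "---" in row
        assert aln.n_columns == len(base)

    def test_single_record_is_an_error(self):
        with pytest.raises(ValueError):
            build_msa([ProteinRecord("a", "MKT")])


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = Alignment(("a", "b"), ("MKTW", "MKTW"))
        assert distance_matrix(aln, "p")["a", "b"] == 0.0

    def test_closed_form_single_difference(self):
        row_a = "A" * 100
        row_b = "C" + "A" * 99
        aln = Alignment(("a", "b"), (row_a, row_b))
        assert distance_matrix(aln, "p")["a", "b"] == pytest.approx(0.01)
        assert distance_matrix(aln, "poisson")["a", "b"] == pytest.approx(-math.log(0.99))

    def test_gapped_columns_are_pairwise_deleted(self):
        aln = Alignment(("a", "b"), ("MK-W", "MKTW"))
        assert distance_matrix(aln, "p")["a", "b"] == 0.0

    def test_poisson_dominates_p_on_random_alignments(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            base = rng.choice(letters, size=60)
            rows = []
            for _ in range(4):
                row = base.copy()
                sites = rng.random(60) < 0.3
                row[sites] = rng.choice(letters, size=int(sites.sum()))
                rows.append("".join(row))
            aln = Alignment(("a", "b", "c", "d"), tuple(rows))
            p = distance_matrix(aln, "p")
            d = distance_matrix(aln, "poisson")
            assert np.all(np.asarray(d.data) >= np.asarray(p.data) - 1e-12)
            assert np.allclose(d.data, np.asarray(d.data).T)

    def test_saturated_pair_errors_under_poisson(self):
        aln = Alignment(("a", "b"), ("AAAA", "CCCC"))
        with pytest.raises(ValueError, match="p=1"):
            distance_matrix(aln, "poisson")

    def test_no_comparable_sites_errors_naming_the_pair(self):
        aln = Alignment(("a", "b"), ("AA--", "--CC"))
        with pytest.raises(ValueError, match="a.*b"):
            distance_matrix(aln, "p")


def _tree_tip_distance(tree, a, b):
    return float(tree.tip_tip_distances()[a, b])


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]), ids=["a", "b", "c"]
        )
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.4) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.4 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.4 - 0.3) / 2)

    def test_additive_five_taxon_matrix_recovered_exactly(self):
        # distances generated from ((a:1,b:2):3,(c:4,d:5):6,e:7)
        ids = list("abcde")
        D = np.array(
            [
                [0, 3, 14, 15, 11],
                [3, 0, 15, 16, 12],
                [14, 15, 0, 9, 17],
                [15, 16, 9, 0, 18],
                [11, 12, 17, 18, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(D, ids=ids))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert _tree_tip_distance(tree, a, b) == pytest.approx(D[i, j], abs=1e-9)
        assert _bipartitions(tree, frozenset(ids)) == {
            frozenset({"c", "d"}),
            frozenset({"c", "d", "e"}),
        }

    def test_ties_broken_by_lexicographic_pair(self):
        # fully symmetric matrix: every Q equal; (a, b) must join first
        D = np.ones((4, 4)) - np.eye(4)
        tree = neighbor_joining(DistanceMatrix(D, ids=["d", "c", "b", "a"]))
        assert _bipartitions(tree, frozenset("abcd")) == {frozenset({"c", "d"})}

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(17)
        ids = list("abcdef")
        dist, _ = random_additive_matrix(ids, rng)
        D = np.zeros((6, 6))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    D[i, j] = dist[(x, y)]
        t1 = neighbor_joining(DistanceMatrix(D, ids=ids))
        perm = [3, 1, 5, 0, 2, 4]
        Dp = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(DistanceMatrix(Dp, ids=[ids[k] for k in perm]))
        taxa = frozenset(ids)
        assert _bipartitions(t1, taxa) == _bipartitions(t2, taxa)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            neighbor_joining(_fake_dm(D))

    def test_matches_exhaustive_least_squares_oracle_on_additive_matrices(self):
        rng = np.random.default_rng(99)
        for case in range(20):
            n = int(rng.integers(4, 7))
            ids = [f"t{k}" for k in range(n)]
            dist, true_parts = random_additive_matrix(ids, rng)
            D = np.zeros((n, n))
            for i, x in enumerate(ids):
                for j, y in enumerate(ids):
                    if i != j:
                        D[i, j] = dist[(x, y)]
            tree = neighbor_joining(DistanceMatrix(D, ids=ids))
            nj_parts = _bipartitions(tree, frozenset(ids))
            oracle_parts = best_ls_topology(ids, lambda a, b: dist[(a, b)])
            assert nj_parts == oracle_parts == true_parts

    def test_agrees_with_independent_nj_implementation(self):
        rng = np.random.default_rng(31)
        ids = [f"t{k}" for k in range(7)]
        dist, _ = random_additive_matrix(ids, rng)
        D = np.zeros((7, 7))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i != j:
                    D[i, j] = dist[(x, y)]
        dm = DistanceMatrix(D, ids=ids)
        ours = _bipartitions(neighbor_joining(dm), frozenset(ids))
        theirs = _bipartitions(skbio_nj(dm), frozenset(ids))
        assert ours == theirs


class _fake_dm:
    """Minimal stand-in carrying an intentionally asymmetric matrix."""

    def __init__(self, data):
        self.data = data
        self.ids = [f"x{i}" for i in range(len(data))]


class TestBootstrap:
    @staticmethod
    def _structured_alignment():
        rows = (
            "AAAAAAAAAACCCCCCCCCC",
            "AAAAAAAAAGCCCCCCCCCC",
            "TTTTTTTTTTGGGGGGGGGG",
            "TTTTTTTTTCGGGGGGGGGG",
            "TTTTTTTTTTGGGGGGGGGA",
        )
        return Alignment(("a1", "a2", "b1", "b2", "b3"), rows)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap_support(self._structured_alignment(), 1, seed=4, model="p")
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_clear_split_gets_high_support(self):
        tree = bootstrap_support(self._structured_alignment(), 100, seed=42, model="p")
        taxa = frozenset(("a1", "a2", "b1", "b2", "b3"))
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if side in ({"b1", "b2", "b3"}, {"a1", "a2"}) or taxa - side == {"a1", "a2"}:
                assert node.support >= 95

    def test_supports_within_range_and_reproducible(self):
        t1 = bootstrap_support(self._structured_alignment(), 50, seed=7, model="p")
        t2 = bootstrap_support(self._structured_alignment(), 50, seed=7, model="p")
        s1 = sorted(n.support for n in t1.non_tips() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips() if hasattr(n, "support"))
        assert s1 == s2
        assert all(0.0 <= s <= 100.0 for s in s1)

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(Alignment(("a", "b", "c"), ("A", "A", "A")), 10, seed=0)


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        aln = TestBootstrap._structured_alignment()
        tree = bootstrap_support(aln, 25, seed=9, model="p")
        text = write_newick(tree)
        back = read_newick(text)
        assert {t.name for t in back.tips()} == {t.name for t in tree.tips()}
        for tip in tree.tips():
            twin = back.find(tip.name)
            assert twin.length == pytest.approx(tip.length, abs=1e-9)
        original_supports = sorted(
            n.support for n in tree.non_tips() if hasattr(n, "support")
        )
        round_tripped = sorted(
            float(n.name) for n in back.non_tips() if n.name is not None
        )
        assert original_supports == round_tripped


class TestGroupAssignment:
    def test_anchors_alone_keep_their_own_groups(self, family_anchors):
        queries = [rec for rec, _ in family_anchors]
        result = assign_groups(queries, family_anchors)
        expected = {rec.id: g for rec, g in family_anchors}
        assert {a.protein_id: a.group for a in result} == expected

    def test_perturbed_anchor_is_assigned_to_its_group(self, family_anchors):
        rng = np.random.default_rng(8)
        rec, group = family_anchors[0]
        seq = list(rec.sequence)
        n_mut = max(1, int(0.05 * len(seq)))
        sites = rng.choice(len(seq), size=n_mut, replace=False)
        for s in sites:
            seq[s] = "A" if seq[s] != "A" else "G"
        query = ProteinRecord("perturbed", "".join(seq))
        (assignment,) = assign_groups([query], family_anchors)
        assert assignment.group == group

    def test_missing_anchor_groups_are_reported(self, family_anchors):
        partial = family_anchors[:5]
        with pytest.raises(ValueError, match="VI"):
            assign_groups([partial[0][0]], partial)
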
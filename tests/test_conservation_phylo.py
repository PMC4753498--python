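"""Column conservation, identity clustering, NJ trees and bootstrap supports."""

import numpy as np
import pytest

from gluegene import (
    Msa,
    NucSeq,
    ProtSeq,
    classify_columns,
    identity_matrix,
    infer_locus_clusters,
    nj_bootstrap_tree,
    nj_tree,
    progressive_align,
)
from gluegene.conservation_phylo import _bipartitions, _canonical
from gluegene.synthetic_data import (
    DEFAULT_SPECIES_TREE,
    simulate_alignment_on_tree,
)


class TestClassifyColumns:
    def test_basic_labels(self):
        msa = Msa(("a", "b", "c", "d"), ("AKSA", "AKTA", "ARSA", "AKSA"))
        cons = classify_columns(msa)
        # col0 identical; col1 K/R within the basic class; col2 S/T; col3 identical
        assert cons.labels == (
            "invariant",
            "class_conserved",
            "class_conserved",
            "invariant",
        )
        assert cons.counts["invariant"] == 2
        assert sum(cons.fractions.values()) == pytest.approx(1.0)

    def test_gap_makes_column_gapped(self):
        msa = Msa(("a", "b"), ("A-C", "AAC"))
        assert classify_columns(msa).labels[1] == "gapped"

    def test_variable_column(self):
        msa = Msa(("a", "b"), ("AW", "AD"))
        assert classify_columns(msa).labels[1] == "variable"

    def test_row_order_invariance(self):
        rows = ("AKSA", "AKTA", "ARSA", "AKSA")
        ids = ("a", "b", "c", "d")
        c1 = classify_columns(Msa(ids, rows))
        c2 = classify_columns(Msa(ids[::-1], rows[::-1]))
        assert c1.counts == c2.counts

    def test_ragged_msa_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Msa(("a", "b"), ("ACD", "AC"))

    def test_bad_class_partition_rejected(self):
        msa = Msa(("a", "b"), ("AA", "AA"))
        with pytest.raises(ValueError, match="partition"):
            classify_columns(msa, classes=("AG", "ST"))


class TestIdentityMatrix:
    def test_identical_pair(self):
        s = NucSeq("a", "ACGTACGT")
        ids, mat = identity_matrix([s, NucSeq("b", s.bases)])
        assert mat[0, 1] == 1.0

    def test_hand_count(self):
        ids, mat = identity_matrix([NucSeq("a", "ACGT"), NucSeq("b", "ACGA")])
        assert mat[0, 1] == 0.75

    def test_symmetry_on_random_sequences(self):
        rng = np.random.default_rng(81)
        seqs = [
            NucSeq(f"s{i}", "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(6)
        ]
        _, mat = identity_matrix(seqs)
        assert np.allclose(mat, mat.T) and np.allclose(np.diag(mat), 1.0)

    def test_aligned_msa_mode_skips_gap_columns(self):
        msa = Msa(("a", "b"), ("AC-T", "ACGT"))
        _, mat = identity_matrix(msa, mode="aligned_msa")
        assert mat[0, 1] == 1.0  # 3 comparable columns, all matching

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            identity_matrix([NucSeq("a", "ACGT"), ProtSeq("b", "MSTW")])


class TestLocusClusters:
    def test_hand_clustering(self):
        ids = ("A", "B", "C")
        mat = np.array([[1.0, 0.985, 0.50], [0.985, 1.0, 0.51], [0.50, 0.51, 1.0]])
        la = infer_locus_clusters(ids, mat, threshold=0.97)
        assert la.clusters == (("A", "B"), ("C",))
        assert la.locus_count == 2

    def test_all_similar_single_locus(self):
        ids = ("A", "B", "C")
        mat = np.full((3, 3), 0.99)
        np.fill_diagonal(mat, 1.0)
        assert infer_locus_clusters(ids, mat).locus_count == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(82)
        n = 8
        mat = rng.uniform(0.4, 1.0, size=(n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        ids = tuple(f"s{i}" for i in range(n))
        counts = [
            infer_locus_clusters(ids, mat, t).locus_count
            for t in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            infer_locus_clusters(("a", "b"), np.eye(2), threshold=0.0)


def _additive_dm_4taxa():
    # tree ((A:1,B:2):1,(C:3,D:4)): path-length distances
    from skbio import DistanceMatrix

    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    return DistanceMatrix(d, ids=list("ABCD"))


class TestNeighborJoining:
    def test_additive_4taxon_topology_and_branch_lengths(self):
        tree = nj_tree(_additive_dm_4taxa())
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        bips = _bipartitions(tree, frozenset("ABCD"))
        assert bips == {_canonical(frozenset("AB"), frozenset("ABCD"))}
        # the single internal edge has length 1
        internal = [
            n.length for n in tree.non_tips(include_self=False) if n.length
        ]
        assert internal == [1.0]

    def test_three_taxa_closed_form(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(
            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float),
            ids=list("ABC"),
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # x+y=2, x+z=3, y+z=4 -> x=0.5, y=1.5, z=2.5
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_fewer_than_three_taxa_rejected(self):
        msa = Msa(("a", "b"), ("ACDEF", "ACDEW"))
        with pytest.raises(ValueError, match="at least 3"):
            nj_bootstrap_tree(msa)

    def test_additive_6taxon_recovers_generating_topology(self):
        # distances measured on the species tree itself are additive
        from gluegene.synthetic_data import _parse_tree

        ref = _parse_tree(DEFAULT_SPECIES_TREE)
        names = [t.name for t in ref.tips()]
        n = len(names)
        d = np.zeros((n, n))
        dists = ref.tip_tip_distances()
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                d[i, j] = dists[a, b]
        from skbio import DistanceMatrix

        tree = nj_tree(DistanceMatrix(d, ids=names))
        taxa = frozenset(names)
        assert _bipartitions(tree, taxa) == _bipartitions(ref, taxa)


class TestBootstrap:
    def test_same_seed_bitwise_reproducible(self):
        recs = simulate_alignment_on_tree(DEFAULT_SPECIES_TREE, 120, seed=83)
        msa = Msa.from_records(recs)
        a = nj_bootstrap_tree(msa, n_bootstrap=50, seed=7)
        b = nj_bootstrap_tree(msa, n_bootstrap=50, seed=7)
        assert a.supports == b.supports
        assert a.to_newick() == b.to_newick()

    def test_clean_alignment_gives_high_support(self):
        recs = simulate_alignment_on_tree(DEFAULT_SPECIES_TREE, 300, seed=84)
        msa = Msa.from_records(recs)
        pt = nj_bootstrap_tree(msa, n_bootstrap=100, seed=8)
        assert pt.supports and min(pt.supports.values()) >= 50.0

    def test_newick_contains_supports_and_taxa(self):
        recs = simulate_alignment_on_tree(DEFAULT_SPECIES_TREE, 200, seed=85)
        pt = nj_bootstrap_tree(Msa.from_records(recs), n_bootstrap=20, seed=9)
        nwk = pt.to_newick()
        for taxon in pt.taxa:
            assert taxon in nwk


class TestProgressiveAlign:
    def test_identical_sequences_unchanged(self):
        seqs = [ProtSeq(f"s{i}", "MSTVGKLPQW") for i in range(3)]
        msa = progressive_align(seqs)
        assert set(msa.rows) == {"MSTVGKLPQW"}

    def test_planted_deletion_gapped(self):
        seqs = [
            ProtSeq("long1", "MSTVGKLPQWAEDF"),
            ProtSeq("short", "MSTVGKLPQWDF"),
            ProtSeq("long2", "MSTVGKLPQWAEDF"),
        ]
        msa = progressive_align(seqs)
        assert len(set(len(r) for r in msa.rows)) == 1
        by_id = dict(zip(msa.ids, msa.rows))
        assert by_id["short"].replace("-", "") == "MSTVGKLPQWDF"
        assert "-" in by_id["short"]
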
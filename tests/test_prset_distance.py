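"""Rescaled residue distances, neighbour joining, class assignment."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from teleotd.prset_distance import (
    PairwiseDistanceMatrix,
    RESIDUES,
    aligned_pair_distance,
    assign_classes,
    load_substitution_matrix,
    neighbor_joining,
    pairwise_distance_matrix,
    rescale_substitution_matrix,
    root_by_outgroup,
)


def tree_distance_matrix(newick):
    """Additive distance matrix (patristic distances) of a newick tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.distance(
            tree.taxon_namespace.get_taxon(labels[i]),
            tree.taxon_namespace.get_taxon(labels[j]),
        )
        mat[i, j] = mat[j, i] = d
    return tree, PairwiseDistanceMatrix(
        labels, mat, np.ones((n, n), dtype=np.int64)
    )


class TestRescaledMatrix:
    def test_blosum62_a_r_entry(self, residue_distance):
        # B(A,R) = -1, B(A,A) = 4, B(R,R) = 5 -> D = 1 + 4.5 = 5.5
        assert residue_distance["A", "R"] == pytest.approx(5.5)

    def test_zero_diagonal_symmetric_nonnegative(self, residue_distance):
        D = residue_distance.distances
        assert np.allclose(np.diag(D), 0)
        assert np.array_equal(D, D.T)
        for i, j in itertools.combinations(range(20), 2):
            assert D[i, j] >= 0

    def test_formula_against_raw_blosum(self, blosum62, residue_distance):
        B = blosum62.scores
        for i, j in [(0, 5), (3, 19), (7, 7), (12, 2)]:
            expected = -B[i, j] + (B[i, i] + B[j, j]) / 2
            assert residue_distance.distances[i, j] == expected


class TestAlignedPairDistance:
    def test_identical_rows_zero(self, residue_distance):
        assert aligned_pair_distance("ACDEF", "ACDEF",
                                     residue_distance) == 0.0

    def test_hand_computed_two_columns(self, residue_distance):
        # D(A,A)=0, D(R,A)=5.5; gap column excluded -> 5.5/2
        assert aligned_pair_distance(
            "AR-", "AA-", residue_distance
        ) == pytest.approx(2.75)

    def test_gap_only_overlap_rejected(self, residue_distance):
        with pytest.raises(ValueError, match="no aligned"):
            aligned_pair_distance("A--", "-A-", residue_distance)

    def test_symmetric_and_gap_padding_invariant(self, residue_distance):
        a, b = "ARNDC", "AKNEC"
        d = aligned_pair_distance(a, b, residue_distance)
        assert aligned_pair_distance(b, a, residue_distance) == d
        assert aligned_pair_distance(
            a + "--", b + "--", residue_distance
        ) == pytest.approx(d)

    def test_unknown_residues_excluded(self, residue_distance):
        d_with_x = aligned_pair_distance("ARX", "AAX", residue_distance)
        assert d_with_x == pytest.approx(
            aligned_pair_distance("AR", "AA", residue_distance)
        )


class TestPairwiseMatrix:
    def test_identical_rows_zero_matrix(self, residue_distance):
        M = pairwise_distance_matrix(
            [("a", "ACD"), ("b", "ACD"), ("c", "ACD")], residue_distance
        )
        assert np.allclose(M.matrix, 0)

    def test_matches_double_loop_oracle(self, blosum62, residue_distance):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(10):
            chars = rng.choice(list(RESIDUES + "-"), size=40)
            rows.append((f"s{i}", "".join(chars)))
        M = pairwise_distance_matrix(rows, residue_distance)
        B = blosum62.scores
        idx = {r: k for k, r in enumerate(RESIDUES)}
        for i, j in itertools.combinations(range(10), 2):
            tot, n = 0.0, 0
            for x, y in zip(rows[i][1], rows[j][1]):
                if x in idx and y in idx:
                    a, b = idx[x], idx[y]
                    tot += -B[a, b] + (B[a, a] + B[b, b]) / 2
                    n += 1
            if n:
                assert M.matrix[i, j] == pytest.approx(tot / n)
                assert M.n_aligned[i, j] == n
            else:
                assert np.isnan(M.matrix[i, j])

    def test_row_permutation_permutes_labels(self, residue_distance):
        rows = [("a", "ACDEF"), ("b", "AKDEF"), ("c", "ARNEF")]
        M1 = pairwise_distance_matrix(rows, residue_distance)
        M2 = pairwise_distance_matrix(rows[::-1], residue_distance)
        d1, d2 = M1.as_dict(), M2.as_dict()
        for pair, v in d1.items():
            assert d2[pair] == pytest.approx(v)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        mat = np.array([[0, 3.0, 5.0], [3.0, 0, 6.0], [5.0, 6.0, 0]])
        M = PairwiseDistanceMatrix(labels, mat,
                                   np.ones((3, 3), dtype=np.int64))
        tree = neighbor_joining(M)
        lengths = {
            lf.taxon.label: lf.edge.length
            for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_recovers_additive_six_taxon_tree(self):
        newick = "((A:1,B:2):1.5,(C:0.5,(D:1,E:2.5):1):2,F:3);"
        true_tree, M = tree_distance_matrix(newick)
        nj = neighbor_joining(M)
        nj2 = dendropy.Tree.get(
            data=nj.as_string(schema="newick"), schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        true_tree.encode_bipartitions()
        nj2.encode_bipartitions()
        assert treecompare.symmetric_difference(true_tree, nj2) == 0
        # branch lengths: patristic distances reproduce the input exactly
        pdm = nj2.phylogenetic_distance_matrix()
        for i, a in enumerate(M.labels):
            for j, b in enumerate(M.labels):
                if i < j:
                    d = pdm.distance(
                        true_tree.taxon_namespace.get_taxon(a),
                        true_tree.taxon_namespace.get_taxon(b),
                    )
                    assert d == pytest.approx(M.matrix[i, j], abs=1e-9)

    def test_deterministic_on_tied_input(self):
        labels = ["A", "B", "C", "D"]
        mat = np.full((4, 4), 2.0)
        np.fill_diagonal(mat, 0.0)
        M = PairwiseDistanceMatrix(labels, mat,
                                   np.ones((4, 4), dtype=np.int64))
        t1 = neighbor_joining(M).as_string(schema="newick")
        t2 = neighbor_joining(M).as_string(schema="newick")
        assert t1 == t2
        assert "A" in t1.split(",")[0]  # lexicographically smallest pair first

    def test_agrees_with_scikit_bio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        newick = "((A:1,B:2):1.5,(C:0.5,(D:1,E:2.5):1):2,F:3);"
        true_tree, M = tree_distance_matrix(newick)
        dm = skbio.DistanceMatrix(M.matrix, ids=M.labels)
        ref = skbio.tree.nj(dm)
        ref_dp = dendropy.Tree.get(
            data=str(ref), schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        ours = dendropy.Tree.get(
            data=neighbor_joining(M).as_string(schema="newick"),
            schema="newick", taxon_namespace=true_tree.taxon_namespace,
        )
        ref_dp.encode_bipartitions()
        ours.encode_bipartitions()
        assert treecompare.symmetric_difference(ref_dp, ours) == 0

    def test_too_few_taxa_rejected(self):
        M = PairwiseDistanceMatrix(
            ["A", "B"], np.array([[0, 1.0], [1.0, 0]]),
            np.ones((2, 2), dtype=np.int64),
        )
        with pytest.raises(ValueError):
            neighbor_joining(M)


class TestRootByOutgroup:
    def _tree(self):
        newick = "((A:1,B:2):1.5,(C:0.5,(D:1,E:2.5):1):2,F:3);"
        _, M = tree_distance_matrix(newick)
        return neighbor_joining(M)

    def test_leaf_set_unchanged(self):
        tree = self._tree()
        before = {lf.taxon.label for lf in tree.leaf_node_iter()}
        rooted = root_by_outgroup(tree, "F")
        after = {lf.taxon.label for lf in rooted.leaf_node_iter()}
        assert before == after

    def test_outgroup_child_of_root(self):
        rooted = root_by_outgroup(self._tree(), "F")
        children = rooted.seed_node.child_nodes()
        labels = {
            c.taxon.label for c in children if c.taxon is not None
        }
        assert "F" in labels
        assert rooted.is_rooted

    def test_rerooting_idempotent_topology(self):
        r1 = root_by_outgroup(self._tree(), "F")
        r2 = root_by_outgroup(r1, "F")
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=r1.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=r2.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        assert treecompare.symmetric_difference(a, b) == 0

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            root_by_outgroup(self._tree(), "Z")


class TestAssignClasses:
    def block_matrix(self, sizes, within=0.0, between=10.0):
        labels = []
        blocks = []
        for b, size in enumerate(sizes):
            labels += [f"b{b}_{i}" for i in range(size)]
            blocks += [b] * size
        n = len(labels)
        mat = np.full((n, n), between)
        for i in range(n):
            for j in range(n):
                if blocks[i] == blocks[j]:
                    mat[i, j] = within
        np.fill_diagonal(mat, 0.0)
        return PairwiseDistanceMatrix(
            labels, mat, np.ones((n, n), dtype=np.int64)
        ), blocks

    def test_perfectly_separated_blocks_recovered(self):
        M, blocks = self.block_matrix([3, 4, 2, 3])
        asg = assign_classes(M, k=4)
        got = [asg.labels[lab] for lab in M.labels]
        # same block -> same class, different block -> different class
        for i, j in itertools.combinations(range(len(blocks)), 2):
            assert (got[i] == got[j]) == (blocks[i] == blocks[j])

    def test_class_one_closest_to_reference(self):
        rng = np.random.default_rng(0)
        M, blocks = self.block_matrix([3, 3, 3, 3], within=0.5, between=8.0)
        # make block distances to the reference increase with block index
        ref = M.labels[0]
        asg = assign_classes(M, k=4, reference=ref)
        assert asg.labels[ref] == 1
        assert asg.roman(ref) == "I"

    def test_planted_clusters_recovered_under_noise(self):
        correct = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            M, blocks = self.block_matrix([5, 5, 5, 5],
                                          within=1.0, between=10.0)
            noise = rng.normal(0, 0.3, M.matrix.shape)
            noisy = M.matrix + (noise + noise.T) / 2
            np.fill_diagonal(noisy, 0.0)
            noisy = np.clip(noisy, 0, None)
            M2 = PairwiseDistanceMatrix(M.labels, noisy, M.n_aligned)
            asg = assign_classes(M2, k=4)
            got = np.array([asg.labels[lab] for lab in M2.labels])
            # count pairwise co-assignment agreement with the planted truth
            for i, j in itertools.combinations(range(len(blocks)), 2):
                total += 1
                correct += (
                    (got[i] == got[j]) == (blocks[i] == blocks[j])
                )
        assert correct / total >= 0.95

    def test_k_equal_n_singletons(self, residue_distance):
        rows = [("a", "ACDEF"), ("b", "AKREF"), ("c", "WWNEF")]
        M = pairwise_distance_matrix(rows, residue_distance)
        asg = assign_classes(M, k=3)
        assert sorted(asg.labels.values()) == [1, 2, 3]

    def test_k_larger_than_n_rejected(self, residue_distance):
        rows = [("a", "ACDEF"), ("b", "AKREF")]
        M = pairwise_distance_matrix(rows, residue_distance)
        with pytest.raises(ValueError):
            assign_classes(M, k=3)
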
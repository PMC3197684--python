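import dendropy
import numpy as np
import pytest

from conftest import brute_force_path_lengths, random_rooted_tree
from cryptotyper.phylo import (
    DistanceMatrix,
    DistanceSummary,
    PhyloError,
    PhyloTree,
    bootstrap_support,
    delimit,
    group_summary,
    intra_individual_summary,
    nj_tree,
    p_distance_matrix,
    patristic_matrix,
)
from cryptotyper.seqalign import AlignmentBlock, SequenceRecord


def _rec(rid, bases):
    return SequenceRecord(id=rid, bases=bases)


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        dm = p_distance_matrix(AlignmentBlock([_rec("a", "ACGT"), _rec("b", "ACGT")]))
        assert dm.get("a", "b") == 0.0

    def test_single_mismatch_over_four_sites(self):
        dm = p_distance_matrix(AlignmentBlock([_rec("a", "ACGT"), _rec("b", "ACGA")]))
        assert dm.get("a", "b") == pytest.approx(0.25)

    def test_matches_naive_double_loop_recount(self):
        rng = np.random.default_rng(23)
        alphabet = np.array(list("ACGT-N"))
        rows = [
            _rec(f"r{i}", "".join(alphabet[rng.integers(0, 6, 80)])) for i in range(10)
        ]
        # ensure comparability everywhere
        rows.append(_rec("anchor", "A" * 80))
        block = AlignmentBlock(rows)
        dm = p_distance_matrix(block)
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows[i].bases, rows[j].bases
                comp = diff = 0
                for x, y in zip(a, b):
                    if x in "ACGT" and y in "ACGT":
                        comp += 1
                        diff += x != y
                assert dm.values[i, j] == pytest.approx(diff / comp)

    def test_pairwise_deletion_uses_retained_columns_only(self):
        block = AlignmentBlock(
            [_rec("a", "AAAT"), _rec("b", "AAAA")], retained_mask=[1, 1, 1, 0]
        )
        assert p_distance_matrix(block).get("a", "b") == 0.0

    def test_incomparable_pair_reported_by_name(self):
        block = AlignmentBlock([_rec("a", "A-"), _rec("b", "-A")])
        with pytest.raises(PhyloError, match="a.*b"):
            p_distance_matrix(block)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        tree = nj_tree(dm)
        lengths = {
            lf.taxon.label: lf.edge.length
            for lf in tree._dtree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.05)
        assert lengths["B"] == pytest.approx(0.15)
        assert lengths["C"] == pytest.approx(0.25)

    def test_recovers_additive_matrices_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            newick, labels, adj = random_rooted_tree(rng, 6)
            dm = DistanceMatrix(labels, brute_force_path_lengths(adj, labels))
            rebuilt = patristic_matrix(nj_tree(dm))
            order = [rebuilt.labels.index(l) for l in labels]
            assert np.allclose(rebuilt.values[np.ix_(order, order)], dm.values, atol=1e-9)

    def test_ultrametric_four_taxa_balanced_topology(self):
        d = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.2],
                [0.6, 0.6, 0.2, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        split = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert split in tree.splits()

    def test_too_few_taxa_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1.0], [1.0, 0]])))


class TestPatristic:
    def test_two_leaf_tree(self):
        dm = patristic_matrix(PhyloTree.from_newick("(a:0.1,b:0.3);"))
        assert dm.get("a", "b") == pytest.approx(0.4)

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            newick, labels, adj = random_rooted_tree(rng, 8)
            expected = brute_force_path_lengths(adj, labels)
            dm = patristic_matrix(PhyloTree.from_newick(newick))
            order = [dm.labels.index(l) for l in labels]
            assert np.allclose(dm.values[np.ix_(order, order)], expected, atol=1e-12)

    def test_ultrametric_tree_all_pairs_twice_height(self):
        dm = patristic_matrix(
            PhyloTree.from_newick("((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2);")
        )
        off = dm.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off[off > 0.21], 0.6)  # cross-cluster pairs
        assert dm.get("a", "b") == pytest.approx(0.2)

    def test_missing_branch_length_reported(self):
        with pytest.raises(PhyloError, match="b"):
            patristic_matrix(PhyloTree.from_newick("(a:0.1,b,c:0.2);"))


class TestNewickDialects:
    def test_support_read_from_internal_labels(self):
        t = PhyloTree.from_newick("((a:1,b:1)95:1,(c:1,d:1)87:1,e:1);")
        assert sorted(t.support_values().values()) == [87.0, 95.0]

    def test_support_read_from_comments(self):
        t = PhyloTree.from_newick("((a:1,b:1)[&support=95]:1,(c:1,d:1)[87]:1,e:1);")
        assert sorted(t.support_values().values()) == [87.0, 95.0]


class TestBootstrap:
    @staticmethod
    def _two_cluster_block(rng, n_per=5, between=0.10, within=0.001, L=1000):
        base = rng.integers(0, 4, L)
        other = base.copy()
        hit = rng.random(L) < between
        other[hit] = (other[hit] + rng.integers(1, 4, hit.sum())) % 4
        bases = np.array(list("ACGT"))
        rows = []
        for g, anc in (("x", base), ("y", other)):
            for i in range(n_per):
                leaf = anc.copy()
                hit = rng.random(L) < within
                leaf[hit] = (leaf[hit] + rng.integers(1, 4, hit.sum())) % 4
                rows.append(_rec(f"{g}{i}", "".join(bases[leaf])))
        return AlignmentBlock(rows)

    def test_deep_split_gets_high_support(self):
        block = self._two_cluster_block(np.random.default_rng(4))
        tree, supports = bootstrap_support(block, n_replicates=500, seed=0)
        leaves = frozenset(r.id for r in block.rows)
        key = frozenset(
            {frozenset(f"x{i}" for i in range(5)), frozenset(f"y{i}" for i in range(5))}
        )
        assert supports[key] >= 98.0

    def test_reproducible_for_fixed_seed(self):
        block = self._two_cluster_block(np.random.default_rng(9))
        _, s1 = bootstrap_support(block, n_replicates=50, seed=3)
        _, s2 = bootstrap_support(block, n_replicates=50, seed=3)
        assert s1 == s2

    def test_single_replicate_supports_are_zero_or_hundred(self):
        block = self._two_cluster_block(np.random.default_rng(6))
        _, supports = bootstrap_support(block, n_replicates=1, seed=1)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_invalid_replicate_count_rejected(self):
        block = self._two_cluster_block(np.random.default_rng(8))
        with pytest.raises(PhyloError):
            bootstrap_support(block, n_replicates=0, seed=0)


class TestSummaries:
    def test_constant_distances_collapse_summary(self):
        s = DistanceSummary.from_values([0.3] * 6)
        assert (s.median, s.ci_low, s.ci_high, s.min, s.max) == (0.3,) * 5

    def test_percentiles_against_sort_and_interpolate(self):
        # {1,2,3,4,100}: 2.5th pct at rank 0.1 -> 1.1; 97.5th at rank 3.9 -> 90.4
        s = DistanceSummary.from_values([1, 2, 3, 4, 100])
        assert s.median == 3
        assert s.ci_low == pytest.approx(1.1)
        assert s.ci_high == pytest.approx(90.4)
        assert (s.min, s.max, s.n_pairs) == (1, 100, 5)

    def test_group_summary_invariant_under_label_permutation(self, its_pdist, its_groups):
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(its_pdist.labels))
        shuffled = DistanceMatrix(
            [its_pdist.labels[i] for i in perm],
            its_pdist.values[np.ix_(perm, perm)],
        )
        for mode in (("within", "I"), ("between", "I", "II")):
            a = group_summary(its_pdist, its_groups, mode)
            b = group_summary(shuffled, its_groups, mode)
            assert a == b

    def test_intra_individual_median_of_three_clone_distances(self):
        labels = ["s1_c1", "s1_c2", "s1_c3", "s2_c1"]
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 0.02
        vals[0, 2] = vals[2, 0] = 0.05
        vals[1, 2] = vals[2, 1] = 0.03
        vals[3, :3] = vals[:3, 3] = 0.2
        dm = DistanceMatrix(labels, vals)
        out = intra_individual_summary(dm, {l: l.split("_")[0] for l in labels})
        assert list(out) == ["s1"]
        assert out["s1"].median == pytest.approx(0.03)
        assert out["s1"].n_pairs == 3

    def test_no_multiclone_specimen_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(PhyloError):
            intra_individual_summary(dm, {"a": "s1", "b": "s2"})


class TestDelimit:
    def test_synthetic_two_type_data_is_delimited(self, its_pdist, its_groups):
        rep = delimit(its_pdist, its_groups)
        assert rep.distinct
        assert rep.between.min > max(s.ci_high for s in rep.within.values())

    def test_identical_sequences_in_both_groups_not_delimited(self):
        block = AlignmentBlock([_rec(f"r{i}", "ACGTACGT") for i in range(4)])
        dm = p_distance_matrix(block)
        rep = delimit(dm, {"r0": "g1", "r1": "g1", "r2": "g2", "r3": "g2"})
        assert not rep.distinct

    def test_wrong_group_count_rejected(self, its_pdist):
        with pytest.raises(PhyloError):
            delimit(its_pdist, {l: "only" for l in its_pdist.labels})
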
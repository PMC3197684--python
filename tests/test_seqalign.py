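import numpy as np
import pytest

from cryptotyper.seqalign import (
    AlignmentBlock,
    SeqAlignError,
    SequenceRecord,
    classify_sites,
    consensus_sequence,
    merge_alignments,
    read_fasta,
    write_fasta,
)


def _rec(rid, bases, **kw):
    return SequenceRecord(id=rid, bases=bases, **kw)


class TestFastaIO:
    def test_roundtrip_preserves_records_and_metadata(self, tmp_path):
        rng = np.random.default_rng(5)
        records = [
            _rec(
                f"r{i}",
                "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)]),
                specimen_id=f"sp{i}",
                station_id="S01",
                marker="ITS",
                genotype="I" if i % 2 else "II",
            )
            for i in range(10)
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path)
        back = read_fasta(path)
        assert back == records

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_non_iupac_character_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">r1\nACGJ\n")
        with pytest.raises(SeqAlignError, match="r1"):
            read_fasta(path)

    def test_rna_u_mapped_to_t_and_uppercased(self):
        assert _rec("r", "acgu").bases == "ACGT"


def _naive_homology_merge(align_a, align_b):
    """Independent oracle: per-column statement comparison by explicit
    loops over sequences and ungapped residue counting."""
    ids = align_a.ids

    def statements(block):
        stmts = []
        for j in range(block.length):
            stmt = []
            for rid in ids:
                bases = block.row(rid).bases
                if bases[j] == "-":
                    stmt.append(None)
                else:
                    stmt.append(sum(1 for c in bases[:j] if c != "-"))
            stmts.append(tuple(stmt))
        return stmts

    sa = statements(align_a)
    sb = set(statements(align_b))
    return [j for j, s in enumerate(sa) if s in sb]


class TestMergeAlignments:
    def test_identity_merge_returns_same_columns(self):
        a = AlignmentBlock([_rec("x", "AC-GT"), _rec("y", "ACTGT")])
        merged = merge_alignments(a, a)
        assert [r.bases for r in merged.rows] == [r.bases for r in a.rows]

    def test_gap_shift_removes_exactly_discordant_columns(self):
        # same two sequences, alignment B slides y's gap one column right
        a = AlignmentBlock([_rec("x", "ACGTACGTAC"), _rec("y", "AC-TACGTAC")])
        b = AlignmentBlock([_rec("x", "ACGTACGTAC"), _rec("y", "ACT-ACGTAC")])
        merged = merge_alignments(a, b)
        expected = _naive_homology_merge(a, b)
        # the two columns spanned by the discordant gap placement drop out
        assert expected == [0, 1, 4, 5, 6, 7, 8, 9]
        got = _naive_homology_merge(a, AlignmentBlock(merged.rows))
        assert merged.length == len(expected)
        assert [r.bases for r in merged.rows] == [
            "".join(a.rows[k].bases[j] for j in expected) for k in range(2)
        ]

    def test_mutated_sequence_rejected(self):
        a = AlignmentBlock([_rec("x", "ACGT"), _rec("y", "AGGT")])
        b = AlignmentBlock([_rec("x", "ACGT"), _rec("y", "ATGT")])
        with pytest.raises(SeqAlignError, match="y"):
            merge_alignments(a, b)

    def test_different_sequence_sets_rejected(self):
        a = AlignmentBlock([_rec("x", "ACGT"), _rec("y", "ACGT")])
        b = AlignmentBlock([_rec("x", "ACGT"), _rec("z", "ACGT")])
        with pytest.raises(SeqAlignError):
            merge_alignments(a, b)

    def test_idempotent_and_never_wider_on_perturbed_alignments(self):
        # emulate a manual vs automatic alignment pair: same sequences,
        # alignment B slides one gap of one row to a nearby column
        rng = np.random.default_rng(17)
        for _ in range(20):
            width = 20
            rows = []
            for k in range(3):
                chars = list(
                    "".join(np.array(list("ACGT"))[rng.integers(0, 4, width)])
                )
                for j in rng.choice(width, size=3, replace=False):
                    chars[j] = "-"
                rows.append("".join(chars))
            a = AlignmentBlock([_rec(f"s{k}", r) for k, r in enumerate(rows)])
            moved = list(rows)
            k = int(rng.integers(0, 3))
            chars = list(moved[k])
            gap_pos = [j for j, c in enumerate(chars) if c == "-"]
            src = int(rng.choice(gap_pos))
            dst = max(0, min(width - 1, src + int(rng.choice([-1, 1]))))
            chars[src], chars[dst] = chars[dst], chars[src]
            moved[k] = "".join(chars)
            b = AlignmentBlock([_rec(f"s{k}", r) for k, r in enumerate(moved)])

            merged = merge_alignments(a, b)
            assert merged.length <= min(a.length, b.length)
            # re-merging changes nothing as long as no residue column was
            # dropped (otherwise the merged rows are no longer the same
            # sequences and the precondition rejects the input)
            if all(merged.row(r.id).ungapped == r.ungapped for r in b.rows):
                again = merge_alignments(merged, b)
                assert [r.bases for r in again.rows] == [r.bases for r in merged.rows]
            else:
                with pytest.raises(SeqAlignError):
                    merge_alignments(merged, b)


class TestConsensus:
    def test_identical_rows_reproduce_the_row(self):
        a = AlignmentBlock([_rec(f"r{i}", "ACGT-") for i in range(10)])
        assert consensus_sequence(a).symbols == "ACGTN"

    @pytest.mark.parametrize(
        "column,expected",
        [("A" * 7 + "T" * 3, "A"), ("A" * 5 + "T" * 5, "N"), ("A" * 6 + "-" * 4, "A")],
    )
    def test_threshold_rule(self, column, expected):
        a = AlignmentBlock([_rec(f"r{i}", c) for i, c in enumerate(column)])
        assert consensus_sequence(a, threshold=0.6).symbols == expected

    def test_empty_group_rejected(self):
        a = AlignmentBlock([_rec("r", "ACGT")])
        with pytest.raises(SeqAlignError):
            consensus_sequence(a, group_rows=[])


class TestClassifySites:
    def test_query_identical_to_consensus_a(self):
        cons_a = consensus_sequence(AlignmentBlock([_rec("a", "ACGTAC")]))
        cons_b = consensus_sequence(AlignmentBlock([_rec("b", "ACTTAG")]))
        cls = classify_sites("ACGTAC", cons_a, cons_b)
        n_diff = sum(x != y for x, y in zip("ACGTAC", "ACTTAG"))
        assert cls.counts() == (n_diff, 0, 0)

    def test_hand_built_twelve_column_toy(self):
        # column-by-column design (query vs consensus A vs consensus B):
        #  0-7: all agree; 8: q=A=consA, consB=T (syn A); 9: same (syn A);
        #  10: q=G=consB, consA=C (syn B); 11: q=T, consA=consB=A (autapo)
        cons_a = consensus_sequence(AlignmentBlock([_rec("a", "ACGTACGTAACA")]))
        cons_b = consensus_sequence(AlignmentBlock([_rec("b", "ACGTACGTTTGA")]))
        query = "ACGTACGTAAGT"
        cls = classify_sites(query, cons_a, cons_b)
        assert cls.counts() == (2, 1, 1)
        assert cls.positions_synapomorphy_a == [8, 9]
        assert cls.positions_synapomorphy_b == [10]
        assert cls.positions_autapomorphy == [11]
        # strict rule drops the agreeing-consensus autapomorphy
        assert classify_sites(query, cons_a, cons_b, strict_autapomorphy=True).counts() == (2, 1, 0)

    def test_counts_invariant_under_consistent_column_permutation(self):
        rng = np.random.default_rng(3)
        a, b = "ACGTACGTAACA", "ACGTACGTTTGA"
        q = "ACGTACGTAAGT"
        perm = rng.permutation(len(q))
        shuffle = lambda s: "".join(s[j] for j in perm)  # noqa: E731
        cons = lambda s: consensus_sequence(AlignmentBlock([_rec("r", s)]))  # noqa: E731
        assert (
            classify_sites(shuffle(q), cons(shuffle(a)), cons(shuffle(b))).counts()
            == classify_sites(q, cons(a), cons(b)).counts()
        )

    def test_masked_and_uncalled_columns_excluded(self):
        cons_a = consensus_sequence(AlignmentBlock([_rec("a", "AANA")]))
        cons_b = consensus_sequence(AlignmentBlock([_rec("b", "TTTT")]))
        mask = [True, False, True, True]
        cls = classify_sites("AAAA", cons_a, cons_b, mask=mask)
        assert cls.counts() == (2, 0, 0)  # col 1 masked, col 2 uncalled

    def test_length_mismatch_rejected(self):
        cons = consensus_sequence(AlignmentBlock([_rec("a", "ACGT")]))
        with pytest.raises(SeqAlignError):
            classify_sites("ACG", cons, cons)
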
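from functools import lru_cache

import numpy as np
import pytest

from smartchar.edit_quant import (
    DEFAULT_SCORES,
    AmpliconRef,
    align_read,
    heatmap_table,
    quantify,
)
from smartchar.seqio import SeqRecord
from smartchar.simulate import EditTruth, simulate_amplicon_reads


def _oracle_score(q: str, r: str, scores=DEFAULT_SCORES) -> float:
    """Independent affine-gap global alignment score.

    Top-down recursion with memoization over explicit (position, last-op)
    states: every alignment path is represented, including the gap-to-gap
    transitions the production kernel folds away.
    """
    s_m, s_x, go, ge = scores
    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # score of the best alignment of q[:i] with r[:j] whose LAST op kind
        # is `state` (0 diag, 1 insertion, 2 deletion); -inf if impossible
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -1e18
        out = -1e18
        if state == 0 and i > 0 and j > 0:
            s = s_m if q[i - 1] == r[j - 1] else s_x
            out = max(rec(i - 1, j - 1, k) for k in (0, 1, 2)) + s
        elif state == 1 and i > 0:
            out = max(
                rec(i - 1, j, 0) + go,
                rec(i - 1, j, 1) + ge,
                rec(i - 1, j, 2) + go,
            )
        elif state == 2 and j > 0:
            out = max(
                rec(i, j - 1, 0) + go,
                rec(i, j - 1, 2) + ge,
                rec(i, j - 1, 1) + go,
            )
        return out

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        return max(rec(len(q), len(r), k) for k in (0, 1, 2))
    finally:
        sys.setrecursionlimit(old)


def _apply_ops(read_seq: str, ref_seq: str, ops) -> bool:
    """Check an op list is a consistent alignment of read against ref."""
    qi = ri = 0
    for op, length in ops:
        if op in "=X":
            for _ in range(length):
                same = read_seq[qi] == ref_seq[ri]
                if op == "=" and not same:
                    return False
                if op == "X" and same:
                    return False
                qi += 1
                ri += 1
        elif op == "I":
            qi += length
        else:
            ri += length
    return qi == len(read_seq) and ri == len(ref_seq)


class TestAlignRead:
    def test_identical_read_all_match(self, amplicon):
        read = SeqRecord("r", amplicon.sequence)
        aln = align_read(read, amplicon)
        assert aln.ops == [("=", len(amplicon.sequence))]
        assert aln.identity == 1.0

    def test_three_nt_deletion_single_op(self, amplicon):
        seq = amplicon.sequence
        read = SeqRecord("r", seq[:50] + seq[53:])
        aln = align_read(read, amplicon)
        dels = [(op, length) for op, length in aln.ops if op == "D"]
        assert dels == [("D", 3)]
        assert not any(op == "I" for op, _ in aln.ops)

    def test_insertion_recovered(self, amplicon):
        seq = amplicon.sequence
        read = SeqRecord("r", seq[:50] + "CATG" + seq[50:])
        aln = align_read(read, amplicon)
        assert [(op, length) for op, length in aln.ops if op == "I"] == [("I", 4)]

    def test_low_identity_rejected(self, amplicon, rng):
        bases = np.array(list("ACGT"))
        read = SeqRecord("junk", "".join(bases[rng.integers(0, 4, 120)]))
        assert align_read(read, amplicon) is None

    def test_score_matches_exhaustive_dp_on_small_instances(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(100):
            q = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 21)))])
            r = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 21)))])
            ref = AmpliconRef(r + "A" * 0, window=(1, 1), protospacer_start=1,
                              protospacer_len=1)
            aln = align_read(SeqRecord("q", q), ref, min_identity=0.0)
            assert aln.score == pytest.approx(_oracle_score(q, r)), (q, r)
            assert _apply_ops(q, r, aln.ops)

    def test_planted_cigars_recovered_without_error(self, amplicon):
        truth = EditTruth(indel_spec=(46, 2, "del", 1.0), error_rate=0.0)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=50, seed=8)
        for read in reads:
            aln = align_read(read, amplicon)
            assert [(op, length) for op, length in aln.ops if op in "ID"] == [("D", 2)]


class TestQuantify:
    def test_mock_control_is_all_zero(self, amplicon):
        truth = EditTruth(error_rate=0.0)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=500, seed=9)
        m = quantify(reads, amplicon)
        assert m.sub_counts.sum() == 0
        assert m.indel_fraction == 0.0
        assert m.n_reads_aligned == 500

    def test_planted_conversion_recovered_within_3_sigma(self, amplicon):
        frac, n = 0.4, 3000
        truth = EditTruth(edit_spec=[(45, "A", "G", frac)], error_rate=0.001)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=n, seed=10)
        m = quantify(reads, amplicon)
        sigma = np.sqrt(frac * (1 - frac) / n)
        assert abs(m.edit_fraction(45, "G") - frac) <= 3 * sigma

    def test_window_indel_fraction_recovered(self, amplicon):
        frac, n = 0.95, 2000
        truth = EditTruth(indel_spec=(46, 1, "del", frac), error_rate=0.0)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=n, seed=11)
        m = quantify(reads, amplicon)
        sigma = np.sqrt(frac * (1 - frac) / n)
        assert abs(m.indel_fraction - frac) <= 3 * sigma

    def test_out_of_window_indel_not_counted(self, amplicon):
        # deletion at amplicon position 5, far from the editing window
        truth = EditTruth(indel_spec=(5, 2, "del", 1.0), error_rate=0.0)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=50, seed=12)
        m = quantify(reads, amplicon)
        assert m.indel_fraction == 0.0
        whole = quantify(reads, amplicon, whole_amplicon_indels=True)
        assert whole.indel_fraction == 1.0

    def test_coverage_conservation(self, amplicon):
        truth = EditTruth(edit_spec=[(45, "A", "G", 0.5)], error_rate=0.01)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=300, seed=13)
        m = quantify(reads, amplicon)
        # substitutions at a position can never exceed its coverage
        assert (m.sub_counts.sum(axis=1) <= m.coverage).all()
        # error-free positions: full coverage equals aligned reads
        assert m.coverage.max() == m.n_reads_aligned

    def test_input_order_invariance(self, amplicon):
        truth = EditTruth(edit_spec=[(45, "A", "G", 0.3)], error_rate=0.005)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=200, seed=14)
        m1 = quantify(reads, amplicon)
        m2 = quantify(list(reversed(reads)), amplicon)
        np.testing.assert_array_equal(m1.sub_counts, m2.sub_counts)
        np.testing.assert_array_equal(m1.coverage, m2.coverage)
        assert m1.indel_fraction == m2.indel_fraction

    def test_no_accepted_alignment_is_an_error(self, amplicon, rng):
        bases = np.array(list("ACGT"))
        junk = [SeqRecord("j", "".join(bases[rng.integers(0, 4, 120)])) for _ in range(5)]
        with pytest.raises(ValueError, match="zero accepted alignments"):
            quantify(junk, amplicon)


class TestHeatmapTable:
    def test_one_row_per_from_base_occurrence(self, amplicon):
        truth = EditTruth(error_rate=0.0)
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=20, seed=15)
        m = quantify(reads, amplicon)
        table = heatmap_table(m, amplicon, ("A", "G"))
        assert len(table) == amplicon.protospacer.count("A")
        assert (table["percent"] == 0).all()

    def test_no_from_base_gives_empty_table(self):
        # protospacer without any G: an A->G table has rows, a G->A table none
        ref = AmpliconRef(
            sequence="TTGGCACCTTAACCTTAACCTTGGCC",
            window=(1, 4),
            protospacer_start=7,
            protospacer_len=12,
        )
        assert "G" not in ref.protospacer
        reads = [SeqRecord(f"r{i}", ref.sequence) for i in range(10)]
        m = quantify(reads, ref)
        assert heatmap_table(m, ref, ("G", "A")).empty
        assert len(heatmap_table(m, ref, ("A", "G"))) == ref.protospacer.count("A")

    def test_window_profile_recovered(self, amplicon):
        # protospacer positions of planted A->G edits: 4 (in window), 14 (outside)
        off = amplicon.protospacer_start - 1
        truth = EditTruth(
            edit_spec=[(off + 4, "A", "G", 0.6), (off + 14, "A", "G", 0.0)],
            error_rate=0.0,
        )
        reads, _ = simulate_amplicon_reads(amplicon, truth, n=2000, seed=17)
        m = quantify(reads, amplicon)
        table = heatmap_table(m, amplicon, ("A", "G")).set_index("protospacer_position")
        sigma = 100 * np.sqrt(0.6 * 0.4 / 2000)
        assert abs(table.loc[4, "percent"] - 60.0) <= 3 * sigma
        assert table.loc[14, "percent"] == 0.0
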
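"""Identity profiles and homopolymer tables vs naive column-walk oracles."""

import numpy as np
import pytest

from nanosurvey import (
    SeqRecord,
    get_preset,
    homopolymer_accuracy,
    homopolymer_error_partition,
    identity_profile,
    simulate_reads,
)
from nanosurvey.core import AlignmentRecord, Cigar
from nanosurvey.profile import CLASS_NAMES, HomopolymerTable
from .conftest import random_seq


def rec_for(ref_id, ref_len, t_start, cigar_str, query_id="r",
            strand="+", secondary=False):
    cig = Cigar.from_string(cigar_str)
    return AlignmentRecord(
        query_id=query_id, query_len=cig.query_span,
        q_start=0, q_end=cig.query_span, strand=strand,
        target_id=ref_id, target_len=ref_len,
        t_start=t_start, t_end=t_start + cig.target_span, cigar=cig,
        is_secondary=secondary,
    )


def naive_homopolymer_walk(ref_seq, rec, read_seq):
    """Independent oracle: expand every column and classify each reference
    run of length >= 2 by direct inspection."""
    cols = []  # (op, tpos, qbase)
    qpos, tpos = 0, rec.t_start
    for op, n in rec.cigar:
        for _ in range(n):
            if op == "I":
                cols.append((op, tpos, read_seq[qpos]))
                qpos += 1
            elif op == "D":
                cols.append((op, tpos, None))
                tpos += 1
            else:
                cols.append((op, tpos, read_seq[qpos]))
                qpos += 1
                tpos += 1
    results = {}
    i = 0
    while i < len(ref_seq):
        j = i
        while j < len(ref_seq) and ref_seq[j] == ref_seq[i]:
            j += 1
        ell = j - i
        if ell >= 2 and i >= rec.t_start and j <= rec.t_end:
            base = ref_seq[i]
            n_match = sum(1 for op, t, q in cols if op == "=" and i <= t < j)
            n_x = sum(1 for op, t, q in cols if op == "X" and i <= t < j)
            n_d = sum(1 for op, t, q in cols if op == "D" and i <= t < j)
            n_i = sum(1 for op, t, q in cols
                      if op == "I" and i <= t <= j and q == base)
            if n_x == 0 and n_d == 0 and n_i == 0:
                cls = "correct"
            else:
                net = n_i - n_d
                cls = ("deletion" if net < 0
                       else "insertion" if net > 0 else "substitution")
            results[(base, i, ell)] = cls
        i = j
    return results


class TestIdentityProfile:
    def test_hand_built_identities(self):
        recs = [
            rec_for("t", 100, 0, "90=10X", "a"),   # 0.9
            rec_for("t", 100, 0, "80=20X", "b"),   # 0.8
            rec_for("t", 100, 0, "70=30X", "c"),   # 0.7
        ]
        prof = identity_profile(recs)
        p = prof["all"]
        assert p.mean_identity == pytest.approx(0.8)
        assert p.median_identity == pytest.approx(0.8)
        assert p.histogram.sum() == 3

    def test_unaligned_reads_counted(self):
        recs = [rec_for("t", 100, 0, "100=", "a")]
        prof = identity_profile(recs, read_ids=["a", "b", "c", "d"])
        assert prof["all"].fraction_aligned == pytest.approx(0.25)

    def test_two_primary_records_error(self):
        recs = [rec_for("t", 100, 0, "50=", "a"), rec_for("t", 100, 50, "50=", "a")]
        with pytest.raises(ValueError, match="two primary"):
            identity_profile(recs)

    def test_secondary_records_ignored(self):
        recs = [rec_for("t", 100, 0, "50=", "a"),
                rec_for("t", 100, 50, "50=", "a", secondary=True)]
        prof = identity_profile(recs)
        assert prof["all"].n_reads_aligned == 1


HAND_CASES = [
    # (reference, cigar at t_start 0, read)  — small alignments with known
    # homopolymer fates, checked against the naive column walk
    ("CAAAAG", "1=1D4=", "CAAAG"),          # run (A,4) net deletion
    ("CAAAAG", "2=1I4=", "CAAAAAG"),        # same-base insertion -> insertion
    ("CAAAAG", "6=", "CAAAAG"),             # correct
    ("CAAAAG", "1=1X4=", "CTAAAG"),         # mismatch outside the run
    ("CAAAAG", "2=1X3=", "CATAAG"),         # substitution inside the run
    ("TTGGGGA", "2=4D1I1=", "TTCA"),        # run fully deleted
    ("ACCA", "2=2I2=", "ACCGGA"),           # different-base insertion ignored
]


class TestHomopolymerTable:
    @pytest.mark.parametrize("ref_seq,cigar,read_seq", HAND_CASES)
    def test_matches_naive_column_walk(self, ref_seq, cigar, read_seq):
        ref = SeqRecord("t", ref_seq)
        rec = rec_for("t", len(ref_seq), 0, cigar)
        reads = {"r": SeqRecord("r", read_seq)}
        table = homopolymer_accuracy([ref], [rec], reads=reads)
        oracle = naive_homopolymer_walk(ref_seq, rec, read_seq)
        got = {
            "correct": int(table.n_correct.sum()),
            "deletion": int(table.n_net_deletion.sum()),
            "insertion": int(table.n_net_insertion.sum()),
            "substitution": int(table.n_substitution_only.sum()),
        }
        want = {k: 0 for k in got}
        for cls in oracle.values():
            want[cls] += 1
        assert got == want
        assert int(table.n_runs.sum()) == len(oracle)

    def test_counting_closure_on_simulation(self):
        rng = np.random.default_rng(8)
        genome = [SeqRecord("g", random_seq(rng, 60_000))]
        reads, truth = simulate_reads(genome, get_preset("R7.3_2D"),
                                      seed=2, n_reads=60)
        table = homopolymer_accuracy(genome, truth,
                                     reads={r.id: r for r in reads})
        total = (table.n_correct + table.n_net_deletion
                 + table.n_net_insertion + table.n_substitution_only)
        assert np.array_equal(total, table.n_runs)
        assert table.n_runs.sum() > 1_000

    def test_fraction_correct_non_increasing_in_length(self):
        rng = np.random.default_rng(9)
        genome = [SeqRecord("g", random_seq(rng, 150_000))]
        reads, truth = simulate_reads(genome, get_preset("R9_2D"),
                                      seed=3, n_reads=150)
        table = homopolymer_accuracy(genome, truth,
                                     reads={r.id: r for r in reads})
        for cls in CLASS_NAMES:
            fracs = [table.fraction_correct(cls, ell) for ell in range(2, 7)]
            for a, b in zip(fracs, fracs[1:]):
                assert b <= a + 0.06  # non-increasing up to sampling noise

    def test_truncated_runs_skipped(self):
        ref = SeqRecord("t", "AAAACGT")
        rec = rec_for("t", 7, 2, "5=")  # starts inside the A-run
        table = homopolymer_accuracy([ref], [rec])
        assert table.n_runs.sum() == 0

    def test_unknown_reference_errors(self):
        rec = rec_for("elsewhere", 100, 0, "10=")
        with pytest.raises(ValueError, match="not in reference"):
            homopolymer_accuracy([SeqRecord("t", "ACGT" * 10)], [rec])


class TestErrorPartition:
    def test_arithmetic(self):
        table = HomopolymerTable.empty()
        table.n_runs[0, 4] = 10
        table.n_correct[0, 4] = 6
        table.n_net_deletion[0, 4] = 2
        table.n_net_insertion[0, 4] = 1
        table.n_substitution_only[0, 4] = 1
        part = homopolymer_error_partition(table)
        assert part["deletion_fraction"] == pytest.approx(0.5)
        assert part["insertion_fraction"] == pytest.approx(0.25)

    def test_no_errors_undefined(self):
        table = HomopolymerTable.empty()
        table.n_runs[0, 2] = 5
        table.n_correct[0, 2] = 5
        with pytest.raises(ValueError, match="undefined"):
            homopolymer_error_partition(table)
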
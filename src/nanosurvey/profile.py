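"""Per-read identity distributions and homopolymer accuracy profiling.

Works from base-level alignments (truth SAM from the simulator, or any
aligner output with =/X/I/D ops).  Homopolymer classification walks every
maximal reference run of one base (length >= 2) fully contained in an
alignment's target span and classifies it from the alignment columns over
the run plus query-side insertions of the same base immediately flanking
it:

* **correct** — exactly `len` matching columns, no attributable insertion;
* **net deletion / net insertion** — the run's query-consumed same-base
  length shrank / grew;
* **substitution only** — length preserved but >= 1 mismatch column.

A run overlapping two alignment records *of the same read* (split chains)
is counted once, in the record with higher identity (tie: first by target
coordinate); every read covering a run contributes one observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import encode
from .core import (
    OP_DEL,
    OP_INS,
    OP_MATCH,
    OP_MISMATCH,
    AlignmentRecord,
    SeqRecord,
    revcomp,
)
from .simulate import rle

CLASS_NAMES = ("AT", "CG")
_CLASS_OF_BASE = np.array([0, 1, 1, 0, 0], dtype=np.int64)


# ---------------------------------------------------------------------------
# identity profile


@dataclass
class ClassProfile:
    label: str
    n_reads_total: int
    n_reads_aligned: int
    mean_identity: float
    median_identity: float
    histogram: np.ndarray  # 100 bins of 1 percentage point, [0,100]

    @property
    def fraction_aligned(self) -> float:
        return self.n_reads_aligned / self.n_reads_total if self.n_reads_total else 0.0

    @property
    def mean_error_rate(self) -> float:
        return 1.0 - self.mean_identity


@dataclass
class ErrorProfile:
    classes: dict[str, ClassProfile] = field(default_factory=dict)

    def __getitem__(self, label: str) -> ClassProfile:
        return self.classes[label]


def identity_profile(
    records: list[AlignmentRecord],
    read_ids: list[str] | None = None,
    class_labels: dict[str, str] | None = None,
) -> ErrorProfile:
    """Per-read identity statistics, one profile per read class.

    ``read_ids`` lists every read (aligned or not) so fraction_aligned is
    meaningful; it defaults to the reads present in ``records``.  A read
    with two primary records is an error.
    """
    primary: dict[str, AlignmentRecord] = {}
    for r in records:
        if r.is_secondary or r.is_supplementary:
            continue
        if r.query_id in primary:
            raise ValueError(f"read {r.query_id} has two primary records")
        primary[r.query_id] = r
    if read_ids is None:
        read_ids = list(primary)
    labels = class_labels or {}
    by_class: dict[str, list[str]] = {}
    for rid in read_ids:
        by_class.setdefault(labels.get(rid, "all"), []).append(rid)

    profile = ErrorProfile()
    for label, rids in by_class.items():
        idents = np.array(
            [primary[r].identity for r in rids if r in primary], dtype=float
        )
        hist, _ = np.histogram(idents * 100.0, bins=100, range=(0.0, 100.0))
        hist[-1] += int((idents == 1.0).sum())  # identity 100% into top bin
        profile.classes[label] = ClassProfile(
            label=label,
            n_reads_total=len(rids),
            n_reads_aligned=len(idents),
            mean_identity=float(idents.mean()) if len(idents) else float("nan"),
            median_identity=float(np.median(idents)) if len(idents) else float("nan"),
            histogram=hist,
        )
    return profile


# ---------------------------------------------------------------------------
# homopolymer table


@dataclass
class HomopolymerTable:
    """Counts keyed by (base class, run length); lengths > max_len pool
    into the top row (reported as e.g. 7 meaning '7+')."""

    max_len: int
    n_runs: np.ndarray  # shape (2, max_len + 1); rows 0/1 unused below len 2
    n_correct: np.ndarray
    n_net_deletion: np.ndarray
    n_net_insertion: np.ndarray
    n_substitution_only: np.ndarray

    @classmethod
    def empty(cls, max_len: int = 7) -> "HomopolymerTable":
        z = lambda: np.zeros((2, max_len + 1), dtype=np.int64)
        return cls(max_len, z(), z(), z(), z(), z())

    def fraction_correct(self, base_class: str | None = None,
                         run_length: int | None = None) -> float:
        """Fraction of runs reproduced exactly; pool over class and/or length
        when the corresponding argument is None."""
        sel_c = slice(None) if base_class is None else CLASS_NAMES.index(base_class)
        sel_l = slice(None) if run_length is None else min(run_length, self.max_len)
        n = self.n_runs[sel_c, sel_l].sum()
        if n == 0:
            raise ValueError("no runs observed for that (class, length)")
        return float(self.n_correct[sel_c, sel_l].sum() / n)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, cls in enumerate(CLASS_NAMES):
            for ell in range(2, self.max_len + 1):
                n = int(self.n_runs[ci, ell])
                if n == 0:
                    continue
                rows.append(
                    {
                        "base_class": cls,
                        "run_length": f"{ell}+" if ell == self.max_len else str(ell),
                        "n_runs": n,
                        "n_correct": int(self.n_correct[ci, ell]),
                        "n_net_deletion": int(self.n_net_deletion[ci, ell]),
                        "n_net_insertion": int(self.n_net_insertion[ci, ell]),
                        "n_substitution_only": int(self.n_substitution_only[ci, ell]),
                        "fraction_correct": self.n_correct[ci, ell] / n,
                    }
                )
        return pd.DataFrame(rows)


class _TargetRuns:
    """Homopolymer runs (length >= 2) of one reference sequence."""

    __slots__ = ("starts", "ends", "lens", "bases")

    def __init__(self, seq: str):
        starts, lens, bases = rle(encode(seq))
        keep = (lens >= 2) & (bases < 4)
        self.starts = starts[keep]
        self.lens = lens[keep]
        self.ends = self.starts + self.lens
        self.bases = bases[keep]


def _record_columns(rec: AlignmentRecord, oriented_query_codes: np.ndarray | None):
    """Expand a CIGAR into per-column op, target-position and query-base arrays."""
    ops = np.repeat(rec.cigar.ops, rec.cigar.counts)
    tcons = (ops != OP_INS).astype(np.int64)
    tpos = rec.t_start + np.cumsum(tcons) - tcons
    qbase = None
    if oriented_query_codes is not None:
        qcons = (ops != OP_DEL).astype(np.int64)
        qpos = np.cumsum(qcons) - qcons
        if rec.strand == "+":
            q0 = rec.q_start
        else:
            q0 = rec.query_len - rec.q_end
        qidx = np.minimum(q0 + qpos, len(oriented_query_codes) - 1)
        qbase = np.where(ops == OP_INS, oriented_query_codes[qidx], np.uint8(255))
    return ops, tpos, qbase


def homopolymer_accuracy(
    reference: list[SeqRecord],
    records: list[AlignmentRecord],
    reads: dict[str, SeqRecord] | None = None,
    max_len: int = 7,
) -> HomopolymerTable:
    """Classify every covered reference homopolymer run from the alignments.

    ``reads`` (id -> SeqRecord, FASTQ orientation) supplies query bases so
    that inserted bases can be tested for run membership; without it, any
    insertion inside or flanking a run is attributed to the run.
    Runs truncated by alignment ends are skipped.
    """
    ref = {r.id: r for r in reference}
    runs_by_target = {rid: _TargetRuns(r.seq) for rid, r in ref.items()}
    table = HomopolymerTable.empty(max_len)

    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        if r.cigar is None or len(r.cigar) == 0:
            raise ValueError(f"{r.query_id}: homopolymer profiling needs a CIGAR")
        if r.target_id not in ref:
            raise ValueError(f"alignment target {r.target_id!r} not in reference")
        by_query.setdefault(r.query_id, []).append(r)

    for qid, recs in by_query.items():
        recs = sorted(recs, key=lambda r: (-r.identity, r.target_id, r.t_start))
        counted: dict[str, np.ndarray] = {}
        qcodes_cache: dict[str, np.ndarray] = {}
        for rec in recs:
            runs = runs_by_target[rec.target_id]
            i0 = int(np.searchsorted(runs.starts, rec.t_start, side="left"))
            i1 = int(np.searchsorted(runs.ends, rec.t_end, side="right"))
            if i1 <= i0:
                continue
            sub = slice(i0, i1)
            # dedup within the read
            mask = np.ones(i1 - i0, dtype=bool)
            if rec.target_id in counted:
                mask &= ~counted[rec.target_id][sub]
            else:
                counted[rec.target_id] = np.zeros(len(runs.starts), dtype=bool)
            # runs must start inside the span too (searchsorted on ends only
            # bounds the right side)
            mask &= runs.starts[sub] >= rec.t_start
            if not mask.any():
                continue
            qcodes = None
            if reads is not None and qid in reads:
                key = rec.strand
                if key not in qcodes_cache:
                    s = reads[qid].seq
                    qcodes_cache[key] = encode(s if key == "+" else revcomp(s))
                qcodes = qcodes_cache[key]
            ops, tpos, qbase = _record_columns(rec, qcodes)
            c_match = np.concatenate(([0], np.cumsum(ops == OP_MATCH)))
            c_x = np.concatenate(([0], np.cumsum(ops == OP_MISMATCH)))
            c_d = np.concatenate(([0], np.cumsum(ops == OP_DEL)))
            if qbase is not None:
                c_ins_b = [
                    np.concatenate(([0], np.cumsum((ops == OP_INS) & (qbase == b))))
                    for b in range(4)
                ]
            else:
                c_ins_any = np.concatenate(([0], np.cumsum(ops == OP_INS)))

            s_arr = runs.starts[sub][mask]
            e_arr = runs.ends[sub][mask]
            b_arr = runs.bases[sub][mask]
            l_arr = runs.lens[sub][mask]
            lo = np.searchsorted(tpos, s_arr, side="left")
            hi = np.searchsorted(tpos, e_arr, side="left")
            hi2 = np.searchsorted(tpos, e_arr, side="right")
            n_x = c_x[hi] - c_x[lo]
            n_d = c_d[hi] - c_d[lo]
            if qbase is not None:
                n_ins = np.zeros(len(s_arr), dtype=np.int64)
                for b in range(4):
                    pick = b_arr == b
                    if pick.any():
                        n_ins[pick] = (c_ins_b[b][hi2] - c_ins_b[b][lo])[pick]
            else:
                n_ins = c_ins_any[hi2] - c_ins_any[lo]
            correct = (n_x == 0) & (n_d == 0) & (n_ins == 0)
            net = n_ins - n_d
            cls_idx = _CLASS_OF_BASE[b_arr]
            len_idx = np.minimum(l_arr, max_len)
            np.add.at(table.n_runs, (cls_idx, len_idx), 1)
            np.add.at(table.n_correct, (cls_idx, len_idx), correct)
            np.add.at(table.n_net_deletion, (cls_idx, len_idx), ~correct & (net < 0))
            np.add.at(table.n_net_insertion, (cls_idx, len_idx), ~correct & (net > 0))
            np.add.at(
                table.n_substitution_only, (cls_idx, len_idx), ~correct & (net == 0)
            )
            idx = np.nonzero(mask)[0] + i0
            counted[rec.target_id][idx] = True
    return table


def homopolymer_error_partition(table: HomopolymerTable) -> dict[str, float]:
    """Error-type fractions among erroneous runs, pooled over class and length."""
    n_err = int((table.n_runs - table.n_correct).sum())
    if n_err == 0:
        raise ValueError("partition undefined: zero erroneous runs")
    return {
        "deletion_fraction": int(table.n_net_deletion.sum()) / n_err,
        "insertion_fraction": int(table.n_net_insertion.sum()) / n_err,
        "substitution_fraction": int(table.n_substitution_only.sum()) / n_err,
    }
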
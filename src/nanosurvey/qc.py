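"""Short-read quality control: end trimming, length filter, contaminant pairs.

Mirrors a conventional Illumina preprocessing pass: bases below Q20 are
trimmed from both read ends, reads shorter than 30 nt after trimming are
discarded, and read pairs matching a contaminant genome (e.g. phiX) are
removed.  Adapter trimming is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import KmerIndex, align_pair
from .core import SeqRecord


@dataclass
class TrimResult:
    record: SeqRecord | None
    kept: bool
    reason: str | None = None


def quality_trim(record: SeqRecord, qmin: int = 20, minlen: int = 30) -> TrimResult:
    """Trim low-quality ends, then length-filter.

    From each end, bases are removed inward until the first base with
    Q >= qmin; the result is kept iff its length is >= minlen.  The output
    sequence is always a contiguous substring of the input.
    """
    if record.quals is None:
        raise ValueError(f"{record.id}: quality_trim requires qualities")
    ok = np.nonzero(record.quals >= qmin)[0]
    if len(ok) == 0:
        return TrimResult(None, False, "no base at or above qmin")
    lo, hi = int(ok[0]), int(ok[-1]) + 1
    if hi - lo < minlen:
        return TrimResult(None, False, f"trimmed length {hi - lo} < {minlen}")
    return TrimResult(
        SeqRecord(record.id, record.seq[lo:hi], record.quals[lo:hi]), True
    )


def _matches_contaminant(mate: SeqRecord, index: KmerIndex, contaminant: SeqRecord,
                         min_id: float, min_cov: float) -> bool:
    try:
        hits = align_pair(mate, contaminant, index=index)
    except ValueError:  # mate shorter than k
        return False
    for h in hits:
        cov = (h.q_end - h.q_start) / len(mate)
        if h.identity >= min_id and cov >= min_cov:
            return True
    return False


def filter_contaminant_pairs(pairs, contaminant: SeqRecord,
                             min_id: float = 0.90, min_cov: float = 0.50):
    """Drop read pairs where either mate aligns to the contaminant.

    A mate matches if it aligns with identity >= min_id over >= min_cov of
    its own length.  Kept pairs are returned in input order.
    """
    if len(contaminant.seq) == 0:
        raise ValueError("contaminant sequence is empty")
    index = KmerIndex(contaminant.seq)
    kept = []
    for r1, r2 in pairs:
        if _matches_contaminant(r1, index, contaminant, min_id, min_cov):
            continue
        if _matches_contaminant(r2, index, contaminant, min_id, min_cov):
            continue
        kept.append((r1, r2))
    return kept
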
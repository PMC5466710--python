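"""Structural-variant detection from whole-genome alignment coordinates.

Pipeline: best-alignment filtering (1-to-1 semantics, the delta-filter -1
idea reimplemented), then a walk along each contig's ordered segments —
adjacent segments on different chromosomes call a translocation with
breakpoints at the facing segment ends; a maximal block of segments whose
orientation opposes its same-chromosome flanks calls an inversion spanning
the block's reference interval.  Chimeric assembly joins are separated from
genuine rearrangements by back-aligning reads to the assembly: a junction
no read spans contiguously is a chimera, not biology.

The default minimum segment size (10 kb) suppresses TE-sized relocations
(~5.8 kb elements) from the rearrangement list; subtelomeric calls are not
masked, only flagged by their junction annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import AlignmentRecord, SeqRecord


@dataclass
class Segment:
    """One filtered alignment segment of a contig on the reference."""

    contig_id: str
    q_start: int
    q_end: int
    target_id: str
    t_start: int
    t_end: int
    strand: str
    identity: float

    @property
    def score(self) -> float:
        return self.identity * (self.q_end - self.q_start)

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass
class SVEvent:
    type: str  # translocation | inversion | chimera
    contig_id: str
    chromA: str
    posA: int
    chromB: str
    posB: int
    length: int | None = None  # posB - posA for inversions
    junction_features: list[str] = field(default_factory=list)
    read_support: int | None = None
    n_junctions: int = 1


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _trim_segment(seg: Segment, kept: list[Segment],
                  max_overlap_frac: float) -> Segment | None:
    """Trim a candidate against already-selected segments.

    Overlap beyond ``max_overlap_frac`` of the candidate (on query within
    the same contig, or on reference anywhere) is cut away from the
    offending end, scaling the paired coordinates proportionally.
    """
    for other in kept:
        changed = True
        while changed and seg is not None:
            changed = False
            qlen = seg.q_end - seg.q_start
            if qlen <= 0:
                return None
            # query-side conflict
            if other.contig_id == seg.contig_id:
                ov = _overlap(seg.q_start, seg.q_end, other.q_start, other.q_end)
                if ov > max_overlap_frac * qlen:
                    seg = _cut_query(seg, other.q_start, other.q_end)
                    changed = True
                    continue
            # reference-side conflict
            if other.target_id == seg.target_id:
                ov = _overlap(seg.t_start, seg.t_end, other.t_start, other.t_end)
                if ov > max_overlap_frac * qlen:
                    seg = _cut_target(seg, other.t_start, other.t_end)
                    changed = True
    return seg


def _remake(seg: Segment, q: tuple[int, int], t: tuple[int, int]) -> Segment:
    return Segment(seg.contig_id, q[0], q[1], seg.target_id, t[0], t[1],
                   seg.strand, seg.identity)


def _cut_query(seg: Segment, lo: int, hi: int) -> Segment | None:
    """Remove the query overlap with [lo, hi); keep the larger remaining
    side, scaling target coordinates proportionally."""
    left = max(0, min(lo, seg.q_end) - seg.q_start)
    right = max(0, seg.q_end - max(hi, seg.q_start))
    if left == 0 and right == 0:
        return None
    qlen, tlen = seg.q_end - seg.q_start, seg.t_end - seg.t_start
    if left >= right:
        t_keep = int(round(left / qlen * tlen))
        q = (seg.q_start, seg.q_start + left)
        t = (seg.t_start, seg.t_start + t_keep) if seg.strand == "+" \
            else (seg.t_end - t_keep, seg.t_end)
    else:
        t_keep = int(round(right / qlen * tlen))
        q = (seg.q_end - right, seg.q_end)
        t = (seg.t_end - t_keep, seg.t_end) if seg.strand == "+" \
            else (seg.t_start, seg.t_start + t_keep)
    return _remake(seg, q, t)


def _cut_target(seg: Segment, lo: int, hi: int) -> Segment | None:
    """Remove the reference overlap with [lo, hi); keep the larger remaining
    side, scaling query coordinates proportionally."""
    left = max(0, min(lo, seg.t_end) - seg.t_start)
    right = max(0, seg.t_end - max(hi, seg.t_start))
    if left == 0 and right == 0:
        return None
    qlen, tlen = seg.q_end - seg.q_start, seg.t_end - seg.t_start
    if left >= right:
        q_keep = int(round(left / tlen * qlen))
        t = (seg.t_start, seg.t_start + left)
        q = (seg.q_start, seg.q_start + q_keep) if seg.strand == "+" \
            else (seg.q_end - q_keep, seg.q_end)
    else:
        q_keep = int(round(right / tlen * qlen))
        t = (seg.t_end - right, seg.t_end)
        q = (seg.q_end - q_keep, seg.q_end) if seg.strand == "+" \
            else (seg.q_start, seg.q_start + q_keep)
    return _remake(seg, q, t)


def filter_best_alignments(records: list[AlignmentRecord],
                           min_segment: int = 10_000,
                           max_overlap_frac: float = 0.5
                           ) -> dict[str, list[Segment]]:
    """Greedy 1-to-1 filtering by score = identity x aligned length.

    Candidates are taken best-first; where a candidate overlaps an already
    selected segment by more than ``max_overlap_frac`` (of its own length)
    on query or reference it is trimmed, and dropped if the remainder is
    shorter than ``min_segment``.  Deterministic: ties break by target
    coordinate.  Returns per-contig segment chains sorted by query start.
    """
    cands = []
    for r in records:
        if r.is_secondary:
            continue
        cands.append(
            Segment(r.query_id, r.q_start, r.q_end, r.target_id,
                    r.t_start, r.t_end, r.strand, r.identity)
        )
    cands.sort(key=lambda s: (-s.score, s.target_id, s.t_start, s.q_start))
    kept: list[Segment] = []
    for seg in cands:
        seg = _trim_segment(seg, kept, max_overlap_frac)
        if seg is None or len(seg) < min_segment or seg.t_end <= seg.t_start:
            continue
        kept.append(seg)
    chains: dict[str, list[Segment]] = {}
    for seg in kept:
        chains.setdefault(seg.contig_id, []).append(seg)
    for segs in chains.values():
        segs.sort(key=lambda s: s.q_start)
    return chains


def _facing_end(seg: Segment, side: str) -> int:
    """Reference coordinate of the segment end facing a junction.

    ``side`` is 'right' for the end reached last in query order."""
    if side == "right":
        return seg.t_end if seg.strand == "+" else seg.t_start
    return seg.t_start if seg.strand == "+" else seg.t_end


def detect_rearrangements(chains: dict[str, list[Segment]],
                          min_segment: int = 10_000,
                          dedup_window: int = 2_000) -> list[SVEvent]:
    """Call translocations and inversions from filtered segment chains.

    Events seen at multiple junctions (e.g. the two junctions of a
    reciprocal translocation) are deduplicated by breakpoint proximity
    (<= 2 x dedup_window), keeping a junction count.
    """
    events: list[SVEvent] = []
    for contig in sorted(chains):
        segs = [s for s in chains[contig] if len(s) >= min_segment]
        if len(segs) < 2:
            continue
        for a, b in zip(segs, segs[1:]):
            if a.target_id != b.target_id:
                events.append(
                    SVEvent(
                        "translocation", contig,
                        a.target_id, _facing_end(a, "right"),
                        b.target_id, _facing_end(b, "left"),
                    )
                )
        # inversions: interior opposite-strand blocks on one chromosome
        i = 0
        while i < len(segs):
            j = i
            while (j + 1 < len(segs)
                   and segs[j + 1].target_id == segs[i].target_id
                   and segs[j + 1].strand == segs[i].strand):
                j += 1
            block = segs[i: j + 1]
            left = segs[i - 1] if i > 0 else None
            right = segs[j + 1] if j + 1 < len(segs) else None
            same_chrom = lambda s: s is not None and s.target_id == block[0].target_id
            opposing = [s for s in (left, right) if same_chrom(s)]
            if opposing and all(s.strand != block[0].strand for s in opposing) \
                    and (same_chrom(left) and same_chrom(right)):
                s0 = min(s.t_start for s in block)
                e0 = max(s.t_end for s in block)
                events.append(
                    SVEvent("inversion", contig, block[0].target_id, s0,
                            block[0].target_id, e0, length=e0 - s0)
                )
            i = j + 1

    deduped: list[SVEvent] = []
    for ev in events:
        merged = False
        for kept in deduped:
            if kept.type != ev.type:
                continue
            pair_kept = frozenset((kept.chromA, kept.chromB))
            pair_ev = frozenset((ev.chromA, ev.chromB))
            if pair_kept != pair_ev:
                continue
            d = 2 * dedup_window
            same = (abs(kept.posA - ev.posA) <= d and abs(kept.posB - ev.posB) <= d)
            flipped = (kept.chromA == ev.chromB
                       and abs(kept.posA - ev.posB) <= d
                       and abs(kept.posB - ev.posA) <= d)
            if same or flipped:
                kept.n_junctions += 1
                merged = True
                break
        if not merged:
            deduped.append(ev)
    deduped.sort(key=lambda e: (e.type, e.chromA, e.posA, e.chromB, e.posB))
    return deduped


def chimera_check(contig: SeqRecord, junction: int,
                  read_alignments: list[AlignmentRecord],
                  anchor: int = 1_000, max_del_gap: int = 100) -> SVEvent:
    """Count reads spanning [junction-anchor, junction+anchor) contiguously.

    A spanning read must cover the window in a single primary record with
    no deletion run longer than ``max_del_gap`` inside the window.  Zero
    support marks the junction as a chimeric (assembly) join.
    """
    lo, hi = junction - anchor, junction + anchor
    if lo < 0 or hi > len(contig.seq):
        raise ValueError(
            f"anchor window [{lo},{hi}) outside contig {contig.id} "
            f"(length {len(contig.seq)})"
        )
    support = 0
    for r in read_alignments:
        if r.is_secondary or r.is_supplementary or r.target_id != contig.id:
            continue
        if r.t_start > lo or r.t_end < hi:
            continue
        if r.cigar is not None and _max_del_in_window(r, lo, hi) > max_del_gap:
            continue
        support += 1
    return SVEvent(
        "chimera" if support == 0 else "spanned_junction",
        contig.id, contig.id, junction, contig.id, junction,
        read_support=support,
    )


def _max_del_in_window(r: AlignmentRecord, lo: int, hi: int) -> int:
    tpos = r.t_start
    worst = 0
    for op, n in r.cigar:
        if op in "=XD":
            if op == "D" and tpos < hi and tpos + n > lo:
                worst = max(worst, n)
            tpos += n
    return worst


def annotate_junctions(events: list[SVEvent], feature_hits,
                       window: int = 2_000) -> list[SVEvent]:
    """Attach families of feature hits within +-window of each breakpoint."""
    for ev in events:
        fams = set()
        for h in feature_hits:
            for chrom, pos in ((ev.chromA, ev.posA), (ev.chromB, ev.posB)):
                if h.target_id != chrom:
                    continue
                if h.start < pos + window and h.end > pos - window:
                    fams.add(h.family)
        ev.junction_features = sorted(fams)
    return events
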
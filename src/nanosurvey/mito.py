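"""Mitochondrial contig circularization and origin rotation.

An assembler emits a circular genome as a linear contig whose two ends
duplicate the circularization zone.  ``circularize`` detects that terminal
self-overlap by aligning the first 20% of the contig against the last 20%
and trims the suffix copy; ``rotate_to_start`` then rotates (and if needed
reverse-complements) the circle so it begins at the same origin as a
reference mitochondrial sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import align_pair
from .core import SeqRecord, revcomp


@dataclass
class CircularSequence:
    seq: str
    origin_offset: int = 0  # rotation applied by rotate_to_start
    trimmed_overlap_len: int = 0
    circular: bool = True  # False = not circularizable
    flipped: bool = False  # reverse-complemented during rotation

    def __len__(self) -> int:
        return len(self.seq)


def circularize(contig: SeqRecord, min_overlap: int = 1_000,
                min_id: float = 0.95, search_frac: float = 0.20,
                end_slack: int = 100) -> CircularSequence:
    """Trim the duplicated terminal overlap of a circular contig.

    The overlap must anchor a contig prefix (within ``end_slack`` of the
    start) onto a contig suffix (within ``end_slack`` of the end) with
    identity >= min_id over >= min_overlap bases; otherwise the sequence is
    returned unchanged and flagged not circularizable.  Two conflicting
    overlap chains of equal score raise an ambiguity error.
    """
    L = len(contig.seq)
    if L <= 2 * min_overlap:
        raise ValueError("contig shorter than twice the minimum overlap")
    w = max(int(search_frac * L), min_overlap + end_slack)
    w = min(w, L // 2)
    prefix = SeqRecord("prefix", contig.seq[:w])
    suffix = SeqRecord("suffix", contig.seq[L - w:])
    recs = align_pair(prefix, suffix)
    cands = []
    for r in recs:
        if r.strand != "+":
            continue
        span = r.q_end - r.q_start
        if span < min_overlap or r.identity < min_id:
            continue
        if r.q_start > end_slack or r.t_end < w - end_slack:
            continue
        cands.append(r)
    if not cands:
        return CircularSequence(contig.seq, 0, 0, circular=False)
    cands.sort(key=lambda r: (-r.n_match, r.t_start))
    best = cands[0]
    if len(cands) > 1 and cands[1].n_match == best.n_match:
        alt = cands[1]
        if abs(alt.t_start - best.t_start) > end_slack:
            raise ValueError("ambiguous circularization: two equal overlap chains")
    # suffix copy of prefix position 0 starts at (L - w) + t_start - q_start
    cut = L - w + best.t_start - best.q_start
    return CircularSequence(
        contig.seq[:cut], 0, L - cut, circular=True
    )


def rotate_to_start(circular: CircularSequence, reference_mt: SeqRecord,
                    anchor_len: int = 500, min_id: float = 0.80
                    ) -> CircularSequence:
    """Rotate the circle so it starts where the reference starts.

    The reference's first ``anchor_len`` bases are located on the doubled
    circle (both strands); a minus-strand match reverse-complements the
    circle before rotating.
    """
    seq = circular.seq
    L = len(seq)
    anchor = SeqRecord("anchor", reference_mt.seq[:anchor_len])
    doubled = SeqRecord("doubled", seq + seq)
    recs = [r for r in align_pair(anchor, doubled) if r.identity >= min_id]
    if not recs:
        raise ValueError("origin not located in circularized sequence")
    best = max(recs, key=lambda r: r.n_match)
    if best.strand == "+":
        rot = (best.t_start - best.q_start) % L
        rotated = seq[rot:] + seq[:rot]
        flipped = False
    else:
        # anchor end maps to t_start on the forward doubled sequence
        end_fwd = best.t_end + best.q_start
        rc = revcomp(seq)
        rot = (2 * L - end_fwd) % L
        rotated = rc[rot:] + rc[:rot]
        flipped = True
    return CircularSequence(
        rotated, origin_offset=rot,
        trimmed_overlap_len=circular.trimmed_overlap_len,
        circular=circular.circular, flipped=flipped,
    )
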
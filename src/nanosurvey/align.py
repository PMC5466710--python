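"""Anchor-chain pairwise aligner.

Desk-scale stand-in for the external long-read/whole-genome aligners this
toolkit ingests output from (BWA/LAST/NUCmer class).  Strategy:

1. exact shared k-mers (default k=15) between query and target, both strands;
2. colinear chaining by longest-increasing-subsequence, maximizing the number
   of anchored positions with non-crossing order;
3. chains split wherever consecutive anchors imply a gap larger than
   ``max_gap`` on either sequence or a gap-length difference beyond ``band``
   (the contract is to split rather than silently misreport identity);
4. inter-anchor gaps filled by unit-cost global edit-distance alignment
   (edlib), yielding full =/X/I/D CIGARs.

Unit gap costs mirror the gap-open/gap-extend = 1 settings appropriate for
high-error long reads.  Deterministic: ties are broken by smallest t_start,
then q_start.
"""

from __future__ import annotations

from bisect import bisect_left

import edlib
import numpy as np

from .core import AlignmentRecord, Cigar, SeqRecord, revcomp

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """2-bit base codes (A=0,C=1,G=2,T=3); anything else (incl. N) = 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers at every start position; -1 where a k-mer spans N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = codes[i : i + n]
        out = (out << 2) | np.where(window < 4, window, 0).astype(np.int64)
        bad |= window >= 4
    out[bad] = -1
    return out


class KmerIndex:
    """Sorted k-mer table of one target sequence, repeat-capped."""

    def __init__(self, seq: str, k: int = 15, rep_cap: int = 16):
        self.k = k
        km = kmer_ints(encode(seq), k)
        order = np.argsort(km, kind="stable")
        skm = km[order]
        # drop N-containing and over-represented k-mers
        uniq, starts, counts = np.unique(skm, return_index=True, return_counts=True)
        keep_mask = np.ones(len(skm), dtype=bool)
        for u, s, c in zip(uniq, starts, counts):
            if u == -1 or c > rep_cap:
                keep_mask[s : s + c] = False
        self.sorted_kmers = skm[keep_mask]
        self.positions = order[keep_mask]

    def anchors(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(q_positions, t_positions) of exact shared k-mers."""
        lo = np.searchsorted(self.sorted_kmers, query_kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, query_kmers, side="right")
        nhits = hi - lo
        valid = (query_kmers != -1) & (nhits > 0)
        q_idx = np.nonzero(valid)[0]
        if len(q_idx) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        reps = nhits[q_idx]
        qpos = np.repeat(q_idx, reps)
        offs = np.concatenate([np.arange(r) for r in reps])
        tpos = self.positions[np.repeat(lo[q_idx], reps) + offs]
        return qpos.astype(np.int64), tpos.astype(np.int64)


def _best_diagonal_chain(q: np.ndarray, t: np.ndarray, width: int) -> np.ndarray:
    """Best colinear chain, restricted to the densest diagonal band.

    A chain of a near-colinear alignment lives in a narrow band of
    diagonals d = t - q (width ~ accumulated indel drift).  Restricting to
    the densest band before chaining stops chains from zigzagging across
    tandem repeat copies, whose diagonals differ by the unit length.
    Returns indices into q/t in chain order.
    """
    d = t - q
    order = np.argsort(d, kind="stable")
    ds = d[order]
    hi = np.searchsorted(ds, ds + width, side="right")
    counts = hi - np.arange(len(ds))
    i = int(np.argmax(counts))
    band_idx = order[i: hi[i]]
    sub = _lis_chain(q[band_idx], t[band_idx])
    return band_idx[sub]


def _lis_chain(q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Longest chain of anchors strictly increasing in q and t.

    Returns indices into q/t in chain order.  Sorting by (q asc, t desc)
    forbids two anchors at the same query offset in one chain.
    """
    order = np.lexsort((-t, q))
    ts = t[order]
    tails: list[int] = []  # t value ending the best chain of each length
    tail_idx: list[int] = []
    parent = np.full(len(ts), -1, dtype=np.int64)
    for i, tv in enumerate(ts):
        j = bisect_left(tails, tv)
        if j > 0:
            parent[i] = tail_idx[j - 1]
        if j == len(tails):
            tails.append(tv)
            tail_idx.append(i)
        elif tv < tails[j]:
            tails[j] = tv
            tail_idx[j] = i
    chain = []
    i = tail_idx[-1]
    while i != -1:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    return order[np.array(chain, dtype=np.int64)]


def _edlib_cigar_pairs(query: str, target: str) -> list[tuple[str, int]]:
    if not query and not target:
        return []
    if not query:
        return [("D", len(target))]
    if not target:
        return [("I", len(query))]
    res = edlib.align(query, target, mode="NW", task="path")
    pairs = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            pairs.append((ch, int(num)))
            num = ""
    return pairs


def _split_at_gaps(q, t, k, max_gap, band):
    """Split an anchor chain into sub-chains at oversized/banded-out gaps."""
    parts = []
    start = 0
    for i in range(1, len(q)):
        qg = q[i] - (q[i - 1] + k)
        tg = t[i] - (t[i - 1] + k)
        if qg > max_gap or tg > max_gap or abs(qg - tg) > band:
            parts.append((start, i))
            start = i
    parts.append((start, len(q)))
    return parts


def _chain_to_cigar(qseq: str, tseq: str, q: np.ndarray, t: np.ndarray, k: int):
    """Walk a clean (gap-bounded) anchor chain into CIGAR pairs.

    Returns (pairs, q_span_start, q_span_end, t_span_start, t_span_end) in
    the oriented-query frame.
    """
    pairs: list[tuple[str, int]] = []
    q0, t0 = int(q[0]), int(t[0])
    cur_q, cur_t = q0 + k, t0 + k  # exclusive ends covered so far
    pairs.append(("=", k))
    for i in range(1, len(q)):
        qi, ti = int(q[i]), int(t[i])
        qg = qi - cur_q
        tg = ti - cur_t
        if qg < 0 or tg < 0:
            if qg == tg:  # same-diagonal overlapping exact k-mers: pure extension
                ext = qi + k - cur_q
                if ext > 0:
                    pairs.append(("=", ext))
                    cur_q, cur_t = qi + k, ti + k
                continue
            continue  # conflicting overlap; anchor skipped
        pairs.extend(_edlib_cigar_pairs(qseq[cur_q:qi], tseq[cur_t:ti]))
        pairs.append(("=", k))
        cur_q, cur_t = qi + k, ti + k
    return pairs, q0, cur_q, t0, cur_t


def _extend_end(qseq, tseq, band, cap=256):
    """Align a short query overhang onto a target overhang (prefix mode).

    Both strings are given reading *away* from the chain end.  Returns CIGAR
    pairs in away-from-chain order plus consumed target length, or None if
    the extension is poor (>50% edits) or the overhang exceeds the cap.
    """
    if not qseq or not tseq:
        return None
    if len(qseq) > max(band, cap):
        return None
    res = edlib.align(qseq, tseq, mode="SHW", task="path")
    if res["editDistance"] > 0.5 * len(qseq):
        return None
    pairs = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            pairs.append((ch, int(num)))
            num = ""
    t_used = sum(n for op, n in pairs if op in "=XD")
    return pairs, t_used


def align_pair(
    query: SeqRecord,
    target: SeqRecord,
    k: int = 15,
    band: int = 64,
    max_gap: int = 1000,
    rep_cap: int = 16,
    max_chains: int = 60,
    min_span: int | None = None,
    index: "KmerIndex | None" = None,
) -> list[AlignmentRecord]:
    """Align query to target on both strands; one record per clean chain.

    ``min_span`` drops chains anchoring fewer query bases (default: k).
    A prebuilt ``index`` for the target may be supplied to amortize indexing.
    """
    if len(query.seq) < k:
        raise ValueError(f"query {query.id} shorter than k={k}")
    if min_span is None:
        min_span = k
    idx = index if index is not None else KmerIndex(target.seq, k=k, rep_cap=rep_cap)
    k = idx.k
    qlen = len(query.seq)

    strand_data = {}
    for strand in "+-":
        oseq = query.seq if strand == "+" else revcomp(query.seq)
        qk = kmer_ints(encode(oseq), k)
        if len(qk) > 200_000:  # dense anchors: thin for chaining speed
            step = int(np.ceil(len(qk) / 200_000))
            mask = np.arange(len(qk)) % step == 0
            qk = np.where(mask, qk, -1)
        qa, ta = idx.anchors(qk)
        strand_data[strand] = [oseq, qa, ta]

    # diagonal-band width: banding tolerance plus expected indel drift
    diag_width = band + int(0.02 * qlen)
    records: list[AlignmentRecord] = []
    for _ in range(max_chains):
        best = None
        for strand in "+-":
            _, qa, ta = strand_data[strand]
            if len(qa) == 0:
                continue
            chain_idx = _best_diagonal_chain(qa, ta, diag_width)
            if best is None or len(chain_idx) > len(best[1]):
                best = (strand, chain_idx)
        if best is None or len(best[1]) < 2:
            break
        strand, chain_idx = best
        oseq, qa, ta = strand_data[strand]
        cq, ct = qa[chain_idx], ta[chain_idx]
        for s, e in _split_at_gaps(cq, ct, k, max_gap, band):
            sub_q, sub_t = cq[s:e], ct[s:e]
            if len(sub_q) < 2 or int(sub_q[-1]) + k - int(sub_q[0]) < min_span:
                continue
            pairs, oq0, oq1, t0, t1 = _chain_to_cigar(oseq, target.seq, sub_q, sub_t, k)
            # end extension: recover short unanchored tails
            ext = _extend_end(oseq[oq1:], target.seq[t1:], band)
            if ext is not None:
                pairs.extend(ext[0])
                oq1 += sum(n for op, n in ext[0] if op in "=XI")
                t1 += ext[1]
            ext = _extend_end(oseq[:oq0][::-1], target.seq[:t0][::-1], band)
            if ext is not None:
                epairs, t_used = ext
                pairs = [p for p in reversed(epairs)] + pairs
                oq0 -= sum(n for op, n in epairs if op in "=XI")
                t0 -= t_used
            if strand == "+":
                q_start, q_end = oq0, oq1
            else:
                q_start, q_end = qlen - oq1, qlen - oq0
            records.append(
                AlignmentRecord(
                    query_id=query.id, query_len=qlen,
                    q_start=q_start, q_end=q_end, strand=strand,
                    target_id=target.id, target_len=len(target.seq),
                    t_start=t0, t_end=t1,
                    cigar=Cigar.from_pairs(pairs),
                )
            )
        # retire this chain's anchors: same strand, inside its query span
        # and target span — repeat copies elsewhere on the target (e.g.
        # adjacent tandem units) keep their anchors
        q_lo, q_hi = int(cq[0]), int(cq[-1]) + k
        t_lo, t_hi = int(ct.min()), int(ct.max()) + k
        oseq_s, qa_s, ta_s = strand_data[strand]
        keep = ~(
            (qa_s + k > q_lo) & (qa_s < q_hi) & (ta_s >= t_lo) & (ta_s < t_hi)
        )
        strand_data[strand] = [oseq_s, qa_s[keep], ta_s[keep]]
    records.sort(key=lambda r: (r.t_start, r.q_start))
    return records


def align_to_genome(query: SeqRecord, genome: list[SeqRecord], indexes=None, **kw):
    """align_pair against every sequence of a genome; pooled, sorted output."""
    out = []
    for i, chrom in enumerate(genome):
        idx = indexes[i] if indexes is not None else None
        out.extend(align_pair(query, chrom, index=idx, **kw))
    out.sort(key=lambda r: (r.target_id, r.t_start, r.q_start))
    return out
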
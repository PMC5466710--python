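"""Long-read simulation under homopolymer-aware chemistry error models.

The error model has two channels applied to each sampled reference window:

* **homopolymer channel** — every maximal reference run of one base with
  length >= 2 survives exactly with probability ``s(class, length)``; an
  erroneous run changes net length, negative with probability ``rho``
  (deletion-biased chemistries) else positive, with magnitude
  ``Geometric(p_ext)`` (support >= 1).  Deletions are floored so a run keeps
  at least one base.  Length changes are realised as D columns inside the
  run or same-base I columns at its 3' flank, so a profiler classifying
  reference runs recovers ``s`` and ``rho`` exactly up to sampling error.

* **residual channel** — substitutions and non-homopolymer indels applied at
  per-base rates on single-base (non-run) positions only; inserted bases are
  chosen to differ from both neighbours so they are never attributed to an
  adjacent run.  These rates are calibrated (see presets) so the marginal
  per-read error rate, 1 - identity under indel-inclusive accounting,
  matches the chemistry's printed target.

Read starts are uniform over the genome, strands uniform, lengths log-normal
(median per chemistry, capped at 75 kb, truncated at chromosome ends).
Truth alignments are emitted with full =/X/I/D CIGARs; minus-strand reads
are reverse-complemented into the FASTQ record while the truth CIGAR stays
in target-forward orientation (SAM convention).  Identical seeds give
identical output.
"""

from __future__ import annotations

import numpy as np

from .core import (
    OP_DEL,
    OP_INS,
    OP_MATCH,
    OP_MISMATCH,
    AlignmentRecord,
    Cigar,
    SeqRecord,
    revcomp,
)
from .align import encode

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
# base code -> class index: A/T -> 0, C/G -> 1 (N -> 0, never consulted)
_CLASS_OF_BASE = np.array([0, 1, 1, 0, 0], dtype=np.int64)


def rle(codes: np.ndarray):
    """Run-length encode a base-code array -> (starts, lengths, bases)."""
    n = len(codes)
    if n == 0:
        return (np.empty(0, np.int64),) * 2 + (np.empty(0, np.uint8),)
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    np.not_equal(codes[1:], codes[:-1], out=boundary[1:])
    starts = np.nonzero(boundary)[0].astype(np.int64)
    lengths = np.diff(np.append(starts, n))
    return starts, lengths, codes[starts]


class _ChromRLE:
    __slots__ = ("starts", "lengths", "bases", "length")

    def __init__(self, seq: str):
        codes = encode(seq)
        self.starts, self.lengths, self.bases = rle(codes)
        self.length = len(codes)

    def window(self, a: int, b: int):
        """Run lengths/bases clipped to [a, b)."""
        i0 = int(np.searchsorted(self.starts, a, side="right")) - 1
        i1 = int(np.searchsorted(self.starts, b, side="left"))
        s = self.starts[i0:i1]
        e = s + self.lengths[i0:i1]
        lens = np.minimum(e, b) - np.maximum(s, a)
        return lens.astype(np.int64), self.bases[i0:i1]


def _survival_matrix(preset) -> np.ndarray:
    """(2, 8) lookup: class x run length (index clipped to 7)."""
    S = np.ones((2, 8))
    for ci, cls in enumerate(("AT", "CG")):
        for ell in range(2, 8):
            S[ci, ell] = preset.hp_survival[(cls, ell)]
    return S


def synthesize_window(lens, bases, preset, rng, survival=None):
    """Apply the error model to one reference window (given as an RLE).

    Returns (read_codes, cigar) where the read codes are in target-forward
    orientation.
    """
    if survival is None:
        survival = _survival_matrix(preset)
    m = len(lens)
    real = bases < 4
    is_hp = (lens >= 2) & real
    s = survival[_CLASS_OF_BASE[bases], np.minimum(lens, 7)]
    u = rng.random(m)
    hp_err = is_hp & (u >= s)
    is_del = rng.random(m) < preset.hp_deletion_fraction
    mag = rng.geometric(preset.hp_extension, m)
    del_mag = np.minimum(mag, lens - 1)
    hp_del = hp_err & is_del
    hp_ins = hp_err & ~is_del

    is_single = (lens == 1) & real
    v = rng.random(m)
    r_sub, r_del, r_ins = preset.sub_rate, preset.nonhp_del_rate, preset.nonhp_ins_rate
    sub = is_single & (v < r_sub)
    dele = is_single & (v >= r_sub) & (v < r_sub + r_del)
    ins = is_single & (v >= r_sub + r_del) & (v < r_sub + r_del + r_ins)

    # query-consumed length per run
    qlens = lens.copy()
    qlens[hp_del] = (lens - del_mag)[hp_del]
    qlens[hp_ins] = (lens + mag)[hp_ins]
    qlens[dele] = 0
    qlens[ins] = 2

    read = np.repeat(bases, qlens)
    offsets = np.cumsum(qlens) - qlens
    if sub.any():
        nsub = int(sub.sum())
        read[offsets[sub]] = (bases[sub] + 1 + rng.integers(0, 3, nsub)) % 4
    if ins.any():
        b = bases[ins].astype(np.int64)
        prev = np.full(m, -1, dtype=np.int64)
        nxt = np.full(m, -1, dtype=np.int64)
        prev[1:] = bases[:-1]
        nxt[:-1] = bases[1:]
        p, x = prev[ins], nxt[ins]
        c1, c2, c3 = (b + 1) % 4, (b + 2) % 4, (b + 3) % 4
        chosen = np.where(
            (c1 != p) & (c1 != x), c1, np.where((c2 != p) & (c2 != x), c2, c3)
        )
        read[offsets[ins] + 1] = chosen

    # two CIGAR slots per run, interleaved then merged
    opA = np.full(m, OP_MATCH, dtype=np.uint8)
    opA[sub] = OP_MISMATCH
    opA[dele] = OP_DEL
    cntA = lens.copy()
    cntA[hp_del] = (lens - del_mag)[hp_del]
    cntA[dele] = 1
    opB = np.zeros(m, dtype=np.uint8)
    cntB = np.zeros(m, dtype=np.int64)
    opB[hp_del] = OP_DEL
    cntB[hp_del] = del_mag[hp_del]
    opB[hp_ins] = OP_INS
    cntB[hp_ins] = mag[hp_ins]
    opB[ins] = OP_INS
    cntB[ins] = 1

    ops = np.empty(2 * m, dtype=np.uint8)
    counts = np.empty(2 * m, dtype=np.int64)
    ops[0::2], ops[1::2] = opA, opB
    counts[0::2], counts[1::2] = cntA, cntB
    keep = counts > 0
    cigar = Cigar(ops[keep], counts[keep]).merged()
    return read, cigar


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def simulate_reads(
    genome: list[SeqRecord],
    preset,
    coverage: float | None = None,
    seed: int = 0,
    n_reads: int | None = None,
    min_read_len: int = 200,
):
    """Sample reads with errors; returns (reads, truth_alignments).

    Either ``coverage`` (reference bases sampled per genome base) or an
    explicit ``n_reads`` must be given.  Truth alignments carry full CIGARs
    and per-read identity equals the realised error pattern exactly.
    """
    if coverage is None and n_reads is None:
        raise ValueError("either coverage or n_reads is required")
    if coverage is not None and coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    chroms = [_ChromRLE(rec.seq) for rec in genome]
    clens = np.array([c.length for c in chroms], dtype=np.float64)
    cprobs = clens / clens.sum()
    survival = _survival_matrix(preset)
    mu = np.log(preset.read_length_median)
    sigma = preset.read_length_sigma
    qual = 40 if preset.target_error_rate <= 0 else max(
        2, int(round(-10 * np.log10(preset.target_error_rate)))
    )

    reads: list[SeqRecord] = []
    truth: list[AlignmentRecord] = []
    sampled = 0
    target_bases = None if coverage is None else coverage * clens.sum()
    i = 0
    while True:
        if n_reads is not None:
            if len(reads) >= n_reads:
                break
        elif sampled >= target_bases:
            break
        ci = int(rng.choice(len(chroms), p=cprobs))
        chrom = chroms[ci]
        length = int(min(rng.lognormal(mu, sigma), preset.read_cap))
        start = int(rng.integers(0, chrom.length))
        end = min(start + length, chrom.length)
        if end - start < min(min_read_len, chrom.length):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        lens, bases = chrom.window(start, end)
        read_codes, cigar = synthesize_window(lens, bases, preset, rng, survival)
        read_len = len(read_codes)
        if read_len == 0:
            continue
        name = f"read_{i:06d}"
        i += 1
        fwd_seq = _decode(read_codes)
        rec_seq = fwd_seq if strand == "+" else revcomp(fwd_seq)
        quals = np.full(read_len, qual, dtype=np.int32)
        reads.append(SeqRecord(name, rec_seq, quals))
        truth.append(
            AlignmentRecord(
                query_id=name, query_len=read_len,
                q_start=0, q_end=read_len, strand=strand,
                target_id=genome[ci].id, target_len=chrom.length,
                t_start=start, t_end=end, cigar=cigar,
            )
        )
        sampled += end - start
    if not reads:
        raise ValueError("coverage too low: zero reads sampled")
    return reads, truth
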
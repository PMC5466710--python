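"""Core domain types: sequences, pairwise alignments, intervals, CIGAR accounting.

Coordinate convention: 0-based half-open everywhere. SAM (1-based) and GFF
(1-based closed) are converted at the I/O boundary; BED and PAF pass through.

Identity is BLAST-style: matching columns over *all* alignment columns,
indel bases included, so ``error rate = 1 - identity`` covers mismatches,
insertions and deletions alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# CIGAR op codes used internally (uint8 arrays)
OP_MATCH = 0  # '='
OP_MISMATCH = 1  # 'X'
OP_INS = 2  # 'I'  bases present in query, absent in target
OP_DEL = 3  # 'D'  bases present in target, absent in query
_OP_CHARS = np.frombuffer(b"=XID", dtype=np.uint8)
_CHAR_TO_OP = {"=": OP_MATCH, "X": OP_MISMATCH, "I": OP_INS, "D": OP_DEL}

_CONSUMES_QUERY = np.array([1, 1, 1, 0], dtype=np.int64)  # =,X,I
_CONSUMES_TARGET = np.array([1, 1, 0, 1], dtype=np.int64)  # =,X,D


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N, case preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> str:
    """Uppercase and map any character outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq
    return "".join(c if c in VALID_BASES else "N" for c in seq)


@dataclass
class SeqRecord:
    """A named nucleotide sequence with optional per-base Phred qualities."""

    id: str
    seq: str
    quals: np.ndarray | None = None  # Phred scores, ints >= 0

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        self.seq = normalize_seq(self.seq)
        if self.quals is not None:
            self.quals = np.asarray(self.quals, dtype=np.int32)
            if len(self.quals) != len(self.seq):
                raise ValueError(
                    f"{self.id}: quals length {len(self.quals)} != seq length {len(self.seq)}"
                )
            if (self.quals < 0).any():
                raise ValueError(f"{self.id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        q = None if self.quals is None else self.quals[::-1].copy()
        return SeqRecord(self.id, revcomp(self.seq), q)


class Cigar:
    """Run-length encoded alignment path over ops {=, X, I, D}.

    Stored as parallel numpy arrays so megabase-scale paths stay cheap.
    Iterating yields ``(op_char, count)`` pairs.
    """

    __slots__ = ("ops", "counts")

    def __init__(self, ops, counts):
        self.ops = np.asarray(ops, dtype=np.uint8)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.ops.shape != self.counts.shape:
            raise ValueError("ops/counts length mismatch")
        if len(self.counts) and (self.counts <= 0).any():
            raise ValueError("CIGAR counts must be positive")

    @classmethod
    def from_pairs(cls, pairs) -> "Cigar":
        ops = [_CHAR_TO_OP[op] for op, _ in pairs]
        counts = [n for _, n in pairs]
        return cls(ops, counts).merged()

    @classmethod
    def from_string(cls, text: str) -> "Cigar":
        ops, counts, num = [], [], ""
        for ch in text:
            if ch.isdigit():
                num += ch
            else:
                if ch not in _CHAR_TO_OP:
                    raise ValueError(f"unsupported CIGAR op {ch!r}")
                if not num:
                    raise ValueError(f"malformed CIGAR {text!r}")
                ops.append(_CHAR_TO_OP[ch])
                counts.append(int(num))
                num = ""
        if num:
            raise ValueError(f"malformed CIGAR {text!r}")
        return cls(ops, counts).merged()

    def merged(self) -> "Cigar":
        """Merge adjacent runs of the same op."""
        if len(self.ops) < 2:
            return self
        keep = np.empty(len(self.ops), dtype=bool)
        keep[0] = True
        np.not_equal(self.ops[1:], self.ops[:-1], out=keep[1:])
        if keep.all():
            return self
        group = np.cumsum(keep) - 1
        counts = np.zeros(group[-1] + 1, dtype=np.int64)
        np.add.at(counts, group, self.counts)
        return Cigar(self.ops[keep], counts)

    def __iter__(self):
        for op, n in zip(self.ops, self.counts):
            yield chr(_OP_CHARS[op]), int(n)

    def __len__(self) -> int:
        return len(self.ops)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Cigar)
            and np.array_equal(self.ops, other.ops)
            and np.array_equal(self.counts, other.counts)
        )

    def to_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self)

    def op_totals(self) -> np.ndarray:
        """Total column counts per op, indexed [=, X, I, D]."""
        out = np.zeros(4, dtype=np.int64)
        np.add.at(out, self.ops, self.counts)
        return out

    @property
    def query_span(self) -> int:
        return int((self.counts * _CONSUMES_QUERY[self.ops]).sum())

    @property
    def target_span(self) -> int:
        return int((self.counts * _CONSUMES_TARGET[self.ops]).sum())

    def reversed(self) -> "Cigar":
        return Cigar(self.ops[::-1].copy(), self.counts[::-1].copy())


@dataclass
class AlignmentRecord:
    """One pairwise alignment in forward-query coordinates.

    ``q_start``/``q_end`` are always on the forward strand of the query
    (PAF semantics), regardless of ``strand``.  Identity follows the
    indel-inclusive definition (see module docstring).
    """

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    strand: str  # '+' or '-'
    target_id: str
    target_len: int
    t_start: int
    t_end: int
    cigar: Cigar | None = None
    is_secondary: bool = False
    is_supplementary: bool = False
    # identity for coordinate-only records (no cigar); derived otherwise
    _identity_hint: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.q_start <= self.q_end <= self.query_len):
            raise ValueError(
                f"{self.query_id}: query coords [{self.q_start},{self.q_end}) "
                f"outside [0,{self.query_len}]"
            )
        if not (0 <= self.t_start <= self.t_end <= self.target_len):
            raise ValueError(
                f"{self.target_id}: target coords [{self.t_start},{self.t_end}) "
                f"outside [0,{self.target_len}]"
            )
        if self.cigar is not None:
            if self.cigar.query_span != self.q_end - self.q_start:
                raise ValueError(
                    f"{self.query_id}: CIGAR query span {self.cigar.query_span} "
                    f"!= {self.q_end - self.q_start}"
                )
            if self.cigar.target_span != self.t_end - self.t_start:
                raise ValueError(
                    f"{self.query_id}: CIGAR target span {self.cigar.target_span} "
                    f"!= {self.t_end - self.t_start}"
                )

    @property
    def n_match(self) -> int:
        return int(self._totals()[OP_MATCH])

    @property
    def n_mismatch(self) -> int:
        return int(self._totals()[OP_MISMATCH])

    @property
    def n_ins(self) -> int:
        return int(self._totals()[OP_INS])

    @property
    def n_del(self) -> int:
        return int(self._totals()[OP_DEL])

    def _totals(self) -> np.ndarray:
        if self.cigar is None:
            raise ValueError("record has no base-level CIGAR")
        return self.cigar.op_totals()

    @property
    def identity(self) -> float:
        if self.cigar is None or len(self.cigar) == 0:
            if self._identity_hint is not None:
                return self._identity_hint
            raise ValueError("identity undefined: no CIGAR and no identity hint")
        t = self._totals()
        return t[OP_MATCH] / t.sum()

    @property
    def aligned_length(self) -> int:
        """Total alignment columns (the identity denominator)."""
        return int(self._totals().sum())


def cigar_stats(record: AlignmentRecord) -> dict:
    """Match/mismatch/indel counts and identity for a base-level alignment.

    Raises if the record carries no (or an empty) CIGAR.
    """
    if record.cigar is None or len(record.cigar) == 0:
        raise ValueError("cigar_stats requires a non-empty base-level CIGAR")
    t = record.cigar.op_totals()
    total = int(t.sum())
    return {
        "n_match": int(t[OP_MATCH]),
        "n_mismatch": int(t[OP_MISMATCH]),
        "n_ins": int(t[OP_INS]),
        "n_del": int(t[OP_DEL]),
        "identity": t[OP_MATCH] / total,
    }


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a named target."""

    target_id: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.target_id == other.target_id
            and self.start < other.end
            and other.start < self.end
        )
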
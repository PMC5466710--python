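"""Cohort diversity statistics: segregating sites and nucleotide diversity.

Operates on a rectangular haplotype matrix over {A,C,G,T,N,-} with columns
on a common reference frame.  N and '-' entries are treated as uncallable:
a column needs >= 2 callable entries to be assessable, and each isolate
pair is normalized by its own callable-site count (robust to missingness)
before averaging — pi is the mean over unordered pairs of
(pairwise differences / pairwise callable sites).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import SeqRecord

_CALLABLE = np.zeros(256, dtype=bool)
for b in "ACGT":
    _CALLABLE[ord(b)] = True


class HaplotypeMatrix:
    """n_isolates x n_sites matrix of uint8 ASCII codes."""

    def __init__(self, matrix: np.ndarray, ids: list[str] | None = None):
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        self.matrix = matrix
        self.ids = ids or [f"hap_{i}" for i in range(matrix.shape[0])]
        if len(self.ids) != matrix.shape[0]:
            raise ValueError("ids length != number of rows")

    @classmethod
    def from_records(cls, records: list[SeqRecord]) -> "HaplotypeMatrix":
        if not records:
            raise ValueError("no haplotypes")
        lens = {len(r.seq) for r in records}
        if len(lens) != 1:
            raise ValueError("haplotypes must be aligned (equal length)")
        m = np.vstack(
            [np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in records]
        )
        return cls(m, [r.id for r in records])

    @property
    def n_isolates(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def callable_mask(self) -> np.ndarray:
        return _CALLABLE[self.matrix]


def segregating_sites(matrix: HaplotypeMatrix) -> int:
    """Columns with >= 2 distinct alleles among callable entries.

    Columns with < 2 callable entries are skipped.
    """
    m = matrix.matrix
    ok = matrix.callable_mask()
    n_callable = ok.sum(axis=0)
    distinct = np.zeros(m.shape[1], dtype=np.int64)
    for b in "ACGT":
        distinct += ((m == ord(b)) & ok).any(axis=0)
    return int(((distinct >= 2) & (n_callable >= 2)).sum())


def nucleotide_diversity(matrix: HaplotypeMatrix) -> float:
    """Average pairwise per-site divergence (pi) over all unordered pairs."""
    if matrix.n_isolates < 2:
        raise ValueError("pi requires at least two haplotypes")
    m = matrix.matrix
    ok = matrix.callable_mask()
    ratios = []
    for i, j in combinations(range(matrix.n_isolates), 2):
        both = ok[i] & ok[j]
        n_call = int(both.sum())
        if n_call == 0:
            raise ValueError(
                f"pair ({matrix.ids[i]}, {matrix.ids[j]}) has no callable sites"
            )
        diffs = int(((m[i] != m[j]) & both).sum())
        ratios.append(diffs / n_call)
    return float(np.mean(ratios))
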
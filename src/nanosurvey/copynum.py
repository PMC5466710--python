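"""Tandem-gene copy number from read depth ratios and per-read counts.

Two estimators, as used for CUP1/ENA-like loci:

* **depth ratio** — mean per-base depth over the locus divided by the
  median depth of its chromosome, rounded half away from zero.  The region
  mean (rather than median) is deliberate: tandem arrays are short and
  depth-noisy, and the chromosome median already provides the robust
  baseline.
* **read count** — the maximum number of non-overlapping copies of the gene
  unit observed within any single long read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import AlignmentRecord, Interval, SeqRecord
from .features import count_features_in_reads


@dataclass(frozen=True)
class CopyNumberCall:
    gene_id: str
    ratio: float
    copies: int
    method: str  # depth_ratio | read_count


def depth_profile(alignments: list[AlignmentRecord],
                  target_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-position depth from primary alignments (difference-array sweep)."""
    diffs = {tid: np.zeros(L + 1, dtype=np.int64)
             for tid, L in target_lengths.items()}
    for r in alignments:
        if r.is_secondary or r.is_supplementary:
            continue
        if r.target_id not in diffs:
            raise ValueError(f"alignment to undeclared target {r.target_id!r}")
        if r.t_end > target_lengths[r.target_id]:
            raise ValueError(
                f"{r.query_id}: alignment beyond declared length of {r.target_id}"
            )
        diffs[r.target_id][r.t_start] += 1
        diffs[r.target_id][r.t_end] -= 1
    return {tid: np.cumsum(d[:-1]) for tid, d in diffs.items()}


def coverage_copy_number(profile: dict[str, np.ndarray], region: Interval,
                         gene_id: str = "") -> CopyNumberCall:
    """Depth-ratio copy number of a region against its chromosome."""
    if region.target_id not in profile:
        raise ValueError(f"no depth profile for {region.target_id!r}")
    depth = profile[region.target_id]
    if region.end > len(depth):
        raise ValueError("region outside chromosome")
    chrom_median = float(np.median(depth))
    if chrom_median == 0:
        raise ValueError(f"median depth of {region.target_id} is zero")
    ratio = float(depth[region.start: region.end].mean()) / chrom_median
    copies = int(math.floor(ratio + 0.5))  # round half away from zero (ratio >= 0)
    return CopyNumberCall(gene_id, ratio, copies, "depth_ratio")


def tandem_copies_max(gene: SeqRecord, reads: list[SeqRecord],
                      min_id: float = 0.70, min_cov: float = 0.90
                      ) -> CopyNumberCall:
    """Maximum copy count of the gene unit within any single read."""
    per_max, _ = count_features_in_reads([gene], reads, min_id=min_id,
                                         min_cov=min_cov)
    copies = per_max[gene.id]
    return CopyNumberCall(gene.id, float(copies), copies, "read_count")
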
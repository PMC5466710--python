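"""Assembly contiguity and completeness metrics.

Contiguity follows the standard self-referential definitions: Nx is the
length of the contig at which the descending cumulative length first reaches
x% of the assembly's own cumulative size (not the reference size), Lx its
1-based rank.  Genome fraction is the percent of reference bases covered by
at least one retained assembly-to-reference alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlignmentRecord


@dataclass(frozen=True)
class ContiguityReport:
    n_contigs: int
    cumulative_size: int
    max_size: int
    N50: int
    N90: int
    L50: int
    L90: int


def contiguity_stats(lengths) -> ContiguityReport:
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise ValueError("no contig lengths")
    if min(lengths) <= 0:
        raise ValueError("contig lengths must be positive")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    nx = {}
    lx = {}
    for frac, key in ((0.5, 50), (0.9, 90)):
        acc = 0
        for rank, ell in enumerate(desc, 1):
            acc += ell
            if acc >= frac * total:
                nx[key], lx[key] = ell, rank
                break
    return ContiguityReport(
        n_contigs=len(desc), cumulative_size=total, max_size=desc[0],
        N50=nx[50], N90=nx[90], L50=lx[50], L90=lx[90],
    )


def genome_fraction(reference_lengths: dict[str, int],
                    alignments: list[AlignmentRecord],
                    min_id: float = 0.80) -> float:
    """Percent of reference bases covered by alignments with identity >= min_id."""
    by_target: dict[str, list[tuple[int, int]]] = {}
    for r in alignments:
        try:
            ident = r.identity
        except ValueError:
            ident = None
        if ident is not None and ident < min_id:
            continue
        by_target.setdefault(r.target_id, []).append((r.t_start, r.t_end))
    covered = 0
    for tid, ivals in by_target.items():
        if tid not in reference_lengths:
            raise ValueError(f"alignment to unknown reference {tid!r}")
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    total = sum(reference_lengths.values())
    return 100.0 * covered / total


@dataclass(frozen=True)
class CompletenessReport:
    genes_complete: int
    genes_partial: int
    genes_indel_free: int
    genes_missing: int


def gene_completeness(gene_hits, gene_ids) -> CompletenessReport:
    """Classify each library gene from its assembly hits.

    ``gene_hits`` come from the feature mapper with partial hits kept:
    *complete* = >= 1 retained hit (identity/coverage thresholds met);
    *partial* = no retained hit but >= 1 hit covering >= half the gene;
    *indel-free* = >= 1 retained hit whose CIGAR has no I/D columns.
    Each gene counts once, in its best category.
    """
    gene_ids = list(gene_ids)
    known = set(gene_ids)
    status: dict[str, str] = {g: "missing" for g in gene_ids}
    for h in gene_hits:
        g = h.feature_id
        if g not in known:
            raise ValueError(f"hit references unknown gene {g!r}")
        if h.retained:
            indel_free = False
            if h.cigar is not None:
                t = h.cigar.op_totals()
                indel_free = t[2] == 0 and t[3] == 0
            if indel_free:
                status[g] = "indel_free"
            elif status[g] != "indel_free":
                status[g] = "complete"
        elif h.feature_coverage >= 0.5 and status[g] == "missing":
            status[g] = "partial"
    vals = list(status.values())
    complete = sum(s in ("complete", "indel_free") for s in vals)
    return CompletenessReport(
        genes_complete=complete,
        genes_partial=sum(s == "partial" for s in vals),
        genes_indel_free=sum(s == "indel_free" for s in vals),
        genes_missing=sum(s == "missing" for s in vals),
    )
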
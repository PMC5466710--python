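"""Feature mapping and transposable-element cartography.

Locates library features (genes, Ty-like TE families, centromeres,
telomeric repeats) in assemblies and long reads with the standard
retention rule — identity strictly greater than 0.80 over at least 0.90 of
the feature length (relaxed to 0.70 identity in raw reads) — then projects
insertion sites onto a common reference and clusters them into cross-
isolate hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import KmerIndex, align_pair
from .core import AlignmentRecord, Cigar, SeqRecord


@dataclass
class FeatureHit:
    feature_id: str
    family: str
    target_id: str
    start: int
    end: int
    strand: str
    identity: float
    feature_coverage: float
    cigar: Cigar | None = None
    retained: bool = True

    def __len__(self) -> int:
        return self.end - self.start


def _hits_for_feature(feature: SeqRecord, family: str, target: SeqRecord,
                      index: KmerIndex, min_id: float, min_cov: float,
                      partial_cov: float):
    flen = len(feature.seq)
    hits = []
    try:
        recs = align_pair(feature, target, index=index)
    except ValueError:
        return hits
    for r in recs:
        cov = (r.q_end - r.q_start) / flen
        if cov < partial_cov:
            continue
        retained = r.identity > min_id and cov >= min_cov
        hits.append(
            FeatureHit(
                feature_id=feature.id, family=family,
                target_id=target.id, start=r.t_start, end=r.t_end,
                strand=r.strand, identity=r.identity,
                feature_coverage=cov, cigar=r.cigar, retained=retained,
            )
        )
    return hits


def _collapse_same_family(hits: list[FeatureHit]) -> list[FeatureHit]:
    """Among retained hits of one family on one target, keep the best-identity
    hit of each overlapping group."""
    out = []
    by_key: dict[tuple[str, str], list[FeatureHit]] = {}
    for h in hits:
        if not h.retained:
            out.append(h)
            continue
        by_key.setdefault((h.family, h.target_id), []).append(h)
    for group in by_key.values():
        group.sort(key=lambda h: (h.start, h.end))
        kept: list[FeatureHit] = []
        for h in group:
            if kept and h.start < kept[-1].end:  # overlap with previous kept
                if h.identity > kept[-1].identity:
                    kept[-1] = h
            else:
                kept.append(h)
        out.extend(kept)
    return out


def map_features(library: list[SeqRecord], targets: list[SeqRecord],
                 min_id: float = 0.80, min_cov: float = 0.90,
                 partial_cov: float = 0.50,
                 families: dict[str, str] | None = None,
                 k: int = 15) -> list[FeatureHit]:
    """Locate every library feature on every target sequence (both strands).

    Hits with identity > min_id over >= min_cov of the feature length are
    flagged ``retained``; hits covering >= partial_cov are kept unflagged so
    completeness metrics can see partial genes.  Overlapping retained hits
    of the same family collapse to the best-identity one.
    """
    if not library:
        raise ValueError("empty feature library")
    fam = families or {}
    hits: list[FeatureHit] = []
    for target in targets:
        index = KmerIndex(target.seq, k=k)
        for feature in library:
            hits.extend(
                _hits_for_feature(feature, fam.get(feature.id, feature.id),
                                  target, index, min_id, min_cov, partial_cov)
            )
    hits = _collapse_same_family(hits)
    hits.sort(key=lambda h: (h.target_id, h.start, h.end, h.feature_id))
    return hits


def family_counts(hits: list[FeatureHit]) -> dict[str, int]:
    """Retained hits per family (the per-isolate TE content table)."""
    out: dict[str, int] = {}
    for h in hits:
        if h.retained:
            out[h.family] = out.get(h.family, 0) + 1
    return out


def _dedup_reciprocal(hits: list[FeatureHit], frac: float = 0.5):
    """Drop hits overlapping a better hit by > frac reciprocally."""
    hits = sorted(hits, key=lambda h: (-h.identity, h.start))
    kept: list[FeatureHit] = []
    for h in hits:
        dup = False
        for other in kept:
            ov = min(h.end, other.end) - max(h.start, other.start)
            if ov > 0 and ov > frac * len(h) and ov > frac * len(other):
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def count_features_in_reads(library: list[SeqRecord], reads: list[SeqRecord],
                            min_id: float = 0.70, min_cov: float = 0.90,
                            k: int = 11):
    """Per-read feature hit counts with the read-relaxed identity threshold.

    Returns (per_feature_max, per_read_counts) where per_read_counts maps
    read id -> {feature id: count}.  Overlapping hits of one feature in one
    read (> 50% reciprocal overlap, e.g. split alignments of one tandem
    copy) are deduplicated.
    """
    per_read: dict[str, dict[str, int]] = {}
    per_max: dict[str, int] = {f.id: 0 for f in library}
    for read in reads:
        index = KmerIndex(read.seq, k=k)
        counts: dict[str, int] = {}
        for feature in library:
            hits = _hits_for_feature(feature, feature.id, read, index,
                                     min_id, min_cov, partial_cov=min_cov)
            hits = [h for h in hits if h.retained]
            hits = _dedup_reciprocal(hits)
            counts[feature.id] = len(hits)
            per_max[feature.id] = max(per_max[feature.id], len(hits))
        per_read[read.id] = counts
    return per_max, per_read


# ---------------------------------------------------------------------------
# cross-isolate cartography


@dataclass(frozen=True)
class InsertionSite:
    ref_chrom: str
    position: int  # site midpoint on the reference
    family: str
    isolate: str


@dataclass
class Hotspot:
    ref_chrom: str
    start: int
    end: int
    families: list[str]
    isolates: set[str] = field(default_factory=set)

    @property
    def n_isolates(self) -> int:
        return len(self.isolates)


def project_to_reference(hit: FeatureHit, segments, isolate: str
                         ) -> InsertionSite | None:
    """Lift a hit's midpoint through filtered assembly-to-reference segments.

    ``segments`` are near-1-to-1 alignment segments of the hit's contig
    (query interval -> target interval, strand); the midpoint is lifted by
    linear interpolation within the containing segment.  Returns None when
    the hit falls in an unaligned region."""
    mid = (hit.start + hit.end) // 2
    for seg in segments:
        if seg.contig_id != hit.target_id or not (seg.q_start <= mid < seg.q_end):
            continue
        frac = (mid - seg.q_start) / (seg.q_end - seg.q_start)
        if seg.strand == "+":
            pos = seg.t_start + frac * (seg.t_end - seg.t_start)
        else:
            pos = seg.t_end - frac * (seg.t_end - seg.t_start)
        return InsertionSite(seg.target_id, int(round(pos)), hit.family, isolate)
    return None


def find_hotspots(sites: list[InsertionSite], window: int = 1000,
                  min_isolates: int = 7) -> list[Hotspot]:
    """Single-linkage clustering of insertion sites per chromosome.

    Sites within ``window`` of the previous site join the cluster; clusters
    supported by >= min_isolates distinct isolates are hotspots.  Output is
    invariant to the input order of sites.
    """
    by_chrom: dict[str, list[InsertionSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.ref_chrom, []).append(s)
    hotspots = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(by_chrom[chrom],
                             key=lambda s: (s.position, s.isolate, s.family))
        cluster: list[InsertionSite] = []
        for s in chrom_sites + [None]:
            if s is not None and (not cluster or s.position - cluster[-1].position <= window):
                cluster.append(s)
                continue
            if cluster:
                isolates = {c.isolate for c in cluster}
                if len(isolates) >= min_isolates:
                    hotspots.append(
                        Hotspot(
                            ref_chrom=chrom,
                            start=cluster[0].position,
                            end=cluster[-1].position + 1,
                            families=sorted({c.family for c in cluster}),
                            isolates=isolates,
                        )
                    )
            cluster = [s] if s is not None else []
    return hotspots
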
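"""Synthetic genome forge: yeast-like references, derived isolates, assemblies.

Generates, deterministically per seed:

* a multi-chromosome reference with planted features — telomeric repeat
  arrays (~100 bp) at both chromosome ends, one 120 bp centromere per
  chromosome, LTR-retrotransposon-like elements (five families, ~5.8 kb),
  an rDNA-like tandem cluster, tandem gene arrays (CUP1/ENA-like) and
  single-copy genes — with truth coordinates for every instance;
* derived isolate genomes with planted reciprocal translocations,
  inversions, tandem copy-number changes, TE insertions/deletions and
  background SNPs, plus a piecewise isolate-to-reference coordinate map;
* a haplotype cohort drawn from a shared pool of segregating sites whose
  expected average pairwise diversity equals the requested density;
* defective "assemblies": fragmentation at the rDNA cluster, consensus
  homopolymer deletions, and chimeric contigs fused at shared TE copies.

Default sizes are desk-scale (three chromosomes totalling 550 kb) so every
downstream stage runs in seconds while keeping the feature inventory of the
real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import AlignmentRecord, SeqRecord, revcomp
from .seqio import Feature

_BASES = "ACGT"
TELOMERE_UNIT = "TGTGGGTGTGGTG"  # fixed degenerate-free repeat unit


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


@dataclass(frozen=True)
class ForgeConfig:
    """Reference-genome recipe; all lengths in bases."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (220_000, 180_000, 150_000)
    te_families: tuple[tuple[str, int], ...] = (
        ("Ty1", 4), ("Ty2", 3), ("Ty3", 2), ("Ty4", 2), ("Ty5", 1)
    )
    te_length: int = 5_800
    centromere_length: int = 120
    telomere_length: int = 100
    rdna_unit_length: int = 2_000
    rdna_copies: int = 10
    rdna_chrom: int = -1  # index into chromosomes; -1 = last
    tandem_arrays: tuple[tuple[str, int, int], ...] = (
        ("CUP1", 1_500, 7), ("ENA1", 2_000, 4)
    )
    n_genes: int = 12
    gene_length: int = 1_200
    feature_margin: int = 500

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)


@dataclass
class Reference:
    genome: list[SeqRecord]
    features: list[Feature]
    library: dict[str, SeqRecord]  # family/gene id -> consensus sequence
    config: ForgeConfig

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


def _place(rng, occupied: list[tuple[int, int]], flen: int, lo: int, hi: int,
           margin: int, chrom_name: str, tries: int = 400) -> int:
    """Pick a start for a feature of length flen avoiding occupied slots."""
    if hi - flen <= lo:
        raise ValueError(f"features do not fit on {chrom_name}")
    for _ in range(tries):
        s = int(rng.integers(lo, hi - flen))
        e = s + flen
        if all(e + margin <= os or oe + margin <= s for os, oe in occupied):
            occupied.append((s, e))
            return s
    raise ValueError(f"features do not fit on {chrom_name} (placement failed)")


def build_reference(config: ForgeConfig) -> Reference:
    """Forge the reference genome and its truth annotation."""
    rng = np.random.default_rng(config.seed)
    lib: dict[str, SeqRecord] = {}
    for fam, _ in config.te_families:
        lib[fam] = SeqRecord(fam, _random_seq(rng, config.te_length))
    lib["CEN"] = SeqRecord("CEN", _random_seq(rng, config.centromere_length))
    lib["TEL"] = SeqRecord("TEL", TELOMERE_UNIT)
    lib["RDN"] = SeqRecord("RDN", _random_seq(rng, config.rdna_unit_length))
    for gid, unit_len, _ in config.tandem_arrays:
        lib[gid] = SeqRecord(gid, _random_seq(rng, unit_len))
    for gi in range(config.n_genes):
        gid = f"GENE{gi + 1:02d}"
        lib[gid] = SeqRecord(gid, _random_seq(rng, config.gene_length))

    n = config.n_chrom
    chrom_names = [f"chr{i + 1}" for i in range(n)]
    seqs = [np.frombuffer(_random_seq(rng, L).encode(), dtype=np.uint8).copy()
            for L in config.chrom_lengths]
    features: list[Feature] = []
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]

    tel = (TELOMERE_UNIT * (config.telomere_length // len(TELOMERE_UNIT) + 1))
    tel = tel[: config.telomere_length]
    for ci, (name, L) in enumerate(zip(chrom_names, config.chrom_lengths)):
        seqs[ci][: len(tel)] = np.frombuffer(tel.encode(), dtype=np.uint8)
        rc = revcomp(tel)
        seqs[ci][L - len(tel):] = np.frombuffer(rc.encode(), dtype=np.uint8)
        occupied[ci] += [(0, len(tel)), (L - len(tel), L)]
        features.append(Feature(f"TEL{ci+1}L", "telomere", "TEL", name, 0, len(tel), "+"))
        features.append(
            Feature(f"TEL{ci+1}R", "telomere", "TEL", name, L - len(tel), L, "-")
        )
        mid = L // 2
        cen = lib["CEN"].seq
        seqs[ci][mid: mid + len(cen)] = np.frombuffer(cen.encode(), dtype=np.uint8)
        occupied[ci].append((mid, mid + len(cen)))
        features.append(
            Feature(f"CEN{ci+1}", "centromere", "CEN", name, mid, mid + len(cen), "+")
        )

    def paste(ci: int, fid: str, kind: str, family: str, seq: str, strand: str = "+"):
        L = config.chrom_lengths[ci]
        lo = config.telomere_length + config.feature_margin
        s = _place(rng, occupied[ci], len(seq), lo, L - lo, config.feature_margin,
                   chrom_names[ci])
        placed = seq if strand == "+" else revcomp(seq)
        seqs[ci][s: s + len(seq)] = np.frombuffer(placed.encode(), dtype=np.uint8)
        features.append(Feature(fid, kind, family, chrom_names[ci], s, s + len(seq), strand))
        return s

    # rDNA-like tandem cluster on one chromosome
    rci = config.rdna_chrom % n
    rdna_seq = lib["RDN"].seq * config.rdna_copies
    s = paste(rci, "RDN_cluster", "rDNA", "RDN", rdna_seq)
    for k in range(config.rdna_copies):
        u = config.rdna_unit_length
        features.append(
            Feature(f"RDN_{k+1}", "rDNA_unit", "RDN", chrom_names[rci],
                    s + k * u, s + (k + 1) * u, "+")
        )

    for gid, unit_len, copies in config.tandem_arrays:
        ci = int(rng.integers(0, n))
        s = paste(ci, f"{gid}_array", "tandem_array", gid, lib[gid].seq * copies)
        for k in range(copies):
            features.append(
                Feature(f"{gid}_{k+1}", "tandem_gene", gid, chrom_names[ci],
                        s + k * unit_len, s + (k + 1) * unit_len, "+")
            )

    for fam, count in config.te_families:
        for k in range(count):
            ci = int(rng.integers(0, n))
            strand = "+" if rng.random() < 0.5 else "-"
            paste(ci, f"{fam}_{k+1}", "TE", fam, lib[fam].seq, strand)

    for gi in range(config.n_genes):
        gid = f"GENE{gi + 1:02d}"
        ci = int(rng.integers(0, n))
        strand = "+" if rng.random() < 0.5 else "-"
        paste(ci, gid, "gene", gid, lib[gid].seq, strand)

    genome = [
        SeqRecord(name, seqs[ci].tobytes().decode())
        for ci, name in enumerate(chrom_names)
    ]
    features.sort(key=lambda f: (f.target_id, f.start, f.end))
    return Reference(genome, features, lib, config)


# ---------------------------------------------------------------------------
# isolates


@dataclass(frozen=True)
class Piece:
    """One segment of a derived chromosome, mapped back to the reference.

    ``ref_chrom is None`` marks novel (inserted) sequence carried in
    ``novel_seq``.
    """

    ref_chrom: str | None
    start: int
    end: int
    strand: str = "+"
    novel_seq: str | None = None

    def __len__(self) -> int:
        return self.end - self.start if self.ref_chrom is not None else len(self.novel_seq)


@dataclass(frozen=True)
class VariantPlan:
    translocations: tuple = ()  # (chromA, posA, chromB, posB, reciprocal, at_TE)
    inversions: tuple = ()  # (chrom, start, end)
    tandem_cnv: tuple = ()  # (gene_id, new_copies)
    te_insertions: tuple = ()  # (family, chrom, pos)
    te_deletions: tuple = ()  # feature ids of TE copies to remove
    snp_density: float = 0.0


@dataclass
class SVTruth:
    type: str  # translocation | inversion | cnv | te_insertion | te_deletion
    chromA: str
    posA: int
    chromB: str | None = None
    posB: int | None = None
    at_te: bool = False
    detail: str = ""


@dataclass
class Isolate:
    name: str
    genome: list[SeqRecord]
    pieces: dict[str, list[Piece]]  # isolate chromosome -> ordered pieces
    sv_truth: list[SVTruth]
    snps: list[tuple[str, int, str, str]]  # (iso chrom, pos, ref base, alt)
    features: list[Feature]  # reference features lifted to isolate coords

    def project(self, chrom: str, a: int, b: int):
        """Map isolate interval [a, b) to reference portions
        (ref_chrom, start, end, strand); novel pieces are skipped."""
        out = []
        off = 0
        for p in self.pieces[chrom]:
            plen = len(p)
            ps, pe = off, off + plen
            off = pe
            lo, hi = max(a, ps), min(b, pe)
            if lo >= hi or p.ref_chrom is None:
                continue
            if p.strand == "+":
                out.append((p.ref_chrom, p.start + (lo - ps), p.start + (hi - ps), "+"))
            else:
                out.append((p.ref_chrom, p.end - (hi - ps), p.end - (lo - ps), "-"))
        return out


def _split_pieces(pieces: list[Piece], ref_chrom: str, pos: int) -> int:
    """Split the piece containing reference position pos; returns the index
    of the first piece at/after the cut.  Only valid on '+' strand pieces."""
    for i, p in enumerate(pieces):
        if p.ref_chrom != ref_chrom or not (p.start <= pos < p.end):
            continue
        if p.strand != "+":
            raise ValueError("breakpoint inside another planted event")
        if pos == p.start:
            return i
        out = [Piece(ref_chrom, p.start, pos), Piece(ref_chrom, pos, p.end)]
        pieces[i: i + 1] = out
        return i + 1
    raise ValueError(f"position {ref_chrom}:{pos} not found in any unmodified piece")


def _materialize(pieces: list[Piece], ref_seqs: dict[str, str]) -> str:
    parts = []
    for p in pieces:
        if p.ref_chrom is None:
            parts.append(p.novel_seq)
        else:
            s = ref_seqs[p.ref_chrom][p.start: p.end]
            parts.append(s if p.strand == "+" else revcomp(s))
    return "".join(parts)


def choose_te_breakpoint(reference: Reference, chrom: str, rng) -> tuple[int, str]:
    """A breakpoint inside a TE copy on the given chromosome -> (pos, family)."""
    tes = [f for f in reference.features
           if f.kind == "TE" and f.target_id == chrom]
    if not tes:
        raise ValueError(f"no TE copy on {chrom}")
    te = tes[int(rng.integers(0, len(tes)))]
    return (te.start + len(te) // 2, te.family)


def derive_isolate(reference: Reference, plan: VariantPlan, seed: int,
                   name: str = "isolate") -> Isolate:
    """Apply a variant plan to the reference, tracking full truth."""
    rng = np.random.default_rng(seed)
    ref_seqs = {r.id: r.seq for r in reference.genome}
    pieces: dict[str, list[Piece]] = {
        r.id: [Piece(r.id, 0, len(r.seq))] for r in reference.genome
    }
    truth: list[SVTruth] = []

    for chrom, s, e in plan.inversions:
        i = _split_pieces(pieces[chrom], chrom, s)
        j = _split_pieces(pieces[chrom], chrom, e)
        seg = pieces[chrom][i:j]
        inv = [Piece(p.ref_chrom, p.start, p.end,
                     "-" if p.strand == "+" else "+", p.novel_seq)
               for p in reversed(seg)]
        pieces[chrom][i:j] = inv
        truth.append(SVTruth("inversion", chrom, s, chrom, e))

    for gid, new_copies in plan.tandem_cnv:
        arr = next(f for f in reference.features
                   if f.kind == "tandem_array" and f.family == gid)
        unit = next(f for f in reference.features
                    if f.kind == "tandem_gene" and f.family == gid)
        i = _split_pieces(pieces[arr.target_id], arr.target_id, arr.start)
        j = _split_pieces(pieces[arr.target_id], arr.target_id, arr.end)
        new = [Piece(arr.target_id, unit.start, unit.end)
               for _ in range(new_copies)]
        pieces[arr.target_id][i:j] = new
        truth.append(SVTruth("cnv", arr.target_id, arr.start,
                             detail=f"{gid}:{new_copies}"))

    for fam, chrom, pos in plan.te_insertions:
        i = _split_pieces(pieces[chrom], chrom, pos)
        pieces[chrom].insert(
            i, Piece(None, 0, 0, "+", reference.library[fam].seq)
        )
        truth.append(SVTruth("te_insertion", chrom, pos, detail=fam))

    for fid in plan.te_deletions:
        te = next(f for f in reference.features if f.id == fid)
        i = _split_pieces(pieces[te.target_id], te.target_id, te.start)
        j = _split_pieces(pieces[te.target_id], te.target_id, te.end)
        del pieces[te.target_id][i:j]
        truth.append(SVTruth("te_deletion", te.target_id, te.start, detail=fid))

    for chromA, posA, chromB, posB, reciprocal, at_te in plan.translocations:
        ia = _split_pieces(pieces[chromA], chromA, posA)
        ib = _split_pieces(pieces[chromB], chromB, posB)
        headA, tailA = pieces[chromA][:ia], pieces[chromA][ia:]
        headB, tailB = pieces[chromB][:ib], pieces[chromB][ib:]
        pieces[chromA] = headA + tailB
        pieces[chromB] = headB + tailA if reciprocal else headB
        truth.append(SVTruth("translocation", chromA, posA, chromB, posB, at_te))

    # materialize, lift features, then apply background SNPs
    genome: list[SeqRecord] = []
    snps: list[tuple[str, int, str, str]] = []
    lifted: list[Feature] = []
    for chrom, plist in pieces.items():
        seq = _materialize(plist, ref_seqs)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        if plan.snp_density > 0:
            hits = np.nonzero(rng.random(len(codes)) < plan.snp_density)[0]
            for pos in hits:
                old = chr(codes[pos])
                if old == "N":
                    continue
                alt = _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
                codes[pos] = ord(alt)
                snps.append((chrom, int(pos), old, alt))
        genome.append(SeqRecord(chrom, codes.tobytes().decode()))
        off = 0
        for p in plist:
            plen = len(p)
            if p.ref_chrom is not None:
                for f in reference.features:
                    if (f.target_id == p.ref_chrom and f.start >= p.start
                            and f.end <= p.end):
                        if p.strand == "+":
                            s = off + (f.start - p.start)
                            strand = f.strand
                        else:
                            s = off + (p.end - f.end)
                            strand = "-" if f.strand == "+" else "+"
                        lifted.append(replace(f, target_id=chrom, start=s,
                                              end=s + len(f), strand=strand))
            off += plen
    lifted.sort(key=lambda f: (f.target_id, f.start))
    return Isolate(name, genome, pieces, truth, snps, lifted)


# ---------------------------------------------------------------------------
# haplotype cohorts


def forge_cohort(reference: Reference, n_isolates: int, snp_density: float,
                 seed: int):
    """Draw a haplotype cohort from a shared pool of segregating sites.

    Sites are planted at density ``snp_density * 3(n-1)/(n+1)`` with derived
    allele counts uniform on 1..n-1, so the expected average pairwise
    diversity of the cohort equals ``snp_density`` (each site with allele
    count k contributes k(n-k)/C(n,2) pairwise differences).
    """
    from .popgen import HaplotypeMatrix

    if n_isolates < 2:
        raise ValueError("need at least two haplotypes")
    rng = np.random.default_rng(seed)
    n = n_isolates
    ref = "".join(r.seq for r in reference.genome)
    codes = np.frombuffer(ref.encode(), dtype=np.uint8)
    L = len(codes)
    site_density = snp_density * 3 * (n - 1) / (n + 1)
    sites = np.nonzero(rng.random(L) < site_density)[0]
    matrix = np.tile(codes, (n, 1))
    enc = {b: ord(b) for b in _BASES}
    for pos in sites:
        old = chr(codes[pos])
        if old == "N":
            continue
        alt = _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
        k = int(rng.integers(1, n))
        carriers = rng.choice(n, size=k, replace=False)
        matrix[carriers, pos] = enc[alt]
    ids = [f"iso_{i:02d}" for i in range(n)]
    return HaplotypeMatrix(matrix, ids), sites


# ---------------------------------------------------------------------------
# defective assemblies


@dataclass(frozen=True)
class DefectPlan:
    fragment_at_rdna: bool = False
    consensus_hp_del_rate: float = 0.0  # per run of length >= 4
    chimeric_joins: tuple = ()  # (chromA, chromB) fused at a shared TE family


@dataclass
class ChimeraJoin:
    contig_id: str
    junction: int  # contig coordinate of the fusion point
    chromA: str
    chromB: str
    family: str


@dataclass
class Assembly:
    contigs: list[SeqRecord]
    chimeras: list[ChimeraJoin]
    breaks: list[tuple[str, str, int]]  # (contig_id, source chrom, position)
    hp_deletions: list[tuple[str, int, int]]  # (contig_id, run start, run len)


def make_assembly(genome: list[SeqRecord], plan: DefectPlan, seed: int = 0,
                  features: list[Feature] | None = None) -> Assembly:
    """Turn a (reference or isolate) genome into contigs with planted defects."""
    from .simulate import rle
    from .align import encode

    rng = np.random.default_rng(seed)
    feats = features or []
    working: list[tuple[str, str, str]] = [
        (f"ctg_{r.id}", r.seq, r.id) for r in genome
    ]
    chimeras: list[ChimeraJoin] = []
    breaks: list[tuple[str, str, int]] = []

    for chromA, chromB in plan.chimeric_joins:
        byc = {src: i for i, (_, _, src) in enumerate(working)}
        if chromA not in byc or chromB not in byc:
            raise ValueError(f"chromosome {chromA}/{chromB} unavailable for join")
        tesA = {f.family: f for f in feats if f.kind == "TE" and f.target_id == chromA}
        tesB = {f.family: f for f in feats if f.kind == "TE" and f.target_id == chromB}
        shared = sorted(set(tesA) & set(tesB))
        if not shared:
            raise ValueError(
                f"chimeric join {chromA}-{chromB}: no shared TE family"
            )
        fam = shared[0]
        ia, ib = byc[chromA], byc[chromB]
        seqA, seqB = working[ia][1], working[ib][1]
        teA, teB = tesA[fam], tesB[fam]
        fused = seqA[: teA.end] + seqB[teB.end:]
        cid = f"ctg_chimera_{chromA}_{chromB}"
        for i in sorted((ia, ib), reverse=True):
            del working[i]
        working.append((cid, fused, chromA))
        working.append((f"ctg_{chromA}_rest", seqA[teA.end:], chromA))
        working.append((f"ctg_{chromB}_head", seqB[: teB.end], chromB))
        chimeras.append(ChimeraJoin(cid, teA.end, chromA, chromB, fam))

    if plan.fragment_at_rdna:
        cluster = next((f for f in feats if f.id == "RDN_cluster"), None)
        if cluster is None:
            raise ValueError("fragment_at_rdna requires an rDNA cluster feature")
        byc = {src: i for i, (_, _, src) in enumerate(working)}
        i = byc[cluster.target_id]
        cid, seq, src = working[i]
        mid = (cluster.start + cluster.end) // 2
        working[i: i + 1] = [
            (f"{cid}_a", seq[:mid], src), (f"{cid}_b", seq[mid:], src)
        ]
        breaks.append((cid, src, mid))

    contigs: list[SeqRecord] = []
    hp_dels: list[tuple[str, int, int]] = []
    for cid, seq, _src in working:
        if not seq:
            continue
        if plan.consensus_hp_del_rate > 0:
            starts, lens, bases = rle(encode(seq))
            target = (lens >= 4) & (bases < 4)
            hit = target & (rng.random(len(lens)) < plan.consensus_hp_del_rate)
            if hit.any():
                codes = np.frombuffer(seq.encode(), dtype=np.uint8)
                drop = np.ones(len(codes), dtype=bool)
                for s, l in zip(starts[hit], lens[hit]):
                    drop[s] = False
                    hp_dels.append((cid, int(s), int(l)))
                seq = codes[drop].tobytes().decode()
        contigs.append(SeqRecord(cid, seq))
    return Assembly(contigs, chimeras, breaks, hp_dels)


# ---------------------------------------------------------------------------
# auxiliary samplers


def sample_circular_contig(circle: str, rotation: int, overlap_len: int,
                           noise_rate: float = 0.0, seed: int = 0,
                           name: str = "mt_contig") -> SeqRecord:
    """Linearize a circular sequence the way an assembler would emit it:
    rotated by ``rotation`` and with the first ``overlap_len`` bases
    duplicated at the end (the circularization zone), plus optional
    substitution noise."""
    L = len(circle)
    rotation %= L
    lin = circle[rotation:] + circle[:rotation]
    seq = lin + lin[:overlap_len]
    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(codes)) < noise_rate)[0]
        for pos in hits:
            old = chr(codes[pos])
            if old in _BASES:
                codes[pos] = ord(
                    _BASES[(_BASES.index(old) + 1 + int(rng.integers(0, 3))) % 4]
                )
        seq = codes.tobytes().decode()
    return SeqRecord(name, seq)


def simulate_depth_alignments(isolate: Isolate, coverage: float,
                              read_len: int = 250, seed: int = 0
                              ) -> list[AlignmentRecord]:
    """Short-read-like coordinate alignments of isolate reads onto the
    reference, projected through the isolate's truth coordinate map.

    Each read contributes one primary record (its longest reference
    portion), mimicking an aligner soft-clipping reads that straddle
    copy-number junctions."""
    rng = np.random.default_rng(seed)
    lens = {r.id: len(r.seq) for r in isolate.genome}
    chroms = list(lens)
    weights = np.array([lens[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    total = int(coverage * sum(lens.values()) / read_len)
    # reference chromosome lengths from the piece map
    ref_len: dict[str, int] = {}
    for plist in isolate.pieces.values():
        for p in plist:
            if p.ref_chrom is not None:
                ref_len[p.ref_chrom] = max(ref_len.get(p.ref_chrom, 0), p.end)
    out: list[AlignmentRecord] = []
    for i in range(total):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        a = int(rng.integers(0, max(lens[c] - read_len, 1)))
        b = min(a + read_len, lens[c])
        portions = isolate.project(c, a, b)
        if not portions:
            continue
        rc, s, e, strand = max(portions, key=lambda p: p[2] - p[1])
        out.append(
            AlignmentRecord(
                query_id=f"sr_{i:07d}", query_len=read_len,
                q_start=0, q_end=e - s, strand=strand,
                target_id=rc, target_len=ref_len[rc],
                t_start=s, t_end=e, cigar=None, _identity_hint=1.0,
            )
        )
    return out
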
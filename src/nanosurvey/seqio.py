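"""Sequence, alignment and feature-track I/O.

FASTA/FASTQ go through Biopython, SAM through pysam; PAF is parsed directly
(tab-separated, 0-based half-open, with base-level ops carried in the cg:Z
tag).  All records cross this boundary in the package's internal 0-based
half-open convention:

* SAM POS (1-based) -> ``t_start`` (0-based);
* minus-strand SAM query coordinates are flipped onto the forward query
  strand (PAF semantics);
* GFF3 (1-based closed) -> half-open on read, converted back on write;
* BED passes through untouched.

Alignment CIGARs are stored in target-forward orientation, i.e. for a
minus-strand record the path consumes the reverse-complemented query
(SAM/PAF convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

from .core import AlignmentRecord, Cigar, Interval, SeqRecord

# ---------------------------------------------------------------------------
# sequences


def read_seqs(path, fmt: str) -> list[SeqRecord]:
    """Read a FASTA or FASTQ file into SeqRecords (Phred+33 qualities)."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            if rec.id in seen:
                raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            quals = None
            if fmt == "fastq":
                quals = np.array(
                    rec.letter_annotations["phred_quality"], dtype=np.int32
                )
            records.append(SeqRecord(rec.id, str(rec.seq), quals))
    except ValueError:
        raise
    except Exception as exc:  # Biopython parse failures
        raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    return records


def write_seqs(records, path, fmt: str) -> None:
    """Write SeqRecords as FASTA or FASTQ; FASTQ requires qualities."""
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            if fmt == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.seq), 80):
                    fh.write(rec.seq[i : i + 80] + "\n")
            else:
                if rec.quals is None:
                    raise ValueError(f"{rec.id}: FASTQ output requires qualities")
                qline = "".join(chr(min(int(q), 93) + 33) for q in rec.quals)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


# ---------------------------------------------------------------------------
# alignments

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")


def _resolve_m_with_md(cigartuples, md: str) -> list[tuple[int, int]]:
    """Split M runs into =/X using the MD tag; I/D pass through.

    Returns pysam-style (opcode, length) tuples using 7 (=) and 8 (X).
    """
    # expand MD into a per-reference-base match/mismatch stream
    ref_stream: list[bool] = []  # True = match
    for num, dele, sub in _MD_TOKEN.findall(md):
        if num:
            ref_stream.extend([True] * int(num))
        elif dele:
            pass  # deleted reference bases do not appear in M columns
        else:
            ref_stream.append(False)
    out: list[tuple[int, int]] = []
    i = 0
    for op, n in cigartuples:
        if op == 0:  # M
            j = i
            while j < i + n:
                is_match = ref_stream[j]
                k = j
                while k < i + n and ref_stream[k] == is_match:
                    k += 1
                out.append((7 if is_match else 8, k - j))
                j = k
            i += n
        else:
            if op == 2:  # D consumes reference; matches MD '^' runs
                pass
            out.append((op, n))
    return out


def _resolve_m_with_ref(cigartuples, query: str, ref: str, t_start: int):
    """Split M runs into =/X by direct comparison against the reference."""
    out: list[tuple[int, int]] = []
    qi, ti = 0, t_start
    for op, n in cigartuples:
        if op == 0:  # M
            j = 0
            while j < n:
                is_match = query[qi + j] == ref[ti + j]
                k = j
                while k < n and (query[qi + k] == ref[ti + k]) == is_match:
                    k += 1
                out.append((7 if is_match else 8, k - j))
                j = k
            qi += n
            ti += n
        else:
            if op in (1, 4):
                qi += n
            elif op in (2, 3):
                ti += n
            out.append((op, n))
    return out


_PYSAM_TO_CHAR = {7: "=", 8: "X", 1: "I", 2: "D"}


def read_alignments(path, fmt: str, reference: dict | None = None) -> list[AlignmentRecord]:
    """Read SAM or PAF alignments.

    SAM records must use =/X ops, or M with an MD tag, or M with ``reference``
    (a dict id -> sequence) supplied.  PAF records without a cg:Z tag become
    coordinate-only records (identity taken from the match/block columns).
    """
    if fmt == "sam":
        return _read_sam(path, reference)
    if fmt == "paf":
        return _read_paf(path)
    raise ValueError(f"unsupported alignment format {fmt!r}")


def _read_sam(path, reference) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        tlens = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            if seg.is_unmapped:
                continue
            ct = seg.cigartuples or []
            has_m = any(op == 0 for op, _ in ct)
            if has_m:
                if seg.has_tag("MD"):
                    ct = _resolve_m_with_md(ct, seg.get_tag("MD"))
                elif reference is not None and seg.reference_name in reference:
                    ct = _resolve_m_with_ref(
                        ct, seg.query_sequence, reference[seg.reference_name],
                        seg.reference_start,
                    )
                else:
                    raise ValueError(
                        f"{seg.query_name}: M CIGAR without MD tag or reference: "
                        "cannot resolve matches vs mismatches"
                    )
            pairs = [(_PYSAM_TO_CHAR[op], n) for op, n in ct if op in _PYSAM_TO_CHAR]
            lead_clip = ct[0][1] if ct and ct[0][0] in (4, 5) else 0
            trail_clip = ct[-1][1] if len(ct) > 1 and ct[-1][0] in (4, 5) else 0
            cig = Cigar.from_pairs(pairs)
            qspan = cig.query_span
            qlen = lead_clip + qspan + trail_clip
            if seg.is_reverse:
                q_start = trail_clip
                q_end = trail_clip + qspan
                strand = "-"
            else:
                q_start = lead_clip
                q_end = lead_clip + qspan
                strand = "+"
            tlen = tlens.get(seg.reference_name, seg.reference_end)
            rec = AlignmentRecord(
                query_id=seg.query_name,
                query_len=qlen,
                q_start=q_start,
                q_end=q_end,
                strand=strand,
                target_id=seg.reference_name,
                target_len=tlen,
                t_start=seg.reference_start,
                t_end=seg.reference_start + cig.target_span,
                cigar=cig,
                is_secondary=seg.is_secondary,
                is_supplementary=seg.is_supplementary,
            )
            if rec.t_end > rec.target_len:
                raise ValueError(
                    f"{seg.query_name}: alignment end {rec.t_end} exceeds "
                    f"declared length {rec.target_len} of {seg.reference_name}"
                )
            records.append(rec)
    return records


def _read_paf(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF line has <12 columns")
            cg = None
            secondary = False
            for tag in f[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
                elif tag.startswith("tp:A:"):
                    secondary = tag[5:] == "S"
            cigar = Cigar.from_string(cg) if cg else None
            hint = None
            if cigar is None:
                nmatch, blocklen = int(f[9]), int(f[10])
                hint = nmatch / blocklen if blocklen > 0 else None
            records.append(
                AlignmentRecord(
                    query_id=f[0], query_len=int(f[1]),
                    q_start=int(f[2]), q_end=int(f[3]), strand=f[4],
                    target_id=f[5], target_len=int(f[6]),
                    t_start=int(f[7]), t_end=int(f[8]),
                    cigar=cigar, is_secondary=secondary,
                    _identity_hint=hint,
                )
            )
    return records


def write_alignments(records, path, fmt: str, queries: dict | None = None) -> None:
    """Write AlignmentRecords as SAM or PAF (cg:Z carries the CIGAR).

    ``queries`` optionally maps query_id -> forward-strand sequence so SAM
    output can carry SEQ; otherwise SEQ is '*'.
    """
    if fmt == "paf":
        _write_paf(records, path)
    elif fmt == "sam":
        _write_sam(records, path, queries)
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")


def _write_paf(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.cigar is not None and len(r.cigar):
                t = r.cigar.op_totals()
                nmatch, blocklen = int(t[0]), int(t.sum())
                cg = "\tcg:Z:" + r.cigar.to_string()
            else:
                blocklen = max(r.q_end - r.q_start, r.t_end - r.t_start)
                nmatch = int(round((r._identity_hint or 0.0) * blocklen))
                cg = ""
            fh.write(
                f"{r.query_id}\t{r.query_len}\t{r.q_start}\t{r.q_end}\t{r.strand}\t"
                f"{r.target_id}\t{r.target_len}\t{r.t_start}\t{r.t_end}\t"
                f"{nmatch}\t{blocklen}\t60{cg}\n"
            )


def _write_sam(records, path, queries) -> None:
    targets: dict[str, int] = {}
    for r in records:
        targets.setdefault(r.target_id, r.target_len)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid, tlen in targets.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{tlen}\n")
        for r in records:
            flag = 0
            if r.strand == "-":
                flag |= 16
            if r.is_secondary:
                flag |= 256
            if r.is_supplementary:
                flag |= 2048
            if r.strand == "+":
                lead, trail = r.q_start, r.query_len - r.q_end
            else:
                lead, trail = r.query_len - r.q_end, r.q_start
            cig = ""
            if lead:
                cig += f"{lead}S"
            cig += r.cigar.to_string() if r.cigar is not None else "*"
            if trail:
                cig += f"{trail}S"
            seq = "*"
            if queries is not None and r.query_id in queries:
                from .core import revcomp

                s = queries[r.query_id]
                seq = revcomp(s) if r.strand == "-" else s
            fh.write(
                f"{r.query_id}\t{flag}\t{r.target_id}\t{r.t_start + 1}\t60\t"
                f"{cig}\t*\t0\t0\t{seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# feature tracks


@dataclass(frozen=True)
class Feature:
    """An annotated feature on a named sequence (0-based half-open)."""

    id: str
    kind: str  # e.g. gene, TE, centromere, telomere, rDNA, tandem_gene
    family: str  # e.g. Ty1; equals kind when there is no family structure
    target_id: str
    start: int
    end: int
    strand: str = "+"

    def interval(self) -> Interval:
        return Interval(self.target_id, self.start, self.end, self.strand)

    def __len__(self) -> int:
        return self.end - self.start


def write_bed(features, path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.target_id}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n"
            )


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else None
            out.append(Interval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_gff3(features, path, source: str = "nanosurvey") -> None:
    """GFF3 output; converts half-open to 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.id};family={f.family}"
            fh.write(
                f"{f.target_id}\t{source}\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[Feature]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                Feature(
                    id=attrs.get("ID", "."),
                    kind=f[2],
                    family=attrs.get("family", f[2]),
                    target_id=f[0],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    strand=f[6] if f[6] in "+-" else "+",
                )
            )
    return out
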
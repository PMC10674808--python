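"""Sequence I/O and the coordinate/alphabet conventions used package-wide.

All coordinates are 1-based inclusive.  The internal nucleotide alphabet is
RNA ({A, C, G, U}); DNA input is accepted and T is normalized to U on read.
Ambiguity codes are rejected by default; with ``allow_ambiguous=True`` they
are mapped to the sentinel ``N``, which never matches anything downstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class SequenceFormatError(ValueError):
    """Raised for malformed or empty sequence files."""


def normalize_rna(seq: str, *, allow_ambiguous: bool = False, context: str = "") -> str:
    """Uppercase, convert T to U, and validate the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        if allow_ambiguous:
            s = "".join(c if c in RNA_ALPHABET else "N" for c in s)
        else:
            raise SequenceFormatError(
                f"non-ACGU characters {sorted(bad)} in sequence"
                + (f" {context}" if context else "")
                + " (pass allow_ambiguous=True to mask them as N)"
            )
    return s


def reverse_complement(seq: str) -> str:
    """RNA reverse complement (A<->U, G<->C; N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """An identified RNA sequence; the unit all annotation operates on."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_fraction(self) -> float:
        s = self.sequence
        return (s.count("G") + s.count("C")) / len(s)


@dataclass(frozen=True)
class SrnaRead:
    """A trimmed small-RNA read."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceFormatError(f"read {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.start}..{self.end} (1-based inclusive)")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def validate_against(self, genome_length: int) -> None:
        if self.end > genome_length:
            raise ValueError(
                f"interval {self.start}..{self.end} exceeds genome length {genome_length}"
            )


def read_fasta(path: str | os.PathLike, *, allow_ambiguous: bool = False) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords, normalizing T to U.

    Raises SequenceFormatError on an empty file or duplicate record ids.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_rna(str(rec.seq), allow_ambiguous=allow_ambiguous, context=rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise SequenceFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord | SrnaRead], path: str | os.PathLike, *, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = rec.id if not desc or desc == rec.id else desc
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def read_fastq(path: str | os.PathLike, *, allow_ambiguous: bool = False) -> list[SrnaRead]:
    """Read FASTQ (Sanger); qualities are parsed for validation then discarded.

    Raises SequenceFormatError for truncated records, naming the record index.
    """
    reads: list[SrnaRead] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    # drop trailing blank lines, but never below a multiple of four — an
    # empty sequence/quality line inside a record must stay visible
    while lines and lines[-1] == "" and len(lines) % 4 != 0:
        lines.pop()
    if not lines:
        raise SequenceFormatError(f"empty FASTQ file {path}")
    if len(lines) % 4 != 0:
        raise SequenceFormatError(
            f"truncated FASTQ record at index {len(lines) // 4} in {path}"
        )
    for idx in range(0, len(lines), 4):
        head, seq, plus, qual = lines[idx : idx + 4]
        rec_no = idx // 4
        if not head.startswith("@") or not plus.startswith("+"):
            raise SequenceFormatError(f"malformed FASTQ record at index {rec_no} in {path}")
        if not seq:
            raise SequenceFormatError(f"zero-length sequence in FASTQ record {rec_no} in {path}")
        if len(qual) != len(seq):
            raise SequenceFormatError(
                f"quality/sequence length mismatch in FASTQ record {rec_no} in {path}"
            )
        rid = head[1:].split()[0]
        reads.append(SrnaRead(id=rid, sequence=normalize_rna(seq, allow_ambiguous=allow_ambiguous, context=rid)))
    return reads


def write_fastq(reads: Iterable[SrnaRead], path: str | os.PathLike, *, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{quality_char * r.length}\n")


# --- GFF3 -----------------------------------------------------------------

_GFF_SOURCE = "totikit"


def write_gff3(annotation: Optional["GenomeAnnotation"], path: str | os.PathLike) -> None:
    """Emit the genome layout as GFF3 (1-based inclusive, as stored).

    Features: five_prime_UTR, one CDS per ORF, the intergenic region as a
    biological_region, three_prime_UTR.  Zero-length segments are skipped.
    ``annotation=None`` writes a header-only file.
    """
    lines = ["##gff-version 3"]
    if annotation is not None:
        feats = annotation.gff_features()
        _check_no_overlap(feats)
        lines.append(
            f"##sequence-region {annotation.genome_id} 1 {annotation.genome_length}"
        )
        for ftype, iv, attrs in feats:
            phase = "0" if ftype == "CDS" else "."
            lines.append(
                "\t".join(
                    [
                        annotation.genome_id,
                        _GFF_SOURCE,
                        ftype,
                        str(iv.start),
                        str(iv.end),
                        ".",
                        iv.strand,
                        phase,
                        attrs,
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _check_no_overlap(feats) -> None:
    ivs = sorted((iv.start, iv.end, ftype) for ftype, iv, _ in feats)
    for (s1, e1, t1), (s2, e2, t2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping features {t1} ({s1}..{e1}) and {t2} ({s2}..{e2})")


def read_gff3(path: str | os.PathLike) -> list[tuple[str, str, Interval]]:
    """Minimal GFF3 reader used for round-trip checks: (seqid, type, interval)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SequenceFormatError(f"bad GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, _attrs = cols
            out.append((seqid, ftype, Interval(int(start), int(end), strand)))
    return out


def to_seqrecord(rec: GenomeRecord) -> SeqRecord:
    """Bridge to Biopython for interop."""
    return SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
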
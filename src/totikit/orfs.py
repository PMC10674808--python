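"""ORF discovery, genome-layout annotation, translation, and protein mass.

Frame convention: frame ``f`` in {1, 2, 3} means codons start at positions
``p`` with ``(p - f) mod 3 == 0`` (1-based).  ORFs are AUG-initiated and
stop-terminated; nested AUG starts sharing a stop are suppressed in favour
of the longest (5'-most AUG per stop).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from Bio.Data import CodonTable

from .io import GenomeRecord, Interval, reverse_complement

_STANDARD = CodonTable.unambiguous_rna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # {"UAA", "UAG", "UGA"}
START_CODON = "AUG"

# Average residue masses (Da); protein mass = sum + one water.
RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.01524


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def frame_of(start: int) -> int:
    """Frame label (1..3) of a codon starting at 1-based position ``start``."""
    return (start - 1) % 3 + 1


def translate(rna: str, frame_offset: int = 0) -> str:
    """Translate ``rna`` from ``frame_offset`` (0-based) with the standard code.

    Stops at the first stop codon (excluded from the product); trailing
    partial codons are ignored.  Raises ValueError on non-ACGU characters.
    """
    protein = []
    for i in range(frame_offset, len(rna) - 2, 3):
        codon = rna[i : i + 3]
        if codon in STOP_CODONS:
            break
        try:
            protein.append(CODON_TABLE[codon])
        except KeyError:
            raise ValueError(f"untranslatable codon {codon!r} at position {i + 1}") from None
    return "".join(protein)


def protein_mass(protein: str) -> float:
    """Average molecular mass in kDa (full precision; round at reporting)."""
    try:
        da = sum(RESIDUE_MASS_DA[aa] for aa in protein) + WATER_MASS_DA
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None
    return da / 1000.0


@dataclass(frozen=True)
class OrfAnnotation:
    """A single AUG..stop open reading frame and its protein product."""

    interval: Interval
    frame: int
    start_codon: str
    stop_codon: str
    protein: str

    def __post_init__(self) -> None:
        if self.nt_length % 3 != 0:
            raise ValueError(f"ORF length {self.nt_length} not divisible by 3")
        if self.protein_length != self.nt_length // 3 - 1:
            raise ValueError("protein length inconsistent with ORF span")
        if any(aa == "*" for aa in self.protein):
            raise ValueError("internal stop in ORF protein")

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def nt_length(self) -> int:
        return self.interval.length

    @property
    def protein_length(self) -> int:
        return len(self.protein)

    @property
    def protein_mass_kda(self) -> float:
        return round_half_up(protein_mass(self.protein), 2)


def find_orfs(
    genome: GenomeRecord,
    min_aa: int = 100,
    strand_policy: str = "plus",
) -> list[OrfAnnotation]:
    """All maximal AUG-initiated, stop-terminated ORFs >= ``min_aa`` codons.

    Scans the three plus-strand frames (and, with ``strand_policy='both'``,
    the reverse complement).  Within one stop-free stretch only the 5'-most
    AUG is reported (longest-ORF-per-stop).  Result sorted by start.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if strand_policy not in ("plus", "both"):
        raise ValueError("strand_policy must be 'plus' or 'both'")

    orfs = list(_scan_strand(genome.sequence, min_aa, "+"))
    if strand_policy == "both":
        rc = reverse_complement(genome.sequence)
        n = len(rc)
        for orf in _scan_strand(rc, min_aa, "-"):
            iv = Interval(n - orf.interval.end + 1, n - orf.interval.start + 1, "-")
            orfs.append(replace(orf, interval=iv, frame=frame_of(iv.start)))
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.interval.strand))
    return orfs


def _scan_strand(seq: str, min_aa: int, strand: str):
    n = len(seq)
    for offset in range(3):
        start: Optional[int] = None  # 0-based codon start of current ORF
        for i in range(offset, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    aa_len = (i - start) // 3
                    if aa_len >= min_aa:
                        protein = translate(seq[start : i + 3])
                        yield OrfAnnotation(
                            interval=Interval(start + 1, i + 3, strand),
                            frame=frame_of(start + 1),
                            start_codon=START_CODON,
                            stop_codon=codon,
                            protein=protein,
                        )
                    start = None
            elif codon == START_CODON and start is None:
                start = i


def select_orf_pair(orfs: list[OrfAnnotation]) -> tuple[OrfAnnotation, OrfAnnotation]:
    """Pick the two longest non-overlapping ORFs in distinct frames.

    Returns (orf1, orf2) ordered 5' to 3'.  Raises ValueError when no such
    pair exists.
    """
    best: Optional[tuple[int, OrfAnnotation, OrfAnnotation]] = None
    for i, a in enumerate(orfs):
        for b in orfs[i + 1 :]:
            lo, hi = (a, b) if a.start <= b.start else (b, a)
            if lo.end >= hi.start or lo.frame == hi.frame:
                continue
            total = a.nt_length + b.nt_length
            if best is None or total > best[0]:
                best = (total, lo, hi)
    if best is None:
        raise ValueError("no two long ORFs found (non-overlapping, distinct frames)")
    return best[1], best[2]


@dataclass(frozen=True)
class GenomeAnnotation:
    """The full totivirus genome layout in 1-based inclusive coordinates."""

    genome_id: str
    genome_length: int
    gc_percent: float
    utr5: Optional[Interval]
    orf1: OrfAnnotation
    intergenic: Optional[Interval]
    orf2: OrfAnnotation
    utr3: Optional[Interval]

    @property
    def utr5_length(self) -> int:
        return self.utr5.length if self.utr5 else 0

    @property
    def intergenic_length(self) -> int:
        return self.intergenic.length if self.intergenic else 0

    @property
    def utr3_length(self) -> int:
        return self.utr3.length if self.utr3 else 0

    def gff_features(self):
        feats = []
        if self.utr5:
            feats.append(("five_prime_UTR", self.utr5, "ID=utr5"))
        feats.append(("CDS", self.orf1.interval, "ID=orf1"))
        if self.intergenic:
            feats.append(("biological_region", self.intergenic, "ID=intergenic_region"))
        feats.append(("CDS", self.orf2.interval, "ID=orf2"))
        if self.utr3:
            feats.append(("three_prime_UTR", self.utr3, "ID=utr3"))
        return feats

    def to_dict(self) -> dict:
        d = {
            "genome_id": self.genome_id,
            "genome_length": self.genome_length,
            "gc_percent": self.gc_percent,
            "utr5_length": self.utr5_length,
            "intergenic_length": self.intergenic_length,
            "utr3_length": self.utr3_length,
        }
        for name, orf in (("orf1", self.orf1), ("orf2", self.orf2)):
            d[name] = {
                "start": orf.start,
                "end": orf.end,
                "frame": orf.frame,
                "nt_length": orf.nt_length,
                "aa_length": orf.protein_length,
                "mass_kda": orf.protein_mass_kda,
            }
        return d


def compute_gc(genome: GenomeRecord) -> float:
    """GC content in percent, 1 decimal, half-up."""
    return round_half_up(100.0 * genome.gc_fraction(), 1)


def annotate_genome(
    genome: GenomeRecord,
    orf1: OrfAnnotation,
    orf2: OrfAnnotation,
    *,
    allow_overlap: bool = False,
) -> GenomeAnnotation:
    """Derive UTR/intergenic intervals and GC content from the two ORFs."""
    n = genome.length
    if orf2.end > n:
        raise ValueError(f"orf2 end {orf2.end} exceeds genome length {n}")
    if not allow_overlap and orf1.end >= orf2.start:
        raise ValueError("ORFs overlap; pass allow_overlap=True if intended")
    utr5 = Interval(1, orf1.start - 1) if orf1.start > 1 else None
    ir_len = orf2.start - orf1.end - 1
    intergenic = Interval(orf1.end + 1, orf2.start - 1) if ir_len > 0 else None
    utr3 = Interval(orf2.end + 1, n) if orf2.end < n else None
    ann = GenomeAnnotation(
        genome_id=genome.id,
        genome_length=n,
        gc_percent=compute_gc(genome),
        utr5=utr5,
        orf1=orf1,
        intergenic=intergenic,
        orf2=orf2,
        utr3=utr3,
    )
    if not allow_overlap:
        covered = ann.utr5_length + orf1.nt_length + ann.intergenic_length + orf2.nt_length + ann.utr3_length
        assert covered == n, "layout segments must tile the genome"
    return ann
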
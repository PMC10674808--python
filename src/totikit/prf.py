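"""Detection of -1 programmed ribosomal frameshift (PRF) elements.

A -1 PRF element is a slippery heptamer of the canonical form XXXYYYZ
(X in {A,C,G,U} with the three X identical, Y in {A,U} identical,
Z in {A,C,U}) near the ORF1 stop, a short spacer, and a downstream H-type
pseudoknot.  The pseudoknot search runs DOWNSTREAM of the heptamer — the
orientation supported by both reported totivirus elements and the -1 PRF
literature.

The pseudoknot energy model is deliberately simple and fully documented:
per base pair GC -3.0, AU -2.0, GU -1.0 kcal/mol; +0.2 kcal/mol per
unpaired loop nucleotide; +7.0 kcal/mol pseudoknot initiation penalty.
It ranks candidates reproducibly; it is not a thermodynamic prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import GenomeRecord, Interval
from .orfs import OrfAnnotation, STOP_CODONS, CODON_TABLE, protein_mass

SLIPPERY_X = frozenset("ACGU")
SLIPPERY_Y = frozenset("AU")
SLIPPERY_Z = frozenset("ACU")

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
LOOP_PENALTY_PER_NT = 0.2
PK_INIT_PENALTY = 7.0


def is_slippery(heptamer: str) -> bool:
    """Canonical XXXYYYZ grammar check."""
    if len(heptamer) != 7:
        return False
    x, y, z = heptamer[0], heptamer[3], heptamer[6]
    return (
        x in SLIPPERY_X
        and heptamer[1] == x
        and heptamer[2] == x
        and y in SLIPPERY_Y
        and heptamer[4] == y
        and heptamer[5] == y
        and z in SLIPPERY_Z
    )


@dataclass(frozen=True)
class SlipperySite:
    interval: Interval
    heptamer: str
    distance_to_orf1_stop: int
    on_codon_boundary: bool

    def __post_init__(self) -> None:
        if self.interval.length != 7:
            raise ValueError("slippery site must span exactly 7 nt")
        if not is_slippery(self.heptamer):
            raise ValueError(f"{self.heptamer!r} violates the XXXYYYZ grammar")

    @property
    def x(self) -> str:
        return self.heptamer[0]

    @property
    def y(self) -> str:
        return self.heptamer[3]

    @property
    def z(self) -> str:
        return self.heptamer[6]


def scan_slippery(
    genome: GenomeRecord,
    orf1: OrfAnnotation,
    max_upstream: int = 200,
    *,
    require_codon_boundary: bool = True,
) -> list[SlipperySite]:
    """All canonical heptamers whose 3' end lies in [orf1.end - max_upstream, orf1.end].

    ``on_codon_boundary`` marks heptamers whose 3' end falls on an ORF1 codon
    boundary ((end - orf1.start + 1) mod 3 == 0); by default only those are
    returned.  Sorted 5' to 3'.
    """
    seq = genome.sequence
    lo_end = max(orf1.start + 6, orf1.end - max_upstream)
    sites = []
    for end in range(lo_end, orf1.end + 1):  # 1-based heptamer end
        start = end - 6
        if start < 1:
            continue
        hept = seq[start - 1 : end]
        if not is_slippery(hept):
            continue
        on_boundary = (end - orf1.start + 1) % 3 == 0
        if require_codon_boundary and not on_boundary:
            continue
        sites.append(
            SlipperySite(
                interval=Interval(start, end),
                heptamer=hept,
                distance_to_orf1_stop=orf1.end - end,
                on_codon_boundary=on_boundary,
            )
        )
    return sites


# --- H-type pseudoknots ---------------------------------------------------

@dataclass(frozen=True)
class PkParams:
    min_stem: int = 3
    max_stem: int = 10
    max_loop1: int = 20
    max_loop2: int = 15
    max_loop3: int = 40
    max_span: int = 60
    max_window: int = 120


@dataclass(frozen=True)
class Pseudoknot:
    """Two crossing stems; pairs are (5' position, 3' position), 1-based."""

    stem1: tuple[tuple[int, int], ...]
    stem2: tuple[tuple[int, int], ...]
    span: Interval
    loop_lengths: tuple[int, int, int]
    efe_kcal_mol: float

    def all_pairs(self) -> tuple[tuple[int, int], ...]:
        return self.stem1 + self.stem2

    def validate(self, sequence: str, params: Optional[PkParams] = None) -> None:
        params = params or PkParams()
        used: set[int] = set()
        for p5, p3 in self.all_pairs():
            key = (sequence[p5 - 1], sequence[p3 - 1])
            if key not in PAIR_ENERGY:
                raise ValueError(f"positions {p5}/{p3} ({key}) cannot pair")
            if p5 in used or p3 in used:
                raise ValueError(f"position reused in pairing: {p5}/{p3}")
            used.update((p5, p3))
        if len(self.stem1) < params.min_stem or len(self.stem2) < params.min_stem:
            raise ValueError("stem below minimum length")
        s1_5p = {p for p, _ in self.stem1}
        s1_3p = {q for _, q in self.stem1}
        for p5, p3 in self.stem2:
            if not (max(s1_5p) < p5 < min(s1_3p)):
                raise ValueError("stem2 5' partner not inside stem1 loop")
            if p3 <= max(s1_3p):
                raise ValueError("stem2 3' partner not downstream of stem1")


def pk_energy(pk: Pseudoknot, sequence: str, params: Optional[PkParams] = None) -> float:
    """Additive energy: pair terms + loop penalty + initiation penalty."""
    e = sum(PAIR_ENERGY[(sequence[p - 1], sequence[q - 1])] for p, q in pk.all_pairs())
    e += LOOP_PENALTY_PER_NT * sum(pk.loop_lengths)
    e += PK_INIT_PENALTY
    return round(e, 6)


def find_pseudoknots(
    genome: GenomeRecord,
    window: Interval,
    params: Optional[PkParams] = None,
) -> list[Pseudoknot]:
    """Exhaustively enumerate H-type (crossing two-stem) candidates in ``window``.

    Returns candidates sorted by energy ascending (ties: smaller span, then
    5'-most), deduplicated to the best representative per span.
    """
    params = params or PkParams()
    window.validate_against(genome.length)
    if window.length > params.max_window:
        raise ValueError(
            f"window of {window.length} nt exceeds max_window={params.max_window}; "
            "scan a narrower region"
        )
    seq = genome.sequence[window.start - 1 : window.end]
    n = len(seq)

    def pairs_ok(i: int, j: int) -> bool:
        return (seq[i], seq[j]) in PAIR_ENERGY

    # run[i][j]: ladder length of consecutive pairs (i+k, j-k)
    run = [[0] * n for _ in range(n)]
    for i in range(n - 1, -1, -1):
        for j in range(n):
            if j > i and pairs_ok(i, j):
                inner = run[i + 1][j - 1] if i + 1 <= j - 1 else 0
                run[i][j] = 1 + inner

    stems: list[tuple[int, int, int]] = []  # (i, j, s): pairs (i+k, j-k), 0-based local
    for i in range(n):
        for j in range(i + 2 * params.min_stem - 1, n):
            if not pairs_ok(i, j):
                continue
            if i > 0 and j < n - 1 and pairs_ok(i - 1, j + 1):
                continue  # not a maximal-run start; covered by its parent
            m = run[i][j]
            m = min(m, (j - i + 1) // 2)
            for t in range(m):
                for s in range(params.min_stem, min(params.max_stem, m - t) + 1):
                    if (i + t) + s - 1 < (j - t) - s + 1:
                        stems.append((i + t, j - t, s))

    best_by_span: dict[tuple[int, int], Pseudoknot] = {}
    for i1, j1, s1 in stems:
        a_end = i1 + s1 - 1
        b_start = j1 - s1 + 1
        for i2, j2, s2 in stems:
            c_end = i2 + s2 - 1
            d_start = j2 - s2 + 1
            loop1 = i2 - a_end - 1
            if loop1 < 0 or loop1 > params.max_loop1:
                continue
            loop2 = b_start - c_end - 1
            if loop2 < 0 or loop2 > params.max_loop2:
                continue
            loop3 = d_start - j1 - 1
            if loop3 < 0 or loop3 > params.max_loop3:
                continue
            span_len = j2 - i1 + 1
            if span_len > params.max_span:
                continue
            off = window.start  # local 0-based -> genome 1-based
            pk = Pseudoknot(
                stem1=tuple((off + i1 + k, off + j1 - k) for k in range(s1)),
                stem2=tuple((off + i2 + k, off + j2 - k) for k in range(s2)),
                span=Interval(off + i1, off + j2),
                loop_lengths=(loop1, loop2, loop3),
                efe_kcal_mol=0.0,
            )
            e = pk_energy(pk, genome.sequence, params)
            pk = Pseudoknot(pk.stem1, pk.stem2, pk.span, pk.loop_lengths, e)
            key = (pk.span.start, pk.span.end)
            prev = best_by_span.get(key)
            if prev is None or pk.efe_kcal_mol < prev.efe_kcal_mol:
                best_by_span[key] = pk

    out = sorted(
        best_by_span.values(),
        key=lambda p: (p.efe_kcal_mol, p.span.length, p.span.start),
    )
    return out


# --- Assembly and the fusion product --------------------------------------

@dataclass(frozen=True)
class PrfElement:
    slippery: SlipperySite
    pseudoknot: Pseudoknot
    score: float

    @property
    def spacer_length(self) -> int:
        return self.pseudoknot.span.start - self.slippery.interval.end - 1

    def __post_init__(self) -> None:
        if self.spacer_length < 0:
            raise ValueError("pseudoknot overlaps or precedes the slippery site")


def assemble_prf(
    slippery: SlipperySite,
    pks: list[Pseudoknot],
    spacer_bounds: tuple[int, int] = (1, 30),
) -> list[PrfElement]:
    """Combine a slippery site with downstream pseudoknots within spacer bounds.

    Score is the pseudoknot energy (lower = better); result sorted by score.
    """
    lo, hi = spacer_bounds
    elements = []
    for pk in pks:
        spacer = pk.span.start - slippery.interval.end - 1
        if lo <= spacer <= hi:
            elements.append(PrfElement(slippery=slippery, pseudoknot=pk, score=pk.efe_kcal_mol))
    elements.sort(key=lambda e: (e.score, e.pseudoknot.span.length, e.pseudoknot.span.start))
    return elements


@dataclass(frozen=True)
class FusionProduct:
    pre_shift_codons: int
    post_shift_codons: int
    protein: str

    @property
    def protein_length(self) -> int:
        return len(self.protein)

    @property
    def mass_kda(self) -> float:
        from .orfs import round_half_up

        return round_half_up(protein_mass(self.protein), 2)


def _translate_exact(seq: str, genome_offset: int) -> str:
    """Translate a full stretch; an internal stop is an error with its position."""
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(
                f"internal stop codon {codon} at genome position {genome_offset + i}"
            )
        aas.append(CODON_TABLE[codon])
    return "".join(aas)


def fusion_protein(
    genome: GenomeRecord,
    orf1: OrfAnnotation,
    slippery: SlipperySite,
    orf2: OrfAnnotation,
) -> FusionProduct:
    """Derive the ORF1-ORF2 fusion protein produced by a -1 slip at ``slippery``.

    The ribosome translates ORF1 codons up to and including the heptamer's
    final base, slips back one nucleotide (re-reading that base), and
    continues in the -1 frame — which must coincide with the ORF2 frame —
    until the codon before the ORF2 stop.
    """
    slip_end = slippery.interval.end
    if (slip_end - orf1.start + 1) % 3 != 0:
        raise ValueError(
            f"heptamer 3' end {slip_end} is not on an ORF1 codon boundary: "
            f"(end - orf1.start + 1) = {slip_end - orf1.start + 1} is not divisible by 3"
        )
    if (orf2.start - slip_end) % 3 != 0:
        raise ValueError(
            f"post-shift frame inconsistent with ORF2: (orf2.start - end) = "
            f"{orf2.start - slip_end} is not divisible by 3"
        )
    seq = genome.sequence
    pre_nt = seq[orf1.start - 1 : slip_end]
    post_nt = seq[slip_end - 1 : orf2.end - 3]  # re-reads the final heptamer base
    pre = _translate_exact(pre_nt, orf1.start)
    post = _translate_exact(post_nt, slip_end)
    return FusionProduct(
        pre_shift_codons=len(pre),
        post_shift_codons=len(post),
        protein=pre + post,
    )
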
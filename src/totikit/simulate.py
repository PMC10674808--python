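"""Synthetic totivirus-like genomes, host background, and small-RNA reads.

Every dataset is emitted together with a SyntheticTruth record describing
the planted structure, so downstream recovery can be tested exactly.

Genome construction plants, by position: the two long ORFs in different
frames, a canonical slippery heptamer ending on an ORF1 codon boundary, an
H-type pseudoknot downstream of the heptamer (GC stems, U-free loops, so
the planted structure is the unambiguous energy optimum), a GDD tripeptide
in ORF2, and a histidine anchor in ORF1.  Frame constraints keep the
post-shift reading frame stop-free from the heptamer through ORF2, and a
stop codon is planted just upstream in that frame so the only AUG sharing
ORF2's stop is ORF2's own start.  Accidental structure (extra long ORFs,
competing heptamers, a non-planted top pseudoknot) is removed by rejection
sampling; all randomness flows through one seeded generator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import GenomeRecord, Interval, SrnaRead, reverse_complement
from .orfs import STOP_CODONS, find_orfs
from .prf import PkParams, Pseudoknot, find_pseudoknots, is_slippery, scan_slippery
from .srna import ReadMapper
from . import published

_BASES = np.array(list("ACGU"))
_GC_BASES = "GC"


class SyntheticDataError(RuntimeError):
    """Raised when consistent synthetic data cannot be generated."""


@dataclass
class GenomeParams:
    """Layout parameters; defaults reproduce the GcTV2-Gc6 published layout."""

    genome_id: str = "synthetic_totivirus"
    utr5_len: int = 29
    orf1_nt_len: int = 2043
    ir_len: int = 326
    orf2_nt_len: int = 2157
    utr3_len: int = 37
    slippery_heptamer: str = "GGGUUUA"
    slippery_offset_from_stop: int = 108  # orf1.end - heptamer 3' end
    spacer_len: int = 4
    stem1_len: int = 6
    stem2_len: int = 5
    loop_lens: tuple[int, int, int] = (4, 1, 28)
    gc: float = 0.455
    gdd_protein_pos: int = 500
    his_protein_pos: int = 154
    min_aa: int = 100

    # Derived coordinates (1-based inclusive) ------------------------------
    @property
    def genome_length(self) -> int:
        return self.utr5_len + self.orf1_nt_len + self.ir_len + self.orf2_nt_len + self.utr3_len

    @property
    def orf1_start(self) -> int:
        return self.utr5_len + 1

    @property
    def orf1_end(self) -> int:
        return self.utr5_len + self.orf1_nt_len

    @property
    def orf2_start(self) -> int:
        return self.orf1_end + self.ir_len + 1

    @property
    def orf2_end(self) -> int:
        return self.orf2_start + self.orf2_nt_len - 1

    @property
    def slip_end(self) -> int:
        return self.orf1_end - self.slippery_offset_from_stop

    @property
    def slip_start(self) -> int:
        return self.slip_end - 6

    @property
    def pk_start(self) -> int:
        return self.slip_end + self.spacer_len + 1

    @property
    def pk_end(self) -> int:
        return self.pk_start + 2 * (self.stem1_len + self.stem2_len) + sum(self.loop_lens) - 1

    @property
    def fusion_len_aa(self) -> int:
        pre = (self.slip_end - self.orf1_start + 1) // 3
        post = (self.orf2_end - 3 - self.slip_end + 1) // 3
        return pre + post

    def validate(self) -> None:
        checks = [
            (self.orf1_nt_len % 3 == 0, "orf1_nt_len must be divisible by 3"),
            (self.orf2_nt_len % 3 == 0, "orf2_nt_len must be divisible by 3"),
            (is_slippery(self.slippery_heptamer), "slippery_heptamer violates the XXXYYYZ grammar"),
            (
                (self.slip_end - self.orf1_start + 1) % 3 == 0,
                "heptamer 3' end must fall on an ORF1 codon boundary: "
                "(slip_end - orf1_start + 1) mod 3 == 0",
            ),
            (
                (self.orf2_start - self.slip_end) % 3 == 0,
                "post-shift frame must match ORF2: (orf2_start - slip_end) mod 3 == 0",
            ),
            (self.spacer_len >= 1, "spacer_len must be >= 1"),
            (all(l >= 1 for l in self.loop_lens), "pseudoknot loops must each be >= 1 nt"),
            (min(self.stem1_len, self.stem2_len) >= 3, "stems must be >= 3 bp"),
            (self.pk_end <= self.orf1_end - 3, "pseudoknot must end before the ORF1 stop codon"),
            (self.slip_start - 9 > self.orf1_start + 2, "heptamer too close to ORF1 start"),
            (self.utr5_len >= 0 and self.utr3_len >= 0 and self.ir_len >= 1,
             "utr/ir lengths must be non-negative (ir >= 1)"),
            (3 <= self.his_protein_pos * 3 + 2 < self.slip_start - 12 - self.orf1_start,
             "his_protein_pos must lie well upstream of the heptamer"),
            (1 <= self.gdd_protein_pos <= self.orf2_nt_len // 3 - 3,
             "gdd_protein_pos must lie inside the ORF2 protein"),
            (0.0 < self.gc < 1.0, "gc must be in (0, 1)"),
            (self.orf1_nt_len // 3 - 1 >= self.min_aa and self.orf2_nt_len // 3 - 1 >= self.min_aa,
             "planted ORFs must be at least min_aa codons"),
        ]
        for ok, msg in checks:
            if not ok:
                raise SyntheticDataError(msg)

    @classmethod
    def from_layout(cls, layout: dict, **overrides) -> "GenomeParams":
        """Build params from a published layout dict (see totikit.published)."""
        span = layout["pk_end"] - layout["pk_start"] + 1
        pk_geom = _default_pk_geometry(span)
        kwargs = dict(
            genome_id=layout["genome_id"],
            utr5_len=layout["utr5_len"],
            orf1_nt_len=layout["orf1_end"] - layout["orf1_start"] + 1,
            ir_len=layout["ir_len"],
            orf2_nt_len=layout["orf2_end"] - layout["orf2_start"] + 1,
            utr3_len=layout["utr3_len"],
            slippery_heptamer=layout["slippery_heptamer"],
            slippery_offset_from_stop=layout["orf1_end"] - layout["slippery_end"],
            spacer_len=layout["spacer_len"],
            gc=layout["gc_percent"] / 100.0,
            **pk_geom,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _default_pk_geometry(span: int) -> dict:
    """Stem/loop lengths realizing a pseudoknot of the requested span."""
    for s1, s2 in ((6, 5), (5, 5), (5, 4), (4, 4), (4, 3), (3, 3)):
        loops_total = span - 2 * (s1 + s2)
        if loops_total >= 3:
            l1 = max(1, min(4, loops_total - 2))
            l2 = 1
            l3 = loops_total - l1 - l2
            if l3 >= 1:
                return {"stem1_len": s1, "stem2_len": s2, "loop_lens": (l1, l2, l3)}
    raise SyntheticDataError(f"no stem geometry fits a pseudoknot span of {span} nt")


@dataclass
class SyntheticTruth:
    """Planted parameters emitted alongside every simulated dataset."""

    seed: int
    genome: Optional[dict] = None
    reads: Optional[list[dict]] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


# --- genome generation ----------------------------------------------------

def make_genome(
    params: Optional[GenomeParams] = None,
    seed: int = 0,
    *,
    verify_pseudoknot: bool = True,
    max_resample: int = 1000,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Generate a totivirus-like genome with fully known planted structure."""
    params = params or GenomeParams()
    params.validate()
    rng = np.random.default_rng(seed)
    for _ in range(max_resample):
        seq = _attempt_sequence(params, rng)
        if seq is None:
            continue
        genome = GenomeRecord(id=params.genome_id, sequence=seq)
        if _recovered_exactly(genome, params, verify_pseudoknot):
            return genome, _build_truth(params, seed)
    raise SyntheticDataError(
        f"could not generate an accident-free genome in {max_resample} attempts"
    )


def _planted_pseudoknot(params: GenomeParams, sequence: str = "") -> Pseudoknot:
    s1, s2 = params.stem1_len, params.stem2_len
    l1, l2, l3 = params.loop_lens
    p = params.pk_start
    s1a = p
    s2a = s1a + s1 + l1
    s1b = s2a + s2 + l2
    s2b = s1b + s1 + l3
    stem1 = tuple((s1a + k, s1b + s1 - 1 - k) for k in range(s1))
    stem2 = tuple((s2a + k, s2b + s2 - 1 - k) for k in range(s2))
    return Pseudoknot(
        stem1=stem1,
        stem2=stem2,
        span=Interval(params.pk_start, params.pk_end),
        loop_lengths=(l1, l2, l3),
        efe_kcal_mol=0.0,
    )


def _attempt_sequence(params: GenomeParams, rng: np.random.Generator) -> Optional[str]:
    n = params.genome_length
    gc = params.gc
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = list(rng.choice(_BASES, size=n, p=probs))
    fixed = [False] * n

    def plant(pos1: int, chars: str) -> None:  # 1-based
        for k, c in enumerate(chars):
            seq[pos1 - 1 + k] = c
            fixed[pos1 - 1 + k] = True

    plant(params.orf1_start, "AUG")
    plant(params.orf1_end - 2, "UAA")
    plant(params.orf2_start, "AUG")
    plant(params.orf2_end - 2, "UAA")
    plant(params.slip_start, params.slippery_heptamer)
    # stop in the post-shift frame just upstream of the heptamer, so no AUG
    # upstream of ORF2 shares ORF2's stop codon
    plant(params.slip_end - 9, "UAA")
    plant(params.orf1_start + 3 * (params.his_protein_pos - 1), "CAU")
    plant(params.orf2_start + 3 * (params.gdd_protein_pos - 1), "GGUGAUGAU")

    # pseudoknot: GC stems; loops alternate C/A — U-free (no stops, no AUG,
    # nothing that pairs with A) and never three identical bases in a row
    # (a poly-A loop would itself satisfy the slippery-heptamer grammar)
    def loop_fill(length: int) -> str:
        return ("CA" * length)[:length]

    s1_seq = "".join(rng.choice(list(_GC_BASES), size=params.stem1_len))
    s2_seq = "".join(rng.choice(list(_GC_BASES), size=params.stem2_len))
    l1, l2, l3 = params.loop_lens
    pk_block = (
        s1_seq + loop_fill(l1) + s2_seq + loop_fill(l2)
        + reverse_complement(s1_seq) + loop_fill(l3) + reverse_complement(s2_seq)
    )
    plant(params.pk_start, pk_block)

    if not _repair(seq, fixed, params, rng):
        return None
    return "".join(seq)


_PAIRABLE = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _repair(seq: list, fixed: list, params: GenomeParams, rng: np.random.Generator) -> bool:
    """Resample free positions until all frame/extension constraints hold."""
    n = params.genome_length

    def codon(p1: int) -> str:  # 1-based start
        return "".join(seq[p1 - 1 : p1 + 2])

    def resample_codon(p1: int) -> bool:
        free = [i for i in range(p1 - 1, p1 + 2) if 0 <= i < n and not fixed[i]]
        if not free:
            return False
        for i in free:
            seq[i] = str(rng.choice(_BASES))
        return True

    for _ in range(200):
        bad: list[int] = []
        # ORF1 frame: stop-free body
        for p in range(params.orf1_start, params.orf1_end - 3, 3):
            if codon(p) in STOP_CODONS:
                bad.append(p)
        # post-shift frame: stop-free and AUG-free from the heptamer 3' end
        # up to (not including) the ORF2 start codon
        for p in range(params.slip_end, params.orf2_start - 2, 3):
            c = codon(p)
            if c in STOP_CODONS or c == "AUG":
                bad.append(p)
        # ORF2 frame: stop-free body
        for p in range(params.orf2_start, params.orf2_end - 3, 3):
            if codon(p) in STOP_CODONS:
                bad.append(p)
        # 5' UTR: no AUG in the ORF1 frame
        for p in range(params.orf1_start - 3, 0, -3):
            if p + 2 <= params.utr5_len and codon(p) == "AUG":
                bad.append(p)
        if not bad:
            # stems must not be extendable by flanking accidental pairs
            pk = _planted_pseudoknot(params)
            s1a0 = pk.stem1[0][0]
            s1b1 = pk.stem1[0][1]
            s2b1 = pk.stem2[0][1]
            fixes = []  # 1-based free positions whose char enables stem extension
            if (seq[s1a0 - 2], seq[s1b1]) in _PAIRABLE:
                fixes.append(s1a0 - 1)
            if s2b1 < n and (seq[pk.stem2[0][0] - 2], seq[s2b1]) in _PAIRABLE:
                fixes.append(s2b1 + 1)
            if not fixes:
                return True
            for pos1 in fixes:
                if fixed[pos1 - 1]:
                    return False
                seq[pos1 - 1] = "C"  # C breaks pairing with A and never forms a stop/AUG
            continue
        for p in bad:
            if not resample_codon(p):
                return False
    return False


def _recovered_exactly(genome: GenomeRecord, params: GenomeParams, verify_pk: bool) -> bool:
    orfs = find_orfs(genome, min_aa=params.min_aa)
    if len(orfs) != 2:
        return False
    o1, o2 = orfs
    if (o1.start, o1.end) != (params.orf1_start, params.orf1_end):
        return False
    if (o2.start, o2.end) != (params.orf2_start, params.orf2_end):
        return False
    sites = scan_slippery(genome, o1, max_upstream=200)
    if len(sites) != 1 or sites[0].interval != Interval(params.slip_start, params.slip_end):
        return False
    if verify_pk:
        window = Interval(params.slip_end + 1, min(params.slip_end + 120, params.orf1_end))
        pks = find_pseudoknots(genome, window)
        planted = _planted_pseudoknot(params)
        if not pks:
            return False
        top = pks[0]
        if top.span != planted.span or set(top.stem1) != set(planted.stem1) or set(
            top.stem2
        ) != set(planted.stem2):
            return False
    return True


def _build_truth(params: GenomeParams, seed: int) -> SyntheticTruth:
    pk = _planted_pseudoknot(params)
    genome_truth = {
        "genome_id": params.genome_id,
        "genome_length": params.genome_length,
        "utr5": [1, params.orf1_start - 1] if params.utr5_len else None,
        "orf1": [params.orf1_start, params.orf1_end],
        "intergenic": [params.orf1_end + 1, params.orf2_start - 1],
        "orf2": [params.orf2_start, params.orf2_end],
        "utr3": [params.orf2_end + 1, params.genome_length] if params.utr3_len else None,
        "slippery": [params.slip_start, params.slip_end],
        "slippery_heptamer": params.slippery_heptamer,
        "spacer_len": params.spacer_len,
        "pk_span": [params.pk_start, params.pk_end],
        "pk_stem1": [list(p) for p in pk.stem1],
        "pk_stem2": [list(p) for p in pk.stem2],
        "pk_loops": list(params.loop_lens),
        "fusion_len_aa": params.fusion_len_aa,
        "gdd_protein_pos": params.gdd_protein_pos,
        "his_protein_pos": params.his_protein_pos,
    }
    return SyntheticTruth(seed=seed, genome=genome_truth)


# --- host genome ----------------------------------------------------------

def make_host_genome(length: int, gc: float = 0.5, seed: int = 0,
                     genome_id: str = "synthetic_host") -> GenomeRecord:
    """i.i.d. background sequence at the requested GC content."""
    if length < 1000:
        raise ValueError("host genome length must be >= 1 kb")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    return GenomeRecord(id=genome_id, sequence=seq)


# --- small-RNA reads ------------------------------------------------------

DEFAULT_LENGTH_WEIGHTS: dict[int, int] = {
    length: counts[0] for length, counts in published.SRNA_COUNTS_GCTV2.items()
}


def make_srna_reads(
    targets: Sequence[GenomeRecord],
    n_reads: int,
    perfect_fraction: float,
    seed: int = 0,
    *,
    length_weights: Optional[dict[int, float]] = None,
    minus_fraction: float = 0.5,
    target_weights: Optional[Sequence[float]] = None,
    read_prefix: str = "sr",
    verify: bool = True,
) -> tuple[list[SrnaRead], SyntheticTruth]:
    """Reads sampled from ``targets`` with exactly 0 or 1 planted substitutions.

    With ``verify=True`` (default) each read is checked against its origin
    target and redrawn if its true minimum mismatch count differs from the
    planted one (e.g. a mutated read matching elsewhere perfectly), so the
    truth records are exact by construction.
    """
    if not 0.0 <= perfect_fraction <= 1.0:
        raise ValueError("perfect_fraction must be in [0, 1]")
    if not 0.0 <= minus_fraction <= 1.0:
        raise ValueError("minus_fraction must be in [0, 1]")
    weights = length_weights or DEFAULT_LENGTH_WEIGHTS
    lengths = np.array(sorted(weights))
    if int(lengths.min()) < 10:
        raise ValueError("read lengths must be >= 10 nt")
    lprobs = np.array([weights[int(l)] for l in lengths], dtype=float)
    lprobs /= lprobs.sum()
    tw = np.ones(len(targets)) if target_weights is None else np.asarray(target_weights, float)
    tw = tw / tw.sum()
    max_len = int(lengths.max())
    for t in targets:
        if max_len > t.length:
            raise ValueError(f"read length {max_len} exceeds target {t.id} length {t.length}")

    rng = np.random.default_rng(seed)
    mappers = {t.id: ReadMapper(t) for t in targets} if verify else {}
    reads: list[SrnaRead] = []
    truth_rows: list[dict] = []
    for i in range(n_reads):
        planted_mm = 0 if rng.random() < perfect_fraction else 1
        for _ in range(50):
            target = targets[int(rng.choice(len(targets), p=tw))]
            L = int(rng.choice(lengths, p=lprobs))
            pos = int(rng.integers(0, target.length - L + 1))  # 0-based
            strand = "-" if rng.random() < minus_fraction else "+"
            frag = target.sequence[pos : pos + L]
            if strand == "-":
                frag = reverse_complement(frag)
            if planted_mm == 1:
                mut_at = int(rng.integers(0, L))
                old = frag[mut_at]
                new = str(rng.choice([b for b in "ACGU" if b != old]))
                frag = frag[:mut_at] + new + frag[mut_at + 1 :]
            read = SrnaRead(id=f"{read_prefix}{i}", sequence=frag)
            if not verify:
                break
            res = mappers[target.id].map_read(read, max_mm=1)
            if res.mapped and res.mismatches == planted_mm:
                break
        else:
            raise SyntheticDataError(f"could not realize planted mismatch count for read {i}")
        reads.append(read)
        truth_rows.append(
            {
                "read_id": read.id,
                "target_id": target.id,
                "position": pos + 1,
                "strand": strand,
                "length": L,
                "mismatches": planted_mm,
            }
        )
    return reads, SyntheticTruth(seed=seed, reads=truth_rows)
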
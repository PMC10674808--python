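"""Mismatch-tolerant small-RNA read mapping and length/mismatch profiling.

Matching is exact Hamming distance over the RNA alphabet on both strands
(reverse complement is A<->U / G<->C; G·U wobble is NOT a match).  A read is
mapped to a target iff some placement has at most ``max_mm`` mismatches; the
reported count is the minimum over all placements, preferring the plus
strand and then the smallest 1-based target position among ties.

Profiles follow the published table layout: one row per read length
10..30 plus a pooled ">30" row, with total / perfect-match / one-mismatch
counts per target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import GenomeRecord, SrnaRead, reverse_complement
from .orfs import round_half_up

MIN_LENGTH = 10
MAX_BINNED_LENGTH = 30
USRNA_RANGE = (13, 19)
SIRNA_RANGE = (20, 24)

_ENC = {c: i for i, c in enumerate("ACGUN")}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    target_id: str
    mapped: bool
    position: Optional[int] = None  # 1-based start on target, plus-strand coords
    strand: Optional[str] = None
    mismatches: Optional[int] = None


class ReadMapper:
    """Vectorized exhaustive scanner for one target (both strands)."""

    def __init__(self, target: GenomeRecord):
        self.target = target
        self._fwd = _encode(target.sequence)
        self._rev = _encode(reverse_complement(target.sequence))

    def map_read(self, read: SrnaRead, max_mm: int = 1) -> MappingResult:
        L = read.length
        n = self.target.length
        if L > n:
            raise ValueError(f"read {read.id!r} ({L} nt) longer than target ({n} nt)")
        q = _encode(read.sequence)

        fwd_mm = self._mismatch_counts(self._fwd, q)
        rev_mm = self._mismatch_counts(self._rev, q)
        best_fwd = int(fwd_mm.min())
        best_rev = int(rev_mm.min())
        best = min(best_fwd, best_rev)
        if best > max_mm:
            return MappingResult(read.id, self.target.id, mapped=False)
        if best_fwd <= best_rev:  # plus strand preferred on ties
            offset = int(np.argmin(fwd_mm))  # first occurrence = smallest position
            return MappingResult(read.id, self.target.id, True, offset + 1, "+", best_fwd)
        # minus strand: rev offset o covers target positions n-o-L+1 .. n-o
        offsets = np.flatnonzero(rev_mm == best_rev)
        o = int(offsets.max())  # smallest target position
        return MappingResult(read.id, self.target.id, True, n - o - L + 1, "-", best_rev)

    def _mismatch_counts(self, enc: np.ndarray, q: np.ndarray) -> np.ndarray:
        windows = np.lib.stride_tricks.sliding_window_view(enc, len(q))
        # N (sentinel for masked ambiguity) never matches
        mism = (windows != q) | (windows == ord("N")) | (q == ord("N"))
        return mism.sum(axis=1)


def map_read(read: SrnaRead, target: GenomeRecord, max_mm: int = 1) -> MappingResult:
    return ReadMapper(target).map_read(read, max_mm=max_mm)


# --- Profiles -------------------------------------------------------------

def _length_bins() -> list:
    return list(range(MIN_LENGTH, MAX_BINNED_LENGTH + 1)) + [">30"]


def _bin_of(length: int):
    return length if length <= MAX_BINNED_LENGTH else ">30"


@dataclass
class LengthProfile:
    """Per-length x mismatch-class table for one target."""

    target_id: str
    table: pd.DataFrame  # index: 10..30, ">30"; columns: total, perfect_match, one_mismatch

    @classmethod
    def empty(cls, target_id: str) -> "LengthProfile":
        table = pd.DataFrame(
            0,
            index=pd.Index(_length_bins(), name="length"),
            columns=["total", "perfect_match", "one_mismatch"],
            dtype=np.int64,
        )
        return cls(target_id=target_id, table=table)

    @classmethod
    def from_counts(cls, target_id: str, counts: dict) -> "LengthProfile":
        """Build from {length: (total, perfect, one_mismatch)} fixture data."""
        prof = cls.empty(target_id)
        for length, (tot, perf, one) in counts.items():
            prof.table.loc[_bin_of(length) if isinstance(length, int) else length] = (tot, perf, one)
        prof.validate()
        return prof

    def add(self, length: int, mismatches: int) -> None:
        row = _bin_of(length)
        self.table.loc[row, "total"] += 1
        col = "perfect_match" if mismatches == 0 else "one_mismatch"
        self.table.loc[row, col] += 1

    def validate(self) -> None:
        t = self.table
        if not (t["total"] == t["perfect_match"] + t["one_mismatch"]).all():
            raise ValueError(f"profile for {self.target_id}: total != perfect + one_mismatch")

    @property
    def total(self) -> int:
        return int(self.table["total"].sum())

    @property
    def perfect_total(self) -> int:
        return int(self.table["perfect_match"].sum())

    @property
    def one_mismatch_total(self) -> int:
        return int(self.table["one_mismatch"].sum())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.loc["Total"] = out.sum()
        out.to_csv(path, sep="\t")


def build_profile(
    reads: Sequence[SrnaRead],
    targets: Sequence[GenomeRecord],
    max_mm: int = 1,
    *,
    min_length: int = MIN_LENGTH,
) -> dict[str, LengthProfile]:
    """Map every read against every target; per-target length/mismatch table.

    Reads shorter than ``min_length`` are discarded before mapping.  A read
    is counted once per target it maps to (at its minimum mismatch count).
    """
    profiles = {t.id: LengthProfile.empty(t.id) for t in targets}
    mappers = [ReadMapper(t) for t in targets]
    for read in reads:
        if read.length < min_length:
            continue
        for mapper in mappers:
            if read.length > mapper.target.length:
                continue
            res = mapper.map_read(read, max_mm=max_mm)
            if res.mapped:
                profiles[mapper.target.id].add(read.length, res.mismatches)
    for p in profiles.values():
        p.validate()
    return profiles


def fraction_perfect(profile: LengthProfile) -> float:
    """Percent of mapped reads with zero mismatches, 2 decimals, half-up."""
    if profile.total == 0:
        raise ValueError(f"profile for {profile.target_id} is empty; fraction undefined")
    return round_half_up(100.0 * profile.perfect_total / profile.total, 2)


def classify_lengths(profile: LengthProfile) -> dict:
    """usRNA (13-19 nt) / siRNA (20-24 nt) / other counts, modal length, and
    per-length totals suitable for a log-scale histogram."""
    t = profile.table["total"]
    us = si = other = 0
    for row, count in t.items():
        length = MAX_BINNED_LENGTH + 1 if row == ">30" else int(row)
        c = int(count)
        if USRNA_RANGE[0] <= length <= USRNA_RANGE[1]:
            us += c
        elif SIRNA_RANGE[0] <= length <= SIRNA_RANGE[1]:
            si += c
        else:
            other += c
    nonzero = t[t > 0]
    modal = None if nonzero.empty else nonzero.idxmax()
    return {
        "target_id": profile.target_id,
        "usRNA": us,
        "siRNA": si,
        "other": other,
        "modal_length": modal,
        "histogram": {str(k): int(v) for k, v in t.items()},
    }
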
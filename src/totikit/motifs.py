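"""Conserved-residue anchoring in CP/RdRp proteins via pairwise alignment.

Global affine-gap alignment (Gotoh) against packaged reference proteins is
used to transfer known conserved positions — the capsid cap-snatching
histidine and the RdRp motif blocks including GDD — onto query proteins.

A gap run of length k costs ``gap_open + k * gap_extend``.  Traceback
tie-breaking is deterministic: diagonal, then up (gap in reference), then
left (gap in query).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float
    query_to_ref_map: dict[int, int]  # 1-based, match columns only

    def ref_to_query_map(self) -> dict[int, int]:
        return {r: q for q, r in self.query_to_ref_map.items()}


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    query_position: int
    ref_position: Optional[int]
    matched: bool


def _sub_score(matrix, a: str, b: str) -> float:
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        raise ValueError(f"residue pair ({a!r}, {b!r}) not in substitution matrix") from None


def align_global(
    query: str,
    ref: str,
    *,
    query_id: str = "query",
    ref_id: str = "ref",
    sub_matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment under affine gap costs (maximizing score)."""
    if not query or not ref:
        raise ValueError("cannot align an empty sequence")
    matrix = sub_matrix if sub_matrix is not None else _BLOSUM62
    n, m = len(query), len(ref)
    go = gap_open + gap_extend  # cost of opening a 1-long gap

    # state 0 = M (diagonal), 1 = X (up: query residue vs gap), 2 = Y (left)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)

    for i in range(1, n + 1):
        qi = query[i - 1]
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = _sub_score(matrix, qi, ref[j - 1])
            row_m[j] = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) + s
            row_x[j] = max(prev_m[j] - go, prev_x[j] - gap_extend, prev_y[j] - go)
            row_y[j] = max(row_m[j - 1] - go, row_x[j - 1] - go, row_y[j - 1] - gap_extend)

    end_scores = (M[n][m], X[n][m], Y[n][m])
    score = max(end_scores)
    state = end_scores.index(score)  # M preferred, then X (up), then Y (left)

    aq, ar = [], []
    qmap: dict[int, int] = {}
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            aq.append(query[i - 1])
            ar.append(ref[j - 1])
            qmap[i] = j
            s = _sub_score(matrix, query[i - 1], ref[j - 1])
            cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - s
            state = _pick(cands, target)
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            aq.append(query[i - 1])
            ar.append("-")
            cands = (M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend,
                     Y[i - 1][j] - gap_open - gap_extend)
            state = _pick(cands, X[i][j])
            i -= 1
        elif state == 2 and j > 0:
            aq.append("-")
            ar.append(ref[j - 1])
            cands = (M[i][j - 1] - gap_open - gap_extend, X[i][j - 1] - gap_open - gap_extend,
                     Y[i][j - 1] - gap_extend)
            state = _pick(cands, Y[i][j])
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2

    return AlignmentResult(
        query_id=query_id,
        ref_id=ref_id,
        aligned_query="".join(reversed(aq)),
        aligned_ref="".join(reversed(ar)),
        score=score,
        query_to_ref_map=dict(sorted(qmap.items())),
    )


def _pick(cands: tuple[float, float, float], target: float) -> int:
    for k, v in enumerate(cands):  # diagonal, then up, then left
        if abs(v - target) < 1e-9:
            return k
    raise AssertionError("traceback inconsistency")


def anchor_residue(
    query: str,
    ref: str,
    ref_position: int,
    expected_residue: str,
    **align_kwargs,
) -> MotifHit:
    """Transfer a conserved reference position onto the query by alignment.

    If ``ref_position`` aligns to a gap in the query, ``matched`` is False and
    the nearest aligned query residue's position is reported.
    """
    if not 1 <= ref_position <= len(ref):
        raise ValueError(f"ref_position {ref_position} outside reference (1..{len(ref)})")
    aln = align_global(query, ref, **align_kwargs)
    rmap = aln.ref_to_query_map()
    name = f"{expected_residue}-{ref_position}"
    if ref_position in rmap:
        qpos = rmap[ref_position]
        return MotifHit(
            motif_name=name,
            query_position=qpos,
            ref_position=ref_position,
            matched=query[qpos - 1] == expected_residue,
        )
    aligned = sorted(rmap)
    nearest = min(aligned, key=lambda r: (abs(r - ref_position), r)) if aligned else None
    if nearest is None:
        raise ValueError("no aligned columns between query and reference")
    return MotifHit(motif_name=name, query_position=rmap[nearest], ref_position=ref_position, matched=False)


def scan_gdd(
    rdrp: str,
    ref: Optional[str] = None,
    ref_gdd_position: Optional[int] = None,
) -> list[MotifHit]:
    """All GDD tripeptide occurrences; with a reference, the occurrence
    anchored to the reference's GDD (motif-VI region) is flagged matched."""
    hits = []
    canonical_pos = None
    if ref is not None and ref_gdd_position is not None:
        anchor = anchor_residue(rdrp, ref, ref_gdd_position, "G")
        canonical_pos = anchor.query_position if anchor.matched else None
    start = 0
    while True:
        idx = rdrp.find("GDD", start)
        if idx == -1:
            break
        pos = idx + 1
        hits.append(
            MotifHit(
                motif_name="GDD",
                query_position=pos,
                ref_position=ref_gdd_position,
                matched=(canonical_pos == pos) if canonical_pos is not None else True,
            )
        )
        start = idx + 1
    return hits


# --- Packaged references --------------------------------------------------

def load_reference_proteins(role: str) -> dict[str, str]:
    """Packaged CP or RdRp reference proteins (synthetic stand-ins with the
    documented conserved positions; see data/README in the resource dir)."""
    fname = {"cp": "cp_refs.faa", "rdrp": "rdrp_refs.faa"}.get(role)
    if fname is None:
        raise ValueError("role must be 'cp' or 'rdrp'")
    text = resources.files("totikit.data").joinpath(fname).read_text()
    seqs: dict[str, str] = {}
    cur = None
    for line in text.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            seqs[cur] = ""
        elif cur:
            seqs[cur] += line.strip()
    return seqs


def load_reference_motifs() -> list[dict]:
    """Motif table: name, consensus, 1-based position in the first RdRp ref."""
    text = resources.files("totikit.data").joinpath("rdrp_motifs.tsv").read_text()
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


CP_HIS_ANCHORS = {"ScV-LA-CP-standin": 154, "ScV-LBC-CP-standin": 156}
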
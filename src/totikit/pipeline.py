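"""End-to-end orchestration: annotate -> prf-scan -> motif-scan -> srna-profile.

The report is a deterministic function of inputs + config: stages run in a
fixed order, every stage persists its artifacts under the output directory,
and the consolidated JSON report uses sorted keys so reruns are diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .io import GenomeRecord, Interval, read_fasta, read_fastq, write_gff3
from .motifs import CP_HIS_ANCHORS, anchor_residue, load_reference_proteins, scan_gdd
from .orfs import annotate_genome, find_orfs, select_orf_pair
from .prf import PkParams, assemble_prf, find_pseudoknots, fusion_protein, scan_slippery
from .srna import build_profile, classify_lengths, fraction_perfect

log = logging.getLogger("totikit")

_KNOWN_KEYS = {
    "genome_fasta", "reads_fastq", "reads_fasta", "host_fasta", "out_dir", "seed",
    "log_level", "min_aa", "max_upstream", "spacer_bounds", "max_mm", "min_read_length",
    "pk_min_stem", "pk_max_stem", "pk_max_loop1", "pk_max_loop2", "pk_max_loop3",
    "pk_max_span", "pk_max_window",
}


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


@dataclass
class RunConfig:
    genome_fasta: str
    out_dir: str = "totikit_out"
    reads_fastq: Optional[str] = None
    reads_fasta: Optional[str] = None
    host_fasta: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"
    min_aa: int = 100
    max_upstream: int = 200
    spacer_bounds: tuple[int, int] = (1, 30)
    max_mm: int = 1
    min_read_length: int = 10
    pk_params: PkParams = field(default_factory=PkParams)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "genome_fasta" not in raw:
            raise ConfigError("config must set genome_fasta")
        pk_kwargs = {
            k[3:]: raw.pop(k) for k in list(raw) if k.startswith("pk_")
        }
        if "spacer_bounds" in raw:
            sb = tuple(raw["spacer_bounds"])
            if len(sb) != 2 or sb[0] > sb[1] or sb[0] < 0:
                raise ConfigError(f"invalid spacer_bounds {sb}")
            raw["spacer_bounds"] = sb
        cfg = cls(pk_params=PkParams(**pk_kwargs), **raw)
        if cfg.min_aa < 1:
            raise ConfigError("min_aa must be >= 1")
        if cfg.max_mm < 0:
            raise ConfigError("max_mm must be >= 0")
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "genome_fasta", "reads_fastq", "reads_fasta", "host_fasta", "out_dir",
            "seed", "log_level", "min_aa", "max_upstream", "max_mm", "min_read_length",
        )}
        d["spacer_bounds"] = list(self.spacer_bounds)
        d["pk_params"] = dataclass_to_dict(self.pk_params)
        return d


def dataclass_to_dict(obj) -> dict:
    return {f: getattr(obj, f) for f in obj.__dataclass_fields__}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the consolidated report (also written to disk).

    On a stage failure the report marks the stage failed, downstream stages
    are skipped, and StageFailure is raised after the report is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    report: dict = {
        "provenance": {
            "tool": "totikit",
            "version": __version__,
            "seed": config.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
        },
        "stages": {},
        "genomes": {},
        "srna": {},
    }
    failure: Optional[StageFailure] = None

    genomes = []
    annotations = {}
    try:
        log.info("[annotate] reading %s", config.genome_fasta)
        genomes = read_fasta(config.genome_fasta)
        for genome in genomes:
            orfs = find_orfs(genome, min_aa=config.min_aa)
            orf1, orf2 = select_orf_pair(orfs)
            ann = annotate_genome(genome, orf1, orf2)
            annotations[genome.id] = (genome, ann)
            write_gff3(ann, out / f"{_safe(genome.id)}.gff3")
            report["genomes"][genome.id] = {"annotation": ann.to_dict()}
        _write_annotation_tsv(annotations, out / "annotation.tsv")
        report["stages"]["annotate"] = "ok"
    except Exception as e:  # noqa: BLE001
        report["stages"]["annotate"] = f"failed: {e}"
        failure = StageFailure("annotate", e)

    if failure is None:
        try:
            for gid, (genome, ann) in annotations.items():
                entry = _prf_stage(genome, ann, config)
                report["genomes"][gid]["prf"] = entry
            report["stages"]["prf_scan"] = "ok"
        except Exception as e:  # noqa: BLE001
            report["stages"]["prf_scan"] = f"failed: {e}"
            failure = StageFailure("prf_scan", e)

    if failure is None:
        try:
            cp_refs = load_reference_proteins("cp")
            for gid, (genome, ann) in annotations.items():
                report["genomes"][gid]["motifs"] = _motif_stage(ann, cp_refs)
            report["stages"]["motif_scan"] = "ok"
        except Exception as e:  # noqa: BLE001
            report["stages"]["motif_scan"] = f"failed: {e}"
            failure = StageFailure("motif_scan", e)

    if failure is None and (config.reads_fastq or config.reads_fasta):
        try:
            report["srna"] = _srna_stage(config, genomes, out)
            report["stages"]["srna_profile"] = "ok"
        except Exception as e:  # noqa: BLE001
            report["stages"]["srna_profile"] = f"failed: {e}"
            failure = StageFailure("srna_profile", e)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if failure is not None:
        raise failure
    return report


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def _write_annotation_tsv(annotations, path) -> None:
    cols = ["genome_id", "length", "gc_percent", "orf", "start", "end", "frame",
            "nt_len", "aa_len", "mass_kda"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for gid, (_genome, ann) in annotations.items():
            for name, orf in (("orf1", ann.orf1), ("orf2", ann.orf2)):
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            gid, ann.genome_length, ann.gc_percent, name, orf.start,
                            orf.end, orf.frame, orf.nt_length, orf.protein_length,
                            orf.protein_mass_kda,
                        )
                    )
                    + "\n"
                )


def _prf_stage(genome: GenomeRecord, ann, config: RunConfig) -> dict:
    sites = scan_slippery(genome, ann.orf1, max_upstream=config.max_upstream)
    entry: dict = {"slippery_sites": len(sites), "elements": []}
    best = None
    for site in sites:
        win_end = min(site.interval.end + config.pk_params.max_window, ann.orf1.end)
        if win_end <= site.interval.end + 1:
            continue
        pks = find_pseudoknots(genome, Interval(site.interval.end + 1, win_end), config.pk_params)
        for el in assemble_prf(site, pks, config.spacer_bounds):
            rec = {
                "heptamer": el.slippery.heptamer,
                "slippery_start": el.slippery.interval.start,
                "slippery_end": el.slippery.interval.end,
                "spacer_length": el.spacer_length,
                "pk_span": [el.pseudoknot.span.start, el.pseudoknot.span.end],
                "pk_stem1": [list(p) for p in el.pseudoknot.stem1],
                "pk_stem2": [list(p) for p in el.pseudoknot.stem2],
                "efe_kcal_mol": el.pseudoknot.efe_kcal_mol,
            }
            entry["elements"].append(rec)
            if best is None or el.score < best[0].score:
                best = (el, rec)
    entry["elements"].sort(key=lambda r: r["efe_kcal_mol"])
    if best is not None:
        el, rec = best
        entry["best"] = rec
        fusion = fusion_protein(genome, ann.orf1, el.slippery, ann.orf2)
        entry["fusion"] = {
            "pre_shift_codons": fusion.pre_shift_codons,
            "post_shift_codons": fusion.post_shift_codons,
            "protein_length": fusion.protein_length,
            "mass_kda": fusion.mass_kda,
        }
    return entry


def _motif_stage(ann, cp_refs: dict[str, str]) -> dict:
    out: dict = {"cp_his": [], "gdd": []}
    cp = ann.orf1.protein
    for ref_id, ref_pos in CP_HIS_ANCHORS.items():
        ref = cp_refs[ref_id]
        hit = anchor_residue(cp, ref, ref_pos, "H", ref_id=ref_id)
        out["cp_his"].append(
            {"ref_id": ref_id, "ref_position": ref_pos,
             "query_position": hit.query_position, "matched": hit.matched}
        )
    for hit in scan_gdd(ann.orf2.protein):
        out["gdd"].append({"position": hit.query_position})
    return out


def _srna_stage(config: RunConfig, genomes, out: Path) -> dict:
    if config.reads_fastq:
        reads = read_fastq(config.reads_fastq)
    else:
        reads = [r for r in read_fasta(config.reads_fasta)]
        from .io import SrnaRead

        reads = [SrnaRead(id=r.id, sequence=r.sequence) for r in reads]
    targets = list(genomes)
    if config.host_fasta:
        targets += read_fasta(config.host_fasta)
    profiles = build_profile(
        reads, targets, max_mm=config.max_mm, min_length=config.min_read_length
    )
    result = {}
    for tid, profile in profiles.items():
        profile.to_tsv(out / f"profile_{_safe(tid)}.tsv")
        entry = {
            "total": profile.total,
            "perfect_match": profile.perfect_total,
            "one_mismatch": profile.one_mismatch_total,
            "classes": classify_lengths(profile),
        }
        if profile.total > 0:
            entry["fraction_perfect_pct"] = fraction_perfect(profile)
        result[tid] = entry
    return result
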
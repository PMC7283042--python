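"""Stage orchestration: screen -> circularize -> polish -> re-screen -> metrics.

The orchestrator mirrors a finishing workflow for long-read metagenome
assemblies: an optional externally produced assembly is screened for
unspanned (misassembled) sites and broken, candidate genomes are
circularized, the consensus is polished segment-parallel with short reads,
the final sequences are screened once more for unspanned sites, and summary
metrics are emitted. Heavyweight external steps (assemblers, mergers,
long-read polishers, external edit callers) are delegation points driven by
command templates; the bespoke stages run internally and are seeded, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .core import (
    ContigRecord,
    ReadSet,
    read_alignments,
    read_fasta,
    read_fastq,
    write_fasta,
)
from .mapper import map_reads_anchored
from .misassembly import breaks_to_bed, screen_assembly, windows_to_bed
from .circularize import circularize_contig
from .polish import (
    homopolymer_report,
    polish_assembly,
    read_edits_vcf,
    write_edits_vcf,
)
from .metrics import compute_n50

__all__ = [
    "PipelineConfig",
    "Finding",
    "StageError",
    "ConfigError",
    "validate_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "assembly", "long_reads", "long_read_alignments", "short_reads",
    "bin_qc", "outdir", "seed", "threads", "stages", "misassembly",
    "circularize", "polish", "final_screen", "external",
}
_STAGE_NAMES = ("misassembly", "circularize", "polish", "final_screen",
                "metrics")


class StageError(RuntimeError):
    """An internal stage or delegated external command failed."""


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class Finding:
    level: str  # "error" | "warning"
    message: str


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration (YAML on disk; CLI flags win)."""

    assembly: Optional[str] = None
    long_reads: Optional[str] = None
    long_read_alignments: Optional[str] = None
    short_reads: Optional[str] = None
    bin_qc: Optional[str] = None
    outdir: str = "lathework_out"
    seed: Optional[int] = None
    threads: int = 1
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGE_NAMES})
    misassembly: dict = field(default_factory=dict)
    circularize: dict = field(default_factory=dict)
    polish: dict = field(default_factory=dict)
    final_screen: dict = field(default_factory=dict)
    external: dict = field(default_factory=dict)
    unknown_keys: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"unparseable config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
        cfg = cls(**known)
        cfg.unknown_keys = sorted(set(raw) - _KNOWN_KEYS)
        stages = {s: True for s in _STAGE_NAMES}
        stages.update(known.get("stages") or {})
        cfg.stages = stages
        return cfg

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def validate_config(config: PipelineConfig) -> list[Finding]:
    """Blocking errors and advisory warnings; never mutates the config."""
    findings: list[Finding] = []
    err = lambda m: findings.append(Finding("error", m))  # noqa: E731
    warn = lambda m: findings.append(Finding("warning", m))  # noqa: E731
    for key in config.unknown_keys:
        warn(f"unknown config key {key!r} ignored")
    any_stage = any(config.enabled(s) for s in _STAGE_NAMES)
    if any_stage and not config.assembly:
        err("an assembly FASTA is required")
    elif config.assembly and not Path(config.assembly).exists():
        err(f"assembly not found: {config.assembly}")
    needs_long = config.enabled("misassembly") or config.enabled("final_screen")
    if needs_long and not (config.long_reads or config.long_read_alignments):
        err("misassembly screening requires long reads or alignments")
    for name in ("long_reads", "long_read_alignments", "short_reads", "bin_qc"):
        p = getattr(config, name)
        if p and not Path(p).exists():
            err(f"{name} not found: {p}")
    if config.enabled("polish") and not (
        config.short_reads or config.external.get("edit_caller")
    ):
        warn("polish enabled without short reads or an external edit "
             "caller; the stage will be skipped")
    if config.seed is None and any(
        config.enabled(s) for s in ("polish",)
    ):
        err("a seed is required when stochastic stages are enabled")
    return findings


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_external(template: str, **subst) -> None:
    """Run a delegated external command template (e.g. an assembler or
    long-read polisher); nonzero exit raises StageError with its output."""
    cmd = template.format(**subst)
    proc = subprocess.run(
        shlex.split(cmd), capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise StageError(
            f"external command failed ({proc.returncode}): {cmd}\n"
            f"stdout: {proc.stdout[-2000:]}\nstderr: {proc.stderr[-2000:]}"
        )


def _long_alignments(config, assembly, reads_cache):
    """Alignments of long reads to the *current* assembly."""
    if config.long_reads:
        if "long" not in reads_cache:
            reads_cache["long"] = read_fastq(config.long_reads)
        return map_reads_anchored(reads_cache["long"], assembly), reads_cache["long"]
    alns = read_alignments(config.long_read_alignments, assembly=assembly)
    return alns, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order and return the run manifest.

    The manifest records the package version, per-stage parameters and
    SHA-256 checksums of every output, and is written to
    ``<outdir>/manifest.json``.
    """
    findings = validate_config(config)
    errors = [f.message for f in findings if f.level == "error"]
    if errors:
        raise ConfigError("; ".join(errors))
    for f in findings:
        logger.warning("config: %s", f.message)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "lathework",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    if not any(config.enabled(s) for s in _STAGE_NAMES):
        _write_manifest(manifest, outdir)
        return manifest

    assembly = read_fasta(config.assembly)
    reads_cache: dict[str, ReadSet] = {}

    if config.enabled("misassembly"):
        alns, _ = _long_alignments(config, assembly, reads_cache)
        assembly, windows, breaks = screen_assembly(
            assembly, alns, **config.misassembly
        )
        windows_to_bed(windows, outdir / "misassembly_windows.bed")
        breaks_to_bed(breaks, outdir / "misassembly_breaks.bed")
        write_fasta(assembly, outdir / "assembly_broken.fasta")
        manifest["stages"]["misassembly"] = {
            "params": config.misassembly,
            "n_windows": len(windows),
            "n_flagged": sum(w.flagged for w in windows),
            "n_breaks": len(breaks),
        }

    if config.enabled("circularize"):
        alns = None
        if config.long_reads or config.long_read_alignments:
            try:
                alns, _ = _long_alignments(config, assembly, reads_cache)
            except Exception as exc:  # pre-supplied alignments may not match
                logger.warning("circularize: no usable long alignments (%s)", exc)
        rows = []
        out_contigs = []
        for contig in assembly:
            per_contig = (
                [a for a in alns if a.contig_id == contig.id] if alns else None
            )
            new_contig, result = circularize_contig(
                contig, per_contig, **config.circularize
            )
            out_contigs.append(new_contig)
            rows.append(result)
        assembly = out_contigs
        with open(outdir / "circularize_report.tsv", "w") as fh:
            fh.write("contig\tstatus\ttrimmed_bp\tjunction_pos\tevidence"
                     "\tn_support_reads\n")
            for r in rows:
                fh.write(
                    f"{r.contig_id}\t{r.status}\t{r.trimmed_bp}\t"
                    f"{'' if r.junction_pos is None else r.junction_pos}\t"
                    f"{r.evidence}\t{r.n_support_reads}\n"
                )
        write_fasta(assembly, outdir / "assembly_circularized.fasta")
        manifest["stages"]["circularize"] = {
            "params": config.circularize,
            "n_circular": sum(r.status == "circular" for r in rows),
        }

    if config.enabled("polish"):
        pre_polish = assembly
        if config.external.get("edit_caller"):
            vcf_path = outdir / "external_edits.vcf"
            run_external(
                config.external["edit_caller"],
                assembly=outdir / "polish_input.fasta",
                out=vcf_path,
            )
            edits = read_edits_vcf(vcf_path, assembly)
            result = polish_assembly(
                assembly, [], ReadSet(), external_edits=edits,
                seed=config.seed or 0, **config.polish,
            )
        elif config.short_reads:
            short = read_fastq(config.short_reads)
            alns = map_reads_anchored(short, assembly)
            result = polish_assembly(
                assembly, alns, short, seed=config.seed or 0, **config.polish
            )
        else:
            result = None
            logger.warning("polish skipped: no short reads or edit caller")
        if result is not None:
            assembly = result.polished
            write_fasta(assembly, outdir / "assembly_polished.fasta")
            write_edits_vcf(result.edits, pre_polish,
                            outdir / "polish_edits.vcf")
            homopolymer_report(result.edits).to_csv(
                outdir / "homopolymer_report.tsv", sep="\t", index=False
            )
            manifest["stages"]["polish"] = {
                "params": config.polish,
                "n_edits": len(result.edits),
                "n_segments": len(result.segments),
            }

    if config.enabled("final_screen"):
        alns, _ = _long_alignments(config, assembly, reads_cache)
        assembly, windows, breaks = screen_assembly(
            assembly, alns, **(config.final_screen or config.misassembly)
        )
        breaks_to_bed(breaks, outdir / "final_screen_breaks.bed")
        manifest["stages"]["final_screen"] = {
            "params": config.final_screen or config.misassembly,
            "n_breaks": len(breaks),
        }

    write_fasta(assembly, outdir / "assembly_final.fasta")

    if config.enabled("metrics"):
        lengths = [len(c.seq) for c in assembly]
        stats = {
            "n_contigs": len(assembly),
            "total_bp": sum(lengths),
            "n50": compute_n50(lengths),
            "n_circular": sum(c.circular for c in assembly),
        }
        with open(outdir / "assembly_stats.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in stats.items():
                fh.write(f"{k}\t{v}\n")
        manifest["stages"]["metrics"] = stats

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
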
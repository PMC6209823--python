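"""End-to-end orchestration: simulate/load -> linker-process -> map ->
classify -> association stats, with a run manifest.

Configuration is a YAML mapping with blocks ``simulate`` (or ``inputs``
with genome/reads paths), ``linker``, ``mapping`` and optional ``anchor``;
every stage honours the single top-level ``seed``. The manifest records a
config snapshot, input digests and stage-by-stage read counts, which must
telescope (each stage consumes exactly what the previous stage retained).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .genome import ReferenceGenome
from .simulate import SimulationConfig, simulate_library, ConfigurationError
from .linker import LinkerConfig, process_reads, read_sequences, write_post_linker_fasta
from .mapping import MappingParams, map_reads, write_breakcall_bed
from .breaktypes import ORTable, build_or_table, classify_sample
from .stats import table1_analysis, table2_analysis, write_results_tsv
from .breaktypes import SampleBreakSummary

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "validate_inputs", "load_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a YAML mapping")
    return cfg


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def check_telescoping(self) -> None:
        """Each stage's input count must equal the previous stage's
        retained count."""
        order = ["simulate", "preprocess", "map", "classify"]
        prev_retained = None
        for stage in order:
            counts = self.stage_counts.get(stage)
            if counts is None:
                continue
            if prev_retained is not None and counts["input"] != prev_retained:
                raise AssertionError(
                    f"stage counts do not telescope: {stage} input={counts['input']} "
                    f"!= previous retained={prev_retained}"
                )
            prev_retained = counts["retained"]

    def write_json(self, path) -> None:
        self.check_telescoping()
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "stage_counts": self.stage_counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _linker_config(cfg: dict, sim: SimulationConfig | None) -> LinkerConfig:
    lk = cfg.get("linker", {})
    if "first_linker" in lk:
        return LinkerConfig(
            first_linker=lk["first_linker"],
            unique3_length=int(lk.get("unique3_length", 10)),
            max_linker_mismatches_5prime=int(lk.get("max_linker_mismatches_5prime", 2)),
            second_linker=lk.get("second_linker", ""),
        )
    if sim is None:
        raise ConfigurationError(
            "linker.first_linker is required when reads are not simulated"
        )
    return LinkerConfig(
        first_linker=sim.linker_first,
        unique3_length=len(sim.linker_first_unique),
        second_linker=sim.linker_second,
    )


def run_pipeline(config: dict, outdir) -> Path:
    """Run all stages under ``outdir``; returns the output directory.

    Products: genome.fasta/reads/truth (when simulating), retained post-
    linker FASTA, filter logs, breakcalls.bed, or_table.tsv, summary.json,
    stats.tsv and manifest.json. Deterministic for identical config+seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sample_id = config.get("sample_id", "sample")
    manifest = RunManifest(config=config, seed=seed)

    sim_cfg = None
    if "simulate" in config:
        sim_dict = dict(config["simulate"] or {})
        sim_dict.setdefault("seed", seed)
        sim_cfg = SimulationConfig.from_dict(sim_dict)
        genome, truths = simulate_library(sim_cfg, outdir, config.get("read_format", "fastq"))
        reads_path = outdir / f"reads.{config.get('read_format', 'fastq')}"
        genome_path = outdir / "genome.fasta"
        manifest.stage_counts["simulate"] = {"input": len(truths), "retained": len(truths)}
    elif "inputs" in config:
        genome_path = Path(config["inputs"]["genome"])
        reads_path = Path(config["inputs"]["reads"])
        genome = ReferenceGenome.from_fasta(genome_path)
    else:
        raise ConfigurationError("config needs a 'simulate' or 'inputs' block")
    manifest.input_digests = {
        "genome": _digest(genome_path),
        "reads": _digest(reads_path),
    }

    linker_cfg = _linker_config(config, sim_cfg)
    reads = list(read_sequences(reads_path))
    retained, flog = process_reads(reads, linker_cfg)
    write_post_linker_fasta(retained, outdir / "post_linker.fasta")
    flog.write_tsv(outdir / "linker_filter_log.tsv")
    manifest.stage_counts["preprocess"] = {
        "input": len(reads),
        "retained": len(retained),
        **{f"dropped_{k}": v for k, v in flog.counts.items() if k != "retained"},
    }

    map_block = config.get("mapping", {})
    params = MappingParams(
        min_align_length=int(map_block.get("min_align_length", 20)),
        min_identity=float(map_block.get("min_identity", 0.95)),
        seed_k=int(map_block.get("seed_k", 12)),
    )
    calls, mlog = map_reads(retained, genome, params)
    write_breakcall_bed(calls, outdir / "breakcalls.bed")
    mlog.write_tsv(outdir / "mapping_filter_log.tsv")
    manifest.stage_counts["map"] = {
        "input": len(retained),
        "retained": len(calls),
        **{f"dropped_{k}": v for k, v in mlog.counts.items() if k != "mapped"},
    }

    anchor_block = config.get("anchor", {})
    if anchor_block.get("or_table"):
        or_table = ORTable.read_tsv(anchor_block["or_table"], anchor_block.get("sample_id", ""))
    else:
        # this sample is its own anchor (the designated wild type)
        or_table = build_or_table(calls, genome.kmer_background, sample_id)
    or_table.write_tsv(outdir / "or_table.tsv")
    summary = classify_sample(calls, or_table, sample_id)
    summary.write_json(outdir / "summary.json")
    manifest.stage_counts["classify"] = {
        "input": len(calls),
        "retained": summary.retained_total,
        "dropped_no-prior4-class": summary.n_excluded,
    }

    results = [table2_analysis(summary)]
    if anchor_block.get("summary"):
        anchor_summary = SampleBreakSummary.read_json(anchor_block["summary"])
        results = table1_analysis([summary], anchor_summary) + results
    write_results_tsv(results, outdir / "stats.tsv")

    manifest.write_json(outdir / "manifest.json")
    return outdir


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.errors)


_SEQ_ALPHABET = frozenset("ACGTNacgtn")


def _validate_fasta(path, report: ValidationReport) -> None:
    n_records = 0
    with open(path) as fh:
        seq_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if n_records and not seq_seen:
                    report.errors.append(f"{path}:{lineno}: record with no sequence")
                n_records += 1
                seq_seen = False
            elif n_records == 0:
                report.errors.append(f"{path}:{lineno}: sequence before first header")
                return
            else:
                seq_seen = True
                if not set(line) <= _SEQ_ALPHABET:
                    report.errors.append(f"{path}:{lineno}: non-nucleotide characters")
    if n_records == 0:
        report.errors.append(f"{path}: no FASTA records")


def _validate_fastq(path, report: ValidationReport) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        report.errors.append(f"{path}: empty FASTQ")
        return
    if len(lines) % 4 != 0:
        report.errors.append(f"{path}: line count {len(lines)} is not a multiple of 4")
    for i in range(0, len(lines) - len(lines) % 4, 4):
        head, seq, plus, qual = lines[i : i + 4]
        name = head[1:].split()[0] if len(head) > 1 else f"record at line {i + 1}"
        if not head.startswith("@"):
            report.errors.append(f"{path}:{i + 1}: header does not start with '@'")
        if not plus.startswith("+"):
            report.errors.append(f"{path}:{i + 3}: separator does not start with '+'")
        if len(seq) != len(qual):
            report.errors.append(
                f"{path}:{i + 2}: record {name!r} sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )


def validate_inputs(
    genome: str | None = None,
    reads: str | None = None,
    config: dict | None = None,
) -> ValidationReport:
    """Check FASTA/FASTQ well-formedness, linker alphabet and config
    ranges; malformed records are enumerated with line numbers."""
    report = ValidationReport()
    if genome is not None:
        _validate_fasta(genome, report)
    if reads is not None:
        with open(reads) as fh:
            first = fh.readline()
        if first.startswith("@"):
            _validate_fastq(reads, report)
        else:
            _validate_fasta(reads, report)
    if config is not None:
        if "simulate" in config:
            try:
                sim = dict(config["simulate"] or {})
                sim.setdefault("seed", int(config.get("seed", 0)))
                SimulationConfig.from_dict(sim).validate()
            except (ConfigurationError, TypeError) as exc:
                report.errors.append(f"simulate config: {exc}")
        lk = config.get("linker", {})
        for key in ("first_linker", "second_linker"):
            value = lk.get(key, "")
            if value and not set(value.upper()) <= set("ACGT"):
                report.errors.append(f"linker.{key}: non-ACGT characters")
    return report
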
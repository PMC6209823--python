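"""Synthetic break-capture libraries with ground truth.

Emulates linker-mediated capture of endogenous DNA double-strand breaks:
each break end is ligated to a first linker (primer segment + unique 3'
segment), the fragment runs from the break to the first downstream RsaI
site (GT^AC, blunt), and a second linker is ligated to the RsaI-cut end.
The emitted read is therefore

    [first linker][optional inserted sequence][genomic fragment][second linker]

on the strand of the break, and the whole construct is sequenced in a
uniformly random orientation (adapters ligate to either end), so downstream
strand determination is genuinely exercised.

Breaks are sampled with probability proportional to a configurable weight
on the 4-mer immediately 5' of the break ("prior 4-mer"), which is how a
sequence-biased, non-random break landscape is emulated. A configurable
fraction of reads carries an inserted sequence at the break (a modified end
with insertion, MIB), and a configurable fraction has its first-linker 3'
end corrupted so the intact-linker filter has something to reject.

Truth canonicalization
----------------------
When the 3' end of a randomly drawn insert happens to match the reference
immediately upstream of the break, the generated (insert, break position)
pair is not identifiable from the read: any score-maximising local aligner
will absorb the matching bases into the alignment. Truth records are
therefore canonicalized at generation time to the maximal-alignment
representation (the read sequence itself is untouched): trailing insert
bases are merged into the fragment whenever doing so strictly increases a
gapless +1/-2 alignment score. This is a property of break-capture data,
not of any particular aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import ReferenceGenome, reverse_complement

logger = logging.getLogger(__name__)

BASES = "ACGT"
RSAI_SITE = "GTAC"

# Default linker pair: 5' primer segment + unique 3' segment (first linker),
# and the linker ligated to the RsaI-cut far end (second linker). Neither
# contains an RsaI site (the enzyme must not cut within the linkers).
DEFAULT_FIRST_LINKER_PRIMER = "GCGGTGACCCGGGAGATCT"
DEFAULT_FIRST_LINKER_UNIQUE = "CATGTTAGGC"
DEFAULT_SECOND_LINKER = "AGGTCTAGAGTCGACCTGCAGG"

TRUTH_COLUMNS = (
    "read_id",
    "chrom",
    "break_pos",
    "strand",
    "prior4",
    "insertion",
    "linker_intact",
)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass
class SimulationConfig:
    """Conditions of a synthetic break-capture experiment.

    Defaults describe a single 50 kb chromosome at yeast-like GC content
    (0.38), 5000 captured breaks, a wild-type-like MIB fraction (0.15,
    matching the share of insertion-bearing reads among retained wild-type
    breaks), error-free sequencing and a 10% corrupted-linker fraction.
    """

    genome_length: int = 50_000
    n_chromosomes: int = 1
    gc_fraction: float = 0.38
    n_reads: int = 5000
    enriched_4mers: dict[str, float] = field(default_factory=dict)
    mib_rate: float = 0.15
    insert_length_range: tuple[int, int] = (1, 20)
    linker_first_primer: str = DEFAULT_FIRST_LINKER_PRIMER
    linker_first_unique: str = DEFAULT_FIRST_LINKER_UNIQUE
    linker_second: str = DEFAULT_SECOND_LINKER
    corrupt_linker_rate: float = 0.10
    error_rate: float = 0.0
    seed: int = 0

    @property
    def linker_first(self) -> str:
        return self.linker_first_primer + self.linker_first_unique

    def validate(self) -> None:
        probs = {
            "gc_fraction": self.gc_fraction,
            "mib_rate": self.mib_rate,
            "corrupt_linker_rate": self.corrupt_linker_rate,
            "error_rate": self.error_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} is not a probability in [0, 1]")
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ConfigurationError("genome_length and n_chromosomes must be positive")
        if self.n_reads < 0:
            raise ConfigurationError("n_reads must be non-negative")
        lo, hi = self.insert_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(f"invalid insert_length_range {self.insert_length_range}")
        if len(self.linker_first_unique) < 8:
            raise ConfigurationError("first-linker unique 3' segment must be >= 8 bases")
        for kmer, w in self.enriched_4mers.items():
            if len(kmer) != 4 or any(b not in BASES for b in kmer):
                raise ConfigurationError(f"enriched 4-mer {kmer!r} is not a 4-mer over ACGT")
            if w <= 0:
                raise ConfigurationError(f"enriched 4-mer weight must be positive, got {w}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["insert_length_range"] = list(self.insert_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "insert_length_range" in d:
            d["insert_length_range"] = tuple(d["insert_length_range"])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth for one simulated read.

    ``break_pos`` is the 0-based reference coordinate of the first captured
    base (the break sits immediately 5' of it on ``strand``); ``prior4`` is
    the 4 reference bases immediately 5' of the break on the break strand.
    """

    read_id: str
    chrom: str
    break_pos: int
    strand: str
    prior4: str
    insertion: str
    linker_intact: bool

    @property
    def is_mib(self) -> bool:
        return bool(self.insertion)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> ReferenceGenome:
    """Draw i.i.d. chromosome sequences at the configured GC fraction.

    Each chromosome is guaranteed to contain at least one RsaI site
    (redrawn otherwise) so that capture fragments terminate properly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    sequences: dict[str, str] = {}
    for i in range(config.n_chromosomes):
        for attempt in range(100):
            draw = rng.choice(base_arr, size=config.genome_length, p=p)
            seq = draw.tobytes().decode()
            if RSAI_SITE in seq or config.genome_length < len(RSAI_SITE):
                break
        else:  # pragma: no cover - essentially impossible at default settings
            logger.warning("chromosome %d drawn without an RsaI site after 100 tries", i)
        sequences[f"chr{i + 1}"] = seq
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# break sampling
# ---------------------------------------------------------------------------


def _prior4_at(seq: str, pos: int, strand: str) -> str | None:
    """4-mer immediately 5' of the break at ``pos`` on ``strand``; None if
    the window runs off the chromosome end."""
    if strand == "+":
        if pos < 4:
            return None
        return seq[pos - 4 : pos]
    if pos + 4 > len(seq) - 1:
        return None
    return reverse_complement(seq[pos + 1 : pos + 5])


def eligible_break_sites(genome: ReferenceGenome) -> list[tuple[str, int, str, str]]:
    """All (chrom, pos, strand, prior4) with a full prior 4-mer.

    On the + strand the captured fragment starts at ``pos`` and runs right;
    on the - strand it starts at ``pos`` and runs left (read 5'->3' on the
    minus strand). Positions without 4 upstream bases on the break strand
    are excluded.
    """
    sites = []
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        for pos in range(4, L):
            sites.append((chrom, pos, "+", seq[pos - 4 : pos]))
        for pos in range(0, L - 4):
            sites.append((chrom, pos, "-", reverse_complement(seq[pos + 1 : pos + 5])))
    return sites


def _canonical_shift(seq: str, pos: int, strand: str, insert: str) -> tuple[int, str]:
    """Merge trailing insert bases into the fragment when a gapless +1/-2
    local aligner would absorb them (see module docstring).

    Returns the canonical (break position, insert). The shift never crosses
    the point where the prior 4-mer would run off the chromosome.
    """
    m = len(insert)
    best_j, best_score, score = 0, 0, 0
    for j in range(1, m + 1):
        if strand == "+":
            ref_pos = pos - j
            if ref_pos < 4:
                break
            ref_base = seq[ref_pos]
            ins_base = insert[m - j]
        else:
            ref_pos = pos + j
            if ref_pos + 4 > len(seq) - 1:
                break
            ref_base = reverse_complement(seq[ref_pos])
            ins_base = insert[m - j]
        score += 1 if ins_base == ref_base else -2
        if score > best_score:
            best_score, best_j = score, j
    if best_j == 0:
        return pos, insert
    new_pos = pos - best_j if strand == "+" else pos + best_j
    return new_pos, insert[: m - best_j]


def simulate_breaks(
    genome: ReferenceGenome, config: SimulationConfig
) -> list[TruthRecord]:
    """Sample break sites weighted by their prior 4-mer.

    Each eligible position/strand gets weight ``enriched_4mers[prior4]``
    (1.0 if unlisted); sites are drawn with replacement proportionally to
    weight. MIB status, insert sequence and linker intactness are decided
    here so the truth table fully describes the library.
    """
    config.validate()
    if genome.total_length == 0 or len(genome) == 0:
        raise ValueError("empty genome")
    if config.n_reads == 0:
        return []
    sites = eligible_break_sites(genome)
    if not sites:
        raise ValueError("genome has no eligible break sites (chromosomes too short)")
    weights = np.array(
        [config.enriched_4mers.get(p4, 1.0) for (_, _, _, p4) in sites], dtype=float
    )
    rng = np.random.default_rng(config.seed + 1)
    idx = rng.choice(len(sites), size=config.n_reads, p=weights / weights.sum())

    lo, hi = config.insert_length_range
    truths: list[TruthRecord] = []
    for i, site_i in enumerate(idx):
        chrom, pos, strand, p4 = sites[site_i]
        seq = genome[chrom]
        insert = ""
        if rng.random() < config.mib_rate:
            length = int(rng.integers(lo, hi + 1))
            insert = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
            pos, insert = _canonical_shift(seq, pos, strand, insert)
            p4 = _prior4_at(seq, pos, strand)
        intact = rng.random() >= config.corrupt_linker_rate
        truths.append(
            TruthRecord(
                read_id=f"read{i:06d}",
                chrom=chrom,
                break_pos=pos,
                strand=strand,
                prior4=p4,
                insertion=insert,
                linker_intact=intact,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------


def capture_fragment(seq: str, pos: int, strand: str) -> tuple[str, bool]:
    """Genomic fragment from the break to the first downstream RsaI cut.

    RsaI recognizes GTAC and cuts blunt between T and A, so fragments end
    in ``GT`` (on either strand — the site is palindromic). Returns
    (fragment on the read strand, whether the fragment ran to the
    chromosome end because no site was found).
    """
    if strand == "+":
        i = seq.find(RSAI_SITE, pos)
        if i == -1:
            return seq[pos:], True
        return seq[pos : i + 2], False
    j = seq.rfind(RSAI_SITE, 0, pos + 1)
    if j == -1:
        return reverse_complement(seq[: pos + 1]), True
    return reverse_complement(seq[j + 2 : pos + 1]), False


def _mutate_base(base: str, rng) -> str:
    choices = [b for b in BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def _apply_errors(fragment: str, error_rate: float, rng) -> str:
    if error_rate <= 0 or not fragment:
        return fragment
    out = list(fragment)
    hits = np.nonzero(rng.random(len(out)) < error_rate)[0]
    for h in hits:
        out[h] = _mutate_base(out[h], rng)
    return "".join(out)


def _corrupt_linker(linker: str, downstream: str, unique3: str, rng) -> str:
    """Damage the linker 3' end: truncate 1-3 bases or mutate the last base.

    A truncation whose missing bases are coincidentally restored by the
    start of ``downstream`` would be indistinguishable from an intact
    linker at a shifted break, so such corruptions are redrawn: the truth
    table's ``linker_intact`` flag must describe what the read shows.
    """
    for _ in range(50):
        if rng.random() < 0.5:
            n = int(rng.integers(1, 4))
            damaged = linker[:-n]
        else:
            damaged = linker[:-1] + _mutate_base(linker[-1], rng)
        if unique3 not in damaged + downstream:
            return damaged
    return linker[:-1] + _mutate_base(linker[-1], rng)  # pragma: no cover


def simulate_reads(
    genome: ReferenceGenome,
    truths: list[TruthRecord],
    config: SimulationConfig,
    reads_path,
    truth_path,
    read_format: str = "fastq",
) -> None:
    """Emit the read file and the matching truth table.

    Substitution errors apply to the genomic portion only. Reads whose
    fragment runs to a chromosome end (no downstream RsaI site) are still
    emitted, with a log message. Output is byte-identical for identical
    (genome, truths, config).
    """
    if read_format not in ("fastq", "fasta"):
        raise ConfigurationError(f"read_format must be fastq or fasta, got {read_format!r}")
    rng = np.random.default_rng(config.seed + 2)
    linker = config.linker_first
    n_runoff = 0
    with open(reads_path, "w") as rf, open(truth_path, "w") as tf:
        tf.write(f"# rindseq truth table, seed={config.seed}\n")
        tf.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fragment, runoff = capture_fragment(genome[t.chrom], t.break_pos, t.strand)
            n_runoff += runoff
            fragment = _apply_errors(fragment, config.error_rate, rng)
            if t.linker_intact:
                lk = linker
            else:
                downstream = t.insertion + fragment + config.linker_second
                lk = _corrupt_linker(
                    linker, downstream, config.linker_first_unique, rng
                )
            construct = lk + t.insertion + fragment + config.linker_second
            if rng.random() < 0.5:
                construct = reverse_complement(construct)
            if read_format == "fastq":
                rf.write(f"@{t.read_id}\n{construct}\n+\n{'I' * len(construct)}\n")
            else:
                rf.write(f">{t.read_id}\n{construct}\n")
            tf.write(
                "\t".join(
                    [
                        t.read_id,
                        t.chrom,
                        str(t.break_pos),
                        t.strand,
                        t.prior4 or ".",
                        t.insertion or ".",
                        "1" if t.linker_intact else "0",
                    ]
                )
                + "\n"
            )
    if n_runoff:
        logger.info("%d fragments ran to a chromosome end (no downstream RsaI site)", n_runoff)


def read_truth_table(path) -> list[TruthRecord]:
    """Parse a truth TSV written by :func:`simulate_reads`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("read_id\t"):
                continue
            rid, chrom, pos, strand, p4, ins, intact = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    read_id=rid,
                    chrom=chrom,
                    break_pos=int(pos),
                    strand=strand,
                    prior4="" if p4 == "." else p4,
                    insertion="" if ins == "." else ins,
                    linker_intact=intact == "1",
                )
            )
    return out


def simulate_library(
    config: SimulationConfig, outdir, read_format: str = "fastq"
) -> tuple[ReferenceGenome, list[TruthRecord]]:
    """Convenience wrapper: genome + breaks + reads into ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    genome.to_fasta(outdir / "genome.fasta", description=f"seed={config.seed}")
    truths = simulate_breaks(genome, config)
    ext = "fastq" if read_format == "fastq" else "fasta"
    simulate_reads(
        genome, truths, config, outdir / f"reads.{ext}", outdir / "truth.tsv", read_format
    )
    return genome, truths
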
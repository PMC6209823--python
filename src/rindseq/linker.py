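"""First-linker handling: strand determination, the intact-3'-end filter,
and extraction of the post-linker (break-proximal) sequence.

The first linker has two parts: a 5' primer segment shared with the
amplification primer, and a unique 3' segment whose last base abuts the
break. Only reads in which the linker's 3' end is intact testify to a real
break junction (PCR heterogeneity otherwise produces spurious 5' ends), so
the filter demands an exact match of the final ``unique3_length`` bases;
the primer segment tolerates a small number of mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import edlib
from Bio import SeqIO

from .genome import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "LinkerConfig",
    "BreakRead",
    "FilterLog",
    "determine_strand",
    "extract_post_linker",
    "process_reads",
    "read_sequences",
]

AS_IS = "as-is"
REVCOMP = "reverse-complement"
UNDETERMINED = "undetermined"

RETAINED = "retained"
NOT_INTACT = "not-intact"
NO_LINKER = "no-linker"

# minimum suffix/prefix overlap for second-linker trimming
_SECOND_LINKER_MIN_OVERLAP = 6
# RsaI cut GT^AC leaves fragments ending in GT on either strand
_RSAI_HALF_SITE = "GT"


@dataclass
class LinkerConfig:
    """First-linker geometry and matching tolerances.

    ``unique3_length`` is the number of 3'-terminal bases that must match
    exactly (the unique segment); the remaining 5' (primer) bases tolerate
    up to ``max_linker_mismatches_5prime`` mismatches. ``second_linker``
    enables trimming of the far-end adapter from the post-linker sequence
    (empty string disables it).
    """

    first_linker: str
    unique3_length: int = 10
    max_linker_mismatches_5prime: int = 2
    second_linker: str = ""

    def __post_init__(self) -> None:
        self.first_linker = self.first_linker.upper()
        self.second_linker = self.second_linker.upper()
        if not 1 <= self.unique3_length <= len(self.first_linker):
            raise ValueError(
                f"unique3_length={self.unique3_length} outside [1, {len(self.first_linker)}]"
            )

    @property
    def unique3(self) -> str:
        return self.first_linker[-self.unique3_length :]

    @property
    def primer(self) -> str:
        return self.first_linker[: -self.unique3_length]


@dataclass
class BreakRead:
    """One captured read and its linker-processing state.

    ``post_linker_sequence`` (non-empty only when ``linker_intact``) is the
    oriented read content following the linker's final 3' base, with any
    trailing second-linker match and trailing RsaI half-site removed; it
    begins at the break.
    """

    read_id: str
    raw_sequence: str
    orientation: str = UNDETERMINED
    linker_intact: bool = False
    post_linker_sequence: str = ""

    @property
    def oriented_sequence(self) -> str:
        if self.orientation == REVCOMP:
            return reverse_complement(self.raw_sequence)
        return self.raw_sequence


def _linker_identity(linker: str, target: str) -> float:
    """Best infix-alignment identity of the linker inside ``target``."""
    if not target:
        return 0.0
    res = edlib.align(linker, target, mode="HW", task="distance")
    return 1.0 - res["editDistance"] / len(linker)


def determine_strand(raw_sequence: str, linker: LinkerConfig) -> str:
    """Orient a read by aligning the first linker against it and its
    reverse complement; the better-scoring orientation wins.

    Returns ``undetermined`` on a tie or when neither orientation matches
    at least half of the linker.
    """
    if not raw_sequence:
        raise ValueError("empty read sequence")
    fwd = _linker_identity(linker.first_linker, raw_sequence)
    rev = _linker_identity(linker.first_linker, reverse_complement(raw_sequence))
    if max(fwd, rev) < 0.5 or fwd == rev:
        return UNDETERMINED
    return AS_IS if fwd > rev else REVCOMP


def _trim_post_linker(post: str, cfg: LinkerConfig) -> str:
    """Remove a trailing second-linker prefix match (>= 6 bases) and then a
    trailing RsaI half-site."""
    second = cfg.second_linker
    if second:
        max_ov = min(len(post), len(second))
        for i in range(max_ov, _SECOND_LINKER_MIN_OVERLAP - 1, -1):
            if post.endswith(second[:i]):
                post = post[: len(post) - i]
                break
    if post.endswith(_RSAI_HALF_SITE):
        post = post[: -len(_RSAI_HALF_SITE)]
    return post


def extract_post_linker(
    read_id: str, raw_sequence: str, cfg: LinkerConfig, orientation: str = AS_IS
) -> tuple[BreakRead, str]:
    """Locate the linker in an oriented read and apply the intact-3'-end
    filter.

    ``raw_sequence`` is the read as sequenced; ``orientation`` says whether
    the linker lies on it as-is or on its reverse complement. The final
    ``unique3_length`` linker bases must occur exactly; the primer bases
    immediately 5' of that occurrence (as far as the read extends) may
    carry up to ``max_linker_mismatches_5prime`` mismatches. Returns the
    processed read plus its fate: ``retained``, ``not-intact`` (linker
    present but 3' end damaged) or ``no-linker``.
    """
    read = BreakRead(read_id=read_id, raw_sequence=raw_sequence, orientation=orientation)
    oriented_sequence = read.oriented_sequence
    idx = oriented_sequence.find(cfg.unique3)
    if idx >= 0:
        primer = cfg.primer
        # compare the overlapping primer portion position-by-position
        start = idx - len(primer)
        overlap_primer = primer[max(0, -start) :]
        overlap_read = oriented_sequence[max(0, start) : idx]
        mismatches = sum(a != b for a, b in zip(overlap_primer, overlap_read))
        if mismatches <= cfg.max_linker_mismatches_5prime:
            read.linker_intact = True
            read.post_linker_sequence = _trim_post_linker(
                oriented_sequence[idx + cfg.unique3_length :], cfg
            )
            return read, RETAINED
        fate = NOT_INTACT
    else:
        identity = _linker_identity(cfg.first_linker, oriented_sequence)
        fate = NOT_INTACT if identity >= 0.5 else NO_LINKER
    read.linker_intact = False
    return read, fate


@dataclass
class FilterLog:
    """Per-read fates from linker processing, with conservation check."""

    fates: dict[str, str]

    @property
    def counts(self) -> Counter:
        return Counter(self.fates.values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tfate\n")
            for rid, fate in self.fates.items():
                fh.write(f"{rid}\t{fate}\n")


def read_sequences(path, file_format: str | None = None):
    """Yield (read_id, sequence) from FASTA or FASTQ (sniffed by default)."""
    path = str(path)
    if file_format is None:
        with open(path) as fh:
            first = fh.readline()
        file_format = "fastq" if first.startswith("@") else "fasta"
    for rec in SeqIO.parse(path, file_format):
        yield rec.id, str(rec.seq).upper()


def process_reads(
    reads, cfg: LinkerConfig
) -> tuple[list[BreakRead], FilterLog]:
    """Run strand determination + intact-linker filtering over an iterable
    of (read_id, sequence) pairs.

    Every input read is assigned exactly one fate (retained / not-intact /
    no-linker / undetermined); the conservation identity
    retained + dropped + undetermined == total is asserted.
    """
    retained: list[BreakRead] = []
    fates: dict[str, str] = {}
    total = 0
    for read_id, seq in reads:
        total += 1
        orientation = determine_strand(seq, cfg)
        if orientation == UNDETERMINED:
            fates[read_id] = UNDETERMINED
            continue
        read, fate = extract_post_linker(read_id, seq, cfg, orientation)
        fates[read_id] = fate
        if fate == RETAINED:
            retained.append(read)
    log = FilterLog(fates)
    counts = log.counts
    assert (
        counts[RETAINED] + counts[NOT_INTACT] + counts[NO_LINKER] + counts[UNDETERMINED]
        == total
    ), "filter fates do not partition the input reads"
    logger.info("linker filter: %s of %d reads", dict(counts), total)
    return retained, log


def write_post_linker_fasta(reads: list[BreakRead], path) -> None:
    """Retained post-linker sequences as FASTA, orientation in the header."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id} orientation={r.orientation}\n{r.post_linker_sequence}\n")
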
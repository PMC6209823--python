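"""Mapping post-linker sequences to the reference and calling breaks.

The first base of an aligned post-linker sequence corresponds to the
position immediately after the break, so a read whose best alignment
starts at query offset 0 is "mapped from the first base" and its break
coordinate is the reference position of that first aligned base. A read
whose best alignment starts later carries an unaligned 5' prefix, which is
interpreted as a sequence inserted at the break end (a modified end with
insertion, MIB).

Alignment engine
----------------
A seed-and-extend gapless local aligner over the (toy-scale) reference:
12-mer seeds index the genome; every seeded diagonal is scored exhaustively
with +1/match, -2/mismatch and the maximum-scoring segment on the diagonal
is taken (ties resolved toward the later query start, i.e. the shortest
left extension). Gapless scoring keeps the query-offset/insertion
semantics exact, and any exact substring of length >= min_align_length is
guaranteed to be found. Multi-mapped reads are retained only when at least
90% of the best-tier locations share one identical prior 4-mer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter, defaultdict

from .genome import ReferenceGenome, reverse_complement
from .linker import BreakRead

logger = logging.getLogger(__name__)

__all__ = [
    "MappingParams",
    "AlignmentHit",
    "BreakCall",
    "GenomeIndex",
    "align_read",
    "classify_mapping",
    "retain_multimapped",
    "prior4",
    "map_reads",
    "MappingLog",
    "write_breakcall_bed",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -2
# hits within this margin of the top score form the "best tier" considered
# by the multimap rule
BEST_TIER_MARGIN = 1
MULTIMAP_CONSENSUS = 0.9

TOO_SHORT = "too-short"
UNALIGNABLE = "unalignable"
AMBIGUOUS_MULTIMAP = "ambiguous-multimap"
NO_PRIOR4 = "no-prior4"
MAPPED = "mapped"


@dataclass
class MappingParams:
    min_align_length: int = 20
    min_identity: float = 0.95
    seed_k: int = 12

    def validate(self) -> None:
        if self.seed_k > self.min_align_length:
            raise ValueError("seed_k must not exceed min_align_length")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class AlignmentHit:
    """A gapless local alignment of a post-linker sequence.

    ``query_start`` is the offset into the post-linker sequence (in its own
    orientation) of the first aligned base; ``reference_start`` is 0-based
    on the forward reference strand.
    """

    chromosome: str
    strand: str
    reference_start: int
    query_start: int
    aligned_length: int
    identity: float
    score: int

    @property
    def break_position(self) -> int:
        """Reference coordinate of the first captured base on the break
        strand (alignment start for +, alignment right edge for -)."""
        if self.strand == "+":
            return self.reference_start
        return self.reference_start + self.aligned_length - 1


@dataclass
class BreakCall:
    """A mapped break: coordinate, strand, prior 4-mer and any inserted
    sequence (empty insertion == mapped from the first base)."""

    read_id: str
    chromosome: str
    strand: str
    break_position: int
    prior4: str
    insertion: str
    n_locations: int

    @property
    def is_mib(self) -> bool:
        return bool(self.insertion)


class GenomeIndex:
    """k-mer seed index of the forward strand of every chromosome."""

    def __init__(self, genome: ReferenceGenome, k: int = 12):
        self.genome = genome
        self.k = k
        self.seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                self.seeds[seq[i : i + k]].append((chrom, i))
        self.seeds = dict(self.seeds)


def _best_segment_on_diagonal(
    query: str, target: str, diag: int
) -> tuple[int, int, int, int] | None:
    """Maximum-scoring gapless segment of ``query`` vs ``target`` on a
    fixed diagonal (target_pos = query_pos + diag).

    Returns (score, q_start, length, n_matches) or None. Ties are broken
    toward the later query start (score runs restart whenever the running
    score drops to <= 0) and the earlier end.
    """
    q0 = max(0, -diag)
    q1 = min(len(query), len(target) - diag)
    if q1 <= q0:
        return None
    best = None  # (score, start, end, matches)
    cur, cur_start, cur_matches = 0, q0, 0
    for j in range(q0, q1):
        match = query[j] == target[j + diag]
        v = MATCH_SCORE if match else MISMATCH_SCORE
        if cur <= 0:
            cur, cur_start, cur_matches = v, j, int(match)
        else:
            cur += v
            cur_matches += int(match)
        if cur > 0 and (best is None or cur > best[0]):
            best = (cur, cur_start, j + 1, cur_matches)
    if best is None:
        return None
    score, start, end, matches = best
    return score, start, end - start, matches


def align_read(
    post_linker_sequence: str,
    index: GenomeIndex,
    params: MappingParams | None = None,
) -> list[AlignmentHit]:
    """All gapless local alignments of a post-linker sequence meeting the
    length and identity floors, best score first.

    The sequence is aligned as-is (+ hits) and as its reverse complement
    (- hits); exact substrings of length >= min_align_length are always
    found because the seed length never exceeds that floor.
    """
    params = params or MappingParams()
    params.validate()
    seq = post_linker_sequence.upper()
    if len(seq) < params.min_align_length:
        return []
    k = index.k
    hits: list[AlignmentHit] = []
    seen: set[tuple] = set()
    for strand in "+-":
        q = seq if strand == "+" else reverse_complement(seq)
        diagonals: set[tuple[str, int]] = set()
        for i in range(len(q) - k + 1):
            for chrom, pos in index.seeds.get(q[i : i + k], ()):
                diagonals.add((chrom, pos - i))
        for chrom, diag in diagonals:
            target = index.genome[chrom]
            seg = _best_segment_on_diagonal(q, target, diag)
            if seg is None:
                continue
            score, q_start, length, matches = seg
            if length < params.min_align_length:
                continue
            identity = matches / length
            if identity < params.min_identity:
                continue
            if strand == "+":
                query_start = q_start
            else:
                # q is the reverse complement: its aligned interval
                # [q_start, q_start+length) maps back to post-linker
                # coordinates [len - end, len - q_start)
                query_start = len(seq) - (q_start + length)
            key = (chrom, strand, diag + q_start, query_start)
            if key in seen:
                continue
            seen.add(key)
            hits.append(
                AlignmentHit(
                    chromosome=chrom,
                    strand=strand,
                    reference_start=diag + q_start,
                    query_start=query_start,
                    aligned_length=length,
                    identity=identity,
                    score=score,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.chromosome, h.reference_start, h.strand))
    return hits


def prior4(genome: ReferenceGenome, chromosome: str, position: int, strand: str) -> str | None:
    """The 4 reference bases immediately 5' of the break on the break
    strand, reading 5'->3' toward the break; None when the window runs off
    the chromosome end."""
    seq = genome[chromosome]
    if strand == "+":
        if position < 4:
            return None
        return seq[position - 4 : position]
    if position + 4 > len(seq) - 1:
        return None
    return reverse_complement(seq[position + 1 : position + 5])


def retain_multimapped(
    hits: list[AlignmentHit],
    genome: ReferenceGenome,
    consensus: float = MULTIMAP_CONSENSUS,
) -> AlignmentHit | None:
    """Resolve multi-mapped reads by prior-4-mer consensus.

    ``hits`` must already be the best-score tier. A single location is
    accepted outright. Several locations are retained only if >= 90% of
    them share one identical prior 4-mer (locations too close to a
    chromosome 5' end contribute no 4-mer and count against the
    consensus); the representative is then the consensus location with the
    lexicographically smallest (chromosome, break position). Returns None
    on rejection.
    """
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]
    p4s = [prior4(genome, h.chromosome, h.break_position, h.strand) for h in hits]
    counted = Counter(p for p in p4s if p is not None)
    if not counted:
        return None
    top4, n_top = counted.most_common(1)[0]
    if n_top / len(hits) < consensus:
        return None
    candidates = [h for h, p in zip(hits, p4s) if p == top4]
    return min(candidates, key=lambda h: (h.chromosome, h.break_position, h.strand))


def classify_mapping(
    accepted: AlignmentHit,
    post_linker_sequence: str,
    genome: ReferenceGenome,
    read_id: str,
    n_locations: int = 1,
) -> BreakCall | None:
    """Build a BreakCall from the accepted alignment.

    query_start 0 means mapped-from-first-base (empty insertion);
    otherwise the unaligned 5' prefix is the inserted sequence. Returns
    None when the break lies too close to the chromosome end for a prior
    4-mer to exist.
    """
    p4 = prior4(genome, accepted.chromosome, accepted.break_position, accepted.strand)
    if p4 is None:
        return None
    return BreakCall(
        read_id=read_id,
        chromosome=accepted.chromosome,
        strand=accepted.strand,
        break_position=accepted.break_position,
        prior4=p4,
        insertion=post_linker_sequence[: accepted.query_start],
        n_locations=n_locations,
    )


@dataclass
class MappingLog:
    fates: dict[str, str]

    @property
    def counts(self) -> Counter:
        return Counter(self.fates.values())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tfate\n")
            for rid, fate in self.fates.items():
                fh.write(f"{rid}\t{fate}\n")


def map_reads(
    reads: list[BreakRead],
    genome: ReferenceGenome,
    params: MappingParams | None = None,
    index: GenomeIndex | None = None,
) -> tuple[list[BreakCall], MappingLog]:
    """Align retained reads and emit break calls.

    Fates: mapped / too-short / unalignable (no acceptable alignment) /
    ambiguous-multimap / no-prior4.
    """
    params = params or MappingParams()
    if index is None:
        index = GenomeIndex(genome, params.seed_k)
    calls: list[BreakCall] = []
    fates: dict[str, str] = {}
    for read in reads:
        seq = read.post_linker_sequence
        if len(seq) < params.min_align_length:
            fates[read.read_id] = TOO_SHORT
            continue
        hits = align_read(seq, index, params)
        if not hits:
            fates[read.read_id] = UNALIGNABLE
            continue
        tier = [h for h in hits if h.score >= hits[0].score - BEST_TIER_MARGIN]
        accepted = retain_multimapped(tier, genome)
        if accepted is None:
            fates[read.read_id] = AMBIGUOUS_MULTIMAP
            continue
        call = classify_mapping(accepted, seq, genome, read.read_id, n_locations=len(tier))
        if call is None:
            fates[read.read_id] = NO_PRIOR4
            continue
        fates[read.read_id] = MAPPED
        calls.append(call)
    log = MappingLog(fates)
    logger.info("mapping: %s of %d reads", dict(log.counts), len(reads))
    return calls, log


def write_breakcall_bed(calls: list[BreakCall], path) -> None:
    """BED-like TSV: chrom, break_pos, break_pos+1, read_id, n_locations,
    strand, prior4, insertion ('.' if empty). Coordinates 0-based."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tread_id\tn_locations\tstrand\tprior4\tinsertion\n")
        for c in calls:
            fh.write(
                f"{c.chromosome}\t{c.break_position}\t{c.break_position + 1}\t"
                f"{c.read_id}\t{c.n_locations}\t{c.strand}\t{c.prior4}\t{c.insertion or '.'}\n"
            )


def read_breakcall_bed(path) -> list[BreakCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, start, _end, rid, nloc, strand, p4, ins = line.rstrip("\n").split("\t")
            calls.append(
                BreakCall(
                    read_id=rid,
                    chromosome=chrom,
                    strand=strand,
                    break_position=int(start),
                    prior4=p4,
                    insertion="" if ins == "." else ins,
                    n_locations=int(nloc),
                )
            )
    return calls
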
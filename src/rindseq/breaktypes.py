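"""Odds-ratio break typing against the genome 4-mer background.

Breaks detected in the designated wild-type (anchor) sample are compared,
4-mer by 4-mer, with the reference genome composition: for each of the 256
possible prior 4-mers X a 2x2 table is formed from

    A  reads mapped from the first base whose prior 4-mer is X
    B  reads mapped from the first base with any other prior 4-mer
    C  occurrences of X in the reference genome
    D  occurrences of all other 4-mers in the reference genome

and the cross-product odds ratio (A*D)/(C*B) splits the 4-mers into two
classes: OR > 1 (break sites over-represented relative to the genome —
operationally the physiologic break class) and OR <= 1 (the rest). MIB
reads (non-empty insertion) never contribute to A/B but are themselves
cross-classified by the class of their genomic prior 4-mer.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome import ReferenceGenome, reverse_complement
from .mapping import BreakCall

logger = logging.getLogger(__name__)

__all__ = [
    "KmerBackground",
    "ORTable",
    "SampleBreakSummary",
    "count_genome_4mers",
    "build_or_table",
    "classify_sample",
    "ALL_4MERS",
    "OR_GT1",
    "OR_LE1",
]

ALL_4MERS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
OR_GT1 = "OR>1"
OR_LE1 = "OR<=1"
_ACGT = frozenset("ACGT")


@dataclass
class KmerBackground:
    """Overlapping 4-mer counts over both strands of the reference."""

    counts: dict[str, int]
    total: int
    skipped_windows: int = 0


def count_genome_4mers(genome: ReferenceGenome) -> KmerBackground:
    """Count every overlapping 4-mer window on both strands.

    Windows containing non-ACGT characters are skipped (and tallied).
    Chromosomes shorter than 4 contribute nothing. For a clean genome the
    total is 2 * sum(length - 3), and counts are reverse-complement
    symmetric by construction.
    """
    counts: Counter = Counter()
    skipped = 0
    for seq in genome.sequences.values():
        clean = set(seq) <= _ACGT
        for s in (seq, reverse_complement(seq)):
            windows = (s[i : i + 4] for i in range(len(s) - 3))
            if clean:
                counts.update(windows)
            else:
                for window in windows:
                    if set(window) <= _ACGT:
                        counts[window] += 1
                    else:
                        skipped += 1
    if skipped:
        logger.warning("skipped %d genome 4-mer windows with non-ACGT bases", skipped)
    return KmerBackground(dict(counts), total=sum(counts.values()), skipped_windows=skipped)


@dataclass
class ORRow:
    kmer: str
    A: int
    B: int
    C: int
    D: int
    odds_ratio: float
    or_class: str


@dataclass
class ORTable:
    """The 256 wild-type-anchored odds-ratio tables, one per 4-mer."""

    rows: dict[str, ORRow]
    anchor_sample_id: str

    def or_class(self, kmer: str) -> str:
        return self.rows[kmer].or_class

    @property
    def gt1_kmers(self) -> set[str]:
        return {k for k, r in self.rows.items() if r.or_class == OR_GT1}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.kmer, r.A, r.B, r.C, r.D, r.odds_ratio, r.or_class)
                for r in self.rows.values()
            ],
            columns=["kmer", "A", "B", "C", "D", "odds_ratio", "or_class"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, anchor_sample_id: str = "") -> "ORTable":
        df = pd.read_csv(path, sep="\t")
        rows = {
            rec.kmer: ORRow(
                rec.kmer, int(rec.A), int(rec.B), int(rec.C), int(rec.D),
                float(rec.odds_ratio), rec.or_class,
            )
            for rec in df.itertuples()
        }
        return cls(rows, anchor_sample_id)


def build_or_table(
    wildtype_calls: list[BreakCall],
    background: KmerBackground,
    anchor_sample_id: str = "wild-type",
) -> ORTable:
    """Build the 256 anchor contingency tables from wild-type break calls.

    Only mapped-from-first-base calls (empty insertion) contribute to A/B.
    Division by zero (B or C zero with A > 0) yields +inf, classed OR > 1,
    with a warning; A == 0 yields an odds ratio of 0.
    """
    first_base_calls = [c for c in wildtype_calls if not c.insertion]
    a_counts = Counter(c.prior4 for c in first_base_calls)
    total_a = len(first_base_calls)
    rows: dict[str, ORRow] = {}
    for kmer in ALL_4MERS:
        A = a_counts.get(kmer, 0)
        B = total_a - A
        C = background.counts.get(kmer, 0)
        D = background.total - C
        if B == 0 or C == 0:
            if A == 0:
                odds = 0.0
            else:
                odds = float("inf")
                logger.warning(
                    "odds ratio undefined for %s (A=%d B=%d C=%d D=%d); recorded +inf",
                    kmer, A, B, C, D,
                )
        else:
            odds = (A * D) / (C * B)
        rows[kmer] = ORRow(kmer, A, B, C, D, odds, OR_GT1 if odds > 1 else OR_LE1)
    return ORTable(rows, anchor_sample_id)


@dataclass
class SampleBreakSummary:
    """Per-sample break-type composition.

    Mapped-from-first-base reads fall into OR > 1 / OR <= 1 by the anchor
    class of their prior 4-mer; MIB reads are counted separately and also
    split by prior-4-mer class. ``mib_and_or_le1`` and ``n_or_gt1`` are the
    two cells the repair-defect association test uses per sample.
    """

    sample_id: str
    n_or_gt1: int = 0
    n_or_le1: int = 0
    n_mib_or_gt1: int = 0
    n_mib_or_le1: int = 0
    n_excluded: int = 0

    @property
    def n_mib(self) -> int:
        return self.n_mib_or_gt1 + self.n_mib_or_le1

    @property
    def retained_total(self) -> int:
        return self.n_or_gt1 + self.n_or_le1 + self.n_mib

    @property
    def mib_and_or_le1(self) -> int:
        return self.n_mib + self.n_or_le1

    @property
    def percentages(self) -> dict[str, float] | None:
        """Percentage of OR>1, OR<=1 and MIB breaks over the retained
        total; None (rather than NaN) for an empty sample."""
        total = self.retained_total
        if total == 0:
            return None
        return {
            "pct_or_gt1": 100.0 * self.n_or_gt1 / total,
            "pct_or_le1": 100.0 * self.n_or_le1 / total,
            "pct_mib": 100.0 * self.n_mib / total,
        }

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "n_or_gt1": self.n_or_gt1,
            "n_or_le1": self.n_or_le1,
            "n_mib_or_gt1": self.n_mib_or_gt1,
            "n_mib_or_le1": self.n_mib_or_le1,
            "n_mib": self.n_mib,
            "n_excluded": self.n_excluded,
            "retained_total": self.retained_total,
        }
        pct = self.percentages
        if pct is not None:
            d.update(pct)
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SampleBreakSummary":
        return cls(
            sample_id=d["sample_id"],
            n_or_gt1=int(d["n_or_gt1"]),
            n_or_le1=int(d["n_or_le1"]),
            n_mib_or_gt1=int(d["n_mib_or_gt1"]),
            n_mib_or_le1=int(d["n_mib_or_le1"]),
            n_excluded=int(d.get("n_excluded", 0)),
        )

    @classmethod
    def read_json(cls, path) -> "SampleBreakSummary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def classify_sample(
    calls: list[BreakCall], or_table: ORTable, sample_id: str = "sample"
) -> SampleBreakSummary:
    """Tally a sample's break calls by type using the anchor OR classes.

    Pure function of (calls, or_table). Calls whose prior 4-mer is not a
    clean ACGT 4-mer are excluded and counted.
    """
    s = SampleBreakSummary(sample_id=sample_id)
    for call in calls:
        if len(call.prior4) != 4 or call.prior4 not in or_table.rows:
            s.n_excluded += 1
            continue
        gt1 = or_table.or_class(call.prior4) == OR_GT1
        if call.insertion:
            if gt1:
                s.n_mib_or_gt1 += 1
            else:
                s.n_mib_or_le1 += 1
        elif gt1:
            s.n_or_gt1 += 1
        else:
            s.n_or_le1 += 1
    if s.n_excluded:
        logger.info("%s: excluded %d calls without a valid prior 4-mer", sample_id, s.n_excluded)
    return s


def plot_break_composition(summaries: list[SampleBreakSummary], path=None):
    """Stacked-bar chart of the three break-type percentages per sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = [s.sample_id for s in summaries]
    pcts = [s.percentages or {"pct_or_gt1": 0, "pct_or_le1": 0, "pct_mib": 0} for s in summaries]
    gt1 = [p["pct_or_gt1"] for p in pcts]
    le1 = [p["pct_or_le1"] for p in pcts]
    mib = [p["pct_mib"] for p in pcts]
    fig, ax = plt.subplots(figsize=(max(4, len(samples)), 4))
    ax.bar(samples, gt1, label="OR>1 breaks", color="salmon")
    ax.bar(samples, le1, bottom=gt1, label="OR<=1 breaks", color="darkblue")
    ax.bar(samples, mib, bottom=[a + b for a, b in zip(gt1, le1)], label="MIB", color="lightblue")
    ax.set_ylabel("% of retained breaks")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
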
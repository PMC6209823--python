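"""Reference genome container.

Chromosome sequences are held as plain uppercase strings; FASTA round-trips
go through Biopython. The 4-mer background (needed by the odds-ratio break
classifier) is computed lazily and cached on the instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import reverse_complement
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

__all__ = ["ReferenceGenome", "reverse_complement"]


@dataclass
class ReferenceGenome:
    """Named chromosome sequences plus a cached 4-mer background count."""

    sequences: dict[str, str]
    _kmer_background: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path, description: str = "") -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description=description)
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def kmer_background(self):
        """Both-strand overlapping 4-mer counts (cached)."""
        if self._kmer_background is None:
            from .breaktypes import count_genome_4mers

            self._kmer_background = count_genome_4mers(self)
        return self._kmer_background
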
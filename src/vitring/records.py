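"""Sequence records with taxonomic lineage labels, and FASTA/FASTQ I/O.

A reference 16S sequence carries an RDP-style lineage
(``domain;phylum;class;order;family;genus``) in the FASTA description.
Any rank may be the literal marker ``"unclassified"``; the genus rank is
always present, possibly as that marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

UNCLASSIFIED = "unclassified"

RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Lineage:
    """Six-rank taxonomic label; missing ranks default to "unclassified"."""

    domain: str = UNCLASSIFIED
    phylum: str = UNCLASSIFIED
    class_: str = UNCLASSIFIED
    order: str = UNCLASSIFIED
    family: str = UNCLASSIFIED
    genus: str = UNCLASSIFIED

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        ranks = [r.strip() for r in text.strip().strip(";").split(";")]
        ranks = (ranks + [UNCLASSIFIED] * 6)[:6]
        return cls(*ranks)

    def to_string(self) -> str:
        return ";".join(
            (self.domain, self.phylum, self.class_, self.order, self.family, self.genus)
        )

    def rank(self, name: str) -> str:
        if name == "class":
            return self.class_
        if name not in RANK_NAMES:
            raise KeyError(f"unknown rank {name!r}")
        return getattr(self, name)

    @property
    def genus_classified(self) -> bool:
        return self.genus != UNCLASSIFIED


@dataclass
class SeqRecord:
    """An identified nucleotide sequence with an optional lineage."""

    id: str
    seq: str
    lineage: Optional[Lineage] = None
    quality: Optional[str] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        # avoid reallocating already-uppercase sequences
        if not self.seq.isupper() and self.seq:
            self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        qual = self.quality[::-1] if self.quality is not None else None
        return SeqRecord(self.id, revcomp(self.seq), self.lineage, qual)


def _from_bio(rec: BioSeqRecord) -> SeqRecord:
    desc = rec.description or ""
    lineage = None
    # lineage, when present, follows the first whitespace of the header
    parts = desc.split(None, 1)
    if len(parts) == 2 and ";" in parts[1]:
        lineage = Lineage.from_string(parts[1])
    qual = None
    if "phred_quality" in rec.letter_annotations:
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
    return SeqRecord(rec.id, str(rec.seq), lineage, qual)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return [_from_bio(r) for r in SeqIO.parse(str(path), "fasta")]


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return [_from_bio(r) for r in SeqIO.parse(str(path), "fastq")]


def read_seqs(path: str | Path) -> list[SeqRecord]:
    """Read FASTA or FASTQ, sniffing the format from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return read_fasta(path)
    if first == "@":
        return read_fastq(path)
    raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.lineage is not None:
                header += " " + rec.lineage.to_string()
            fh.write(f">{header}\n{rec.seq}\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or "I" * rec.length
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def iter_unique_ids(records: Iterable[SeqRecord]) -> Iterator[SeqRecord]:
    """Yield records, raising on a duplicated id."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        yield rec
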
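"""Nearly full-length 16S reconstruction from shotgun reads.

Shotgun reads classified to the same reference sequence are pooled into a
bin (reverse-strand hits are re-oriented first), assembled with a greedy
overlap-consensus assembler, filtered to contigs of >= 800 bp with mean
read coverage >= 10x, and assigned a species name by alignment against
type-strain 16S sequences at >= 97 % identity.

The assembler grows a contig from the longest unused read by repeatedly
merging the read with the best suffix-prefix overlap (>= ``min_overlap``
bases at <= ``max_mismatch_rate`` mismatches) onto either end, taking a
per-column majority-vote consensus.  It is deterministic and adequate for
the low-error, high-coverage bins this step sees; externally produced
contigs can be injected instead via :func:`adapt_external_contigs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment import align_pair
from .idsearch import Hit
from .records import SeqRecord

DEFAULT_MIN_OVERLAP = 40
DEFAULT_MAX_MISMATCH_RATE = 0.02
DEFAULT_MIN_CONTIG_LEN = 800
DEFAULT_MIN_COVERAGE = 10.0
DEFAULT_SPECIES_IDENTITY = 97.0

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ReadBin:
    """Reads sharing a top-hit reference, oriented to its plus strand."""

    ref_id: str
    reads: list[SeqRecord] = field(default_factory=list)


def bin_reads_by_reference(
    hits: Iterable[Hit], reads: Sequence[SeqRecord]
) -> list[ReadBin]:
    """Group reads by their top-hit reference; minus-strand reads are
    stored reverse-complemented so each bin is consistently oriented."""
    by_id = {r.id: r for r in reads}
    bins: dict[str, ReadBin] = {}
    for hit in hits:
        read = by_id.get(hit.query_id)
        if read is None:
            continue
        if hit.strand == "-":
            read = read.reverse_complement()
        bins.setdefault(hit.ref_id, ReadBin(hit.ref_id)).reads.append(read)
    return [bins[rid] for rid in sorted(bins)]


@dataclass
class Contig:
    seq: str
    mean_coverage: float
    source_ref_id: str
    n_reads: int = 0
    species: Optional[str] = None
    species_identity: Optional[float] = None

    @property
    def length(self) -> int:
        return len(self.seq)


class _GrowingContig:
    """Consensus under construction: per-column base votes."""

    def __init__(self, read: str):
        self.counts = np.zeros((len(read), 4), dtype=np.int32)
        self._add_votes(0, read)
        self.read_bases = len(read)
        self.n_reads = 1

    def _add_votes(self, offset: int, read: str) -> None:
        idx = np.frombuffer(read.encode(), dtype=np.uint8)
        for base, bi in _BASE_INDEX.items():
            cols = np.nonzero(idx == ord(base))[0] + offset
            self.counts[cols, bi] += 1

    @property
    def consensus(self) -> str:
        # majority vote per column; ties resolve to the alphabetically
        # first base for determinism
        best = np.argmax(self.counts, axis=1)
        return "".join(_BASES[i] for i in best)

    def __len__(self) -> int:
        return self.counts.shape[0]

    def merge_right(self, read: str, overlap: int) -> None:
        offset = len(self) - overlap
        grow = offset + len(read) - len(self)
        if grow > 0:
            self.counts = np.vstack(
                [self.counts, np.zeros((grow, 4), dtype=np.int32)]
            )
        self._add_votes(offset, read)
        self.read_bases += len(read)
        self.n_reads += 1

    def merge_left(self, read: str, overlap: int) -> None:
        grow = len(read) - overlap
        if grow > 0:
            self.counts = np.vstack(
                [np.zeros((grow, 4), dtype=np.int32), self.counts]
            )
        self._add_votes(0, read)
        self.read_bases += len(read)
        self.n_reads += 1


def _best_suffix_prefix(
    left: str, right: str, min_overlap: int, max_mismatch_rate: float
) -> Optional[int]:
    """Longest overlap of a suffix of ``left`` with a prefix of ``right``
    within the mismatch budget, or None.

    An exact seed (the first 24 bases of ``right``) located by substring
    search short-circuits the scan; the exhaustive length scan remains as
    a fallback for reads with errors near the junction.
    """
    max_ov = min(len(left), len(right))
    if max_ov < min_overlap:
        return None
    seed = right[: min(24, len(right))]
    pos = left.rfind(seed)
    if pos >= 0:
        ov = len(left) - pos
        if ov <= max_ov:
            mism = sum(
                1 for a, b in zip(left[pos:], right[: ov]) if a != b
            )
            if mism <= max_mismatch_rate * ov:
                return ov
        else:
            # the seed places the read interior to ``left``: no admissible
            # end overlap exists (the read belongs at that interior spot)
            return None
    la = np.frombuffer(left.encode(), dtype=np.uint8)
    ra = np.frombuffer(right.encode(), dtype=np.uint8)
    for ov in range(max_ov, min_overlap - 1, -1):
        mism = int((la[len(la) - ov :] != ra[:ov]).sum())
        if mism <= max_mismatch_rate * ov:
            return ov
    return None


def assemble_bin(
    bin: ReadBin,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> list[Contig]:
    """Greedy overlap-consensus assembly of one read bin.

    Mean coverage of a contig is total read bases placed on it divided by
    its length.  Reads with no admissible overlap become their own
    single-read contigs (removed later by the length filter).
    """
    if not bin.reads:
        raise ValueError("cannot assemble an empty bin")
    remaining = sorted(bin.reads, key=lambda r: (-r.length, r.id))
    contigs: list[Contig] = []
    while remaining:
        growing = _GrowingContig(remaining.pop(0).seq)
        while True:
            consensus = growing.consensus
            best: Optional[tuple[int, int, str]] = None  # (overlap, idx, side)
            for i, read in enumerate(remaining):
                ov = _best_suffix_prefix(
                    consensus, read.seq, min_overlap, max_mismatch_rate
                )
                if ov is not None and (best is None or ov > best[0]):
                    best = (ov, i, "right")
                ov = _best_suffix_prefix(
                    read.seq, consensus, min_overlap, max_mismatch_rate
                )
                if ov is not None and (best is None or ov > best[0]):
                    best = (ov, i, "left")
            if best is None:
                break
            ov, i, side = best
            read = remaining.pop(i)
            if side == "right":
                growing.merge_right(read.seq, ov)
            else:
                growing.merge_left(read.seq, ov)
        seq = growing.consensus
        contigs.append(
            Contig(
                seq,
                growing.read_bases / len(seq),
                bin.ref_id,
                n_reads=growing.n_reads,
            )
        )
    return contigs


def adapt_external_contigs(
    sequences: Iterable[SeqRecord], ref_id: str, coverages: dict[str, float]
) -> list[Contig]:
    """Wrap contigs produced by an external assembler so the downstream
    filtering and species-assignment steps apply unchanged."""
    return [
        Contig(rec.seq, coverages.get(rec.id, 0.0), ref_id)
        for rec in sequences
    ]


def filter_contigs(
    contigs: Iterable[Contig],
    min_len: int = DEFAULT_MIN_CONTIG_LEN,
    min_cov: float = DEFAULT_MIN_COVERAGE,
) -> list[Contig]:
    """Keep contigs of length >= min_len and mean coverage >= min_cov."""
    return [
        c for c in contigs if c.length >= min_len and c.mean_coverage >= min_cov
    ]


def assign_species(
    contig: Contig,
    type_strains: Sequence[SeqRecord],
    species_names: Optional[dict[str, str]] = None,
    min_identity: float = DEFAULT_SPECIES_IDENTITY,
) -> Contig:
    """Assign a species name by best local alignment to type strains.

    The species is set only when the best identity reaches
    ``min_identity``; exact identity ties report all tied names joined
    with ";" in sorted order.
    """
    if not type_strains:
        raise ValueError("type-strain database is empty")
    names = species_names or {}
    results: list[tuple[float, str]] = []
    for strain in type_strains:
        res = align_pair(contig.seq, strain, mode="local")
        results.append((res.identity, names.get(strain.id, strain.id)))
    best_identity = max(identity for identity, _ in results)
    contig.species_identity = best_identity
    if best_identity >= min_identity:
        tied = sorted({name for identity, name in results
                       if identity == best_identity})
        contig.species = ";".join(tied)
    else:
        contig.species = None
    return contig


def write_contigs_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(contigs):
            fh.write(
                f">contig_{i} source_ref={c.source_ref_id} "
                f"length={c.length} coverage={c.mean_coverage:.2f}\n{c.seq}\n"
            )


def write_species_tsv(contigs: Sequence[Contig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tsource_ref\tlength\tcoverage\tspecies\tidentity\n")
        for i, c in enumerate(contigs):
            species = c.species if c.species is not None else "NA"
            ident = (
                f"{c.species_identity:.2f}" if c.species_identity is not None
                else "NA"
            )
            fh.write(
                f"contig_{i}\t{c.source_ref_id}\t{c.length}\t"
                f"{c.mean_coverage:.2f}\t{species}\t{ident}\n"
            )
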
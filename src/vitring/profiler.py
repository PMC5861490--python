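"""Genus composition profiles with 16S copy-number normalization.

Reads whose top hit reaches >= 94 % identity are assigned to the genus of
their reference; reads below that are reported as unassigned and excluded
from relative abundances.  Because genomes carry between one and ~15
copies of the 16S gene, raw read counts overstate taxa with many copies;
normalization weights each read by 1/c, where c is the copy number of the
nearest sequence in a copy-number reference database (one sequence per
genome-sequenced species), inferred per read by the same identity search
used for classification.  A leave-one-out validator quantifies how well
nearest-neighbor copy inference works on a given copy-number database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .idsearch import (
    DEFAULT_MIN_ALN_LEN,
    DEFAULT_MIN_IDENTITY,
    Hit,
    KmerIndex,
    build_index,
    search,
)
from .records import Lineage, SeqRecord

DEFAULT_GENUS_IDENTITY = 94.0
#: copy number assumed when a read finds no hit in the copy-number DB
FALLBACK_COPY_NUMBER = 1


@dataclass
class AssignedRead:
    read_id: str
    ref_id: str
    genus: str
    identity: float
    copy_number: Optional[int] = None  # set by normalization

    @property
    def weight(self) -> float:
        return 1.0 / self.copy_number if self.copy_number else 1.0


@dataclass
class GenusProfile:
    """Per-genus raw counts, weights and relative abundances of a sample."""

    sample_id: str
    assignments: list[AssignedRead] = field(default_factory=list)
    unassigned_ids: list[str] = field(default_factory=list)
    normalized: bool = False

    @property
    def raw_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.assignments:
            counts[a.genus] = counts.get(a.genus, 0) + 1
        return counts

    @property
    def weights(self) -> dict[str, float]:
        if not self.normalized:
            return {g: float(c) for g, c in self.raw_counts.items()}
        w: dict[str, float] = {}
        for a in self.assignments:
            w[a.genus] = w.get(a.genus, 0.0) + a.weight
        return w

    @property
    def rel_abundance(self) -> dict[str, float]:
        w = self.weights
        total = sum(w.values())
        if total == 0.0:
            return {}
        return {g: v / total for g, v in w.items()}

    @property
    def cluster_counts(self) -> dict[str, int]:
        """Read counts per reference cluster (for cluster-level comparison
        and the circular diagrams)."""
        counts: dict[str, int] = {}
        for a in self.assignments:
            counts[a.ref_id] = counts.get(a.ref_id, 0) + 1
        return counts

    def assigned_read_ids(self, genus: str) -> list[str]:
        return [a.read_id for a in self.assignments if a.genus == genus]

    def to_frame(self) -> pd.DataFrame:
        raw = self.raw_counts
        weights = self.weights
        rel = self.rel_abundance
        genera = sorted(raw)
        return pd.DataFrame(
            {
                "genus": genera,
                "raw_count": [raw[g] for g in genera],
                "normalized_weight": [weights[g] for g in genera],
                "relative_abundance": [rel[g] for g in genera],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path, sample_id: Optional[str] = None) -> dict[str, float]:
    """Load a genus-composition TSV back as {genus: relative_abundance}."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["genus"], df["relative_abundance"]))


def assign_genus(
    hits: Iterable[Hit],
    lineage_map: dict[str, Lineage],
    min_identity: float = DEFAULT_GENUS_IDENTITY,
    sample_id: str = "sample",
) -> GenusProfile:
    """Build an unnormalized genus profile from top hits.

    Hits are expected to be top hits already thresholded at the search
    stage (>= 80 % / 100 bp); only those reaching ``min_identity`` count
    toward a genus.  Hits to references without a lineage are counted
    unassigned with a warning.
    """
    profile = GenusProfile(sample_id)
    for hit in hits:
        if hit.identity < min_identity:
            profile.unassigned_ids.append(hit.query_id)
            continue
        lineage = lineage_map.get(hit.ref_id)
        if lineage is None:
            warnings.warn(f"reference {hit.ref_id!r} has no lineage; "
                          f"read {hit.query_id!r} counted unassigned")
            profile.unassigned_ids.append(hit.query_id)
            continue
        profile.assignments.append(
            AssignedRead(hit.query_id, hit.ref_id, lineage.genus, hit.identity)
        )
    return profile


@dataclass
class CopyNumberDB:
    """One 16S sequence per genome-sequenced species with its copy count."""

    records: list[SeqRecord]
    copies: dict[str, int]
    k: int = 16
    _index: Optional[KmerIndex] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.id not in self.copies:
                raise ValueError(f"no copy count for {rec.id!r}")
            if self.copies[rec.id] < 1:
                raise ValueError(f"copy count for {rec.id!r} must be >= 1")

    @property
    def index(self) -> KmerIndex:
        if self._index is None:
            self._index = build_index(self.records, self.k)
        return self._index


def infer_copy_number(
    rec: SeqRecord,
    cndb: CopyNumberDB,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    exclude: Iterable[str] = (),
) -> tuple[int, Optional[Hit]]:
    """Copy number of the nearest copy-number-DB sequence.

    The method assumes the genome of the query shares its 16S copy number
    with its nearest relative in the database.  With no hit at the
    thresholds the fallback copy number 1 is returned (no down-weighting)
    together with ``None``.
    """
    hit = search(rec, cndb.index, min_identity, min_aln_len, exclude=exclude)
    if hit is None:
        return FALLBACK_COPY_NUMBER, None
    return cndb.copies[hit.ref_id], hit


def normalize_profile(
    profile: GenusProfile, per_read_copies: dict[str, int]
) -> GenusProfile:
    """Weight each assigned read by 1/copy-number and recompute
    abundances.  Every assigned read must have an inferred copy >= 1."""
    assignments: list[AssignedRead] = []
    for a in profile.assignments:
        c = per_read_copies.get(a.read_id)
        if c is None:
            raise KeyError(f"no copy number for read {a.read_id!r}")
        if c < 1:
            raise ValueError(f"copy number {c} < 1 for read {a.read_id!r}")
        assignments.append(
            AssignedRead(a.read_id, a.ref_id, a.genus, a.identity, c)
        )
    return GenusProfile(
        profile.sample_id, assignments, list(profile.unassigned_ids),
        normalized=True,
    )


@dataclass(frozen=True)
class LeaveOneOutRecord:
    seq_id: str
    true_copies: int
    inferred_copies: int

    @property
    def fold_error(self) -> float:
        t, i = self.true_copies, self.inferred_copies
        return max(t, i) / min(t, i)


@dataclass
class LeaveOneOutSummary:
    results: list[LeaveOneOutRecord]

    @property
    def fraction_within_twofold(self) -> float:
        if not self.results:
            return float("nan")
        ok = sum(1 for r in self.results if r.fold_error <= 2.0)
        return ok / len(self.results)


def leave_one_out_cn(
    cndb: CopyNumberDB,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
) -> LeaveOneOutSummary:
    """Validate nearest-neighbor copy inference by searching every
    database record against the database minus itself."""
    if len(cndb.records) < 2:
        raise ValueError("leave-one-out needs at least two records")
    results: list[LeaveOneOutRecord] = []
    for rec in cndb.records:
        inferred, _ = infer_copy_number(
            rec, cndb, min_identity, min_aln_len, exclude=(rec.id,)
        )
        results.append(
            LeaveOneOutRecord(rec.id, cndb.copies[rec.id], inferred)
        )
    return LeaveOneOutSummary(results)


def read_copy_number_tsv(path: str | Path) -> dict[str, int]:
    """TSV of (id, copies)."""
    copies: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            sid, c = line.split("\t")[:2]
            copies[sid] = int(c)
    return copies
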
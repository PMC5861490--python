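"""Curation of a high-quality, phylogenetically non-redundant 16S reference set.

The pipeline mirrors how public 16S collections are cleaned before use as
a classification reference:

1. trim every sequence to the conserved gene boundaries — six bases
   upstream of the 8F primer motif (TTGATCCT) at the 5' end, through the
   end of the anti-Shine-Dalgarno motif (CACCTCCTTN) at the 3' end —
   either by direct motif search or by transferring coordinates from a
   local alignment to an already-trimmed guide sequence;
2. drop abnormally short (< 1120 bp) or long (> 1660 bp) sequences and
   sequences containing homopolymer runs of 10 bases or more;
3. sort genus-classified sequences (descending length) ahead of
   genus-unclassified ones so that cluster representatives are
   informative, then greedily cluster at 94 % identity with 90 % mutual
   coverage;
4. drop representatives flagged chimeric by *both* de novo and reference
   chimera screens (flags are caller-supplied annotations) and
   representatives whose genus is "unclassified".

Every stage partitions its input: nothing is silently dropped, and an
audit log records the stage and reason for each removal.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .alignment import PairwiseResult, align_pair
from .records import UNCLASSIFIED, Lineage, SeqRecord

DEFAULT_MIN_BP = 1120
DEFAULT_MAX_BP = 1660
DEFAULT_MAX_HOMOPOLYMER_RUN = 9
DEFAULT_CLUSTER_ID = 0.94
DEFAULT_CLUSTER_COV = 0.9


@dataclass(frozen=True)
class TrimAnchors:
    """Conserved motifs bracketing the 16S gene.

    ``five_prime_margin`` bases upstream of the first 5' motif occurrence
    are kept (clamped at the sequence start); N in the 3' motif matches
    any base.
    """

    five_prime_motif: str = "TTGATCCT"
    five_prime_margin: int = 6
    three_prime_motif: str = "CACCTCCTTN"

    def __post_init__(self) -> None:
        if not self.five_prime_motif or not self.three_prime_motif:
            raise ValueError("trim motifs must be non-empty")
        if self.five_prime_margin < 0:
            raise ValueError("five_prime_margin must be >= 0")


DEFAULT_ANCHORS = TrimAnchors()


@dataclass
class TrimResult:
    record: SeqRecord
    untrimmable: bool = False
    method: Optional[str] = None  # "motif" | "guide" | None


def _motif_regex(motif: str) -> re.Pattern:
    return re.compile("".join("." if c == "N" else re.escape(c) for c in motif))


def trim_to_anchors(
    rec: SeqRecord,
    anchors: TrimAnchors = DEFAULT_ANCHORS,
    guide: Optional[SeqRecord] = None,
) -> TrimResult:
    """Trim a record to the anchor motifs, or to a guide alignment.

    The motif route needs both anchors: the trimmed sequence runs from
    ``five_prime_margin`` bases before the first 5' motif occurrence
    through the end of the first 3' motif occurrence downstream of it.
    When the motifs are absent and a guide (an already-trimmed reference)
    is supplied, the region of the record locally aligning to the guide
    is kept instead.  Records with neither route available are flagged
    untrimmable, never dropped.
    """
    if rec.length == 0:
        raise ValueError(f"{rec.id}: empty sequence")
    start5 = rec.seq.find(anchors.five_prime_motif)
    if start5 >= 0:
        m3 = _motif_regex(anchors.three_prime_motif).search(
            rec.seq, start5 + len(anchors.five_prime_motif)
        )
        if m3 is not None:
            start = max(0, start5 - anchors.five_prime_margin)
            trimmed = rec.seq[start : m3.end()]
            return TrimResult(
                SeqRecord(rec.id, trimmed, rec.lineage), method="motif"
            )
    if guide is not None:
        res = align_pair(rec, guide, mode="local")
        if res.columns > 0:
            a0, a1 = res.a_span
            return TrimResult(
                SeqRecord(rec.id, rec.seq[a0:a1], rec.lineage), method="guide"
            )
    return TrimResult(rec, untrimmable=True)


def filter_by_length(
    recs: Iterable[SeqRecord],
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition records into (kept, removed) by length bounds, inclusive."""
    kept: list[SeqRecord] = []
    removed: list[SeqRecord] = []
    for rec in recs:
        (kept if min_bp <= rec.length <= max_bp else removed).append(rec)
    return kept, removed


def length_in_range(
    length: int, min_bp: int = DEFAULT_MIN_BP, max_bp: int = DEFAULT_MAX_BP
) -> bool:
    return min_bp <= length <= max_bp


def filter_homopolymer(
    recs: Iterable[SeqRecord], max_run: int = DEFAULT_MAX_HOMOPOLYMER_RUN
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Remove records containing a single-base run longer than max_run.

    With the default max_run=9, runs of >= 10 identical bases are removed.
    """
    pattern = re.compile(
        "|".join(f"{b}{{{max_run + 1},}}" for b in "ACGTN")
    )
    kept: list[SeqRecord] = []
    removed: list[SeqRecord] = []
    for rec in recs:
        (removed if pattern.search(rec.seq) else kept).append(rec)
    return kept, removed


def sort_for_clustering(recs: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Genus-classified records first (descending length), then
    genus-unclassified records (descending length); length ties broken by
    id for determinism.  Every record must carry a lineage."""
    for rec in recs:
        if rec.lineage is None:
            raise ValueError(f"{rec.id}: lineage required for clustering order")
    return sorted(
        recs,
        key=lambda r: (not r.lineage.genus_classified, -r.length, r.id),
    )


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)


AlignerFn = Callable[[SeqRecord, SeqRecord], PairwiseResult]


def _default_aligner(a: SeqRecord, b: SeqRecord) -> PairwiseResult:
    return align_pair(a, b, mode="local")


def greedy_cluster(
    ordered: Sequence[SeqRecord],
    id_threshold: float = DEFAULT_CLUSTER_ID,
    query_cov: float = DEFAULT_CLUSTER_COV,
    target_cov: float = DEFAULT_CLUSTER_COV,
    aligner: AlignerFn = _default_aligner,
) -> list[Cluster]:
    """Greedy centroid clustering over a pre-sorted record list.

    Records are scanned in order; each joins the first existing cluster
    whose representative aligns at >= id_threshold identity with both the
    query and the representative covered at >= the coverage fractions
    (aligned span / sequence length); otherwise it founds a new cluster.
    Representatives are therefore always the earliest (longest
    classified) member.
    """
    clusters: list[Cluster] = []
    reps: list[SeqRecord] = []
    for rec in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            res = aligner(rec, rep)
            if res.columns == 0:
                continue
            qcov = (res.a_span[1] - res.a_span[0]) / rec.length
            tcov = (res.b_span[1] - res.b_span[0]) / rep.length
            if (
                res.identity / 100.0 >= id_threshold
                and qcov >= query_cov
                and tcov >= target_cov
            ):
                cluster.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id]))
            reps.append(rec)
    return clusters


@dataclass
class FinalizedDB:
    kept_ids: list[str]
    removed_chimeric: list[str]
    removed_unclassified: list[str]

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def finalize_representatives(
    clusters: Sequence[Cluster],
    chimera_flags: dict[str, tuple[bool, bool]],
    lineages: dict[str, Lineage],
) -> FinalizedDB:
    """Drop representatives flagged by both chimera modes or whose genus
    is "unclassified"; report counts of each removal class.

    chimera_flags maps id -> (denovo_flag, reference_flag); a flag must
    be set in *both* modes to remove.  Flags for unknown ids warn and are
    ignored.
    """
    rep_ids = [c.representative_id for c in clusters]
    rep_set = set(rep_ids)
    for fid in chimera_flags:
        if fid not in rep_set:
            warnings.warn(f"chimera flag for unknown id {fid!r} ignored")
    kept: list[str] = []
    chimeric: list[str] = []
    unclassified: list[str] = []
    for rid in rep_ids:
        denovo, reference = chimera_flags.get(rid, (False, False))
        if denovo and reference:
            chimeric.append(rid)
        elif lineages.get(rid) is None or lineages[rid].genus == UNCLASSIFIED:
            unclassified.append(rid)
        else:
            kept.append(rid)
    return FinalizedDB(kept, chimeric, unclassified)


def subsample_for_phylum_layout(
    records: Sequence[SeqRecord],
    n_per_taxon: int = 30,
    seed: int = 0,
    diverse_phylum: str = "Proteobacteria",
) -> list[SeqRecord]:
    """Per-phylum subsample for the phylum-level circular layout.

    Up to n_per_taxon records are drawn uniformly without replacement
    from each phylum; the designated hyper-diverse phylum (default
    Proteobacteria) is sampled per *class* instead.  Phyla with fewer
    than n_per_taxon records contribute all of them.  Reproducible under
    the seed.
    """
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        if rec.lineage is None:
            raise ValueError(f"{rec.id}: lineage required for subsampling")
        if rec.lineage.phylum == diverse_phylum:
            key = f"{diverse_phylum}/{rec.lineage.class_}"
        else:
            key = rec.lineage.phylum
        groups.setdefault(key, []).append(rec)
    rng = np.random.default_rng(seed)
    sampled: list[SeqRecord] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: r.id)
        if len(members) <= n_per_taxon:
            sampled.extend(members)
        else:
            idx = rng.choice(len(members), size=n_per_taxon, replace=False)
            sampled.extend(members[i] for i in sorted(idx))
    return sampled


@dataclass
class BuildResult:
    final_records: list[SeqRecord]
    clusters: list[Cluster]
    finalized: FinalizedDB
    audit: list[tuple[str, str, str]]  # (id, stage, reason)


def read_chimera_flags(path: str | Path) -> dict[str, tuple[bool, bool]]:
    """TSV of (id, denovo_flag, reference_flag) with 0/1 or true/false."""
    flags: dict[str, tuple[bool, bool]] = {}
    truthy = {"1", "true", "yes"}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("id\t"):
                continue
            fid, denovo, reference = line.split("\t")[:3]
            flags[fid] = (denovo.lower() in truthy, reference.lower() in truthy)
    return flags


def build_database(
    raw: Sequence[SeqRecord],
    chimera_flags: Optional[dict[str, tuple[bool, bool]]] = None,
    anchors: TrimAnchors = DEFAULT_ANCHORS,
    guide: Optional[SeqRecord] = None,
    min_bp: int = DEFAULT_MIN_BP,
    max_bp: int = DEFAULT_MAX_BP,
    max_run: int = DEFAULT_MAX_HOMOPOLYMER_RUN,
    id_threshold: float = DEFAULT_CLUSTER_ID,
    coverage: float = DEFAULT_CLUSTER_COV,
) -> BuildResult:
    """Run the full curation pipeline; see the module docstring."""
    chimera_flags = chimera_flags or {}
    audit: list[tuple[str, str, str]] = []

    trimmed: list[SeqRecord] = []
    for rec in raw:
        result = trim_to_anchors(rec, anchors, guide)
        if result.untrimmable:
            audit.append((rec.id, "trim", "no anchor motifs or guide hit"))
        else:
            trimmed.append(result.record)

    kept, removed = filter_by_length(trimmed, min_bp, max_bp)
    audit.extend((r.id, "length", f"length {r.length} outside "
                  f"[{min_bp},{max_bp}]") for r in removed)

    kept, removed = filter_homopolymer(kept, max_run)
    audit.extend(
        (r.id, "homopolymer", f"run > {max_run} bases") for r in removed
    )

    ordered = sort_for_clustering(kept)
    clusters = greedy_cluster(ordered, id_threshold, coverage, coverage)

    lineages = {r.id: r.lineage for r in kept}
    finalized = finalize_representatives(clusters, chimera_flags, lineages)
    audit.extend((rid, "chimera", "flagged by both modes")
                 for rid in finalized.removed_chimeric)
    audit.extend((rid, "unclassified", "genus unclassified")
                 for rid in finalized.removed_unclassified)

    # carry forward the trimmed sequences, not the raw ones
    trimmed_by_id = {r.id: r for r in trimmed}
    final_records = [trimmed_by_id[rid] for rid in finalized.kept_ids]
    return BuildResult(final_records, clusters, finalized, audit)


def write_audit_tsv(audit: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstage_removed\treason\n")
        for rid, stage, reason in audit:
            fh.write(f"{rid}\t{stage}\t{reason}\n")


def write_cluster_tsv(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\trepresentative_id\n")
        for cluster in clusters:
            for mid in cluster.member_ids:
                fh.write(f"{mid}\t{cluster.representative_id}\n")
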
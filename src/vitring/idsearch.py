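"""Seed-and-extend nucleotide identity search over a persistent k-mer index.

Index construction and searching are deliberately separate steps: the
reference database changes rarely, so the postings table is built once,
serialized to disk, and reloaded for every query batch.  A query is
classified by counting shared k-mer seeds per reference (both strands),
then running a gapped affine extension of the query against a window of
the best-seeded references around the dominant seed diagonal.  The single
top hit passing the identity and alignment-length thresholds is reported;
no hit is a value, not an error.

Default thresholds follow the profiling workflow: identity >= 80 % and
alignment length >= 100 bp, with ties broken by higher identity, longer
alignment, then lexicographic reference id.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .alignment import DEFAULT_SCORING, Scoring, align_pair
from .records import SeqRecord, revcomp

INDEX_FORMAT_VERSION = 1

DEFAULT_K = 16
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_ALN_LEN = 100

# gapped extension window padding around the seeded diagonal, bp
_BAND_PAD = 60
# references with fewer shared seeds than this fraction of the best
# candidate's count are not extended
_MAX_CANDIDATES = 8


@dataclass(frozen=True)
class Hit:
    """Best-match result of an identity search."""

    query_id: str
    ref_id: str
    identity: float
    aln_len: int
    score: float
    strand: str = "+"

    def sort_key(self) -> tuple:
        # higher identity, then longer alignment, then lexicographic ref id
        return (-self.identity, -self.aln_len, self.ref_id)


@dataclass
class KmerIndex:
    """Postings table mapping every non-N k-mer of every reference to
    its (reference id, offset) occurrences, plus the reference sequences
    needed for gapped extension."""

    k: int
    postings: dict[str, list[tuple[str, int]]]
    ref_seqs: dict[str, str]

    @property
    def ref_lengths(self) -> dict[str, int]:
        return {rid: len(s) for rid, s in self.ref_seqs.items()}

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": INDEX_FORMAT_VERSION,
            "k": self.k,
            "postings": {
                kmer: [[rid, pos] for rid, pos in hits]
                for kmer, hits in self.postings.items()
            },
            "ref_seqs": self.ref_seqs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, separators=(",", ":"))

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format in {path}")
        postings = {
            kmer: [(rid, int(pos)) for rid, pos in hits]
            for kmer, hits in payload["postings"].items()
        }
        return cls(int(payload["k"]), postings, dict(payload["ref_seqs"]))


def build_index(refs: Sequence[SeqRecord], k: int = DEFAULT_K) -> KmerIndex:
    """Index every non-N k-mer of every reference sequence."""
    refs = list(refs)
    if not refs:
        raise ValueError("cannot index an empty reference set")
    shortest = min(r.length for r in refs)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest reference length {shortest}")
    postings: dict[str, list[tuple[str, int]]] = {}
    ref_seqs: dict[str, str] = {}
    for rec in refs:
        if rec.id in ref_seqs:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        ref_seqs[rec.id] = rec.seq
        seq = rec.seq
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            postings.setdefault(kmer, []).append((rec.id, pos))
    return KmerIndex(k, postings, ref_seqs)


def _seed_candidates(
    seq: str, index: KmerIndex, exclude: frozenset[str]
) -> dict[str, tuple[int, int]]:
    """Per reference: (total seed count, best diagonal by vote)."""
    k = index.k
    diag_votes: dict[str, Counter] = {}
    postings = index.postings
    for i in range(len(seq) - k + 1):
        hits = postings.get(seq[i : i + k])
        if not hits:
            continue
        for rid, j in hits:
            if rid in exclude:
                continue
            diag_votes.setdefault(rid, Counter())[j - i] += 1
    out: dict[str, tuple[int, int]] = {}
    for rid, votes in diag_votes.items():
        # dominant diagonal; ties to the smallest diagonal for determinism
        best_diag, _ = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        out[rid] = (sum(votes.values()), best_diag)
    return out


def _extend(
    query: SeqRecord,
    seq: str,
    strand: str,
    rid: str,
    diag: int,
    index: KmerIndex,
    scoring: Scoring,
) -> Optional[Hit]:
    ref = index.ref_seqs[rid]
    lo = max(0, diag - _BAND_PAD)
    hi = min(len(ref), diag + len(seq) + _BAND_PAD)
    window = ref[lo:hi]
    if not window:
        return None
    res = align_pair(window, seq, mode="local", scoring=scoring)
    if res.columns == 0:
        return None
    return Hit(query.id, rid, res.identity, res.columns, res.score, strand)


def search(
    query: SeqRecord,
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    scoring: Scoring = DEFAULT_SCORING,
    exclude: Iterable[str] = (),
) -> Optional[Hit]:
    """Top hit of a query against the index, or None below thresholds.

    Both strands are searched; the reverse-complement orientation is
    reported with strand "-".  ``exclude`` removes reference ids from
    consideration (used by leave-one-out validation).
    """
    if query.length < index.k:
        return None
    excluded = frozenset(exclude)
    candidates: list[tuple[int, str, str, int]] = []
    for strand, seq in (("+", query.seq), ("-", revcomp(query.seq))):
        for rid, (count, diag) in _seed_candidates(seq, index, excluded).items():
            candidates.append((count, strand, rid, diag))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[2], c[1]))
    best: Optional[Hit] = None
    for count, strand, rid, diag in candidates[:_MAX_CANDIDATES]:
        seq = query.seq if strand == "+" else revcomp(query.seq)
        hit = _extend(query, seq, strand, rid, diag, index, scoring)
        if hit is None:
            continue
        if hit.identity < min_identity or hit.aln_len < min_aln_len:
            continue
        if best is None or hit.sort_key() < best.sort_key():
            best = hit
    return best


def search_all(
    queries: Iterable[SeqRecord],
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
    scoring: Scoring = DEFAULT_SCORING,
) -> dict[str, Hit]:
    """Top hits for a query batch, keyed by query id (misses omitted)."""
    hits: dict[str, Hit] = {}
    for q in queries:
        hit = search(q, index, min_identity, min_aln_len, scoring)
        if hit is not None:
            hits[q.id] = hit
    return hits


def negative_screen(
    queries: Sequence[SeqRecord],
    negative_index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_len: int = DEFAULT_MIN_ALN_LEN,
) -> tuple[list[str], list[str]]:
    """Partition positively-hitting queries by a decoy (18S/mitochondrial
    rRNA) database: queries that also hit the decoy set at the same
    thresholds are excluded from profiling.

    Returns (excluded_ids, retained_ids) in input order.
    """
    excluded: list[str] = []
    retained: list[str] = []
    for q in queries:
        hit = search(q, negative_index, min_identity, min_aln_len)
        (excluded if hit is not None else retained).append(q.id)
    return excluded, retained


def write_hits_tsv(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tref_id\tidentity\taln_len\tstrand\tscore\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.ref_id}\t{h.identity:.4f}\t"
                f"{h.aln_len}\t{h.strand}\t{h.score:g}\n"
            )


def read_hits_tsv(path: str | Path) -> list[Hit]:
    hits: list[Hit] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query_id\t"):
            raise ValueError(f"{path}: not a hits TSV")
        for line in fh:
            qid, rid, ident, aln_len, strand, score = line.rstrip("\n").split("\t")
            hits.append(Hit(qid, rid, float(ident), int(aln_len), float(score), strand))
    return hits
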
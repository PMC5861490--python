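"""Affine-gap pairwise alignment shared by clustering, search and species calls.

Thin, deterministic wrapper around :class:`Bio.Align.PairwiseAligner`.
Identity is defined as matches / aligned columns, where columns count
matches, mismatches and gap columns alike; for global mode terminal gap
columns are included, for local mode only the locally aligned region
counts.  Default scoring is BLAST-like: match +1, mismatch -1, gap open
-2, gap extend -1 (a gap of length L costs 2 + (L-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .records import SeqRecord


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairwiseResult:
    """Summary of one pairwise alignment.

    identity is in percent; columns counts all aligned columns including
    gap columns; spans are half-open [start, end) intervals on each input.
    """

    identity: float
    columns: int
    score: float
    a_span: tuple[int, int]
    b_span: tuple[int, int]

    @property
    def aln_len(self) -> int:
        return self.columns


def _make_aligner(mode: str, scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _as_str(s: "str | SeqRecord") -> str:
    return s.seq if isinstance(s, SeqRecord) else s


def align_pair(
    a: "str | SeqRecord",
    b: "str | SeqRecord",
    mode: str = "global",
    scoring: Scoring = DEFAULT_SCORING,
) -> PairwiseResult:
    """Align two sequences and summarise identity, length and spans.

    mode is "global" (Needleman-Wunsch) or "local" (Smith-Waterman),
    both with affine gaps.  A local alignment with no positive-scoring
    region yields identity 0 over 0 columns.
    """
    sa, sb = _as_str(a), _as_str(b)
    if not sa or not sb:
        raise ValueError("align_pair requires non-empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner = _make_aligner(mode, scoring)
    alignments = aligner.align(sa, sb)
    try:
        aln = alignments[0]
    except IndexError:
        return PairwiseResult(0.0, 0, 0.0, (0, 0), (0, 0))
    counts = aln.counts()
    columns = aln.length
    matches = counts.identities
    identity = 100.0 * matches / columns if columns else 0.0
    blocks = aln.aligned
    if blocks.size:
        a_span = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
        b_span = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    else:
        a_span = b_span = (0, 0)
    return PairwiseResult(identity, int(columns), float(aln.score), a_span, b_span)
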
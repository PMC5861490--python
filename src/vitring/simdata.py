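"""Synthetic fixtures: trees, K2P-evolved 16S-like references, mock
communities with known copy numbers, and non-16S decoys.

Everything here is seed-deterministic and ships with a truth table, so
every classification, normalization and reconstruction step can be
scored without downloading real data.  The generator emulates the study
conditions of short-read 16S profiling: ~1.5 kb gene-length references
carrying the conserved 8F-primer and anti-Shine-Dalgarno anchor motifs,
Illumina-like 150 bp reads with uniform start positions and a
substitution-only error model, and read counts proportional to DNA
molarity times 16S copy number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .records import Lineage, SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"
# transition partner of each base (A<->G, C<->T), indexed as ACGT
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners of each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])

FIVE_PRIME_ANCHOR = "TTGATCCT"
THREE_PRIME_ANCHOR = "CACCTCCTTA"  # concrete instance of CACCTCCTTN
DEFAULT_GENE_LENGTH = 1500
DEFAULT_READ_LENGTH = 150


def random_gene_sequence(
    length: int = DEFAULT_GENE_LENGTH,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[str, np.ndarray]:
    """A random 16S-like gene with both trimming anchors embedded.

    The 5' anchor sits after a 6-base leader (so the default trim keeps
    the whole sequence); the 3' anchor forms the last ten bases.
    Returns (sequence, frozen positions) where the frozen positions mark
    anchor columns that evolution must not touch.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if length < 6 + len(FIVE_PRIME_ANCHOR) + len(THREE_PRIME_ANCHOR) + 50:
        raise ValueError("gene length too short to hold the anchors")
    seq = rng.choice(_BASES, size=length)
    start5 = 6
    for i, c in enumerate(FIVE_PRIME_ANCHOR):
        seq[start5 + i] = ord(c)
    start3 = length - len(THREE_PRIME_ANCHOR)
    for i, c in enumerate(THREE_PRIME_ANCHOR):
        seq[start3 + i] = ord(c)
    frozen = np.concatenate(
        [
            np.arange(start5, start5 + len(FIVE_PRIME_ANCHOR)),
            np.arange(start3, length),
        ]
    )
    return seq.tobytes().decode(), frozen


def simulate_tree(
    n_leaves: int,
    seed: int = 0,
    mean_branch: float = 0.05,
    prefix: str = "T",
    min_branch: float = 0.0,
) -> TreeNode:
    """Random topology by uniform pair joins with exponential branch
    lengths (optionally floored at ``min_branch`` so no two leaves are
    nearly identical); leaf names are ``{prefix}0001`` style."""
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = np.random.default_rng(seed)
    nodes = [f"{prefix}{i + 1:04d}" for i in range(n_leaves)]
    newicks = {name: name for name in nodes}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = min_branch + rng.exponential(mean_branch, size=2)
        merged = f"({newicks.pop(a)}:{la:.6f},{newicks.pop(b)}:{lb:.6f})"
        name = f"__anc{len(newicks)}__{a}"
        newicks[name] = merged
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [name]
    return TreeNode.read([newicks[nodes[0]] + ";"])


def _k2p_substitute(
    seq: np.ndarray,
    t: float,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    frozen: Optional[np.ndarray],
) -> np.ndarray:
    """Evolve base indices (0..3) along one branch of length t under the
    Kimura two-parameter model.

    alpha is the transition rate and beta the rate of each of the two
    transversions, giving the exact per-site change probabilities
    P(transition) = 1/4 + e1/4 - e2/2 and P(one transversion) =
    1/4 - e1/4, with e1 = exp(-4 beta t), e2 = exp(-2 (alpha+beta) t).
    """
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    u = rng.random(seq.size)
    out = seq.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2 = (u >= p_ts + p_tv_each) & (u < p_ts + 2.0 * p_tv_each)
    out[ts] = _TRANSITION[seq[ts]]
    out[tv1] = _TRANSVERSIONS[seq[tv1], 0]
    out[tv2] = _TRANSVERSIONS[seq[tv2], 1]
    if frozen is not None:
        out[frozen] = seq[frozen]
    return out


def evolve_sequences(
    tree: TreeNode,
    root_seq: str,
    transition_rate: float = 2.0 / 3.0,
    transversion_rate: float = 1.0 / 6.0,
    seed: int = 0,
    frozen_positions: Optional[np.ndarray] = None,
) -> list[SeqRecord]:
    """Forward K2P simulation down a tree; returns one gap-free aligned
    record per leaf (the alignment is trivial because the model is
    substitution-only).  Anchor motif columns can be frozen so reference
    trimming stays exercisable on the output.

    The default rates give a 2:1 transition:transversion substitution
    ratio and a total rate of 1, so branch lengths are in expected
    substitutions per site."""
    if transition_rate < 0 or transversion_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    lookup = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_BASE_STR):
        lookup[ord(b)] = i
    root = lookup[np.frombuffer(root_seq.encode(), dtype=np.uint8)]
    if (root < 0).any():
        raise ValueError("root sequence must be over {A,C,G,T}")
    records: list[SeqRecord] = []

    def descend(node: TreeNode, state: np.ndarray) -> None:
        for child in node.children:
            t = float(child.length or 0.0)
            child_state = _k2p_substitute(
                state, t, transition_rate, transversion_rate, rng,
                frozen_positions,
            )
            if child.is_tip():
                seq = "".join(_BASE_STR[i] for i in child_state)
                records.append(SeqRecord(child.name, seq))
            else:
                descend(child, child_state)

    descend(tree, root)
    records.sort(key=lambda r: r.id)
    return records


@dataclass
class MockSpecies:
    record: SeqRecord
    genus: str
    species: str
    molarity: float
    copy_number: int


@dataclass
class MockCommunity:
    """A known community: per species a reference sequence, genus and
    species names, DNA molarity and 16S copy number.  The expected read
    share of a species is proportional to molarity x copy number."""

    species: list[MockSpecies]
    read_length: int = DEFAULT_READ_LENGTH
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sp in self.species:
            if sp.molarity <= 0:
                raise ValueError(f"{sp.species}: molarity must be positive")
            if sp.copy_number < 1:
                raise ValueError(f"{sp.species}: copy number must be >= 1")

    @property
    def expected_read_share(self) -> dict[str, float]:
        w = {sp.species: sp.molarity * sp.copy_number for sp in self.species}
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}

    @property
    def molarity_share(self) -> dict[str, float]:
        total = sum(sp.molarity for sp in self.species)
        return {sp.species: sp.molarity / total for sp in self.species}

    @property
    def genus_molarity_share(self) -> dict[str, float]:
        w: dict[str, float] = {}
        for sp in self.species:
            w[sp.genus] = w.get(sp.genus, 0.0) + sp.molarity
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}


def make_mock_community(
    n_species: int = 10,
    seed: int = 0,
    gene_length: int = DEFAULT_GENE_LENGTH,
    copy_numbers: Optional[Sequence[int]] = None,
    error_rate: float = 0.0,
    divergence: float = 0.10,
) -> MockCommunity:
    """A mock community of K2P-diverged species with known copy numbers.

    Species descend from one random ancestor along a random tree whose
    branch lengths are scaled so typical pairwise divergence is around
    ``divergence`` substitutions/site — separable by the 94 % genus
    threshold but solidly within the 80 % search threshold.  Copy numbers
    default to cycling 1..10; molarities are drawn log-uniform over one
    decade.
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, seed=seed, mean_branch=divergence / 2.0,
                         prefix="SP", min_branch=divergence / 3.0)
    root, frozen = random_gene_sequence(gene_length, rng=rng)
    refs = evolve_sequences(
        tree, root, seed=seed + 1, frozen_positions=frozen
    )
    if copy_numbers is None:
        copy_numbers = [(i % 10) + 1 for i in range(n_species)]
    molarities = 10.0 ** rng.uniform(-1.0, 0.0, size=n_species)
    species: list[MockSpecies] = []
    for i, rec in enumerate(refs):
        genus = f"Genus_{i + 1:02d}"
        name = f"Species_{i + 1:02d}"
        rec.lineage = Lineage(
            "Bacteria", f"Phylum_{(i % 4) + 1}", f"Class_{(i % 6) + 1}",
            f"Order_{i + 1}", f"Family_{i + 1}", genus,
        )
        species.append(
            MockSpecies(rec, genus, name, float(molarities[i]),
                        int(copy_numbers[i]))
        )
    return MockCommunity(species, error_rate=error_rate, seed=seed)


def simulate_reads(
    community: MockCommunity,
    n_reads: int,
    seed: Optional[int] = None,
    both_strands: bool = True,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw reads from a mock community with a known truth table.

    Species are sampled with probability proportional to molarity x copy
    number; start positions are uniform; errors are substitutions at the
    community error rate.  Returns (reads, truth) where truth has one row
    per read: read_id, species, genus, source_ref, start, strand.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(community.seed if seed is None else seed)
    weights = np.array(
        [sp.molarity * sp.copy_number for sp in community.species]
    )
    probs = weights / weights.sum()
    choices = rng.choice(len(community.species), size=n_reads, p=probs)
    reads: list[SeqRecord] = []
    truth_rows: list[tuple] = []
    L = community.read_length
    for i, si in enumerate(choices):
        sp = community.species[si]
        ref = sp.record.seq
        if len(ref) < L:
            raise ValueError(f"{sp.species}: reference shorter than read")
        start = int(rng.integers(0, len(ref) - L + 1))
        seq = ref[start : start + L]
        if community.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            errs = np.nonzero(rng.random(L) < community.error_rate)[0]
            for pos in errs:
                cur = _BASE_STR.index(chr(arr[pos]))
                alt = (cur + int(rng.integers(1, 4))) % 4
                arr[pos] = ord(_BASE_STR[alt])
            seq = arr.tobytes().decode()
        strand = "+"
        if both_strands and rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        rid = f"read_{i:06d}"
        reads.append(SeqRecord(rid, seq))
        truth_rows.append(
            (rid, sp.species, sp.genus, sp.record.id, start, strand)
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "species", "genus", "source_ref", "start",
                 "strand"],
    )
    return reads, truth


def make_contaminants(
    n: int,
    kinds: Sequence[str] = ("random",),
    seed: int = 0,
    length: int = DEFAULT_READ_LENGTH,
) -> list[SeqRecord]:
    """Synthetic non-16S decoy sequences (tRNA-like, 23S-like or plain
    random), unrelated to any 16S reference generated here.

    "tRNA-like" decoys are short (~76 bp) and GC-rich; "23S-like" decoys
    are long random sequences; "random" decoys have the requested length.
    All are independent random draws, so their identity to any evolved
    16S reference stays far below the 80 % search threshold.
    """
    rng = np.random.default_rng(seed)
    out: list[SeqRecord] = []
    for i in range(n):
        kind = kinds[i % len(kinds)]
        if kind == "tRNA-like":
            probs = np.array([0.2, 0.3, 0.3, 0.2])  # GC-rich
            size = 76
        elif kind == "23S-like":
            probs = np.full(4, 0.25)
            size = max(length, 500)
        elif kind == "random":
            probs = np.full(4, 0.25)
            size = length
        else:
            raise ValueError(f"unknown contaminant kind {kind!r}")
        seq = rng.choice(_BASES, size=size, p=probs).tobytes().decode()
        out.append(SeqRecord(f"decoy_{kind}_{i:04d}", seq))
    return out
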
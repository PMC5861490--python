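"""Circular phylogenetic layout via tree-topology scanning.

Given a multiple alignment of reference 16S sequences, this module

1. computes all-pairs Kimura two-parameter (K2P) distances,
2. builds a neighbor-joining tree,
3. linearizes the tree into a single leaf order by *tree topology
   scanning*: starting from a chosen initial leaf, the most distant leaf
   is found; the next leaf is the most distant one inside the smallest
   ancestral clade of the previously chosen leaf that still contains
   unordered leaves, expanding outward clade by clade until all leaves
   are ordered;
4. places the ordered leaves on a circle, each consecutive gap
   proportional to the distance between neighbors (the ring closes with
   the last-to-first distance), and
5. assigns each taxon (phylum/class or genus) the circular mean of its
   members' angles.

"Distance" in the scan is the K2P matrix distance by default — the same
quantity compared when the farthest leaf is identified — with patristic
tree distance available as an option; the tree supplies clade structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .records import Lineage, SeqRecord

#: multiplier applied to the largest finite distance to stand in for
#: saturated (log-undefined) K2P pairs
SATURATION_FACTOR = 1.5

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

# byte codes for vectorized column classification
_CODE = np.zeros(256, dtype=np.int8)  # 0 = excluded (gap/N/other)
for _b, _c in (("A", 1), ("G", 2), ("C", 3), ("T", 4)):
    _CODE[ord(_b)] = _c


def k2p_distance(aligned_a: str, aligned_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Columns where either sequence has a gap or ambiguous base are
    excluded.  With P and Q the transition and transversion fractions
    over included columns, d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)).
    Saturated pairs (log argument <= 0) return ``inf``.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = _CODE[np.frombuffer(aligned_a.encode(), dtype=np.uint8)]
    b = _CODE[np.frombuffer(aligned_b.encode(), dtype=np.uint8)]
    ok = (a > 0) & (b > 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable columns")
    av, bv = a[ok], b[ok]
    diff = av != bv
    # purines coded 1,2; pyrimidines 3,4 — a within-group difference is
    # a transition, a between-group difference a transversion
    same_group = ((av <= 2) & (bv <= 2)) | ((av >= 3) & (bv >= 3))
    p = float((diff & same_group).sum()) / n
    q = float((diff & ~same_group).sum()) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1 * math.sqrt(w2))


def build_distance_matrix(
    alignment: Sequence[SeqRecord],
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """All-pairs K2P distances over a gap-aware multiple alignment.

    Saturated pairs are recorded and replaced by 1.5x the largest finite
    distance so downstream tree building stays defined.
    Returns (matrix, saturated_pairs).
    """
    ids = [r.id for r in alignment]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in alignment")
    n = len(alignment)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            dij = k2p_distance(alignment[i].seq, alignment[j].seq)
            if math.isinf(dij):
                saturated.append((ids[i], ids[j]))
            d[i, j] = d[j, i] = dij
    if saturated:
        finite = d[np.isfinite(d)]
        ceiling = float(finite.max()) * SATURATION_FACTOR if finite.size else 1.0
        d[~np.isfinite(d)] = ceiling
    return DistanceMatrix(d, ids), saturated


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei); negative branch-length
    estimates are clamped to zero.  Additive matrices are recovered
    exactly.  Fewer than three taxa yield a trivial tree."""
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa")
    if len(ids) == 2:
        half = dm[ids[0], ids[1]] / 2.0
        return TreeNode.read([f"({ids[0]}:{half},{ids[1]}:{half});"])
    return nj(dm, neg_as_zero=True)


@dataclass
class CircularOrder:
    """An ordered leaf list with neighbor gaps and (optionally) angles."""

    ordered_ids: list[str]
    gaps: np.ndarray  # len(ordered_ids) - 1 consecutive distances
    angles: Optional[np.ndarray] = None  # radians in [0, 2pi), increasing

    def __post_init__(self) -> None:
        if len(self.gaps) != len(self.ordered_ids) - 1:
            raise ValueError("gaps must have one entry per consecutive pair")

    def angle_of(self, leaf_id: str) -> float:
        if self.angles is None:
            raise ValueError("angles not yet computed")
        return float(self.angles[self.ordered_ids.index(leaf_id)])


def _adjacency(tree: TreeNode) -> dict[str, list[tuple[str, float]]]:
    """Undirected adjacency over uniquely named nodes of the tree."""
    counter = 0
    names: dict[int, str] = {}
    for node in tree.traverse(include_self=True):
        if node.is_tip():
            names[id(node)] = node.name
        else:
            names[id(node)] = f"__internal_{counter}"
            counter += 1
    adj: dict[str, list[tuple[str, float]]] = {}
    for node in tree.traverse(include_self=True):
        for child in node.children:
            w = float(child.length or 0.0)
            adj.setdefault(names[id(node)], []).append((names[id(child)], w))
            adj.setdefault(names[id(child)], []).append((names[id(node)], w))
    return adj


def patristic_distances(tree: TreeNode, source: str) -> dict[str, float]:
    """Path-length distances from one leaf to every other leaf."""
    adj = _adjacency(tree)
    if source not in adj:
        raise KeyError(f"leaf {source!r} not in tree")
    dist = {source: 0.0}
    stack = [source]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return {k: v for k, v in dist.items() if not k.startswith("__internal_")}


def tree_topology_scan(
    tree: TreeNode,
    dist: DistanceMatrix,
    initial_id: str,
    use_matrix_distance: bool = True,
) -> CircularOrder:
    """Linearize a tree into a circular leaf order by clade expansion.

    Rooting the tree at the initial leaf, the farthest leaf from the
    initial is chosen first; thereafter, the smallest ancestral clade of
    the last-chosen leaf that still contains unordered leaves supplies
    the next choice (again the farthest from the initial), so the order
    expands outward through peripheral clades.  The far-to-near sequence
    is reversed and prefixed with the initial leaf; consecutive gaps are
    the pairwise distances between list neighbors.

    Distances are read from the K2P matrix by default, or from tree path
    lengths when ``use_matrix_distance`` is False.  Distance ties break
    by lexicographic id.
    """
    tips = {t.name for t in tree.tips()}
    if initial_id not in tips:
        raise KeyError(f"initial leaf {initial_id!r} not in tree")

    if use_matrix_distance:
        d0 = {t: float(dist[initial_id, t]) for t in tips if t != initial_id}
    else:
        d0 = {
            t: v
            for t, v in patristic_distances(tree, initial_id).items()
            if t != initial_id
        }

    # root the topology at the initial leaf: parent pointers + leaf sets
    adj = _adjacency(tree)
    parent: dict[str, Optional[str]] = {initial_id: None}
    order: list[str] = [initial_id]
    stack = [initial_id]
    while stack:
        u = stack.pop()
        for v, _ in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    leafset: dict[str, set[str]] = {n: set() for n in parent}
    for n in reversed(order):
        if not n.startswith("__internal_") and n != initial_id:
            leafset[n].add(n)
        p = parent[n]
        if p is not None:
            leafset[p] |= leafset[n]

    unordered = set(d0)
    emitted: list[str] = []

    def farthest(cands: set[str]) -> str:
        # distance ties break toward the lexicographically smallest id
        return min(cands, key=lambda t: (-d0[t], t))

    current = farthest(unordered)
    emitted.append(current)
    unordered.discard(current)
    while unordered:
        node = parent[current]
        while node is not None:
            cands = leafset[node] & unordered
            if cands:
                current = farthest(cands)
                emitted.append(current)
                unordered.discard(current)
                break
            node = parent[node]
        else:  # pragma: no cover - root leafset contains all leaves
            raise RuntimeError("clade expansion exhausted the tree")

    ordered_ids = [initial_id] + emitted[::-1]

    def pair_dist(a: str, b: str) -> float:
        if use_matrix_distance:
            return float(dist[a, b])
        return patristic_distances(tree, a)[b]

    gaps = np.array(
        [pair_dist(ordered_ids[i], ordered_ids[i + 1])
         for i in range(len(ordered_ids) - 1)]
    )
    return CircularOrder(ordered_ids, gaps)


def circular_positions(
    order: CircularOrder, closing_gap: float
) -> CircularOrder:
    """Assign angles: arc between neighbors proportional to their gap,
    with ``closing_gap`` (the last-to-first distance) completing the
    ring.  All-zero gaps fall back to uniform spacing."""
    n = len(order.ordered_ids)
    total = float(order.gaps.sum()) + float(closing_gap)
    if total <= 0.0:
        angles = 2.0 * math.pi * np.arange(n) / n
    else:
        cum = np.concatenate([[0.0], np.cumsum(order.gaps)])
        angles = 2.0 * math.pi * cum / total
    return CircularOrder(order.ordered_ids, order.gaps, angles)


@dataclass(frozen=True)
class TaxonPosition:
    taxon: str
    angle: float  # radians in [0, 2pi)
    level: str
    n_members: int


def circular_mean(angles: Sequence[float]) -> float:
    """Mean direction of angles via summed unit vectors; a degenerate
    (antipodal) mean ties toward the smallest member angle."""
    s = float(np.sum(np.sin(angles)))
    c = float(np.sum(np.cos(angles)))
    if math.hypot(s, c) < 1e-12:
        return float(min(angles)) % (2.0 * math.pi)
    mean = math.atan2(s, c) % (2.0 * math.pi)
    # guard the half-open interval against rounding at the seam
    return 0.0 if mean >= 2.0 * math.pi else mean


def taxon_positions(
    order: CircularOrder,
    lineage_map: dict[str, Lineage],
    level: str,
) -> list[TaxonPosition]:
    """Circular-mean position of every taxon at the requested rank."""
    if order.angles is None:
        raise ValueError("compute circular_positions first")
    groups: dict[str, list[float]] = {}
    for leaf, angle in zip(order.ordered_ids, order.angles):
        lineage = lineage_map.get(leaf)
        if lineage is None:
            raise KeyError(f"no lineage for leaf {leaf!r}")
        groups.setdefault(lineage.rank(level), []).append(float(angle))
    return [
        TaxonPosition(taxon, circular_mean(angles), level, len(angles))
        for taxon, angles in sorted(groups.items())
    ]


# ---------------------------------------------------------------------------
# I/O

def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"    {len(dm.ids)}\n")
        for rid in dm.ids:
            row = "  ".join(f"{dm[rid, other]:.6f}" for other in dm.ids)
            fh.write(f"{rid}  {row}\n")


def read_phylip_matrix(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        n = int(fh.readline().strip())
        ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(ids) != n:
        raise ValueError(f"{path}: expected {n} rows, found {len(ids)}")
    return DistanceMatrix(np.array(rows), ids)


def write_layout_json(
    order: CircularOrder,
    lineage_map: dict[str, Lineage],
    path: str | Path,
    taxa: Optional[Sequence[TaxonPosition]] = None,
) -> None:
    """JSON layout export: per-leaf {id, angle, taxon} plus optional
    per-taxon ring annotations."""
    if order.angles is None:
        raise ValueError("compute circular_positions first")
    leaves = [
        {
            "id": leaf,
            "angle": float(angle),
            "taxon": lineage_map[leaf].genus if leaf in lineage_map else None,
        }
        for leaf, angle in zip(order.ordered_ids, order.angles)
    ]
    payload: dict = {"leaves": leaves}
    if taxa is not None:
        payload["taxa"] = [
            {"taxon": t.taxon, "angle": t.angle, "level": t.level,
             "n_members": t.n_members}
            for t in taxa
        ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_layout_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
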
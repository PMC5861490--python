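"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths and third-party
aligners: a plain-Python affine-gap Gotoh dynamic program with traceback,
and dendropy-based patristic distance computation.
"""

from __future__ import annotations

import dendropy

NEG_INF = float("-inf")


def gotoh_align(
    a: str,
    b: str,
    mode: str = "global",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
):
    """Exhaustive affine-gap DP with traceback.

    Gap scoring matches the convention where the first gapped position
    costs ``gap_open`` and each further position ``gap_extend``.
    Returns (score, identity_percent, columns).
    """
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    local = mode == "local"
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend if not local else NEG_INF
        if local:
            M[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend if not local else NEG_INF
        if local:
            M[0][j] = 0.0
    best = (0.0, 0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            diag = max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            mv = diag + s if diag > NEG_INF else NEG_INF
            if local and mv < 0.0:
                mv = 0.0
            Mi[j] = mv
            Xi[j] = max(
                Mp[j] + gap_open,
                Xp[j] + gap_extend,
                Yp[j] + gap_open,
            )
            Yi[j] = max(
                Mi[j - 1] + gap_open,
                Yi[j - 1] + gap_extend,
                Xi[j - 1] + gap_open,
            )
            if local and Mi[j] > best[0]:
                # strict improvement: of co-optimal end cells keep the
                # earliest, i.e. the most compact alignment
                best = (Mi[j], i, j)
    if local:
        score, ei, ej = best
    else:
        score = max(M[n][m], X[n][m], Y[n][m])
        ei, ej = n, m

    # traceback counting matches and columns
    i, j = ei, ej
    if local:
        state = "M"
    else:
        state = max(
            (("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])),
            key=lambda kv: kv[1],
        )[0]
    matches = columns = 0
    while i > 0 or j > 0:
        if state == "M":
            cur = M[i][j]
            if local and cur == 0.0:
                break
            if i == 0 or j == 0:
                # global boundary: remaining run is all gap
                state = "X" if i > 0 else "Y"
                continue
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = cur - s
            if local and prev == 0.0 and M[i - 1][j - 1] != prev:
                # local alignment start reached via the 0 reset
                if X[i - 1][j - 1] != prev and Y[i - 1][j - 1] != prev:
                    i, j = i - 1, j - 1
                    break
            if M[i - 1][j - 1] == prev:
                state = "M"
            elif X[i - 1][j - 1] == prev:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            cur = X[i][j]
            columns += 1
            if X[i - 1][j] + gap_extend == cur:
                state = "X"
            elif M[i - 1][j] + gap_open == cur:
                state = "M"
            else:
                state = "Y"
            i -= 1
        else:
            cur = Y[i][j]
            columns += 1
            if Y[i][j - 1] + gap_extend == cur:
                state = "Y"
            elif M[i][j - 1] + gap_open == cur:
                state = "M"
            else:
                state = "X"
            j -= 1
        if local and state == "M" and M[i][j] == 0.0 and (i == 0 or j == 0):
            break
    identity = 100.0 * matches / columns if columns else 0.0
    return score, identity, columns


def patristic_matrix(newick: str) -> dict[tuple[str, str], float]:
    """All-pairs leaf path distances from a newick string via dendropy."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for t1 in taxa:
        for t2 in taxa:
            out[(t1.label, t2.label)] = (
                0.0 if t1 is t2 else pdm.patristic_distance(t1, t2)
            )
    return out


def scan_order_by_dfs(newick: str, initial: str, dist: dict) -> list[str]:
    """Independent formulation of the clade-expansion leaf ordering.

    Rooting at the initial leaf and visiting child clades in increasing
    order of their most-distant-from-initial leaf yields the near-to-far
    ordering directly (ties on distance break by smallest leaf label).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    node = next(
        l for l in tree.leaf_node_iter() if l.taxon.label == initial
    )
    tree.reroot_at_node(node, update_bipartitions=False)

    def leaves_under(nd):
        return [l.taxon.label for l in nd.leaf_iter()]

    order: list[str] = []

    def visit(nd):
        if nd.is_leaf():
            label = nd.taxon.label
            if label != initial:
                order.append(label)
            return
        children = sorted(
            nd.child_nodes(),
            key=lambda c: (
                max(dist[(initial, l)] for l in leaves_under(c)
                    if l != initial)
                if any(l != initial for l in leaves_under(c)) else -1.0,
                min(leaves_under(c)),
            ),
        )
        for child in children:
            visit(child)

    visit(tree.seed_node)
    return [initial] + order
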
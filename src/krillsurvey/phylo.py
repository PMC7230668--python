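"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

For a protein multiple alignment (an input here — alignment itself is
upstream), the pairwise p-distance is the fraction of differing residues
over columns where both sequences are ungapped, optionally Poisson-
corrected (-ln(1-p), p capped at 0.95). Trees are built with the
Saitou-Nei neighbor-joining algorithm, which recovers the generating
tree exactly on additive distance matrices; clade confidence comes from
column-resampling bootstrap, each internal edge scored with the
percentage of replicate trees containing the same bipartition.

Trees are scikit-bio ``TreeNode`` objects (unrooted, represented with a
trifurcating root); supports are stored on internal nodes as
``node.support`` and written as internal labels in Newick output.
"""

from __future__ import annotations

import math
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .seq_io import SeqRecord

__all__ = [
    "p_distance",
    "nj_build",
    "bootstrap_support",
    "tree_bipartitions",
    "write_newick",
]

_P_CAP = 0.95


def _pairwise_p(a: str, b: str) -> float:
    diff = comparable = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable (both-ungapped) columns")
    return diff / comparable


def p_distance(
    alignment: Sequence[SeqRecord], poisson: bool = False
) -> DistanceMatrix:
    """Pairwise p-distances of an aligned protein set.

    With ``poisson=True`` distances are corrected as -ln(1-p), with p
    capped at 0.95 to keep saturated pairs finite.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(r.seq) for r in alignment}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _pairwise_p(alignment[i].seq.upper(), alignment[j].seq.upper())
            if poisson:
                p = -math.log(1.0 - min(p, _P_CAP))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, [r.id for r in alignment])


def nj_build(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei) of a distance matrix.

    At each step the pair minimising the Q-criterion
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is joined, ties
    broken by the smallest (i,j) index pair in the current matrix order.
    Branch lengths follow the standard NJ formulas; negative estimates
    are clamped to zero and counted on the returned tree as
    ``tree.negative_branches_clamped``.
    """
    taxa = list(dm.ids)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: List[TreeNode] = [TreeNode(name=t) for t in taxa]
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        sums = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if q < best_q - 1e-12:  # strict improvement; earliest pair wins ties
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = clamp(li)
        cj.length = clamp(lj)
        parent.extend([ci, cj])
        # distances from the new node to the others
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        d2 = np.zeros((r - 1, r - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # final three-point join
    (a, b, c) = nodes
    da, db, dc = d[0, 1], d[0, 2], d[1, 2]
    root = TreeNode()
    a.length = clamp(0.5 * (da + db - dc))
    b.length = clamp(0.5 * (da + dc - db))
    c.length = clamp(0.5 * (db + dc - da))
    root.extend([a, b, c])
    root.negative_branches_clamped = clamped
    return root


def tree_bipartitions(tree: TreeNode) -> Set[FrozenSet[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented by the side of the split that does
    not contain the lexicographically smallest taxon, as a frozenset of
    tip names.
    """
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    all_tips = frozenset(tips)
    out: Set[FrozenSet[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        if anchor in side:
            side = all_tips - side
        out.add(side)
    return out


def bootstrap_support(
    alignment: Sequence[SeqRecord],
    replicates: int = 1000,
    seed: Optional[int] = None,
    poisson: bool = False,
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``replicates``
    times; each internal edge of the full-data tree carries
    ``node.support``, the percentage (0-100 integer) of successful
    replicates whose tree contains the same bipartition. Replicates
    whose resampled columns defeat the distance computation (no
    comparable columns for some pair) are skipped and counted as
    ``tree.failed_replicates``. An all-identical alignment yields
    ``tree.degenerate = True``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base_dm = p_distance(alignment, poisson=poisson)
    tree = nj_build(base_dm)
    tree.degenerate = not np.any(np.asarray(base_dm.data) > 0)

    rng = np.random.default_rng(seed)
    ncols = len(alignment[0].seq)
    counts: Dict[FrozenSet[str], int] = {bp: 0 for bp in tree_bipartitions(tree)}
    failed = 0
    ok = 0
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = [
            SeqRecord(id=r.id, seq="".join(r.seq[c] for c in cols))
            for r in alignment
        ]
        try:
            rep_tree = nj_build(p_distance(resampled, poisson=poisson))
        except ValueError:
            failed += 1
            continue
        ok += 1
        for bp in tree_bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1

    denom = ok if ok else 1
    supports = {bp: round(100.0 * c / denom) for bp, c in counts.items()}
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    all_tips = frozenset(tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if side in supports:
            node.support = supports[side]
    tree.failed_replicates = failed
    tree.completed_replicates = ok
    return tree


def write_newick(
    tree: TreeNode, path, outgroup: Optional[str] = None
) -> None:
    """Write Newick with branch lengths and integer supports as internal
    labels, optionally rooted (for display) on a named outgroup leaf."""
    # supports keyed by bipartition survive copying/rerooting
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    all_tips = frozenset(tips)

    def norm(node) -> FrozenSet[str]:
        side = frozenset(t.name for t in node.tips())
        return all_tips - side if anchor in side else side

    supports = {
        norm(n): getattr(n, "support")
        for n in tree.non_tips(include_self=False)
        if getattr(n, "support", None) is not None
    }
    tree = tree.copy()
    if outgroup is not None:
        tip = tree.find(outgroup)
        tree = tree.root_at(tip.parent)
    for node in tree.non_tips(include_self=False):
        # skbio's newick writer emits node.support as the internal label
        node.support = supports.get(norm(node))
    tree.write(str(path), format="newick")
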
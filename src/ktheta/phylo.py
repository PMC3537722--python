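"""Neighbor-joining trees, bootstrap supports, rooting, and sister-clade pairs.

Trees are :class:`dendropy.Tree` objects with branch lengths in
substitutions/site.  Bipartitions are keyed by the frozenset of leaf labels
on the side of the split that excludes the alphabetically first leaf, which
makes the key independent of rooting.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .distances import DistanceMatrix, distance_matrix
from .errors import TreeError, OutgroupError
from .seqio import Alignment

__all__ = [
    "neighbor_joining",
    "root_on_outgroup",
    "bootstrap_supports",
    "supported_sister_pairs",
    "bipartition_key",
    "tree_bipartitions",
    "leaf_set",
    "annotate_supports",
]

logger = logging.getLogger(__name__)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Build an unrooted NJ tree by Q-criterion agglomeration.

    On an additive input matrix the leaf-to-leaf path lengths reproduce the
    matrix exactly.  Ties in the Q criterion are broken by the
    lexicographically smallest label pair (internal clusters are represented
    by their smallest member label), so the result is deterministic across
    platforms.  Negative branch-length estimates are clamped to zero with the
    deficit moved to the sister branch.
    """
    n = dm.n
    if n < 3:
        raise TreeError("neighbor joining requires at least 3 taxa")
    if np.any(dm.saturated):
        raise TreeError("distance matrix contains saturated (flagged) entries")

    tns = dendropy.TaxonNamespace(list(dm.labels))
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in dm.labels]
    reps = list(dm.labels)  # representative (smallest) label per cluster
    D = dm.values.astype(float).copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0.0:
            logger.debug("clamping negative branch length %.3g to 0", li)
            lj += li
            li = 0.0
        if lj < 0.0:
            logger.debug("clamping negative branch length %.3g to 0", lj)
            li += lj
            li = max(li, 0.0)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=0)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = {(min(int(a), int(b)), max(int(a), int(b))) for a, b in np.argwhere(Q == qmin)}
        i, j = min(cand, key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))))
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = clamp(li, lj)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(k) if x not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        reps = [reps[x] for x in keep] + [min(reps[i], reps[j])]

    tree = dendropy.Tree(taxon_namespace=tns)
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        tree.seed_node.add_child(node)
        node.edge.length = max(length, 0.0)
        if length < 0.0:
            logger.debug("clamping negative terminal branch length %.3g to 0", length)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartition bookkeeping


def leaf_set(node: dendropy.Node) -> frozenset[str]:
    """Frozenset of leaf labels below *node* (inclusive for a leaf)."""
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bipartition_key(side: Iterable[str], all_labels: Iterable[str]) -> frozenset[str]:
    """Rooting-independent key for the split *side* vs the rest.

    Returns whichever side of the split excludes the alphabetically first
    label of the full leaf set.
    """
    side = frozenset(side)
    universe = frozenset(all_labels)
    ref = min(universe)
    return side if ref not in side else universe - side


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Keys of all non-trivial bipartitions induced by internal edges."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.postorder_internal_node_iter(exclude_seed_node=True):
        side = leaf_set(node)
        if len(side) >= 2 and len(labels) - len(side) >= 2:
            out.add(bipartition_key(side, labels))
    return out


def annotate_supports(tree: dendropy.Tree, supports: Mapping[frozenset, float]) -> dendropy.Tree:
    """Write support percentages onto internal node labels (in place)."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for node in tree.postorder_internal_node_iter(exclude_seed_node=True):
        side = leaf_set(node)
        if len(side) >= 2 and len(labels) - len(side) >= 2:
            sup = supports.get(bipartition_key(side, labels))
            if sup is not None:
                node.label = f"{sup:g}"
    return tree


# ---------------------------------------------------------------------------
# rooting


def root_on_outgroup(tree: dendropy.Tree, outgroup: Iterable[str]) -> dendropy.Tree:
    """Root a tree so the outgroup is sister to everything else.

    The outgroup must be a proper nonempty subset of the leaves and must be
    monophyletic in the unrooted tree.  Rooting an already-correctly-rooted
    tree is a no-op (idempotent).
    """
    og = frozenset(outgroup)
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not og:
        raise OutgroupError("outgroup is empty")
    if not og <= labels:
        raise OutgroupError(f"outgroup labels not in tree: {sorted(og - labels)}")
    if og == labels:
        raise OutgroupError("outgroup cannot contain every leaf")

    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2 and any(leaf_set(c) == og for c in root_children):
        return tree.clone(depth=1)

    work = tree.clone(depth=1)
    target = None
    for node in work.postorder_node_iter():
        if node is work.seed_node:
            continue
        side = leaf_set(node)
        if side == og or labels - side == og:
            target = node
            break
    if target is None:
        # find the smallest clade containing the outgroup to report conflicts
        best = labels
        for node in work.postorder_node_iter():
            side = leaf_set(node)
            if og <= side and len(side) < len(best):
                best = side
        raise OutgroupError(
            f"outgroup is not monophyletic; smallest containing clade also holds "
            f"{sorted(best - og)}"
        )
    length = target.edge.length or 0.0
    work.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    work.is_rooted = True
    # make sure the outgroup side is attached directly at the root
    return work


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_supports(
    aln: Alignment,
    model: str,
    B: int,
    seed,
    tree: dendropy.Tree | None = None,
) -> dict[frozenset, float]:
    """Nonparametric bootstrap supports for the point-estimate NJ tree.

    Columns are resampled with replacement *B* times; each replicate matrix is
    re-joined and its bipartitions tallied against those of the point-estimate
    tree.  Returns ``{bipartition key: percent of replicates}``; deterministic
    given *seed*.
    """
    if B < 1:
        raise ValueError("bootstrap replicate count B must be >= 1")
    rng = np.random.default_rng(seed)
    if tree is None:
        tree = neighbor_joining(distance_matrix(aln, model))
    reference = tree_bipartitions(tree)
    counts = {bp: 0 for bp in reference}
    for _ in range(B):
        cols = rng.integers(0, aln.L, size=aln.L)
        replicate = Alignment(ids=aln.ids, residues=aln.residues[:, cols])
        rep_tree = neighbor_joining(distance_matrix(replicate, model))
        rep_bps = tree_bipartitions(rep_tree)
        for bp in reference:
            if bp in rep_bps:
                counts[bp] += 1
    return {bp: 100.0 * c / B for bp, c in counts.items()}


# ---------------------------------------------------------------------------
# supported sister pairs


def collapse_unsupported(
    tree: dendropy.Tree,
    supports: Mapping[frozenset, float],
    threshold: float,
) -> dendropy.Tree:
    """Copy of *tree* with internal edges below *threshold* support collapsed."""
    work = tree.clone(depth=1)
    labels = frozenset(lf.taxon.label for lf in work.leaf_node_iter())
    for node in list(work.postorder_internal_node_iter(exclude_seed_node=True)):
        side = leaf_set(node)
        if len(side) < 2 or len(labels) - len(side) < 2:
            continue  # trivial split: always retained
        sup = supports.get(bipartition_key(side, labels), 0.0)
        if sup < threshold:
            parent = node.parent_node
            for child in node.child_nodes():
                parent.add_child(child)
            parent.remove_child(node)
    return work


def mean_between(dm: DistanceMatrix, a: Iterable[str], b: Iterable[str]) -> float:
    """Mean pairwise distance between two disjoint label sets."""
    ia = [dm.index(x) for x in a]
    ib = [dm.index(x) for x in b]
    return float(dm.values[np.ix_(ia, ib)].mean())


def _fold_order(children_sets, dm: DistanceMatrix | None):
    """Pair-emission order for a multifurcation (nearest children first)."""
    sets = list(children_sets)
    if len(sets) == 2:
        return [(sets[0], sets[1])]
    if dm is None:
        order = list(range(len(sets)))
        first, second = order[0], order[1]
    else:
        pairs = [
            (mean_between(dm, sets[i], sets[j]), i, j)
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        ]
        _, first, second = min(pairs, key=lambda t: (t[0], sorted((min(sets[t[1]]), min(sets[t[2]])))))
    emitted = [(sets[first], sets[second])]
    placed = [first, second]
    remaining = [x for x in range(len(sets)) if x not in placed]
    while remaining:
        if dm is None:
            nxt, partner = remaining[0], placed[0]
        else:
            cand = [
                (mean_between(dm, sets[i], sets[j]), i, j)
                for i in remaining
                for j in placed
            ]
            _, nxt, partner = min(cand, key=lambda t: (t[0], min(sets[t[1]]), min(sets[t[2]])))
        emitted.append((sets[nxt], sets[partner]))
        placed.append(nxt)
        remaining.remove(nxt)
    return emitted


def supported_sister_pairs(
    tree: dendropy.Tree,
    supports: Mapping[frozenset, float],
    threshold: float = 70.0,
    dm: DistanceMatrix | None = None,
) -> list[tuple[frozenset, frozenset]]:
    """Ordered candidate sister-clade pairs after collapsing weak edges.

    Internal edges with support below *threshold* are collapsed; the
    remaining sister pairs are emitted tips-first (postorder).  At a
    multifurcation the two mutually closest children (mean between-clade
    uncorrected distance, from *dm*) are paired first and each further child
    is paired with its nearest already-placed child; without *dm* children
    are folded in tree order.  An empty list (no supported pair) is a valid
    result, not an error.
    """
    collapsed = collapse_unsupported(tree, supports, threshold)
    pairs: list[tuple[frozenset, frozenset]] = []
    for node in collapsed.postorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) < 2:
            continue
        pairs.extend(_fold_order([leaf_set(c) for c in kids], dm))
    return pairs
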
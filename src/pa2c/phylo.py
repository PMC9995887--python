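"""Distances, neighbor-joining trees, bootstrap support and monophyly tests.

Pairwise distances come from global protein alignment (BLOSUM62, affine
gap open 10 / extend 1) as the mismatch fraction p over aligned non-gap
columns, optionally Poisson-corrected (-ln(1-p)).  Trees are built with
the Saitou-Nei neighbor-joining agglomeration; joins tie-break
lexicographically on cluster representative labels so the output is a
pure function of the input matrix.  Bootstrap support resamples columns
of a reference alignment, rebuilds the tree per replicate and reports the
percentage of replicates containing each internal bipartition.

Trees are :class:`skbio.TreeNode` objects (newick I/O comes for free);
distance matrices are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from pa2c.core import Pa2cError, ProteinRecord

GAP_OPEN = -10.0
GAP_EXTEND = -1.0
#: distance cap for the Poisson correction when p >= P_CAP
P_CAP = 0.95
MAX_POISSON = -math.log(1.0 - P_CAP)


class PhyloError(Pa2cError):
    pass


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def alignment_score(a: str, b: str) -> float:
    """Global BLOSUM62 alignment score (used by the nearest-centroid classifier)."""
    return float(_aligner().score(a, b))


def _aligned_rows(a: str, b: str) -> tuple[str, str]:
    alignment = _aligner().align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def _p_from_rows(row_a: str, row_b: str) -> Optional[float]:
    """Mismatch fraction over columns where neither row is gapped."""
    shared = 0
    mismatch = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        shared += 1
        if ca != cb:
            mismatch += 1
    if shared == 0:
        return None
    return mismatch / shared


def _apply_model(p: Optional[float], model: str) -> float:
    if p is None:
        return MAX_POISSON if model == "poisson" else 1.0
    if model == "p":
        return p
    if model == "poisson":
        if p >= P_CAP:
            return MAX_POISSON
        return -math.log(1.0 - p)
    raise PhyloError(f"unknown distance model {model!r}")


def pairwise_distance(a: ProteinRecord, b: ProteinRecord, model: str = "p") -> float:
    """Alignment-based distance between two proteins.

    ``model='p'`` returns the raw mismatch fraction; ``'poisson'`` applies
    -ln(1-p), capped at -ln(0.05) when p >= 0.95.
    """
    if a.sequence == b.sequence:
        return 0.0
    row_a, row_b = _aligned_rows(a.sequence, b.sequence)
    return _apply_model(_p_from_rows(row_a, row_b), model)


def distance_matrix(records: Sequence[ProteinRecord], model: str = "p") -> DistanceMatrix:
    """Symmetric pairwise-alignment distance matrix over a record set."""
    n = len(records)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(records[i], records[j], model)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=[r.id for r in records])


def distance_matrix_from_alignment(
    alignment: Mapping[str, str], model: str = "p"
) -> DistanceMatrix:
    """Distances from a fixed multiple alignment (no re-alignment)."""
    ids = list(alignment)
    rows = [alignment[i] for i in ids]
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _apply_model(_p_from_rows(rows[i], rows[j]), model)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=ids)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with a deterministic lexicographic tie-break.

    The returned tree is unrooted (trifurcating root).  Negative branch
    lengths are clamped to zero; the number of clamped branches is stored
    on the tree as ``tree.negative_clamped``.
    """
    ids = list(matrix.ids)
    if len(ids) < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    if len(set(ids)) != len(ids):
        raise PhyloError("duplicate taxon labels")

    dist: dict[frozenset, float] = {}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            dist[frozenset((a, ids[j]))] = float(matrix[i, j])

    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in ids}
    active = sorted(ids)  # representatives, kept lexicographically sorted
    clamped = 0

    def d(a: str, b: str) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        r = len(active)
        rowsum = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * d(a, b) - rowsum[a] - rowsum[b]
                # strict < plus sorted iteration order = lexicographic tie-break
                if q < best_q - 1e-12:
                    best_q = q
                    best = (a, b)
        a, b = best
        dab = d(a, b)
        la = dab / 2 + (rowsum[a] - rowsum[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0:
            la, clamped = 0.0, clamped + 1
        if lb < 0:
            lb, clamped = 0.0, clamped + 1
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        new = TreeNode(children=[child_a, child_b])
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = (d(a, c) + d(b, c) - dab) / 2
            dist[frozenset((rep, c))] = duc
        nodes[rep] = new
        active = sorted(set(active) - {a, b} | {rep})

    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    children = []
    for rep, length in zip((a, b, c), (la, lb, lc)):
        node = nodes.pop(rep)
        if length < 0:
            length, clamped = 0.0, clamped + 1
        node.length = length
        children.append(node)
    tree = TreeNode(children=children)
    tree.negative_clamped = clamped
    return tree


def _leafset(node: TreeNode) -> frozenset:
    return frozenset(tip.name for tip in node.tips()) or frozenset([node.name])


def bipartitions(tree: TreeNode, internal_only: bool = False) -> set[frozenset]:
    """Canonical bipartitions of an unrooted tree.

    Each edge splits the leaves in two; the returned set holds, per edge,
    the side NOT containing the lexicographically smallest leaf, so the
    representation is invariant to re-rooting.  Trivial splits (single
    leaf / all leaves) are excluded when ``internal_only`` is set.
    """
    all_leaves = frozenset(tip.name for tip in tree.tips())
    ref = min(all_leaves)
    out = set()
    for node in tree.traverse(include_self=False):
        if internal_only and node.is_tip():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_leaves - side
        if not side or side == all_leaves:
            continue
        if internal_only and len(side) in (1, len(all_leaves) - 1):
            continue
        out.add(side)
    return out


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int,
    seed: int,
    model: str = "p",
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree from an alignment plus column-resampling bootstrap supports.

    Support is the percentage of replicates whose NJ tree contains each
    internal bipartition of the base tree.  Replicate r draws its columns
    from ``numpy.random.default_rng([seed, r])``, so runs are reproducible
    and replicates independent.  Supports are also written onto the base
    tree's internal nodes (``node.name``) for newick export.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    ids = list(alignment)
    length = len(next(iter(alignment.values())))
    if any(len(row) != length for row in alignment.values()):
        raise PhyloError("alignment rows have unequal lengths")

    base_tree = nj_tree(distance_matrix_from_alignment(alignment, model))
    base_bips = bipartitions(base_tree, internal_only=True)
    counts = {bip: 0 for bip in base_bips}

    rows = [alignment[i] for i in ids]
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, length, size=length)
        resampled = {
            ids[k]: "".join(rows[k][c] for c in cols) for k in range(len(ids))
        }
        rep_tree = nj_tree(distance_matrix_from_alignment(resampled, model))
        rep_bips = bipartitions(rep_tree, internal_only=True)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1

    supports = {bip: 100.0 * c / n_reps for bip, c in counts.items()}
    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    for node in base_tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = _leafset(node)
        if ref in side:
            side = all_leaves - side
        if side in supports:
            node.name = f"{supports[side]:g}"
    return base_tree, supports


def clade_split_supports(
    supports: Mapping[frozenset, float],
    labels: Mapping[str, str],
) -> dict[str, float]:
    """Bootstrap support of each clade's separating bipartition.

    For every label group, looks up the support of the bipartition that
    splits exactly that group from the rest (0.0 when the base tree does
    not contain it, e.g. the group is not monophyletic there).
    """
    all_leaves = frozenset(labels)
    ref = min(all_leaves)
    out = {}
    for clade in sorted(set(labels.values())):
        members = frozenset(l for l, c in labels.items() if c == clade)
        canonical = all_leaves - members if ref in members else members
        out[clade] = supports.get(canonical, 0.0)
    return out


def clade_monophyly(
    tree: TreeNode, labels: Mapping[str, str]
) -> tuple[int, dict[str, bool]]:
    """Count label groups that are monophyletic on an unrooted tree.

    A group is monophyletic iff some edge separates exactly its leaves
    from all others (singleton groups and a group holding every leaf are
    trivially monophyletic).  Every leaf must be labeled.
    """
    leaves = {tip.name for tip in tree.tips()}
    missing = leaves - set(labels)
    if missing:
        raise PhyloError(f"unlabeled leaves: {sorted(missing)}")
    groups: dict[str, set] = {}
    for leaf in leaves:
        groups.setdefault(labels[leaf], set()).add(leaf)

    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    splits = bipartitions(tree, internal_only=False)
    result = {}
    for clade, members in groups.items():
        members = frozenset(members)
        if len(members) <= 1 or members == all_leaves:
            result[clade] = True
            continue
        canonical = all_leaves - members if ref in members else members
        result[clade] = canonical in splits
    return sum(result.values()), result


def tree_placement_clade(
    query: ProteinRecord,
    references: Sequence[ProteinRecord],
    labels: Mapping[str, str],
    model: str = "p",
) -> str:
    """Clade call by NJ insertion of the query among labeled references.

    The query joins the tree; its attachment node has (up to) two
    neighbor subtrees besides the query itself.  If every label-pure
    neighbor subtree carries the same clade label the query takes that
    label; with no pure neighbor, or pure neighbors that disagree (the
    query sits on an edge between clades), the call is ``unresolved``.
    Needs at least two references per clade.
    """
    by_clade: dict[str, int] = {}
    for ref in references:
        by_clade[labels[ref.id]] = by_clade.get(labels[ref.id], 0) + 1
    if not by_clade or min(by_clade.values()) < 2:
        raise PhyloError("reference panel needs >= 2 members per clade")
    if query.id in {r.id for r in references}:
        raise PhyloError("query id collides with a reference id")

    tree = nj_tree(distance_matrix(list(references) + [query], model))
    tip = next(t for t in tree.tips() if t.name == query.id)
    attachment = tip.parent
    all_leaves = frozenset(t.name for t in tree.tips())
    neighbors: list[frozenset] = []
    for child in attachment.children:
        if child is not tip:
            neighbors.append(_leafset(child))
    if attachment.parent is not None:
        up = all_leaves - _leafset(attachment)
        if up:
            neighbors.append(up)
    pure = {
        next(iter({labels[leaf] for leaf in side}))
        for side in neighbors
        if len({labels[leaf] for leaf in side}) == 1
    }
    if len(pure) == 1:
        return pure.pop()
    return "unresolved"
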
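"""Guide-tree construction and consensus-weighted progressive alignment.

All-vs-all pairwise alignments give a normalized similarity per structure
pair; complete-linkage agglomeration on ``d = 1 - similarity`` produces a
binary merge order in which the most similar structures are joined first.
Each merge aligns two *alignment nodes* — a single structure, or a stack of
previously aligned structures collapsed to column-averaged coordinates —
and combines them into a new node.

The feedback novelty: every node carries a *consensus* row counting how
many residues are aligned at each of its columns (times the consensus
weight cw). Before two nodes are aligned, each node's consensus is scaled
by half the number of structures in the *other* node and concatenated to
its coordinates as a fourth dimension entering the RBF score. Columns that
are fully aligned in both nodes then have near-equal consensus values,
score high, and resist gap insertion — conserved core blocks stay intact
as progressive alignment proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp import GAP
from .pairwise import AlignmentParams, pairwise_align, tree_score

__all__ = [
    "GuideTree",
    "AlignmentNode",
    "MultipleAlignment",
    "build_guide_tree",
    "leaf_node",
    "combine_nodes",
    "multiple_align",
]


@dataclass
class GuideTree:
    """Binary merge order: (left_id, right_id, new_id) triples.

    Leaf ids are structure ids; internal nodes get fresh ids. The final
    triple creates the root.
    """

    merge_order: list[tuple[str, str, str]]
    heights: list[float]

    @property
    def root_id(self) -> str:
        return self.merge_order[-1][2]

    def to_newick(self) -> str:
        clades: dict[str, str] = {}
        height: dict[str, float] = {}
        for (left, right, new), h in zip(self.merge_order, self.heights):
            lh = h - height.get(left, 0.0)
            rh = h - height.get(right, 0.0)
            lrep = clades.pop(left, left)
            rrep = clades.pop(right, right)
            clades[new] = f"({lrep}:{lh:.6g},{rrep}:{rh:.6g})"
            height[new] = h
        return clades[self.root_id] + ";"


def build_guide_tree(scores: dict[frozenset, float] | np.ndarray,
                     ids: list[str] | None = None) -> GuideTree:
    """Agglomerate structures most-similar-first.

    ``scores`` maps unordered id pairs to normalized pairwise similarities
    in [0, 1] (or is a symmetric matrix, with ``ids`` giving row labels).
    Distances are ``1 - score``; the distance between merged clusters is
    the *maximum* over their members (complete linkage), so a cluster is
    only as close as its farthest member — giving a smooth progression
    from tight families outwards. Ties break lexicographically on node
    ids, making the order deterministic.
    """
    if isinstance(scores, np.ndarray):
        if ids is None:
            raise ValueError("ids required with a score matrix")
        table = {
            frozenset((ids[i], ids[j])): float(scores[i, j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        }
    else:
        table = dict(scores)
        if ids is None:
            ids = sorted({i for key in table for i in key})
    if len(ids) < 2:
        raise ValueError("need at least 2 structures")
    for key, val in table.items():
        if not (0.0 <= val <= 1.0 + 1e-9):
            raise ValueError(f"score for {set(key)} outside [0, 1]: {val}")

    dist = {k: 1.0 - v for k, v in table.items()}
    active = list(ids)
    merge_order: list[tuple[str, str, str]] = []
    heights: list[float] = []
    counter = 0
    while len(active) > 1:
        best = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                a, b = active[a_idx], active[b_idx]
                d = dist[frozenset((a, b))]
                key = (d, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pick = (a, b)
        a, b = sorted(pick)
        new_id = f"node{counter}"
        counter += 1
        for other in active:
            if other in (a, b):
                continue
            dist[frozenset((other, new_id))] = max(
                dist[frozenset((other, a))], dist[frozenset((other, b))]
            )
        active = [x for x in active if x not in (a, b)] + [new_id]
        merge_order.append((a, b, new_id))
        heights.append(best[0])
    return GuideTree(merge_order=merge_order, heights=heights)


@dataclass
class AlignmentNode:
    """A stack of aligned structures collapsed to one alignable object.

    coords : (L, 3) column-averaged alpha-carbon coordinates
    sec_codes : length-L codes inherited through the merges
    counts : residues aligned at each column (1..n_structures)
    consensus : counts * cw
    members : structure id -> length-L integer row (residue index or -1)
    """

    coords: np.ndarray
    sec_codes: str
    counts: np.ndarray
    consensus: np.ndarray
    n_structures: int
    members: dict[str, np.ndarray]

    @property
    def ca_coords(self) -> np.ndarray:  # alignable-object interface
        return self.coords

    def __len__(self) -> int:
        return len(self.coords)


def leaf_node(structure, cw: float = 1.0) -> AlignmentNode:
    n = len(structure)
    return AlignmentNode(
        coords=np.array(structure.ca_coords, dtype=float),
        sec_codes=structure.sec_codes,
        counts=np.ones(n, dtype=int),
        consensus=np.full(n, cw, dtype=float),
        n_structures=1,
        members={structure.id: np.arange(n)},
    )


def combine_nodes(
    a: AlignmentNode, b: AlignmentNode, params: AlignmentParams | None = None
) -> AlignmentNode:
    """Align two nodes and merge them into their parent node.

    The working consensus of each node (its consensus scaled by half the
    other node's structure count) rides along as a fourth coordinate in
    the RBF score. After alignment, parent coordinates are the unweighted
    mean of the two children at doubly-occupied columns and the occupied
    child's coordinates elsewhere; the secondary code comes from the
    non-gapped child (the first child where both are present); counts add;
    the stored consensus is counts * cw; member rows inherit the new gaps.
    """
    params = params or AlignmentParams()
    cw = params.consensus_weight

    a_work = _WorkingNode(a, a.consensus * (b.n_structures / 2.0))
    b_work = _WorkingNode(b, b.consensus * (a.n_structures / 2.0))
    aln, transform = pairwise_align(a_work, b_work, params)

    a_coords = transform.apply(a.coords)
    length = len(aln.pairs)
    coords = np.empty((length, 3))
    counts = np.zeros(length, dtype=int)
    sec = []
    for p, (i, j) in enumerate(aln.pairs):
        if i != GAP and j != GAP:
            coords[p] = 0.5 * (a_coords[i] + b.coords[j])
            counts[p] = a.counts[i] + b.counts[j]
            sec.append(a.sec_codes[i])
        elif i != GAP:
            coords[p] = a_coords[i]
            counts[p] = a.counts[i]
            sec.append(a.sec_codes[i])
        else:
            coords[p] = b.coords[j]
            counts[p] = b.counts[j]
            sec.append(b.sec_codes[j])

    members: dict[str, np.ndarray] = {}
    a_cols = np.asarray([i for i, _ in aln.pairs])
    b_cols = np.asarray([j for _, j in aln.pairs])
    for sid, row in a.members.items():
        members[sid] = np.where(a_cols == GAP, GAP, row[a_cols])
    for sid, row in b.members.items():
        members[sid] = np.where(b_cols == GAP, GAP, row[b_cols])

    return AlignmentNode(
        coords=coords,
        sec_codes="".join(sec),
        counts=counts,
        consensus=counts * cw,
        n_structures=a.n_structures + b.n_structures,
        members=members,
    )


class _WorkingNode:
    """A node view with the merge-time (scaled) consensus attached."""

    def __init__(self, node: AlignmentNode, working_consensus: np.ndarray):
        self.ca_coords = node.coords
        self.sec_codes = node.sec_codes
        self.consensus = working_consensus


@dataclass
class MultipleAlignment:
    """Per-structure gapped residue-index rows over shared columns."""

    rows: dict[str, np.ndarray]
    column_count: int

    def __post_init__(self) -> None:
        for sid, row in self.rows.items():
            if len(row) != self.column_count:
                raise ValueError(f"row {sid!r} has wrong length")

    @property
    def structure_ids(self) -> list[str]:
        return list(self.rows)

    def gapless_column_mask(self) -> np.ndarray:
        mask = np.ones(self.column_count, dtype=bool)
        for row in self.rows.values():
            mask &= np.asarray(row) != GAP
        return mask

    def gapped_sequences(self, structures) -> dict[str, str]:
        by_id = {s.id: s for s in structures}
        out = {}
        for sid, row in self.rows.items():
            seq = by_id[sid].sequence
            out[sid] = "".join("-" if i == GAP else seq[i] for i in row)
        return out

    @classmethod
    def from_gapped_sequences(cls, gapped: dict[str, str]) -> "MultipleAlignment":
        lengths = {len(s) for s in gapped.values()}
        if len(lengths) != 1:
            raise ValueError("ragged gapped sequences")
        rows = {}
        for sid, seq in gapped.items():
            row, k = [], 0
            for ch in seq:
                if ch == "-":
                    row.append(GAP)
                else:
                    row.append(k)
                    k += 1
            rows[sid] = np.asarray(row)
        return cls(rows=rows, column_count=lengths.pop())


class MultipleAlignmentError(RuntimeError):
    pass


def multiple_align(
    structures, params: AlignmentParams | None = None, return_state: bool = False
):
    """Progressive multiple structure alignment.

    All-vs-all pairwise alignment -> guide tree -> fold of
    :func:`combine_nodes` over the merge order; the root node's member
    rows are the alignment. With ``return_state=True`` also returns the
    guide tree, the pairwise similarity table and the root node.
    """
    params = params or AlignmentParams()
    structures = list(structures)
    if len(structures) < 2:
        raise MultipleAlignmentError("need at least 2 structures")
    ids = [s.id for s in structures]
    if len(set(ids)) != len(ids):
        raise MultipleAlignmentError(f"duplicate structure ids in {ids}")

    scores: dict[frozenset, float] = {}
    for x in range(len(structures)):
        for y in range(x + 1, len(structures)):
            s1, s2 = structures[x], structures[y]
            try:
                aln, _ = pairwise_align(s1, s2, params)
            except Exception as exc:
                raise MultipleAlignmentError(
                    f"pairwise alignment failed for ({s1.id}, {s2.id}): {exc}"
                ) from exc
            scores[frozenset((s1.id, s2.id))] = min(1.0, tree_score(aln))

    tree = build_guide_tree(scores, ids=ids)
    nodes: dict[str, AlignmentNode] = {
        s.id: leaf_node(s, params.consensus_weight) for s in structures
    }
    for left, right, new in tree.merge_order:
        try:
            nodes[new] = combine_nodes(nodes.pop(left), nodes.pop(right), params)
        except Exception as exc:
            raise MultipleAlignmentError(
                f"progressive merge ({left}, {right}) failed: {exc}"
            ) from exc
    root = nodes[tree.root_id]
    msa = MultipleAlignment(
        rows={sid: root.members[sid] for sid in ids},
        column_count=len(root),
    )
    if return_state:
        return msa, tree, scores, root
    return msa
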
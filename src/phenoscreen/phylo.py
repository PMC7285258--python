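"""Distance-based trees of OPF representatives and reference sequences.

Trees are explicitly distance-based stand-ins for full ML inference:
Kimura-corrected protein distances feed neighbor joining, the result is
midpoint rooted, and clade robustness comes from column-bootstrap supports.
The downstream use of these trees is structural (which clade a
representative falls into), which this pipeline preserves.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from phenoscreen.families import GAP, MultipleAlignment

log = logging.getLogger(__name__)

#: distance assigned when the Kimura correction's domain is exceeded
DEFAULT_DISTANCE_CEILING = 5.0


def kimura_correction(D: float, ceiling: float = DEFAULT_DISTANCE_CEILING) -> float:
    """Kimura's protein-distance correction d = -ln(1 - D - 0.2 D^2)."""
    arg = 1.0 - D - 0.2 * D * D
    if arg <= 0.0:
        return ceiling
    return min(-math.log(arg), ceiling)


def protein_distance(
    aln: MultipleAlignment, ceiling: float = DEFAULT_DISTANCE_CEILING
) -> DistanceMatrix:
    """Pairwise Kimura-corrected p-distances over mutually ungapped columns."""
    if aln.n_rows < 2:
        raise ValueError("need >=2 aligned sequences")
    ids = [sid for sid, _ in aln.rows]
    seqs = [s for _, s in aln.rows]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pairs = [
                (a, b)
                for a, b in zip(seqs[i], seqs[j])
                if a != GAP and b != GAP
            ]
            if not pairs:
                raise ValueError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            D = sum(1 for a, b in pairs if a != b) / len(pairs)
            mat[i, j] = mat[j, i] = kimura_correction(D, ceiling)
    return DistanceMatrix(mat, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch-length estimates clamp to 0."""
    ids = list(dm.ids)
    if len(ids) < 2:
        raise ValueError("need >=2 labels")
    if len(ids) == 2:
        d = float(dm[ids[0], ids[1]])
        a = TreeNode(name=ids[0], length=d / 2)
        b = TreeNode(name=ids[1], length=d / 2)
        return TreeNode(children=[a, b])
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    On an all-zero-length tree the midpoint is undefined; the tree is then
    rooted at its first edge with a warning.
    """
    tree = tree.copy()
    tips = list(tree.tips())
    if len(tips) < 2:
        return tree
    maxdist = max(
        tree.find(a.name).distance(tree.find(b.name))
        for i, a in enumerate(tips)
        for b in tips[i + 1 :]
    )
    if maxdist == 0:
        log.warning("all branch lengths zero; rooting at an arbitrary edge")
        return tree
    rooted = tree.root_at_midpoint()
    return rooted


def _bipartitions(tree: TreeNode, *, trivial: bool = False) -> set[frozenset]:
    """Canonical bipartitions (tip-name sets) of a tree's internal edges.

    Each edge splits the tips in two; the side NOT containing the
    alphabetically first tip is the canonical representative, so rooted and
    unrooted versions of the same topology agree.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    ref = min(all_tips)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if trivial or 2 <= len(side) <= len(all_tips) - 2:
            out.add(side)
    return out


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    ceiling: float = DEFAULT_DISTANCE_CEILING,
):
    """Column-bootstrap supports on the NJ tree of an alignment.

    Columns are resampled with replacement, the tree rebuilt per replicate,
    and each internal bipartition of the original tree scored as the
    percentage of replicates containing it.  Returns the midpoint-rooted
    tree with supports as internal-node labels, plus the support map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    # canonical row order: replicate ties then break identically however
    # the input rows were ordered, so supports are label-permutation
    # invariant
    aln = MultipleAlignment(
        rows=tuple(sorted(aln.rows)), family_id=aln.family_id
    )
    base_tree = nj_tree(protein_distance(aln, ceiling))
    target = _bipartitions(base_tree)
    found = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    cols = aln.n_cols
    for _ in range(n_reps):
        idx = rng.integers(0, cols, size=cols)
        rows = tuple(
            (sid, "".join(s[j] for j in idx)) for sid, s in aln.rows
        )
        rep_aln = MultipleAlignment(rows=rows, family_id=aln.family_id)
        try:
            rep_tree = nj_tree(protein_distance(rep_aln, ceiling))
        except ValueError:  # replicate with an all-gap pair: no signal
            continue
        for bp in _bipartitions(rep_tree):
            if bp in found:
                found[bp] += 1
    support = {bp: 100.0 * k / n_reps for bp, k in found.items()}
    rooted = midpoint_root(base_tree)
    all_tips = frozenset(t.name for t in rooted.tips())
    ref = min(all_tips)
    for node in rooted.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if side in support:
            node.name = f"{support[side]:g}"
    return rooted, support


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
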
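"""Distance-based trees: neighbor joining, midpoint rooting, clade checks.

Trees are scikit-bio ``TreeNode`` objects throughout (newick in/out via
``read_newick``/``write_newick``).  Distances are p-distances derived
from the identity matrices of the homogeneity module.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .alignment import MultipleAlignment
from .homogeneity import IdentityMatrix, identity_matrix


class TreeError(ValueError):
    pass


def distance_matrix(source: IdentityMatrix | MultipleAlignment) -> DistanceMatrix:
    """p-distance matrix (1 − identity/100) from an alignment or identity matrix."""
    if isinstance(source, MultipleAlignment):
        source = identity_matrix(source)
    return DistanceMatrix(source.to_distance(), ids=list(source.ids))


def nj_tree(d: DistanceMatrix | IdentityMatrix) -> TreeNode:
    """Canonical neighbor joining; negative branch estimates clamp to zero."""
    if isinstance(d, IdentityMatrix):
        d = distance_matrix(d)
    if d.shape[0] < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    return nj(d, neg_as_zero=True)


def midpoint_root(t: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(t.tips())
    if len(tips) < 2:
        raise TreeError("midpoint rooting needs at least 2 leaves")
    if all((n.length or 0.0) == 0.0 for n in t.traverse() if not n.is_root()):
        return t.copy()  # zero-length tree: rooting position is arbitrary
    if len(tips) == 2:  # the midpoint sits halfway along the single path
        half = tips[0].distance(tips[1]) / 2.0
        return TreeNode(children=[TreeNode(name=tips[0].name, length=half),
                                  TreeNode(name=tips[1].name, length=half)])
    return t.root_at_midpoint()


def leaf_names(t: TreeNode) -> list[str]:
    return [n.name for n in t.tips()]


def bipartitions(t: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree, each as the smaller
    side's leaf set (ties resolved lexicographically)."""
    leaves = frozenset(leaf_names(t))
    out: set[frozenset[str]] = set()
    for node in t.non_tips(include_self=False):
        side = frozenset(n.name for n in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        if len(side) < len(other) or (len(side) == len(other)
                                      and sorted(side) < sorted(other)):
            out.add(side)
        else:
            out.add(other)
    return out


def is_monophyletic(t: TreeNode, leaf_subset) -> bool:
    """True iff some edge bipartition separates exactly *leaf_subset*."""
    subset = frozenset(leaf_subset)
    leaves = frozenset(leaf_names(t))
    unknown = subset - leaves
    if unknown:
        raise TreeError(f"unknown leaves: {sorted(unknown)}")
    if len(subset) in (1, len(leaves)):
        return True
    if len(subset) == len(leaves) - 1:  # complement is a single leaf
        return True
    for node in t.non_tips(include_self=False):
        side = frozenset(n.name for n in node.tips())
        if side == subset or leaves - side == subset:
            return True
    return False


def bootstrap_support(aln: MultipleAlignment, n_reps: int = 200,
                      seed: int = 0) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ bootstrap by alignment-column resampling.

    Returns the NJ tree of the original alignment with internal-node
    names set to percent support, plus the support of every original
    non-trivial bipartition (fraction of replicate trees containing it).
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    if aln.n_cols < 2:
        raise TreeError("alignment has fewer than 2 columns")
    tree = nj_tree(identity_matrix(aln))
    orig = bipartitions(tree)
    counts = {bp: 0 for bp in orig}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rows = ["".join(r[j] for j in cols) for r in aln.rows]
        rep_aln = MultipleAlignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet)
        try:
            rep_tree = nj_tree(identity_matrix(rep_aln))
        except Exception:
            continue  # e.g. an all-gap resample; contributes no support
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    support = {bp: c / n_reps for bp, c in counts.items()}
    for node in tree.non_tips(include_self=False):
        side = frozenset(n.name for n in node.tips())
        leaves = frozenset(leaf_names(tree))
        key = side if side in support else leaves - side
        if key in support:
            node.name = f"{100.0 * support[key]:.0f}"
    return tree, support


def write_newick(t: TreeNode, path) -> None:
    t.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
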
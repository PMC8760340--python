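"""Distance-based protein phylogenetics: Poisson distances, neighbor
joining, bootstrap support, and monophyly testing.

Distances are Poisson-corrected p-distances, ``d = -ln(1 - p)`` with
``p`` the mismatch fraction over columns where both sequences carry a
residue.  Trees are unrooted neighbor-joining trees; bootstrap support for
an internal edge is the percentage of column-resampled replicates whose NJ
tree contains the same leaf bipartition.  A label set is monophyletic iff
some edge bipartition separates it exactly from all remaining taxa.

Rooting on an outgroup is a display operation only and never changes any
bipartition; maximum-likelihood inference can be plugged in by supplying a
replacement for :func:`nj_tree` to :func:`bootstrap_support`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .seqio import AlignedRecord, GAP

P_CLAMP = 0.95  # p-distances at/above this are clamped (Poisson correction diverges)


def protein_distance(alignment: Sequence[AlignedRecord]) -> DistanceMatrix:
    """Poisson-corrected distance matrix from an aligned protein set."""
    if len(alignment) < 2:
        raise ValueError("need at least two aligned sequences")
    lengths = {len(r.seq) for r in alignment}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    taxa = [r.id for r in alignment]
    arrs = [np.frombuffer(r.seq.encode(), dtype="S1") for r in alignment]
    gap = GAP.encode()
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (arrs[i] != gap) & (arrs[j] != gap)
            ns = int(shared.sum())
            if ns == 0:
                raise ValueError(f"{taxa[i]} and {taxa[j]} share no aligned columns")
            p = float((arrs[i][shared] != arrs[j][shared]).mean())
            if p >= P_CLAMP:
                warnings.warn(f"p-distance {p:.2f} clamped to {P_CLAMP} "
                              f"for pair ({taxa[i]}, {taxa[j]})")
                p = P_CLAMP
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(d, taxa)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; negative branch lengths clamped)."""
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    tree = nj(matrix)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def canonical_bipartition(side: frozenset[str], taxa: frozenset[str]) -> frozenset[str]:
    """Pick the side of a split that contains the lexicographically smallest
    taxon, so each unrooted bipartition has a single canonical key."""
    anchor = min(taxa)
    return side if anchor in side else taxa - side


def edge_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical non-trivial bipartitions induced by the tree's internal edges."""
    taxa = frozenset(leaf.name for leaf in tree.tips())
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(canonical_bipartition(side, taxa))
    return out


@dataclass
class Phylogeny:
    """An unrooted tree plus per-bipartition bootstrap support (0-100)."""

    tree: TreeNode
    supports: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.name for leaf in self.tree.tips())

    def annotate(self) -> TreeNode:
        """Copy of the tree with supports written as internal node names."""
        t = self.tree.copy()
        taxa = self.taxa
        for node in t.non_tips(include_self=False):
            side = frozenset(leaf.name for leaf in node.tips())
            key = canonical_bipartition(side, taxa)
            if key in self.supports:
                node.name = f"{self.supports[key]:g}"
        return t

    def write_newick(self, path) -> None:
        self.annotate().write(str(path), format="newick")


def bootstrap_support(alignment: Sequence[AlignedRecord], n_reps: int, seed: int,
                      tree_builder: Callable[[DistanceMatrix], TreeNode] = nj_tree
                      ) -> Phylogeny:
    """NJ tree on the full alignment plus bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    alignment is run through the same distance + tree pipeline, and support
    for an original internal bipartition is the percentage of replicates
    containing it.  Fully reproducible given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base_tree = tree_builder(protein_distance(alignment))
    phy = Phylogeny(tree=base_tree)
    original = edge_bipartitions(base_tree)
    counts = {bp: 0 for bp in original}
    rng = np.random.default_rng(seed)
    ncol = len(alignment[0].seq)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep = [AlignedRecord(id=r.id, seq="".join(r.seq[c] for c in cols))
               for r in alignment]
        try:
            rep_tree = tree_builder(protein_distance(rep))
        except ValueError:
            continue  # replicate with a zero-overlap pair contributes nothing
        rep_bps = edge_bipartitions(rep_tree)
        for bp in original:
            if bp in rep_bps:
                counts[bp] += 1
    phy.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return phy


def is_monophyletic(phylogeny: Phylogeny | TreeNode, labelset: set[str]
                    ) -> tuple[bool, float | None]:
    """Does ``labelset`` form a clade, and with what bootstrap support?

    True iff some edge bipartition equals (labelset | complement).  Leaf
    edges and the full taxon set are trivially monophyletic with support
    100.  Support is ``None`` when the tree carries no bootstrap values for
    that edge.
    """
    phy = phylogeny if isinstance(phylogeny, Phylogeny) else Phylogeny(tree=phylogeny)
    taxa = phy.taxa
    labels = frozenset(labelset)
    unknown = labels - taxa
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(labels) in (1, len(taxa)):
        return True, 100.0
    key = canonical_bipartition(labels, taxa)
    if key in edge_bipartitions(phy.tree):
        return True, phy.supports.get(key)
    return False, None


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
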
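"""Species trees, Grafen branch lengths, and the phylogenetic correlation matrix.

The analyses need a correlation structure among species, not divergence
times: node heights are assigned by Grafen's rule — a node subtending
``m`` of the ``N`` study tips sits at height ``((m - 1)/(N - 1))**rho`` —
which makes the tree ultrametric with root height 1 without any fossil
calibration. Under a Brownian model on that tree, the correlation between
two species equals the root-to-MRCA depth of their most recent common
ancestor, giving a unit-diagonal positive-semidefinite matrix that enters
the hierarchical models as the covariance of the phylogenetic random
intercept.

Polytomies are resolved to binary by inserting nodes that inherit their
parent's height (zero-length edges), so the arbitrary resolution order
cannot change the correlation matrix.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "SpeciesTree",
    "PhyloCovariance",
    "read_newick",
    "parse_newick",
    "resolve_polytomies",
    "grafen_lengths",
    "phylo_correlation",
]


@dataclass
class SpeciesTree:
    """A rooted species-level tree (wraps a dendropy tree)."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self.tree.preorder_node_iter()
            if not n.is_leaf()
        )

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class PhyloCovariance:
    """Unit-diagonal phylogenetic correlation matrix with its species order."""

    species: list[str]
    matrix: np.ndarray

    def reorder(self, species: list[str]) -> "PhyloCovariance":
        missing = [s for s in species if s not in self.species]
        if missing:
            raise ValueError(f"species absent from phylogeny: {missing}")
        idx = [self.species.index(s) for s in species]
        return PhyloCovariance(list(species), self.matrix[np.ix_(idx, idx)])


def parse_newick(newick: str) -> SpeciesTree:
    """Parse a Newick string into a rooted species tree.

    Existing branch lengths are irrelevant downstream (Grafen scaling
    overwrites them). Trees explicitly flagged unrooted (``[&U]``) and
    duplicated tip labels are rejected.
    """
    if "[&U]" in newick:
        raise ValueError("unrooted input: the analyses require a rooted tree")
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    if len(labels) < 2:
        raise ValueError("tree must have at least two tips")
    return SpeciesTree(tree)


def read_newick(path) -> SpeciesTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def resolve_polytomies(t: SpeciesTree, seed: int = 0) -> SpeciesTree:
    """Resolve multifurcations to a strictly binary tree.

    Inserted nodes are tagged so that Grafen scaling gives them their
    parent's height (a zero-length inserted edge); the resolution order is
    deterministic given the seed.
    """
    tree = t.tree.clone(depth=1)
    for node in tree.preorder_node_iter():
        node.inserted = getattr(node, "inserted", False)
    rng = random.Random(seed)
    for node in list(tree.preorder_node_iter()):
        while len(node.child_nodes()) > 2:
            children = node.child_nodes()
            a, b = rng.sample(range(len(children)), 2)
            ca, cb = children[a], children[b]
            new = dendropy.Node()
            new.inserted = True
            node.remove_child(ca)
            node.remove_child(cb)
            new.add_child(ca)
            new.add_child(cb)
            node.add_child(new)
    return SpeciesTree(tree)


def grafen_lengths(t: SpeciesTree, rho: float = 1.0) -> SpeciesTree:
    """Assign Grafen node heights and derive branch lengths.

    Height of a node = ((number of descendant tips - 1)/(N - 1))**rho, so
    tips sit at height 0 and the root at height 1; a branch's length is the
    height drop from parent to child. Nodes inserted by polytomy resolution
    inherit their parent's height, keeping zero-length resolution edges.
    """
    tree = t.tree.clone(depth=1)
    tips = [leaf for leaf in tree.leaf_node_iter()]
    n = len(tips)
    if n < 2:
        raise ValueError("Grafen scaling needs at least two tips")
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.n_tips = 1
        else:
            node.n_tips = sum(c.n_tips for c in node.child_nodes())
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.height = 0.0
        elif getattr(node, "inserted", False) and node.parent_node is not None:
            node.height = node.parent_node.height
        else:
            node.height = ((node.n_tips - 1) / (n - 1)) ** rho
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = node.parent_node.height - node.height
    return SpeciesTree(tree)


def phylo_correlation(t: SpeciesTree, species: list[str] | None = None) -> PhyloCovariance:
    """Correlation matrix from a Grafen-scaled tree.

    Entry (i, j) is the root-to-MRCA depth of tips i and j (total depth is
    1, so the diagonal is exactly 1). If ``species`` is given, the matrix
    is returned in that order and every listed species must be a tip.
    """
    tree = t.tree
    root = tree.seed_node
    if getattr(root, "height", None) is None:
        raise ValueError("tree must be Grafen-scaled before building the matrix")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mat = np.zeros((n, n))
    np.fill_diagonal(mat, 1.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.tip_idx = [index[node.taxon.label]]
            continue
        depth = root.height - node.height  # root-to-node depth; total depth = 1
        kids = node.child_nodes()
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for a in kids[i].tip_idx:
                    for b in kids[j].tip_idx:
                        mat[a, b] = mat[b, a] = depth
        node.tip_idx = [ix for c in kids for ix in c.tip_idx]
    cov = PhyloCovariance(labels, mat)
    if species is not None:
        cov = cov.reorder(list(species))
    return cov
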
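"""Phylogenetic tree handling: Newick IO and a flat index for the pruning pass.

Trees are dendropy objects at the surface; the likelihood engine consumes a
``TreeIndex`` — postorder arrays of parent pointers, branch lengths and leaf
labels — which is cheap to traverse and easy to vectorize over.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if source.strip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


@dataclass
class TreeIndex:
    """Flattened rooted tree: nodes in postorder, root last.

    ``parent[i]`` is the postorder index of node i's parent (-1 for root);
    ``edge_length[i]`` the branch above node i; ``leaf_taxon[i]`` the taxon
    name for leaves, None for internal nodes.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    leaf_taxon: list[str | None]
    children: list[list[int]]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @property
    def taxa(self) -> list[str]:
        return [t for t in self.leaf_taxon if t is not None]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeIndex":
        nodes = list(tree.postorder_node_iter())
        order = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        edge_length = np.zeros(len(nodes))
        leaf_taxon: list[str | None] = [None] * len(nodes)
        children: list[list[int]] = [[] for _ in nodes]
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = order[id(node.parent_node)]
                parent[i] = p
                children[p].append(i)
                length = node.edge.length
                edge_length[i] = 0.0 if length is None else float(length)
                if edge_length[i] < 0:
                    raise ValueError("negative branch length")
            if node.is_leaf():
                if node.taxon is None:
                    raise ValueError("leaf without a taxon label")
                leaf_taxon[i] = node.taxon.label
        labels = [t for t in leaf_taxon if t is not None]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        return cls(parent, edge_length, leaf_taxon, children)


def tree_index(tree: dendropy.Tree | TreeIndex) -> TreeIndex:
    if isinstance(tree, TreeIndex):
        return tree
    return TreeIndex.from_dendropy(tree)
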
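"""Lightweight rooted phylogeny wrapper.

Newick parsing is delegated to dendropy; the tree is then flattened into
index arrays (parent pointers, branch lengths, a postorder) that the
simulator and the pruning likelihood iterate over.  Branch lengths are in
expected neutral substitutions per nucleotide site, matching the unit-flow
normalization of the mutation matrices.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np


class PhyloTree:
    """A rooted tree with branch lengths, flattened to arrays.

    Nodes are numbered in postorder (leaves interleaved, root last).
    ``parent[n]`` is -1 for the root; ``length[n]`` is the length of the
    branch above node ``n`` (0 for the root).  Leaf labels must be unique.
    """

    def __init__(self, dtree: dendropy.Tree) -> None:
        nodes = list(dtree.postorder_node_iter())
        self.n_nodes = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=np.intp)
        self.length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                bl = nd.edge.length
                if bl is None:
                    raise ValueError("every non-root branch needs a length")
                if bl < 0:
                    raise ValueError("branch lengths must be non-negative")
                self.length[i] = float(bl)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValueError("every leaf needs a label")
                self.labels[i] = nd.taxon.label
        if len(set(self.labels.values())) != len(self.labels):
            raise ValueError("leaf labels must be unique")
        self.root = self.n_nodes - 1
        self.postorder = np.arange(self.n_nodes)
        self.leaves = np.array(sorted(self.labels), dtype=np.intp)
        self._dtree = dtree

    # ------------------------------------------------------------------ #

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Parse a Newick string or file path."""
        text = str(source)
        if "(" not in text and Path(text).exists():
            text = Path(text).read_text()
        dtree = dendropy.Tree.get(data=text, schema="newick")
        return cls(dtree)

    @classmethod
    def balanced(cls, n_leaves: int, branch_length: float, prefix: str = "t") -> "PhyloTree":
        """Balanced-as-possible binary tree with equal branch lengths."""
        if n_leaves < 2:
            raise ValueError("need at least two leaves")

        def build(labels: list[str]) -> str:
            if len(labels) == 1:
                return f"{labels[0]}:{branch_length}"
            mid = len(labels) // 2
            return f"({build(labels[:mid])},{build(labels[mid:])}):{branch_length}"

        labels = [f"{prefix}{k}" for k in range(1, n_leaves + 1)]
        mid = len(labels) // 2
        newick = f"({build(labels[:mid])},{build(labels[mid:])});"
        return cls.from_newick(newick)

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick").strip()

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        """Copy of the tree with the given per-node branch lengths."""
        clone = PhyloTree(self._dtree.clone(depth=1))
        clone.length = np.asarray(lengths, dtype=float).copy()
        clone.length[clone.root] = 0.0
        for nd, i in zip(clone._dtree.postorder_node_iter(), range(clone.n_nodes)):
            if nd.parent_node is not None:
                nd.edge.length = float(clone.length[i])
        return clone

    # ------------------------------------------------------------------ #

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def total_length(self) -> float:
        """Sum of branch lengths over the tree."""
        return float(self.length.sum())

    def branch_nodes(self) -> np.ndarray:
        """Node indices carrying a branch (everything but the root)."""
        return np.array([i for i in range(self.n_nodes) if i != self.root], dtype=np.intp)
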
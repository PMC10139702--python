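"""Rooted phylogenies as flat arrays, with Newick IO through dendropy.

The likelihood machinery wants contiguous arrays rather than node objects:
a tree is stored as parent pointers, branch lengths and a post-order
traversal, with tips occupying the first ``n_tips`` indices. Newick parsing
and serialization delegate to :mod:`dendropy`; a trifurcating root is
accepted and treated as the root node.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["TreeError", "PhyloTree"]


class TreeError(ValueError):
    """Malformed tree input (duplicate tips, unknown names, bad Newick)."""


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, indexed for pruning.

    Node indices 0..n_tips-1 are the tips (in ``tip_names`` order);
    internal nodes follow, the root last. ``parent[root] == -1`` and
    ``lengths[root]`` is 0.
    """

    tip_names: list[str]
    parent: np.ndarray  # (n_nodes,) int, -1 at root
    lengths: np.ndarray  # (n_nodes,) float, expected substitutions/site
    children: list[list[int]]

    def __post_init__(self) -> None:
        n = len(self.parent)
        roots = [i for i in range(n) if self.parent[i] == -1]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        if len(set(self.tip_names)) != len(self.tip_names):
            dupes = {t for t in self.tip_names if self.tip_names.count(t) > 1}
            raise TreeError(f"duplicate tip names: {sorted(dupes)}")
        if (self.lengths[: self.n_tips] < 0).any() or (self.lengths < 0).any():
            raise TreeError("negative branch length")

    # -- basic structure ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    def postorder(self) -> list[int]:
        """Node indices, children always before their parent."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def tip_index(self, name: str) -> int:
        try:
            return self.tip_names.index(name)
        except ValueError:
            raise TreeError(f"tip {name!r} not in tree") from None

    def mrca(self, names: list[str]) -> int:
        """Index of the most recent common ancestor of the named tips."""
        paths = []
        for name in names:
            v = self.tip_index(name)
            path = []
            while v != -1:
                path.append(v)
                v = int(self.parent[v])
            paths.append(path[::-1])
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        if k == 0:
            raise TreeError("tips share no common ancestor (disconnected tree?)")
        return paths[0][k - 1]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if node ``a`` lies on the path from ``b`` to the root (a != b)."""
        v = int(self.parent[b])
        while v != -1:
            if v == a:
                return True
            v = int(self.parent[v])
        return False

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            tip_names=list(self.tip_names),
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            children=[list(c) for c in self.children],
        )

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        """Parse a rooted Newick tree from a string or file path."""
        text = str(source)
        origin = "<string>"
        if isinstance(source, Path) or (
            "(" not in text and Path(text).exists()
        ):
            origin = str(source)
            text = Path(source).read_text()
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"{origin}: could not parse Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        dnodes = list(dtree.preorder_node_iter())
        tips = [nd for nd in dnodes if nd.is_leaf()]
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        tip_names = []
        for nd in tips:
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("tree has an unnamed tip")
            tip_names.append(nd.taxon.label.replace(" ", "_"))
        index = {id(nd): i for i, nd in enumerate(tips)}
        # root goes last so post-order arrays end at the root
        internals_sorted = internals[1:] + internals[:1] if internals else []
        for j, nd in enumerate(internals_sorted):
            index[id(nd)] = len(tips) + j
        n = len(dnodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n, dtype=float)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in dnodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = float(nd.edge.length or 0.0)
        return cls(tip_names=tip_names, parent=parent, lengths=lengths, children=children)

    def to_newick(self) -> str:
        def render(v: int) -> str:
            if not self.children[v]:
                label = self.tip_names[v]
            else:
                label = ""
            if self.children[v]:
                inner = ",".join(render(c) for c in self.children[v])
                label = f"({inner})"
            if self.parent[v] == -1:
                return label
            return f"{label}:{self.lengths[v]:.10g}"

        return render(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")
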
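"""Phylogenetic-tree plumbing for the codon likelihood engine.

Trees are read from Newick (via dendropy) into a flat postorder array
representation.  Branch lengths are in expected substitutions per codon.
Foreground branches for branch-site tests are marked either with the
codeml-style ``#1`` suffix in the Newick string or programmatically with
:meth:`PhyloTree.mark_foreground` (a single taxon marks its terminal
branch; several taxa mark the stem branch of their MRCA, or the whole
clade with ``mode="clade"``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

from .errors import MitocompError

_FG_MARK = re.compile(r"#\s*1$")


@dataclass
class Node:
    index: int
    parent: int  # -1 for root
    length: float
    is_tip: bool
    taxon: str | None = None
    foreground: bool = False
    children: list[int] = field(default_factory=list)


class PhyloTree:
    """Rooted tree in postorder arrays (children always precede parents)."""

    def __init__(self, nodes: list[Node]):
        self.nodes = nodes
        self.root = len(nodes) - 1
        self.tips = [n for n in nodes if n.is_tip]
        self.taxa = tuple(n.taxon for n in self.tips)
        if len(set(self.taxa)) != len(self.taxa):
            raise MitocompError("duplicate taxon labels in tree")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, foreground=None, mode: str = "stem") -> "PhyloTree":
        """Parse a Newick string; ``#1`` label suffixes mark foreground
        branches, or pass ``foreground=`` a taxon / tuple of taxa."""
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
        marked: list[dendropy.Node] = []
        for nd in tree.preorder_node_iter():
            label = nd.taxon.label if nd.taxon else nd.label
            if label and _FG_MARK.search(label):
                clean = _FG_MARK.sub("", label).strip()
                if nd.taxon:
                    nd.taxon.label = clean
                else:
                    nd.label = clean or None
                marked.append(nd)
        nodes: list[Node] = []
        index_of: dict[int, int] = {}
        for nd in tree.postorder_node_iter():
            idx = len(nodes)
            index_of[id(nd)] = idx
            is_tip = nd.is_leaf()
            taxon = nd.taxon.label if (is_tip and nd.taxon) else (nd.label if is_tip else None)
            if is_tip and not taxon:
                raise MitocompError("tree has an unlabeled tip")
            length = nd.edge.length if nd.edge.length is not None else 0.0
            if length < 0:
                raise MitocompError(f"negative branch length on {taxon or 'internal'}")
            nodes.append(
                Node(index=idx, parent=-1, length=float(length), is_tip=is_tip,
                     taxon=taxon, foreground=nd in marked)
            )
        for nd in tree.postorder_node_iter():
            for child in nd.child_nodes():
                ci = index_of[id(child)]
                nodes[index_of[id(nd)]].children.append(ci)
                nodes[ci].parent = index_of[id(nd)]
        out = cls(nodes)
        if foreground is not None:
            out.mark_foreground(foreground, mode=mode)
        return out

    # -- foreground marking ------------------------------------------------

    def mark_foreground(self, spec, mode: str = "stem") -> None:
        """Mark foreground branch(es).

        ``spec``: a taxon name (terminal branch) or an iterable of taxon
        names (the stem branch of their MRCA; ``mode="clade"`` additionally
        marks every branch inside the clade).
        """
        for n in self.nodes:
            n.foreground = False
        taxa = [spec] if isinstance(spec, str) else list(spec)
        missing = set(taxa) - set(self.taxa)
        if missing:
            raise MitocompError(f"foreground taxa not in tree: {sorted(missing)}")
        if len(taxa) == 1:
            tip = next(n for n in self.tips if n.taxon == taxa[0])
            tip.foreground = True
            return
        mrca = self._mrca([n.index for n in self.tips if n.taxon in taxa])
        self.nodes[mrca].foreground = True
        if mode == "clade":
            stack = list(self.nodes[mrca].children)
            while stack:
                i = stack.pop()
                self.nodes[i].foreground = True
                stack.extend(self.nodes[i].children)
        elif mode != "stem":
            raise ValueError(f"unknown foreground mode {mode!r}")

    def _mrca(self, indices: list[int]) -> int:
        paths = []
        for i in indices:
            path = []
            while i != -1:
                path.append(i)
                i = self.nodes[i].parent
            paths.append(set(path))
        common = set.intersection(*paths)
        return min(common, key=lambda i: -self._depth(i))

    def _depth(self, i: int) -> int:
        d = 0
        while self.nodes[i].parent != -1:
            i = self.nodes[i].parent
            d += 1
        return d

    # -- queries / manipulation --------------------------------------------

    @property
    def n_foreground(self) -> int:
        return sum(n.foreground for n in self.nodes if n.parent != -1)

    def scaled(self, factor: float) -> "PhyloTree":
        """New tree with all branch lengths multiplied by ``factor``."""
        nodes = [
            Node(n.index, n.parent, n.length * factor, n.is_tip, n.taxon,
                 n.foreground, list(n.children))
            for n in self.nodes
        ]
        return PhyloTree(nodes)

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent != -1)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            n = self.nodes[i]
            if n.is_tip:
                label = n.taxon
            else:
                label = "(" + ",".join(fmt(c) for c in n.children) + ")"
            mark = " #1" if n.foreground else ""
            if n.parent == -1:
                return f"{label};"
            return f"{label}{mark}:{n.length:.6f}"

        return fmt(self.root)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_taxa={len(self.taxa)}, n_foreground={self.n_foreground})"
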
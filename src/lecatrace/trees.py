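"""Rooted topologies for gene-content parsimony.

A tree is a recursive :class:`Clade` over string leaf labels; internal nodes
may be binary or multifurcating and carry no branch lengths (gene-content
parsimony here is purely topological).  The edge above a node is identified
by the node's *signature*: the '+'-joined sorted tuple of its leaf labels.
The edge above the root is the root edge — a gain mapped there means the
character was already present in the common ancestor.

Newick reading/writing goes through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterator

import dendropy

__all__ = ["Clade", "leaf", "clade", "from_newick", "ROOT_EDGE"]

#: Conventional name reported for the edge above the root.
ROOT_EDGE = "root"


@dataclass(frozen=True)
class Clade:
    """A rooted (sub)tree.  Leaves have a label and no children."""

    label: str | None = None
    children: tuple["Clade", ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if self.is_leaf and not self.label:
            raise ValueError("leaf nodes need a non-empty label")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @cached_property
    def leaf_names(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)
        names: list[str] = []
        for c in self.children:
            names.extend(c.leaf_names)
        return tuple(names)

    @cached_property
    def signature(self) -> str:
        """Stable identifier of the edge above this node."""
        return "+".join(sorted(self.leaf_names))

    def validate(self) -> None:
        names = self.leaf_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node in self.postorder():
            if not node.is_leaf and len(node.children) < 2:
                raise ValueError("internal nodes must have >=2 children")

    def postorder(self) -> Iterator["Clade"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def edges(self) -> list["Clade"]:
        """All nodes, each standing for the edge above it (root included)."""
        return list(self.postorder())

    def find_lca(self, leaves: set[str]) -> "Clade":
        """Smallest clade containing all of ``leaves``."""
        missing = leaves - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        node = self
        while True:
            carriers = [c for c in node.children if leaves & set(c.leaf_names)]
            if len(carriers) == 1 and not node.is_leaf:
                node = carriers[0]
            else:
                return node

    def to_newick(self) -> str:
        def render(node: Clade) -> str:
            if node.is_leaf:
                return node.label
            return "(" + ",".join(render(c) for c in node.children) + ")"

        return render(self) + ";"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.to_newick()


def leaf(name: str) -> Clade:
    return Clade(label=name)


def clade(*children: Clade | str) -> Clade:
    return Clade(children=tuple(leaf(c) if isinstance(c, str) else c for c in children))


def from_newick(newick: str) -> Clade:
    """Parse a Newick string into a :class:`Clade` (topology only)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")

    def convert(node) -> Clade:
        if node.is_leaf():
            return leaf(node.taxon.label if node.taxon else node.label)
        return Clade(children=tuple(convert(c) for c in node.child_nodes()))

    root = convert(tree.seed_node)
    root.validate()
    return root
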
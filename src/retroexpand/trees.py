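"""Rooted, dated trees for species histories and gene families.

Trees are stored as plain linked ``Node`` objects carrying an absolute age in
millions of years (MY) before present (present = 0; extinct tips may have
positive ages). Branch lengths are implicit: ``parent.age - child.age``.
Newick serialization writes branch lengths in MY; parsing recovers ages by
anchoring the deepest tip at age 0 unless tip ages are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for structurally invalid trees (e.g. child older than parent)."""


@dataclass
class Node:
    name: str = ""
    age: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None
    # annotations used by the gene-family simulator / reconciliation
    event: Optional[str] = None       # retro | duplication | speciation | loss | extant
    species: Optional[str] = None     # species (branch) a gene node lives on

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def find(self, name: str) -> Optional["Node"]:
        for n in self.walk():
            if n.name == name:
                return n
        return None

    def ancestors(self) -> Iterator["Node"]:
        n = self.parent
        while n is not None:
            yield n
            n = n.parent

    def copy(self) -> "Node":
        clone = Node(self.name, self.age, event=self.event, species=self.species)
        for c in self.children:
            clone.add(c.copy())
        return clone

    # -- construction / validation -------------------------------------------

    def validate_ages(self) -> None:
        for n in self.walk():
            for c in n.children:
                if c.age >= n.age:
                    raise TreeError(
                        f"node {c.name or '<anon>'} (age {c.age}) is not younger "
                        f"than its parent {n.name or '<anon>'} (age {n.age})"
                    )
            if n.is_leaf and n.age < 0:
                raise TreeError(f"tip {n.name} has negative age {n.age}")

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.walk())

    # -- newick ---------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                label = n.name
            else:
                label = f"({','.join(fmt(c) for c in n.children)}){n.name}"
            if n.parent is not None:
                label += f":{n.parent.age - n.age:.6f}"
            return label

        return fmt(self) + ";"


def mrca(a: Node, b: Node) -> Node:
    seen = {id(a)}
    anc_a = [a] + list(a.ancestors())
    seen = {id(n) for n in anc_a}
    if id(b) in seen:
        return b
    for n in [b] + list(b.ancestors()):
        if id(n) in seen:
            return n
    raise TreeError("nodes do not share a root")


def prune_to_leaves(root: Node, keep: set[str]) -> Optional[Node]:
    """Restrict a tree to the named leaves, suppressing unary nodes.

    Returns a new tree (deep copy); ``None`` when no named leaf is present.
    Node ages, events and species annotations are preserved.
    """

    def rec(node: Node) -> Optional[Node]:
        if node.is_leaf:
            if node.name in keep:
                return Node(node.name, node.age, event=node.event, species=node.species)
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        out = Node(node.name, node.age, event=node.event, species=node.species)
        for c in kept:
            out.add(c)
        return out

    return rec(root)


def from_newick(text: str, tip_ages: Optional[dict[str, float]] = None) -> Node:
    """Parse newick with branch lengths in MY into an aged ``Node`` tree.

    Ages are assigned by placing the deepest root-to-tip path's tip at age 0,
    then overriding with ``tip_ages`` when given (ages must be consistent with
    branch lengths for the tips named there; remaining tips keep derived ages).
    """
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    root = tree.seed_node

    def convert(dnode) -> Node:
        n = Node(name=(dnode.taxon.label if dnode.taxon else (dnode.label or "")))
        for c in dnode.child_nodes():
            child = convert(c)
            child.parent = n
            n.children.append(child)
        return n

    out = convert(root)
    depth: dict[int, float] = {}
    _assign_depths(root, out, 0.0, depth)
    max_depth = max(depth[id(n)] for n in out.walk() if n.is_leaf)
    if tip_ages:
        # anchor: any named tip fixes the total tree height
        heights = []
        for n in out.walk():
            if n.is_leaf and n.name in tip_ages:
                heights.append(depth[id(n)] + tip_ages[n.name])
        if heights:
            max_depth = heights[0]
    for n in out.walk():
        n.age = max_depth - depth[id(n)]
    return out


def _assign_depths(dnode, node: Node, d: float, depth: dict[int, float]) -> None:
    depth[id(node)] = d
    for dc, c in zip(dnode.child_nodes(), node.children):
        bl = dc.edge.length or 0.0
        _assign_depths(dc, c, d + bl, depth)


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """Rooted binary species tree with node ages in MY before present.

    Tips with age 0 are extant; tips with positive age are extinct taxa
    sampled before the present (e.g. mammoth, mastodon).
    """

    root: Node

    def __post_init__(self) -> None:
        self.root.validate_ages()

    def find(self, name: str) -> Node:
        n = self.root.find(name)
        if n is None:
            raise KeyError(f"no node named {name!r}")
        return n

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def tip_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def is_extant(self, name: str) -> bool:
        return self.find(name).age == 0

    def clade_names(self, name: str) -> set[str]:
        """Names of every node inside the clade rooted at ``name`` (inclusive)."""
        return {n.name for n in self.find(name).walk() if n.name}

    def path_to(self, tip: str) -> list[Node]:
        """Nodes from root to the named tip (inclusive)."""
        n = self.find(tip)
        path = [n] + list(n.ancestors())
        return list(reversed(path))

    def to_newick(self) -> str:
        return self.root.to_newick()


#: Calibration ages (MY) for the elephant/hyrax/manatee clade and relatives:
#: Paenungulata crown at 64.2 MY, mastodon-elephant split at 25 MY, African
#: vs (Asian elephant, mammoth) split at 8 MY. Remaining splits use standard
#: timetree values; extinct tips carry specimen ages.
_PAENUNGULATA_SPEC = {
    "name": "Afrotheria",
    "age": 80.0,
    "children": [
        {"name": "outgroup"},
        {
            "name": "Paenungulata",
            "age": 64.2,
            "children": [
                {"name": "hyrax"},
                {
                    "name": "Tethytheria",
                    "age": 60.0,
                    "children": [
                        {"name": "manatee"},
                        {
                            "name": "Proboscidea",
                            "age": 25.0,
                            "children": [
                                {"name": "mastodon", "age": 0.09},
                                {
                                    "name": "Elephantidae",
                                    "age": 8.0,
                                    "children": [
                                        {"name": "african_elephant"},
                                        {
                                            "name": "Elephas_Mammuthus",
                                            "age": 6.0,
                                            "children": [
                                                {"name": "asian_elephant"},
                                                {"name": "mammoth", "age": 0.011},
                                            ],
                                        },
                                    ],
                                },
                            ],
                        },
                    ],
                },
            ],
        },
    ],
}


def _from_spec(spec: dict) -> Node:
    node = Node(name=spec.get("name", ""), age=float(spec.get("age", 0.0)))
    for child in spec.get("children", []):
        node.add(_from_spec(child))
    return node


def build_species_tree(preset_or_spec="paenungulata") -> SpeciesTree:
    """Build a dated species tree from a preset name, nested spec, or newick.

    ``"paenungulata"`` gives the seven-taxon elephant/hyrax/manatee tree used
    throughout the study scenario. A dict spec uses keys ``name``, ``age``
    (MY before present, default 0 for tips) and ``children``. A newick string
    with branch lengths in MY is also accepted.
    """
    if isinstance(preset_or_spec, SpeciesTree):
        return preset_or_spec
    if isinstance(preset_or_spec, dict):
        root = _from_spec(preset_or_spec)
    elif isinstance(preset_or_spec, str):
        key = preset_or_spec.strip()
        if key.lower() == "paenungulata":
            root = _from_spec(_PAENUNGULATA_SPEC)
        elif key.startswith("("):
            root = from_newick(key)
        else:
            raise ValueError(f"unknown species tree preset {preset_or_spec!r}")
    else:
        raise TypeError("expected preset name, newick string, or nested spec dict")
    return SpeciesTree(root)
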
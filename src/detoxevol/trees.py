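"""Rooted species and gene trees.

The species tree used throughout the package is the five-taxon hemipteran
tree (Nlug,((Clec,Rpro)CR,(Hhal,Nvir)HN)HET)root, with every terminal and
internal branch named so that duplication/loss events can be charged to a
specific branch.  Gene trees carry species information in their leaf names
(4-letter species tag prefix, e.g. ``Hhal_CYP3_g7``).

Newick parsing and serialisation go through dendropy; the in-memory
structures here are deliberately small so that reconciliation and the
birth-death simulator can manipulate them cheaply.
"""

from __future__ import annotations

import re
from typing import Dict, Iterator, List, Optional, Sequence

import dendropy

#: Default species tree: topology and branch names used in the comparative
#: analysis.  CR = Clec+Rpro ancestor, HN = Hhal+Nvir ancestor, HET = the
#: heteropteran ancestor (CR+HN).
DEFAULT_SPECIES_TREE_NEWICK = "(Nlug,((Clec,Rpro)CR,(Hhal,Nvir)HN)HET)root;"

SPECIES_TAGS = ("Nlug", "Clec", "Rpro", "Hhal", "Nvir")

#: Default leaf-name pattern: 4-letter species tag prefix.
DEFAULT_LEAF_PATTERN = r"^([A-Z][a-z]{3})"


class TreeError(ValueError):
    """Raised for malformed or unsupported tree inputs."""


class GeneNode:
    """A node of a rooted gene tree.

    Leaves have a ``name`` and no children.  Internal nodes may carry an
    ``event`` tag (``"speciation"`` or ``"duplication"``) and the species-tree
    ``branch`` the event occurred on; the simulator fills these in, the
    reconciler ignores them.
    """

    __slots__ = ("name", "children", "event", "branch")

    def __init__(self, name: Optional[str] = None,
                 children: Optional[List["GeneNode"]] = None,
                 event: Optional[str] = None,
                 branch: Optional[str] = None):
        self.name = name
        self.children = children if children is not None else []
        self.event = event
        self.branch = branch

    # -- structure ---------------------------------------------------------

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["GeneNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> List["GeneNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.postorder())

    def max_out_degree(self) -> int:
        return max((len(n.children) for n in self.postorder()), default=0)

    def copy(self) -> "GeneNode":
        node = GeneNode(self.name, [c.copy() for c in self.children],
                        self.event, self.branch)
        return node

    # -- serialisation -----------------------------------------------------

    def to_newick(self, include_internal_names: bool = True) -> str:
        def fmt(node: GeneNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name if (include_internal_names and node.name) else ""
            return f"({inner}){label}"
        return fmt(self) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "GeneNode":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"unparseable newick: {exc}") from exc
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "GeneNode":
        def convert(dnode) -> GeneNode:
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            if name is not None:
                name = name.replace(" ", "_")
            return cls(name, [convert(c) for c in dnode.child_nodes()])
        return convert(tree.seed_node)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneNode({self.to_newick()!r})"


class SpeciesTree:
    """Rooted binary species tree with uniquely labelled nodes.

    Every node label doubles as the name of the branch above it; duplications
    occurring above the root are charged to the root's own label.
    """

    def __init__(self, newick: str = DEFAULT_SPECIES_TREE_NEWICK):
        self.newick = newick
        root = GeneNode.from_newick(newick)
        self._autolabel(root)
        if not root.is_binary():
            raise TreeError("species tree must be binary")
        self.root = root
        self.parent: Dict[str, Optional[str]] = {}
        self.children: Dict[str, List[str]] = {}
        self.depth: Dict[str, int] = {}
        self._index(root, None, 0)
        self.labels = list(self.parent)
        if len(self.labels) != len(set(self.labels)):
            raise TreeError("species tree node labels must be unique")
        self.leaf_labels = [n.name for n in root.leaves()]
        self.root_label = root.name

    @staticmethod
    def _autolabel(root: GeneNode) -> None:
        counter = [0]
        for node in root.postorder():
            if node.name is None:
                if node is root:
                    node.name = "root"
                else:
                    counter[0] += 1
                    node.name = f"N{counter[0]}"

    def _index(self, node: GeneNode, parent: Optional[str], depth: int) -> None:
        if node.name in self.parent:
            raise TreeError(f"duplicate species-tree label {node.name!r}")
        self.parent[node.name] = parent
        self.children[node.name] = [c.name for c in node.children]
        self.depth[node.name] = depth
        for child in node.children:
            self._index(child, node.name, depth + 1)

    # -- queries -----------------------------------------------------------

    def is_leaf(self, label: str) -> bool:
        return not self.children[label]

    def ancestors(self, label: str) -> List[str]:
        """Labels from ``label`` up to and including the root."""
        out = [label]
        while self.parent[out[-1]] is not None:
            out.append(self.parent[out[-1]])
        return out

    def lca(self, a: str, b: str) -> str:
        seen = set(self.ancestors(a))
        for label in self.ancestors(b):
            if label in seen:
                return label
        raise TreeError(f"no common ancestor of {a!r} and {b!r}")

    def lca_many(self, labels: Sequence[str]) -> str:
        it = iter(labels)
        acc = next(it)
        for label in it:
            acc = self.lca(acc, label)
        return acc

    def path_down(self, ancestor: str, descendant: str) -> List[str]:
        """Node labels from ``ancestor`` to ``descendant``, inclusive."""
        up = []
        label = descendant
        while label != ancestor:
            up.append(label)
            label = self.parent[label]
            if label is None:
                raise TreeError(f"{ancestor!r} is not an ancestor "
                                f"of {descendant!r}")
        up.append(ancestor)
        return list(reversed(up))

    def distance_down(self, ancestor: str, descendant: str) -> int:
        """Number of edges on the path from ancestor down to descendant."""
        return len(self.path_down(ancestor, descendant)) - 1

    def sibling(self, label: str) -> str:
        parent = self.parent[label]
        if parent is None:
            raise TreeError("root has no sibling")
        other = [c for c in self.children[parent] if c != label]
        return other[0]

    def branch_labels(self) -> List[str]:
        """All branch names, terminal branches first, then internal, then root."""
        internal = [l for l in self.labels
                    if not self.is_leaf(l) and l != self.root_label]
        return list(self.leaf_labels) + internal + [self.root_label]


def default_species_tree() -> SpeciesTree:
    return SpeciesTree(DEFAULT_SPECIES_TREE_NEWICK)


def parse_species_mapping(gene_tree: GeneNode,
                          species_tree: SpeciesTree,
                          pattern: str = DEFAULT_LEAF_PATTERN) -> Dict[str, str]:
    """Map every gene-tree leaf name to a species-tree leaf label.

    The default pattern extracts a 4-letter species tag prefix from each leaf
    name.  A leaf whose tag is not a terminal label of the species tree is an
    error that names the offending leaf.
    """
    regex = re.compile(pattern)
    mapping: Dict[str, str] = {}
    valid = set(species_tree.leaf_labels)
    for leaf in gene_tree.leaves():
        name = leaf.name or ""
        match = regex.match(name)
        tag = match.group(1) if match and match.groups() else (
            match.group(0) if match else None)
        if tag is None or tag not in valid:
            raise TreeError(
                f"leaf {name!r} does not carry a recognised species tag "
                f"(expected one of {sorted(valid)})")
        mapping[name] = tag
    return mapping
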
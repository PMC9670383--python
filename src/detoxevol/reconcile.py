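"""Duplication-loss reconciliation of gene trees against the species tree.

The reconciler performs classical LCA (last-common-ancestor) mapping: each
gene-tree leaf maps to its species, each internal node to the LCA of its
children's images.  A node is a duplication when its image equals the image
of one of its children, otherwise it is a speciation.  Losses are charged to
the specific species-tree branch on which the vanished lineage disappeared:
for a gene-tree edge (v, c) whose images span the species path
M(v) = s0 -> s1 -> ... -> sk = M(c), one loss is charged to the sibling
branch at every intermediate node (and, for a duplication at v, also at s0).
The resulting cost - total duplications plus losses - is the minimum
duplication-loss cost for the given rooted gene tree.

Aggregation over families produces a branch x family event matrix with
duplication and loss rows per branch, mirroring the per-branch gain/loss
accounting of the comparative study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .trees import (DEFAULT_LEAF_PATTERN, GeneNode, SpeciesTree, TreeError,
                    parse_species_mapping)

ROOT_BRANCH = "root"


@dataclass
class ReconciliationResult:
    """Per-node event calls and per-branch duplication/loss counts."""

    node_events: Dict[int, Tuple[str, str]]  # id(node) -> (species label, event)
    duplications: Dict[str, int]             # branch -> count
    losses: Dict[str, int]                   # branch -> count
    leaf_counts: Dict[str, int]              # species -> number of gene leaves

    @property
    def cost(self) -> int:
        return sum(self.duplications.values()) + sum(self.losses.values())

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())


def _resolve_polytomies(node: GeneNode, species_tree: SpeciesTree,
                        mapping: Mapping[str, str]) -> GeneNode:
    """Resolve each polytomy into the local binary structure that favours
    deep (speciation-like) joins.

    Children are merged greedily, always joining the pair whose species-tree
    LCA is deepest; ties break on the lexicographically smallest leaf name.
    This minimises the duplications introduced by the resolution for the
    common case of a polytomy over distinct species.
    """
    children = [_resolve_polytomies(c, species_tree, mapping)
                for c in node.children]
    if len(children) <= 2:
        out = GeneNode(node.name, children, node.event, node.branch)
        return out

    def image(n: GeneNode) -> str:
        labels = [mapping[l] for l in n.leaf_names()]
        return species_tree.lca_many(labels)

    def min_leaf(n: GeneNode) -> str:
        return min(n.leaf_names())

    while len(children) > 2:
        best = None
        for i in range(len(children)):
            for j in range(i + 1, len(children)):
                lca = species_tree.lca(image(children[i]), image(children[j]))
                key = (-species_tree.depth[lca],
                       min(min_leaf(children[i]), min_leaf(children[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        merged = GeneNode(None, [children[i], children[j]])
        children = ([c for k, c in enumerate(children) if k not in (i, j)]
                    + [merged])
    return GeneNode(node.name, children, node.event, node.branch)


def lca_reconcile(gene_tree: GeneNode,
                  species_tree: SpeciesTree,
                  mapping: Optional[Mapping[str, str]] = None,
                  pattern: str = DEFAULT_LEAF_PATTERN,
                  polytomies: str = "error") -> ReconciliationResult:
    """Most-parsimonious duplication-loss reconciliation of a rooted gene tree.

    Parameters
    ----------
    gene_tree : GeneNode
        Rooted gene tree.  Must be binary unless ``polytomies="resolve"``.
    species_tree : SpeciesTree
        Rooted binary species tree with named branches.
    mapping : mapping, optional
        Leaf name -> species label.  Derived from leaf names via ``pattern``
        when omitted.
    polytomies : {"error", "resolve"}
        Multifurcating nodes are rejected by default; ``"resolve"`` replaces
        each polytomy by the local resolution that favours speciations.
    """
    if gene_tree is None or gene_tree.n_leaves() == 0:
        raise TreeError("gene tree has no leaves")
    if mapping is None:
        mapping = parse_species_mapping(gene_tree, species_tree, pattern)
    for leaf in gene_tree.leaf_names():
        if leaf not in mapping:
            raise TreeError(f"leaf {leaf!r} missing from the species mapping")

    if not gene_tree.is_binary():
        if polytomies == "resolve":
            gene_tree = _resolve_polytomies(gene_tree, species_tree, mapping)
        else:
            raise TreeError(
                "gene tree contains polytomies; pass polytomies='resolve' "
                "to resolve them towards speciations")

    dup: Dict[str, int] = {}
    loss: Dict[str, int] = {}
    node_events: Dict[int, Tuple[str, str]] = {}
    leaf_counts: Dict[str, int] = {}

    def charge_loss(branch: str) -> None:
        loss[branch] = loss.get(branch, 0) + 1

    def walk(node: GeneNode) -> str:
        if node.is_leaf:
            sp = mapping[node.name]
            leaf_counts[sp] = leaf_counts.get(sp, 0) + 1
            node_events[id(node)] = (sp, "leaf")
            return sp
        images = [walk(c) for c in node.children]
        m = species_tree.lca_many(images)
        is_dup = any(m == ci for ci in images)
        event = "duplication" if is_dup else "speciation"
        node_events[id(node)] = (m, event)
        if is_dup:
            # charge to the branch above the image; a duplication mapping to
            # the species root predates the first split and goes on "root"
            branch = ROOT_BRANCH if m == species_tree.root_label else m
            dup[branch] = dup.get(branch, 0) + 1
        for ci in images:
            path = species_tree.path_down(m, ci)
            # intermediate speciations on the path each shed a sibling lineage
            start = 0 if is_dup else 1
            for idx in range(start, len(path) - 1):
                charge_loss(species_tree.sibling(path[idx + 1]))
        return m

    walk(gene_tree)
    return ReconciliationResult(node_events=node_events,
                                duplications=dup, losses=loss,
                                leaf_counts=leaf_counts)


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def _unrooted_adjacency(tree: GeneNode):
    """Adjacency list of the unrooted topology underlying ``tree``.

    A degree-2 root is suppressed.  Nodes are represented by ids into a node
    table so subtrees can be rebuilt from any edge.
    """
    nodes: List[Optional[str]] = []
    adj: List[List[int]] = []

    def new_node(name: Optional[str]) -> int:
        nodes.append(name)
        adj.append([])
        return len(nodes) - 1

    def build(node: GeneNode) -> int:
        me = new_node(node.name if node.is_leaf else None)
        for child in node.children:
            cid = build(child)
            adj[me].append(cid)
            adj[cid].append(me)
        return me

    root_id = build(tree)
    if len(adj[root_id]) == 2:  # suppress the rooted tree's degree-2 root
        a, b = adj[root_id]
        adj[a] = [x for x in adj[a] if x != root_id] + [b]
        adj[b] = [x for x in adj[b] if x != root_id] + [a]
        adj[root_id] = []
    return nodes, adj, root_id


def root_by_min_dl(gene_tree: GeneNode,
                   species_tree: SpeciesTree,
                   mapping: Optional[Mapping[str, str]] = None,
                   pattern: str = DEFAULT_LEAF_PATTERN) -> GeneNode:
    """Root an (effectively unrooted) gene tree on the branch minimising the
    total duplication-loss cost.

    Every branch of the unrooted topology is tried; ties break on the
    lexicographically smallest pair of minimal leaf names flanking the
    candidate root branch, making the result deterministic.
    """
    if gene_tree.n_leaves() < 3:
        return gene_tree.copy()
    if mapping is None:
        mapping = parse_species_mapping(gene_tree, species_tree, pattern)

    nodes, adj, _ = _unrooted_adjacency(gene_tree)

    def subtree(at: int, came_from: int) -> GeneNode:
        neighbours = [n for n in adj[at] if n != came_from]
        if not neighbours:
            return GeneNode(nodes[at])
        return GeneNode(None, [subtree(n, at) for n in neighbours])

    seen = set()
    best: Optional[Tuple[Tuple, GeneNode]] = None
    for u in range(len(nodes)):
        for v in adj[u]:
            if (v, u) in seen:
                continue
            seen.add((u, v))
            left = subtree(u, v)
            right = subtree(v, u)
            rooted = GeneNode(None, [left, right])
            cost = lca_reconcile(rooted, species_tree, mapping).cost
            key = (cost, tuple(sorted((min(left.leaf_names()),
                                       min(right.leaf_names())))))
            if best is None or key < best[0]:
                best = (key, rooted)
    return best[1]


# ---------------------------------------------------------------------------
# Event matrix
# ---------------------------------------------------------------------------

DEFAULT_FAMILY_GROUPS = ("MIT", "CYP2", "CYP3", "CYP4", "GST", "CCE")

EVENT_ROWS = ("Duplications", "Losses")


@dataclass
class EventMatrix:
    """Branch x family-group table of duplication and loss counts.

    Stored as a DataFrame indexed by (branch, event) with one column per
    family group; row and column totals are always recomputed from the cells.
    """

    table: pd.DataFrame
    branches: Tuple[str, ...] = field(default=())
    groups: Tuple[str, ...] = field(default=DEFAULT_FAMILY_GROUPS)

    def __post_init__(self):
        if not self.branches:
            self.branches = tuple(dict.fromkeys(
                self.table.index.get_level_values(0)))
        self.groups = tuple(self.table.columns)

    @classmethod
    def zeros(cls, branches: Sequence[str],
              groups: Sequence[str] = DEFAULT_FAMILY_GROUPS) -> "EventMatrix":
        index = pd.MultiIndex.from_product([list(branches), list(EVENT_ROWS)],
                                           names=["branch", "event"])
        table = pd.DataFrame(0, index=index, columns=list(groups), dtype=int)
        return cls(table=table, branches=tuple(branches))

    def add(self, branch: str, event: str, group: str, count: int) -> None:
        self.table.loc[(branch, event), group] += int(count)

    def get(self, branch: str, event: str, group: Optional[str] = None) -> int:
        row = self.table.loc[(branch, event)]
        return int(row.sum()) if group is None else int(row[group])

    def branch_total(self, branch: str, event: str) -> int:
        return self.get(branch, event)

    def group_total(self, group: str) -> int:
        """Duplications plus losses summed over all branches for one group."""
        return int(self.table[group].sum())

    def total_events(self, groups: Optional[Sequence[str]] = None) -> int:
        groups = list(groups) if groups is not None else list(self.groups)
        return int(self.table[groups].to_numpy().sum())

    def event_total(self, event: str,
                    groups: Optional[Sequence[str]] = None) -> int:
        groups = list(groups) if groups is not None else list(self.groups)
        sub = self.table.xs(event, level="event")[groups]
        return int(sub.to_numpy().sum())

    def with_totals(self) -> pd.DataFrame:
        """Table-layout frame with a Total column and a Total row."""
        out = self.table.copy()
        out["Total"] = out.sum(axis=1)
        totals = out.groupby(level="event", sort=False).sum()
        for event in EVENT_ROWS:
            if event in totals.index:
                out.loc[("Total", event), :] = totals.loc[event]
        return out.astype(int)

    def to_tsv(self, path) -> None:
        self.with_totals().to_csv(path, sep="\t")

    @classmethod
    def from_cells(cls, cells: Iterable[Tuple[str, str, str, int]],
                   branches: Optional[Sequence[str]] = None,
                   groups: Sequence[str] = DEFAULT_FAMILY_GROUPS
                   ) -> "EventMatrix":
        cells = list(cells)
        if branches is None:
            branches = list(dict.fromkeys(branch for branch, _, _, _ in cells))
        matrix = cls.zeros(branches, groups)
        for branch, event, group, count in cells:
            matrix.add(branch, event, group, count)
        return matrix


def aggregate_event_matrix(results: Mapping[str, ReconciliationResult],
                           family_grouping: Mapping[str, str],
                           species_tree: SpeciesTree,
                           groups: Optional[Sequence[str]] = None
                           ) -> EventMatrix:
    """Sum per-family reconciliation events into a branch x group matrix."""
    for family in results:
        if family not in family_grouping:
            raise KeyError(f"family {family!r} has no group assignment")
    if groups is None:
        groups = tuple(dict.fromkeys(family_grouping[f] for f in results))
        if not groups:
            groups = DEFAULT_FAMILY_GROUPS
    branches = [b for b in species_tree.branch_labels()
                if b != species_tree.root_label]
    branches.append(ROOT_BRANCH)
    matrix = EventMatrix.zeros(branches, groups)
    for family, result in results.items():
        group = family_grouping[family]
        for branch, count in result.duplications.items():
            matrix.add(branch, "Duplications", group, count)
        for branch, count in result.losses.items():
            matrix.add(branch, "Losses", group, count)
    return matrix


def annotate_species_tree_with_events(event_matrix: EventMatrix,
                                      species_tree: SpeciesTree
                                      ) -> Tuple[pd.DataFrame, str]:
    """Per-branch gains/losses table plus an annotated newick string.

    Each branch is labelled ``+G/-L`` with G the summed duplications and L
    the summed losses across family groups; the newick carries the same
    annotation as a bracketed comment after each node label.
    """
    known = set(species_tree.labels) | {ROOT_BRANCH}
    unknown = [b for b in event_matrix.branches
               if b not in known and b != "Total"]
    if unknown:
        raise TreeError(f"event-matrix branches not on the species tree: "
                        f"{unknown}")

    rows = []
    per_branch = {}
    for branch in event_matrix.branches:
        gains = event_matrix.get(branch, "Duplications")
        losses = event_matrix.get(branch, "Losses")
        per_branch[branch] = (gains, losses)
        rows.append({"branch": branch, "gains": gains, "losses": losses,
                     "label": f"+{gains}/-{losses}"})
    frame = pd.DataFrame(rows).set_index("branch")

    def fmt(node: GeneNode) -> str:
        branch = node.name
        if branch == species_tree.root_label:
            branch = ROOT_BRANCH
        gains, losses = per_branch.get(branch, (0, 0))
        comment = f"[+{gains}/-{losses}]"
        if node.is_leaf:
            return f"{node.name}{comment}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.name}{comment}"

    return frame, fmt(species_tree.root) + ";"
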
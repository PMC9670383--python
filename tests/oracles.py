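"""Independent reference implementations used only for cross-checking.

These deliberately avoid the package's own code paths: trees are plain
nested tuples, the species tree is a hand-rolled parent map, the minimal
duplication-loss cost is found by exhaustive enumeration over all valid
node mappings, cluster detection is all-pairs gap testing plus networkx
connected components, and the chi-square statistic is the closed-form
2x2 formula.
"""

from __future__ import annotations

from itertools import product
from math import sqrt
from typing import Dict, Iterable, List, Tuple, Union

import networkx as nx

TupleTree = Union[str, Tuple["TupleTree", "TupleTree"]]


class OracleSpeciesTree:
    """Species tree as an explicit parent map."""

    def __init__(self, parent: Dict[str, str], root: str):
        self.parent = parent
        self.root = root
        self.nodes = sorted(set(parent) | {root})

    @classmethod
    def three_species(cls) -> "OracleSpeciesTree":
        # (A,(B,C)) with internal node BC and root R
        return cls({"A": "R", "BC": "R", "B": "BC", "C": "BC"}, "R")

    def ancestors(self, node: str) -> List[str]:
        out = [node]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out

    def is_ancestor_or_equal(self, anc: str, node: str) -> bool:
        return anc in self.ancestors(node)

    def lca(self, a: str, b: str) -> str:
        seen = set(self.ancestors(a))
        for node in self.ancestors(b):
            if node in seen:
                return node
        raise AssertionError("disconnected species tree")

    def dist_down(self, anc: str, node: str) -> int:
        path = self.ancestors(node)
        return path.index(anc)

    def children(self, node: str) -> List[str]:
        return [n for n, p in self.parent.items() if p == node]


def tuple_tree_leaves(tree: TupleTree) -> List[str]:
    if isinstance(tree, str):
        return [tree]
    return tuple_tree_leaves(tree[0]) + tuple_tree_leaves(tree[1])


def brute_force_min_dl(tree: TupleTree, species: OracleSpeciesTree,
                       leaf_species: Dict[str, str]) -> int:
    """Minimal duplication+loss cost over ALL valid reconciliation maps.

    A map assigns each internal node a species-tree node that is an
    ancestor-or-equal of both children's images.  A node is a speciation
    when its children's images lie in distinct child subtrees of its own
    image, otherwise a duplication; each child edge contributes
    path-length losses (minus one for speciation edges).
    """
    internals: List[Tuple] = []

    def collect(node: TupleTree):
        if isinstance(node, str):
            return
        internals.append(node)
        collect(node[0])
        collect(node[1])

    collect(tree)

    def image_leafset_lca(node: TupleTree) -> str:
        labels = [leaf_species[l] for l in tuple_tree_leaves(node)]
        acc = labels[0]
        for lab in labels[1:]:
            acc = species.lca(acc, lab)
        return acc

    candidates = {id(n): species.ancestors(image_leafset_lca(n))
                  for n in internals}

    best = None
    for assignment in product(*(candidates[id(n)] for n in internals)):
        mapping = {id(n): s for n, s in zip(internals, assignment)}

        def img(node: TupleTree) -> str:
            return (leaf_species[node] if isinstance(node, str)
                    else mapping[id(node)])

        valid = True
        cost = 0
        for node in internals:
            m = img(node)
            child_imgs = [img(node[0]), img(node[1])]
            if not all(species.is_ancestor_or_equal(m, ci)
                       for ci in child_imgs):
                valid = False
                break
            # speciation iff the two child images enter distinct child
            # subtrees of m
            sides = []
            for ci in child_imgs:
                if ci == m:
                    sides.append(None)
                else:
                    path = species.ancestors(ci)
                    sides.append(path[path.index(m) - 1])
            is_spec = (sides[0] is not None and sides[1] is not None
                       and sides[0] != sides[1])
            cost += 0 if is_spec else 1
            for ci in child_imgs:
                d = species.dist_down(m, ci)
                cost += d - 1 if is_spec else d
        if valid and (best is None or cost < best):
            best = cost
    assert best is not None
    return best


def enumerate_tuple_trees(n_leaves: int, species_labels: Iterable[str]
                          ) -> List[TupleTree]:
    """All rooted binary leaf-labelled tree shapes with species-labelled
    leaves, deduplicated up to child order."""
    species_labels = list(species_labels)

    def shapes(n: int) -> List[TupleTree]:
        if n == 1:
            return ["?"]
        out = []
        for k in range(1, n):
            for left in shapes(k):
                for right in shapes(n - k):
                    out.append((left, right))
        return out

    def canonical(t: TupleTree):
        if isinstance(t, str):
            return t
        a, b = canonical(t[0]), canonical(t[1])
        return tuple(sorted((a, b), key=repr))

    trees = set()
    for shape in shapes(n_leaves):
        slots = []

        def count(t):
            if isinstance(t, str):
                slots.append(None)
                return
            count(t[0])
            count(t[1])

        count(shape)
        for labels in product(species_labels, repeat=len(slots)):
            idx = [0]

            def fill(t):
                if isinstance(t, str):
                    label = labels[idx[0]]
                    idx[0] += 1
                    return label
                return (fill(t[0]), fill(t[1]))

            trees.add(canonical(fill(shape)))
    return sorted(trees, key=repr)


def tuple_tree_to_newick(tree: TupleTree, counter=None) -> str:
    """Newick with unique leaf names '<Species>_<k>'."""
    if counter is None:
        counter = {}

    def fmt(node: TupleTree) -> str:
        if isinstance(node, str):
            counter[node] = counter.get(node, 0) + 1
            return f"{node}_{counter[node]}"
        return f"({fmt(node[0])},{fmt(node[1])})"

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------

def brute_force_clusters(annotations, max_gap: int) -> List[frozenset]:
    """All-pairs gap testing + connected components; size >= 2 only."""
    graph = nx.Graph()
    anns = list(annotations)
    for ann in anns:
        graph.add_node(ann.gene_id)
    for i in range(len(anns)):
        for j in range(i + 1, len(anns)):
            a, b = anns[i], anns[j]
            if (a.species_tag, a.family, a.scaffold) != \
                    (b.species_tag, b.family, b.scaffold):
                continue
            left, right = (a, b) if a.start <= b.start else (b, a)
            gap = max(0, right.start - left.end - 1)
            if gap < max_gap:
                graph.add_edge(a.gene_id, b.gene_id)
    return sorted((frozenset(c) for c in nx.connected_components(graph)
                   if len(c) >= 2), key=sorted)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def chi2_2x2_closed_form(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square for a 2x2 table: N(ad-bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d))


def bh_step_up(p_values: List[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values, hand-rolled."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def pearson_r_closed_form(x: List[float], y: List[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / sqrt(vx * vy)
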
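"""Synthetic gene families and genome layouts with known ground truth.

Gene families evolve on the species tree under a branch-wise birth-death
process: on each species-tree branch every incoming gene lineage draws a
Poisson number of duplications (each splitting a uniformly chosen descendant
lineage at an ordered random point along the branch, so new copies are
themselves exposed to later events), and every lineage reaching the bottom
of the branch is lost independently with a per-branch probability.  The
expected surviving copy number per species is therefore

    root_copies * prod over branches on the root-to-leaf path of
        (1 + dup_rate) * (1 - loss_prob),

which the test suite checks against Monte-Carlo means.  Every event is
recorded in a truth log (per-branch duplication and loss counts plus
per-node event tags), so reconciliation accuracy can be scored exactly.
Families whose lineages all die are reported with an empty tree and a full
truth log.

The scaffold layout generator places curated genes on synthetic scaffolds
with a controllable fraction of same-family genes arranged in tandem chains
whose gaps sit strictly below the 35-kb clustering threshold, while all
other placements are separated by gaps at or above it - so the true cluster
partition is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .clusters import GeneAnnotation
from .trees import (DEFAULT_SPECIES_TREE_NEWICK, GeneNode, SpeciesTree,
                    TreeError)

RateLike = Union[float, Mapping[str, float]]


def _rate_for(rate: RateLike, branch: str, default: float = 0.0) -> float:
    if isinstance(rate, Mapping):
        return float(rate.get(branch, default))
    return float(rate)


@dataclass
class SimulationConfig:
    """Parameters of the branch-wise birth-death process.

    ``dup_rate`` is the expected number of duplications per incoming lineage
    per branch; ``loss_prob`` the per-lineage loss probability per branch.
    Both may be a single global value or a per-branch mapping.
    ``fixed_duplications`` forces an exact duplication count on selected
    branches (deterministic mode for tests and demonstrations); the forced
    count applies per incoming lineage on that branch.
    """

    species_tree: str = DEFAULT_SPECIES_TREE_NEWICK
    dup_rate: RateLike = 0.3
    loss_prob: RateLike = 0.1
    n_families: int = 100
    root_copies: int = 1
    seed: Optional[int] = None
    fixed_duplications: Optional[Dict[str, int]] = None

    def tree(self) -> SpeciesTree:
        return (self.species_tree
                if isinstance(self.species_tree, SpeciesTree)
                else SpeciesTree(self.species_tree))

    def validate(self) -> None:
        tree = self.tree()  # raises on bad newick / duplicate labels
        rates = (self.dup_rate.values()
                 if isinstance(self.dup_rate, Mapping) else [self.dup_rate])
        if any(r < 0 for r in rates):
            raise ValueError("dup_rate must be >= 0")
        probs = (self.loss_prob.values()
                 if isinstance(self.loss_prob, Mapping) else [self.loss_prob])
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("loss_prob must lie in [0, 1]")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        if self.root_copies < 1:
            raise ValueError("root_copies must be positive")
        if self.fixed_duplications:
            unknown = set(self.fixed_duplications) - set(tree.labels)
            if unknown:
                raise ValueError(f"fixed_duplications names unknown "
                                 f"branches: {sorted(unknown)}")


@dataclass
class EventTruth:
    """Ground-truth event log for one simulated family."""

    family_id: str
    duplications: Dict[str, int] = field(default_factory=dict)
    losses: Dict[str, int] = field(default_factory=dict)
    node_events: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    surviving: Dict[str, int] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return sum(self.duplications.values()) + sum(self.losses.values())

    @property
    def extinct(self) -> bool:
        return sum(self.surviving.values()) == 0


class _SimNode:
    __slots__ = ("children", "event", "branch", "alive", "name")

    def __init__(self, event: Optional[str], branch: Optional[str]):
        self.children: List["_SimNode"] = []
        self.event = event
        self.branch = branch
        self.alive = False     # for leaves: survived to the present
        self.name: Optional[str] = None


def simulate_family_evolution(config: SimulationConfig, family_id: str,
                              seed: Optional[int] = None
                              ) -> Tuple[Optional[GeneNode], EventTruth]:
    """Evolve one gene family on the species tree.

    Returns the pruned gene tree of surviving lineages (``None`` when the
    family went extinct) and the complete event truth log.  Gene-tree leaves
    are named ``<SpeciesTag>_<family_id>_g<N>`` with N counting per species
    in left-to-right order; surviving internal nodes keep their event tag
    and branch, mirrored into the truth log under labels
    ``<family_id>_e<K>``.
    """
    config.validate()
    tree = config.tree()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    truth = EventTruth(family_id=family_id)
    truth.surviving = {sp: 0 for sp in tree.leaf_labels}

    def evolve_branch(lineage: _SimNode, branch: str) -> None:
        """Apply duplications and losses on ``branch`` to one incoming
        lineage, then recurse into child branches for the survivors."""
        rate = _rate_for(config.dup_rate, branch)
        forced = (config.fixed_duplications or {}).get(branch)
        n_events = int(forced) if forced is not None else int(
            rng.poisson(rate))
        current = [lineage]
        for _ in range(n_events):
            # ordered random points: each event splits a uniformly chosen
            # extant descendant of the incoming lineage
            target = current[int(rng.integers(len(current)))]
            left = _SimNode(None, None)
            right = _SimNode(None, None)
            target.children = [left, right]
            target.event = "duplication"
            target.branch = branch
            truth.duplications[branch] = truth.duplications.get(branch, 0) + 1
            current.remove(target)
            current.extend([left, right])
        loss_p = _rate_for(config.loss_prob, branch)
        for tip in current:
            if rng.random() < loss_p:
                truth.losses[branch] = truth.losses.get(branch, 0) + 1
                tip.event = "lost"
                tip.branch = branch
                continue
            if tree.is_leaf(branch):
                tip.event = "extant"
                tip.branch = branch
                tip.alive = True
                truth.surviving[branch] += 1
            else:
                tip.event = "speciation"
                tip.branch = branch
                for child in tree.children[branch]:
                    sub = _SimNode(None, None)
                    tip.children.append(sub)
                    evolve_branch(sub, child)

    # copies entering the root speciate immediately at the root node
    root_nodes: List[_SimNode] = []
    for _ in range(config.root_copies):
        node = _SimNode("speciation", tree.root_label)
        for child in tree.children[tree.root_label]:
            sub = _SimNode(None, None)
            node.children.append(sub)
            evolve_branch(sub, child)
        root_nodes.append(node)
    if len(root_nodes) == 1:
        sim_root = root_nodes[0]
    else:
        # ancient duplications predating the first speciation join the
        # root copies on a synthetic "root" branch
        sim_root = root_nodes[0]
        for other in root_nodes[1:]:
            joined = _SimNode("duplication", "root")
            joined.children = [sim_root, other]
            truth.duplications["root"] = truth.duplications.get("root", 0) + 1
            sim_root = joined

    gene_root = _prune(sim_root, family_id, truth)
    return gene_root, truth


def _prune(sim_root: _SimNode, family_id: str,
           truth: EventTruth) -> Optional[GeneNode]:
    """Drop dead lineages, suppress unary nodes, name the survivors."""
    leaf_counter: Dict[str, int] = {}
    event_counter = [0]

    def convert(node: _SimNode) -> Optional[GeneNode]:
        if not node.children:
            if not node.alive:
                return None
            species = node.branch
            leaf_counter[species] = leaf_counter.get(species, 0) + 1
            name = f"{species}_{family_id}_g{leaf_counter[species]}"
            leaf = GeneNode(name, event="extant", branch=species)
            truth.node_events[name] = (species, "extant")
            return leaf
        kept = [c for c in (convert(child) for child in node.children)
                if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        event_counter[0] += 1
        label = f"{family_id}_e{event_counter[0]}"
        internal = GeneNode(label, kept, event=node.event, branch=node.branch)
        truth.node_events[label] = (node.branch, node.event)
        return internal

    return convert(sim_root)


def simulate_families(config: SimulationConfig,
                      family_prefix: str = "fam"
                      ) -> Tuple[Dict[str, Optional[GeneNode]],
                                 Dict[str, EventTruth]]:
    """Simulate ``config.n_families`` independent families.

    Per-family seeds are spawned from the configured seed so results are
    reproducible and order-independent.
    """
    config.validate()
    seed_seq = np.random.SeedSequence(config.seed)
    child_seeds = seed_seq.spawn(config.n_families)
    trees: Dict[str, Optional[GeneNode]] = {}
    truths: Dict[str, EventTruth] = {}
    for i, child in enumerate(child_seeds, start=1):
        family_id = f"{family_prefix}{i}"
        rng_seed = int(child.generate_state(1)[0] % (2 ** 31))
        tree, truth = simulate_family_evolution(config, family_id,
                                                seed=rng_seed)
        trees[family_id] = tree
        truths[family_id] = truth
    return trees, truths


# ---------------------------------------------------------------------------
# Scaffold layouts
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldLayoutConfig:
    """Synthetic genome layout parameters.

    ``cluster_fraction`` is the fraction of each family's genes laid out in
    tandem chains whose neighbouring gaps are drawn from
    ``within_cluster_gap`` (strictly below 35 kb); all other same-scaffold
    placements are separated by draws from ``background_gap`` (at or above
    35 kb), so truth clusters and detected clusters can be compared exactly.
    """

    n_scaffolds: int = 5
    scaffold_length: int = 3_000_000
    cluster_fraction: float = 0.5
    within_cluster_gap: Tuple[int, int] = (500, 30_000)
    background_gap: Tuple[int, int] = (40_000, 120_000)
    gene_length: Tuple[int, int] = (1_000, 5_000)
    max_chain: int = 4
    seed: Optional[int] = None

    def validate(self, threshold: int = 35_000) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError("need at least one scaffold of positive length")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        lo, hi = self.within_cluster_gap
        if not (0 <= lo <= hi and hi < threshold):
            raise ValueError(
                f"within_cluster_gap must stay strictly below {threshold}")
        blo, bhi = self.background_gap
        if not (threshold <= blo <= bhi):
            raise ValueError(
                f"background_gap must start at or above {threshold}")
        glo, ghi = self.gene_length
        if not (1 <= glo <= ghi):
            raise ValueError("gene_length range invalid")
        if self.max_chain < 2:
            raise ValueError("max_chain must be >= 2")


def synthesize_gene_annotations(
        complement: Mapping[Tuple[str, str], Sequence[str]],
        layout: ScaffoldLayoutConfig,
        seed: Optional[int] = None
) -> Tuple[List[GeneAnnotation], List[frozenset]]:
    """Place genes on synthetic scaffolds with known cluster truth.

    ``complement`` maps (species_tag, family) to the gene ids of that
    family in that species.  Returns the annotations and the true cluster
    partition (frozensets of gene ids, each of size >= 2).

    Raises ``ValueError`` when the configured scaffolds cannot hold the
    requested genes ("scaffold capacity exceeded").
    """
    layout.validate()
    rng = np.random.default_rng(seed if seed is not None else layout.seed)
    annotations: List[GeneAnnotation] = []
    truth: List[frozenset] = []

    # cursors per (species, scaffold index): next free coordinate
    cursors: Dict[Tuple[str, int], int] = {}

    def draw(lohi: Tuple[int, int]) -> int:
        lo, hi = lohi
        return int(rng.integers(lo, hi + 1))

    def place_block(species: str, family: str, gene_ids: Sequence[str],
                    gaps: List[int]) -> List[GeneAnnotation]:
        """Place a run of genes with the given internal gaps on one
        scaffold, after a background gap from whatever precedes it."""
        lengths = [draw(layout.gene_length) for _ in gene_ids]
        block_span = sum(lengths) + sum(gaps)
        for idx in range(layout.n_scaffolds):
            key = (species, idx)
            cursor = cursors.get(key, 1)
            start = cursor if cursor == 1 else cursor + draw(
                layout.background_gap)
            if start + block_span - 1 <= layout.scaffold_length:
                placed = []
                pos = start
                for k, (gid, length) in enumerate(zip(gene_ids, lengths)):
                    ann = GeneAnnotation(
                        gene_id=gid, species_tag=species, family=family,
                        scaffold=f"{species}_scaf{idx + 1}",
                        start=pos, end=pos + length - 1,
                        strand="+" if rng.random() < 0.5 else "-")
                    placed.append(ann)
                    pos = ann.end + 1
                    if k < len(gaps):
                        pos += gaps[k]
                cursors[key] = placed[-1].end + 1
                return placed
        raise ValueError(
            f"scaffold capacity exceeded placing {len(gene_ids)} gene(s) of "
            f"{species}/{family}")

    for (species, family) in sorted(complement):
        gene_ids = list(complement[(species, family)])
        n = len(gene_ids)
        if n == 0:
            continue
        n_clustered = int(round(layout.cluster_fraction * n))
        if n_clustered < 2:
            n_clustered = 0
        order = list(rng.permutation(n))
        to_cluster = [gene_ids[i] for i in order[:n_clustered]]
        singles = [gene_ids[i] for i in order[n_clustered:]]

        while to_cluster:
            size = min(len(to_cluster), layout.max_chain)
            if len(to_cluster) - size == 1:
                size += 1  # never leave a stranded single "clustered" gene
            chain, to_cluster = to_cluster[:size], to_cluster[size:]
            gaps = [draw(layout.within_cluster_gap)
                    for _ in range(len(chain) - 1)]
            placed = place_block(species, family, chain, gaps)
            annotations.extend(placed)
            truth.append(frozenset(a.gene_id for a in placed))
        for gid in singles:
            annotations.extend(place_block(species, family, [gid], []))

    return annotations, truth
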
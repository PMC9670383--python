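"""Genomic cluster detection from gene coordinates.

Two genes belong to a genomic cluster when they are members of the same gene
family, lie on the same scaffold, and are separated by less than 35,000 bp
(strict).  Separation is measured boundary-to-boundary by default - the
number of bases strictly between the two gene intervals, zero when they
overlap - with start-to-start and midpoint metrics available since the
distance convention is a modelling choice.  Clusters are the connected
components (single-linkage chains) of the pairwise proximity graph, so three
genes with adjacent gaps below the threshold form one cluster even when the
outer pair is farther apart.  Genes of other families interleaved in a
cluster neither join nor break it; genes on different scaffolds never
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import stats as _scipy_stats

from .complement import ComplementTable

DEFAULT_MAX_GAP = 35_000


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's location: scaffold interval, 1-based inclusive."""

    gene_id: str
    species_tag: str
    family: str
    scaffold: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def gene_gap(left: GeneAnnotation, right: GeneAnnotation,
             metric: str = "boundary") -> float:
    """Separation between two genes on the same scaffold.

    ``boundary``: bases strictly between the intervals (0 on overlap);
    ``start``: absolute difference of start coordinates;
    ``midpoint``: absolute difference of interval midpoints.
    """
    if metric == "boundary":
        a, b = (left, right) if left.start <= right.start else (right, left)
        return max(0, b.start - a.end - 1)
    if metric == "start":
        return abs(left.start - right.start)
    if metric == "midpoint":
        return abs(left.midpoint - right.midpoint)
    raise ValueError(f"unknown gap metric {metric!r}")


@dataclass(frozen=True)
class Cluster:
    species_tag: str
    family: str
    scaffold: str
    gene_ids: Tuple[str, ...]       # ordered by start coordinate
    span_start: int
    span_end: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClusterSet:
    clusters: List[Cluster]

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def clustered_gene_ids(self) -> set:
        return {g for c in self.clusters for g in c.gene_ids}

    def n_clustered(self) -> int:
        return len(self.clustered_gene_ids())

    def partition(self) -> List[frozenset]:
        return [frozenset(c.gene_ids) for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cluster_id": f"cluster{i + 1}",
                 "species": c.species_tag, "family": c.family,
                 "scaffold": c.scaffold, "n_genes": c.n_genes,
                 "span_start": c.span_start, "span_end": c.span_end,
                 "gene_ids": ",".join(c.gene_ids)}
                for i, c in enumerate(self.clusters)]
        return pd.DataFrame(rows, columns=["cluster_id", "species", "family",
                                           "scaffold", "n_genes",
                                           "span_start", "span_end",
                                           "gene_ids"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def detect_clusters(annotations: Iterable[GeneAnnotation],
                    max_gap: int = DEFAULT_MAX_GAP,
                    metric: str = "boundary",
                    single_linkage: bool = True) -> ClusterSet:
    """Find same-family gene clusters per scaffold.

    With ``single_linkage`` (default) clusters are connected components of
    the graph joining pairs whose gap is strictly below ``max_gap``.  With
    ``single_linkage=False`` a gene extends a cluster only while it stays
    within ``max_gap`` of every current member (complete linkage, greedy
    left-to-right).  Output order is deterministic: species, family,
    scaffold, then leftmost start.
    """
    groups: Dict[Tuple[str, str, str], List[GeneAnnotation]] = {}
    for ann in annotations:
        key = (ann.species_tag, ann.family, ann.scaffold)
        groups.setdefault(key, []).append(ann)

    clusters: List[Cluster] = []
    for (species, family, scaffold) in sorted(groups):
        genes = sorted(groups[(species, family, scaffold)],
                       key=lambda a: (a.start, a.end, a.gene_id))
        n = len(genes)
        if n < 2:
            continue
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        if single_linkage:
            for i in range(n):
                for j in range(i + 1, n):
                    if gene_gap(genes[i], genes[j], metric) < max_gap:
                        parent[find(i)] = find(j)
            components: Dict[int, List[GeneAnnotation]] = {}
            for i in range(n):
                components.setdefault(find(i), []).append(genes[i])
            member_lists = list(components.values())
        else:
            member_lists = []
            current: List[GeneAnnotation] = [genes[0]]
            for gene in genes[1:]:
                if all(gene_gap(gene, m, metric) < max_gap for m in current):
                    current.append(gene)
                else:
                    member_lists.append(current)
                    current = [gene]
            member_lists.append(current)

        for members in member_lists:
            if len(members) < 2:
                continue
            members = sorted(members, key=lambda a: (a.start, a.end,
                                                     a.gene_id))
            clusters.append(Cluster(
                species_tag=species, family=family, scaffold=scaffold,
                gene_ids=tuple(a.gene_id for a in members),
                span_start=min(a.start for a in members),
                span_end=max(a.end for a in members)))

    clusters.sort(key=lambda c: (c.species_tag, c.family, c.scaffold,
                                 c.span_start))
    return ClusterSet(clusters)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    n_points: int


def pearson_correlation(x: Sequence[float], y: Sequence[float]
                        ) -> CorrelationResult:
    """Pearson product-moment correlation of per-unit totals vs clustered
    counts."""
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two points")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("correlation undefined for constant input")
    r = float(_scipy_stats.pearsonr(x, y).statistic)
    return CorrelationResult(pearson_r=r, n_points=len(x))


def summarize_clustering(cluster_set: ClusterSet,
                         complement: ComplementTable,
                         family_superfamily: Optional[Dict[str, str]] = None,
                         decimals: int = 1) -> pd.DataFrame:
    """Per species and family: total genes, clustered genes, percent.

    Totals come from the complement table (the curated gene counts), so a
    family appearing in clusters but absent from the complement is an error.
    ``family_superfamily`` maps cluster family labels to complement
    superfamilies when the two vocabularies differ; by default the cluster
    family label is looked up as a complement group under any superfamily.
    """
    from .stats import compute_proportion

    clustered: Dict[Tuple[str, str], int] = {}
    for cluster in cluster_set:
        key = (cluster.species_tag, cluster.family)
        clustered[key] = clustered.get(key, 0) + cluster.n_genes

    comp = complement.frame
    rows = []
    for (species, family), n_clust in sorted(clustered.items()):
        if family_superfamily is not None:
            superfamily = family_superfamily.get(family)
            sel = comp[(comp["species"] == species)
                       & (comp["superfamily"] == superfamily)
                       & (comp["group"] == family)]
        else:
            sel = comp[(comp["species"] == species)
                       & (comp["group"] == family)]
        if sel.empty:
            raise KeyError(f"family {family!r} of species {species!r} has "
                           "clusters but no complement entry")
        n_total = int(sel["count"].sum())
        rows.append({"species": species, "family": family,
                     "n_total": n_total, "n_clustered": n_clust,
                     "percent_clustered":
                         compute_proportion(n_clust, n_total, decimals)})
    # species-level rows over all families in the complement
    for species in complement.species:
        n_total = complement.grand_total(species)
        n_clust = sum(v for (sp, _), v in clustered.items() if sp == species)
        if n_total == 0:
            continue
        rows.append({"species": species, "family": "ALL",
                     "n_total": n_total, "n_clustered": n_clust,
                     "percent_clustered":
                         compute_proportion(n_clust, n_total, decimals)})
    return pd.DataFrame(rows, columns=["species", "family", "n_total",
                                       "n_clustered", "percent_clustered"])
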
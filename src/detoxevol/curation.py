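"""Complement curation: the filtering rules that turn raw homology-search
output into a curated gene complement.

The similarity searches themselves (BLASTp/tBLASTn, InterProScan) are
published tools whose tabular outputs are this module's inputs.  The rules
implemented here are the computational part of the curation:

* discard proteins shorter than 100 amino acids (strictly shorter; a
  100-residue protein is kept),
* keep only the longest isoform of each gene (ties broken by smallest
  protein id, for determinism),
* retain similarity hits with E-value strictly below 1e-4,
* assign superfamily membership from PFAM domain content
  (PF00067 -> CYP, PF00135 -> CCE, PF02798/PF00043 -> GST) and discard
  records matching none; records matching more than one superfamily are
  flagged as conflicts rather than silently assigned.

Every filter returns the retained records together with a discard log, so
retained + discarded always equals the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd

from .complement import ComplementTable


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str
    species_tag: str
    length: int
    sequence: Optional[str] = None
    superfamily: Optional[str] = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(
                f"protein {self.protein_id!r}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"protein {self.protein_id!r}: length field "
                f"({self.length}) != sequence length ({len(self.sequence)})")


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    target_id: str
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(
                f"hit {self.query_id!r}->{self.target_id!r}: "
                "negative E-value")


@dataclass
class CurationConfig:
    """Curation thresholds; defaults are the study's published settings."""

    min_protein_length: int = 100
    evalue_threshold: float = 1e-4
    superfamily_domains: Dict[str, FrozenSet[str]] = field(
        default_factory=lambda: {
            "CYP": frozenset({"PF00067"}),
            "CCE": frozenset({"PF00135"}),
            "GST": frozenset({"PF02798", "PF00043"}),
        })


@dataclass(frozen=True)
class DiscardEntry:
    record_id: str
    reason: str


DiscardLog = List[DiscardEntry]


def filter_by_length(records: Iterable[ProteinRecord],
                     min_length: int = 100
                     ) -> Tuple[List[ProteinRecord], DiscardLog]:
    """Keep proteins of at least ``min_length`` residues.

    "Shorter than" is read strictly: a protein of exactly ``min_length``
    residues is retained.
    """
    kept: List[ProteinRecord] = []
    log: DiscardLog = []
    for rec in records:
        if rec.length >= min_length:
            kept.append(rec)
        else:
            log.append(DiscardEntry(rec.protein_id,
                                    f"shorter_than_{min_length}aa"))
    return kept, log


def select_longest_isoform(records: Iterable[ProteinRecord]
                           ) -> Tuple[List[ProteinRecord], DiscardLog]:
    """One record per gene: the longest isoform, smallest protein_id on ties."""
    by_gene: Dict[str, List[ProteinRecord]] = {}
    order: List[str] = []
    for rec in records:
        if rec.gene_id not in by_gene:
            order.append(rec.gene_id)
        by_gene.setdefault(rec.gene_id, []).append(rec)
    kept: List[ProteinRecord] = []
    log: DiscardLog = []
    for gene in order:
        isoforms = sorted(by_gene[gene],
                          key=lambda r: (-r.length, r.protein_id))
        kept.append(isoforms[0])
        log.extend(DiscardEntry(r.protein_id, "shorter_isoform")
                   for r in isoforms[1:])
    return kept, log


def filter_hits_by_evalue(hits: Iterable[HitRecord],
                          threshold: float = 1e-4) -> List[HitRecord]:
    """Retain hits with E-value strictly below the threshold."""
    if threshold <= 0:
        raise ValueError("E-value threshold must be positive")
    return [h for h in hits if h.evalue < threshold]


def confirm_family_membership(records: Iterable[ProteinRecord],
                              domain_annotations: Mapping[str, Set[str]],
                              config: Optional[CurationConfig] = None
                              ) -> Tuple[List[ProteinRecord], DiscardLog,
                                         List[str]]:
    """Label each protein with its superfamily from PFAM domain content.

    Returns (labelled records, discard log, conflict ids).  Records whose
    domains match no configured superfamily are discarded; records matching
    several are kept with the flag list rather than silently assigned, and
    carry the lexicographically first matching superfamily label.
    Records without any domain annotation are discarded with an explicit
    reason.
    """
    config = config or CurationConfig()
    kept: List[ProteinRecord] = []
    log: DiscardLog = []
    conflicts: List[str] = []
    for rec in records:
        if rec.protein_id not in domain_annotations:
            log.append(DiscardEntry(rec.protein_id, "no_domain_annotation"))
            continue
        domains = set(domain_annotations[rec.protein_id])
        matches = sorted(fam for fam, accs in config.superfamily_domains.items()
                         if domains & accs)
        if not matches:
            log.append(DiscardEntry(rec.protein_id, "no_target_superfamily"))
            continue
        if len(matches) > 1:
            conflicts.append(rec.protein_id)
        kept.append(ProteinRecord(rec.protein_id, rec.gene_id,
                                  rec.species_tag, rec.length, rec.sequence,
                                  superfamily=matches[0]))
    return kept, log, conflicts


def build_complement_table(records: Iterable[ProteinRecord],
                           group_assignments: Mapping[str, str],
                           known_species: Optional[Iterable[str]] = None
                           ) -> ComplementTable:
    """Count labelled records into a species x superfamily x group table.

    ``group_assignments`` maps protein_id (or gene_id) to a clan/class label
    within the record's superfamily.
    """
    known = set(known_species) if known_species is not None else None
    genes = []
    for rec in records:
        if rec.superfamily is None:
            raise ValueError(f"record {rec.protein_id!r} has no superfamily "
                             "label; run confirm_family_membership first")
        if known is not None and rec.species_tag not in known:
            raise ValueError(f"record {rec.protein_id!r} has unknown species "
                             f"tag {rec.species_tag!r}")
        group = group_assignments.get(rec.protein_id,
                                      group_assignments.get(rec.gene_id))
        if group is None:
            raise KeyError(f"no clan/class assignment for {rec.protein_id!r}")
        genes.append((rec.species_tag, rec.superfamily, group))
    return ComplementTable.from_labeled_genes(genes)


# ---------------------------------------------------------------------------
# TSV input readers
# ---------------------------------------------------------------------------

def read_protein_table(path) -> List[ProteinRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [ProteinRecord(str(r.protein_id), str(r.gene_id), str(r.species),
                          int(r.length))
            for r in frame.itertuples(index=False)]


def read_hit_table(path) -> List[HitRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [HitRecord(str(r.query_id), str(r.target_id), float(r.evalue))
            for r in frame.itertuples(index=False)]


def read_domain_table(path) -> Dict[str, Set[str]]:
    frame = pd.read_csv(path, sep="\t")
    out: Dict[str, Set[str]] = {}
    for r in frame.itertuples(index=False):
        out.setdefault(str(r.protein_id), set()).add(str(r.domain_accession))
    return out


def write_discard_log(log: DiscardLog, path) -> None:
    pd.DataFrame([(e.record_id, e.reason) for e in log],
                 columns=["record_id", "reason"]).to_csv(path, sep="\t",
                                                         index=False)
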
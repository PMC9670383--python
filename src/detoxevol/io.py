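"""Reading and writing the pipeline's standard-format files.

Bundles tie together one newick file per gene family, per-species GFF3
annotation files (``gene`` features, 1-based inclusive coordinates, ``ID=``
attributes), an optional protein FASTA, and a gene -> species/family map as
TSV.  Writing then re-reading a bundle reproduces the in-memory objects
exactly; the round trip is part of the test suite.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clusters import GeneAnnotation
from .trees import GeneNode

GFF_HEADER = "##gff-version 3"


class GFFError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path, annotations: Sequence[GeneAnnotation],
               source: str = "detoxevol") -> None:
    lines = [GFF_HEADER]
    for ann in sorted(annotations, key=lambda a: (a.scaffold, a.start,
                                                  a.gene_id)):
        strand = ann.strand if ann.strand in "+-" else "."
        lines.append("\t".join([
            ann.scaffold, source, "gene", str(ann.start), str(ann.end),
            ".", strand, ".", f"ID={ann.gene_id}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gff_attributes(field: str) -> Dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff_genes(path) -> List[Tuple[str, str, int, int, str]]:
    """All ``gene`` rows of a GFF3 file as (id, scaffold, start, end, strand).

    Malformed rows raise with the offending line number.
    """
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFError(f"{path}: line {lineno}: expected 9 "
                               f"tab-separated fields, got {len(fields)}")
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GFFError(f"{path}: line {lineno}: non-integer "
                               "coordinates") from exc
            attrs = _parse_gff_attributes(fields[8])
            if "ID" not in attrs:
                raise GFFError(f"{path}: line {lineno}: gene row without "
                               "an ID attribute")
            rows.append((attrs["ID"], fields[0], start, end, fields[6]))
    return rows


def read_gff_subset(gff_path, gene_ids: Sequence[str],
                    family_map: Mapping[str, Tuple[str, str]]
                    ) -> Tuple[List[GeneAnnotation], List[str]]:
    """Annotations for the requested gene ids found in a GFF3 file.

    ``family_map`` maps gene_id -> (species_tag, family).  Requested ids
    absent from the file are returned in the missing list, not raised.
    """
    wanted: Set[str] = set(gene_ids)
    for gid in wanted:
        if gid not in family_map:
            raise KeyError(f"gene {gid!r} missing from the family map")
    found: List[GeneAnnotation] = []
    seen: Set[str] = set()
    for gid, scaffold, start, end, strand in read_gff_genes(gff_path):
        if gid not in wanted or gid in seen:
            continue
        species, family = family_map[gid]
        found.append(GeneAnnotation(gene_id=gid, species_tag=species,
                                    family=family, scaffold=scaffold,
                                    start=start, end=end,
                                    strand=strand if strand in "+-" else "?"))
        seen.add(gid)
    missing = sorted(wanted - seen)
    return found, missing


# ---------------------------------------------------------------------------
# Family map and FASTA
# ---------------------------------------------------------------------------

def write_family_map(path, family_map: Mapping[str, Tuple[str, str]]) -> None:
    frame = pd.DataFrame(
        [(gid, sp, fam) for gid, (sp, fam) in sorted(family_map.items())],
        columns=["gene_id", "species", "family"])
    frame.to_csv(path, sep="\t", index=False)


def read_family_map(path) -> Dict[str, Tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t")
    return {str(r.gene_id): (str(r.species), str(r.family))
            for r in frame.itertuples(index=False)}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def write_bundle(out_dir,
                 trees: Mapping[str, Optional[GeneNode]],
                 annotations: Sequence[GeneAnnotation],
                 family_map: Mapping[str, Tuple[str, str]],
                 sequences: Optional[Mapping[str, str]] = None) -> Path:
    """Write a consistent bundle of trees, annotations, map and sequences.

    Empty families (extinct in simulation) get an empty newick file so the
    family list round-trips.  Raises on gene-id collisions or annotations
    missing from the family map.
    """
    out = Path(out_dir)
    seen: Set[str] = set()
    for ann in annotations:
        if ann.gene_id in seen:
            raise ValueError(f"duplicate gene id {ann.gene_id!r}")
        seen.add(ann.gene_id)
        if ann.gene_id not in family_map:
            raise ValueError(f"annotation {ann.gene_id!r} missing from the "
                             "family map")
    (out / "trees").mkdir(parents=True, exist_ok=True)
    for family, tree in sorted(trees.items()):
        text = tree.to_newick() if tree is not None else ""
        (out / "trees" / f"{family}.nwk").write_text(text + "\n")
    by_species: Dict[str, List[GeneAnnotation]] = {}
    for ann in annotations:
        by_species.setdefault(ann.species_tag, []).append(ann)
    for species in sorted(by_species):
        write_gff3(out / f"{species}.gff3", by_species[species])
    write_family_map(out / "gene_families.tsv", family_map)
    if sequences is not None:
        write_fasta(out / "proteins.fasta", sequences)
    return out


def read_bundle(bundle_dir) -> Tuple[Dict[str, Optional[GeneNode]],
                                     List[GeneAnnotation],
                                     Dict[str, Tuple[str, str]],
                                     Optional[Dict[str, str]]]:
    """Inverse of :func:`write_bundle`."""
    bundle = Path(bundle_dir)
    trees: Dict[str, Optional[GeneNode]] = {}
    for path in sorted((bundle / "trees").glob("*.nwk")):
        text = path.read_text().strip()
        trees[path.stem] = GeneNode.from_newick(text) if text else None
    family_map = read_family_map(bundle / "gene_families.tsv")
    annotations: List[GeneAnnotation] = []
    for gff in sorted(bundle.glob("*.gff3")):
        for gid, scaffold, start, end, strand in read_gff_genes(gff):
            species, family = family_map[gid]
            annotations.append(GeneAnnotation(
                gene_id=gid, species_tag=species, family=family,
                scaffold=scaffold, start=start, end=end,
                strand=strand if strand in "+-" else "?"))
    fasta = bundle / "proteins.fasta"
    sequences = read_fasta(fasta) if fasta.exists() else None
    return trees, annotations, family_map, sequences
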
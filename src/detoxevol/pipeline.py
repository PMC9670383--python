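"""End-to-end orchestration: from config to report bundle.

Three modes share one reporting backend:

* ``simulate`` - generate gene families with the birth-death simulator, lay
  them on synthetic scaffolds, then run reconciliation, cluster detection
  and enrichment on the synthetic data (ground truth is written alongside);
* ``analyze`` - run the same analysis on user-supplied gene trees, GFF
  files and a gene -> family map;
* ``fixtures`` - reproduce the packaged complement and event-matrix tables
  and the summary statistics derived from them.

All randomness flows from the single configured seed, and no output embeds
timestamps, so two runs with the same config are byte-identical.  Any stage
failure removes the partially written outputs and re-raises with the stage
name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import curation as cur
from .clusters import (DEFAULT_MAX_GAP, detect_clusters, pearson_correlation,
                       summarize_clustering)
from .complement import ComplementTable
from .fixtures import (CYP_EVENT_GROUPS, fixture_discrepancies,
                       load_study_fixture)
from .io import read_bundle, read_family_map, read_gff_subset, write_bundle
from .reconcile import (EventMatrix, aggregate_event_matrix,
                        annotate_species_tree_with_events, lca_reconcile)
from .simulate import (ScaffoldLayoutConfig, SimulationConfig,
                       simulate_families, synthesize_gene_annotations)
from .stats import (SCHEME_VS_OTHER_SUPERFAMILIES, SCHEME_WITHIN_SUPERFAMILY,
                    adjust_p, build_contingency, fold_ratio,
                    pearson_chi_square)
from .trees import DEFAULT_SPECIES_TREE_NEWICK, GeneNode, SpeciesTree

#: Superfamily each event-matrix group belongs to.
GROUP_SUPERFAMILY = {"MIT": "CYP", "CYP2": "CYP", "CYP3": "CYP",
                     "CYP4": "CYP", "GST": "GST", "CCE": "CCE"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    mode: str = "simulate"                      # simulate | analyze | fixtures
    out_dir: str = "detoxevol_out"
    seed: int = 0
    # thresholds (single source of truth for the published defaults)
    max_gap: int = DEFAULT_MAX_GAP
    min_length: int = 100
    evalue: float = 1e-4
    correction: str = "BH"
    species_tree: str = DEFAULT_SPECIES_TREE_NEWICK
    # simulate mode
    dup_rate: float = 0.3
    loss_prob: float = 0.1
    n_families: int = 30
    root_copies: int = 1
    cluster_fraction: float = 0.5
    # analyze mode inputs
    gene_trees_dir: Optional[str] = None
    gff_paths: Dict[str, str] = field(default_factory=dict)
    family_map_path: Optional[str] = None
    protein_table_path: Optional[str] = None
    domain_table_path: Optional[str] = None
    hit_table_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: PipelineConfig) -> List[str]:
    """Empty list iff the config is runnable; each problem names its field."""
    problems: List[str] = []
    if config.mode not in ("simulate", "analyze", "fixtures"):
        problems.append(f"mode: unknown mode {config.mode!r}")
    if config.max_gap <= 0:
        problems.append("max_gap: must be positive")
    if config.min_length <= 0:
        problems.append("min_length: must be positive")
    if config.evalue <= 0:
        problems.append("evalue: must be positive")
    try:
        SpeciesTree(config.species_tree)
    except Exception as exc:
        problems.append(f"species_tree: {exc}")
    if config.mode == "simulate":
        try:
            SimulationConfig(species_tree=config.species_tree,
                             dup_rate=config.dup_rate,
                             loss_prob=config.loss_prob,
                             n_families=config.n_families,
                             root_copies=config.root_copies).validate()
        except Exception as exc:
            problems.append(f"simulation: {exc}")
        if not 0 <= config.cluster_fraction <= 1:
            problems.append("cluster_fraction: must lie in [0, 1]")
    if config.mode == "analyze":
        if not config.gene_trees_dir:
            problems.append("gene_trees_dir: required in analyze mode")
        elif not Path(config.gene_trees_dir).is_dir():
            problems.append(f"gene_trees_dir: {config.gene_trees_dir} "
                            "does not exist")
        if not config.family_map_path:
            problems.append("family_map_path: required in analyze mode")
        elif not Path(config.family_map_path).is_file():
            problems.append(f"family_map_path: {config.family_map_path} "
                            "does not exist")
        for species, path in sorted(config.gff_paths.items()):
            if not Path(path).is_file():
                problems.append(f"gff_paths[{species}]: {path} "
                                "does not exist")
    return problems


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the configured mode and write the report bundle.

    Returns the machine-readable summary that is also written to
    ``summary.json``.
    """
    problems = validate_config(config)
    if problems:
        raise PipelineError("stage config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    log_lines: List[str] = []

    def log(message: str) -> None:
        log_lines.append(message)

    def register(path: Path) -> Path:
        written.append(path)
        return path

    try:
        if config.mode == "fixtures":
            summary = _run_fixtures(config, out, register, log)
        elif config.mode == "simulate":
            summary = _run_simulate(config, out, register, log)
        else:
            summary = _run_analyze(config, out, register, log)
        summary_path = register(out / "summary.json")
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True)
                                + "\n")
        register(out / "run.log").write_text("\n".join(log_lines) + "\n")
        return summary
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:
        _cleanup(written)
        raise PipelineError(f"stage {getattr(exc, '_stage', 'unknown')}: "
                            f"{exc}") from exc


def _cleanup(paths: List[Path]) -> None:
    for path in paths:
        try:
            if path.is_file():
                path.unlink()
        except OSError:
            pass


def _stage(name: str):
    """Decorator-free stage wrapper: tag exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not hasattr(exc, "_stage"):
                try:
                    exc._stage = name
                except Exception:
                    pass
            return False
    return _Ctx()


# ---------------------------------------------------------------------------
# Shared reporting backend
# ---------------------------------------------------------------------------

def _report_complement(complement: ComplementTable, out, register, log
                       ) -> Dict[str, object]:
    complement.to_tsv(register(out / "complement.tsv"))
    totals = complement.totals_frame()
    totals.to_csv(register(out / "complement_totals.tsv"), sep="\t")
    log(f"complement: {len(complement.frame)} count cells, "
        f"{len(complement.species)} species")
    return {sp: {col: int(totals.loc[sp, col]) for col in totals.columns}
            for sp in totals.index}


def _report_events(matrix: EventMatrix, species_tree: SpeciesTree,
                   out, register, log) -> Dict[str, object]:
    matrix.to_tsv(register(out / "event_matrix.tsv"))
    branch_frame, annotated = annotate_species_tree_with_events(
        matrix, species_tree)
    branch_frame.to_csv(register(out / "branch_events.tsv"), sep="\t")
    register(out / "species_tree_annotated.nwk").write_text(annotated + "\n")
    log(f"events: {matrix.total_events()} total "
        f"({matrix.event_total('Duplications')} duplications, "
        f"{matrix.event_total('Losses')} losses)")
    return {
        "total_events": matrix.total_events(),
        "duplications": matrix.event_total("Duplications"),
        "losses": matrix.event_total("Losses"),
        "per_branch": {b: [matrix.get(b, "Duplications"),
                           matrix.get(b, "Losses")]
                       for b in matrix.branches},
    }


def _report_enrichment(complement: ComplementTable, correction: str,
                       out, register, log) -> int:
    import pandas as pd

    rows = []
    species = sorted(complement.species)
    superfamilies = sorted(set(complement.frame["superfamily"]))
    for a, b in combinations(species, 2):
        for fam in superfamilies:
            table = build_contingency(SCHEME_VS_OTHER_SUPERFAMILIES, a, b,
                                      complement, superfamily=fam)
            _append_test(rows, table, fam, a, b)
            for group in sorted(set(
                    complement.frame.loc[
                        complement.frame["superfamily"] == fam, "group"])):
                try:
                    table = build_contingency(
                        SCHEME_WITHIN_SUPERFAMILY, a, b, complement,
                        superfamily=fam, group=group)
                except ValueError:
                    continue  # zero margins (group absent in both species)
                _append_test(rows, table, f"{fam}:{group}", a, b)
    frame = pd.DataFrame(rows, columns=["scheme", "species_a", "species_b",
                                        "group", "a", "b", "c", "d", "chi2",
                                        "p", "low_expected"])
    if len(frame):
        frame["p_adj"] = adjust_p(frame["p"].to_numpy(), method=correction)
    else:
        frame["p_adj"] = []
    frame.to_csv(register(out / "enrichment.tsv"), sep="\t", index=False,
                 float_format="%.6g")
    log(f"enrichment: {len(frame)} chi-square tests "
        f"({correction}-adjusted)")
    return len(frame)


def _append_test(rows: list, table, group: str, a: str, b: str) -> None:
    try:
        result = pearson_chi_square(table)
    except ValueError:
        return  # zero margin: test undefined for this pair
    rows.append({"scheme": table.scheme, "species_a": a, "species_b": b,
                 "group": group, "a": table.a, "b": table.b, "c": table.c,
                 "d": table.d, "chi2": result.chi2, "p": result.p_value,
                 "low_expected": result.low_expected_flag})


def _report_clusters(annotations, complement_by_family, config, out,
                     register, log) -> Dict[str, object]:
    clusters = detect_clusters(annotations, max_gap=config.max_gap)
    clusters.to_tsv(register(out / "clusters.tsv"))
    stats = summarize_clustering(clusters, complement_by_family, decimals=2)
    stats.to_csv(register(out / "cluster_stats.tsv"), sep="\t", index=False)
    log(f"clusters: {len(clusters)} clusters covering "
        f"{clusters.n_clustered()} genes (max_gap={config.max_gap})")
    species_rows = stats[stats["family"] == "ALL"]
    summary = {"n_clusters": len(clusters),
               "n_clustered_genes": clusters.n_clustered()}
    if len(species_rows) >= 2:
        x = species_rows["n_total"].tolist()
        y = species_rows["n_clustered"].tolist()
        if len(set(x)) > 1 and len(set(y)) > 1:
            corr = pearson_correlation(x, y)
            summary["pearson_r_total_vs_clustered"] = round(
                corr.pearson_r, 4)
    return summary


# ---------------------------------------------------------------------------
# Modes
# ---------------------------------------------------------------------------

def _run_fixtures(config: PipelineConfig, out: Path, register, log
                  ) -> Dict[str, object]:
    with _stage("fixtures"):
        complement = load_study_fixture("table1")
        matrix = load_study_fixture("table2")
        species_tree = SpeciesTree(config.species_tree)
        summary: Dict[str, object] = {"mode": "fixtures"}
        summary["complement_totals"] = _report_complement(
            complement, out, register, log)
        events = _report_events(matrix, species_tree, out, register, log)
        events["cyp_total_events"] = matrix.total_events(CYP_EVENT_GROUPS)
        events["cce_total_events"] = matrix.total_events(["CCE"])
        ratio = fold_ratio(matrix, "CYP3")
        events["cyp3_fold_ratio"] = ratio.truncated
        summary["events"] = events
        for problem in fixture_discrepancies():
            log(f"fixture discrepancy: {problem}")
        _report_enrichment(complement, config.correction, out, register, log)
        return summary


def _run_simulate(config: PipelineConfig, out: Path, register, log
                  ) -> Dict[str, object]:
    from .reconcile import DEFAULT_FAMILY_GROUPS

    with _stage("simulate"):
        sim = SimulationConfig(species_tree=config.species_tree,
                               dup_rate=config.dup_rate,
                               loss_prob=config.loss_prob,
                               n_families=config.n_families,
                               root_copies=config.root_copies,
                               seed=config.seed)
        trees, truths = simulate_families(sim)
        extinct = sum(1 for t in trees.values() if t is None)
        log(f"simulate: {len(trees)} families, {extinct} extinct "
            f"(dup_rate={config.dup_rate}, loss_prob={config.loss_prob})")
        grouping = {fam: DEFAULT_FAMILY_GROUPS[i % len(DEFAULT_FAMILY_GROUPS)]
                    for i, fam in enumerate(sorted(trees))}

    with _stage("complement"):
        counts: Dict[Tuple[str, str, str], int] = {}
        family_genes: Dict[Tuple[str, str], List[str]] = {}
        family_map: Dict[str, Tuple[str, str]] = {}
        for fam in sorted(trees):
            tree = trees[fam]
            if tree is None:
                continue
            for leaf in tree.leaf_names():
                species = leaf.split("_", 1)[0]
                group = grouping[fam]
                key = (species, GROUP_SUPERFAMILY[group], group)
                counts[key] = counts.get(key, 0) + 1
                family_genes.setdefault((species, fam), []).append(leaf)
                family_map[leaf] = (species, fam)
        complement = ComplementTable.from_counts(
            (sp, sf, gr, n) for (sp, sf, gr), n in sorted(counts.items()))
        by_family = ComplementTable.from_counts(
            (sp, GROUP_SUPERFAMILY[grouping[fam]], fam, len(genes))
            for (sp, fam), genes in sorted(family_genes.items()))

    with _stage("reconcile"):
        species_tree = SpeciesTree(config.species_tree)
        results = {fam: lca_reconcile(tree, species_tree)
                   for fam, tree in trees.items() if tree is not None}
        matrix = aggregate_event_matrix(results, grouping, species_tree,
                                        groups=DEFAULT_FAMILY_GROUPS)
        true_events = sum(t.n_events for t in truths.values())
        log(f"reconcile: inferred cost "
            f"{sum(r.cost for r in results.values())} over "
            f"{len(results)} families (true event count {true_events})")

    with _stage("layout"):
        layout = ScaffoldLayoutConfig(cluster_fraction=config.cluster_fraction,
                                      seed=config.seed)
        annotations, truth_clusters = synthesize_gene_annotations(
            family_genes, layout, seed=config.seed)
        log(f"layout: {len(annotations)} genes placed, "
            f"{len(truth_clusters)} true clusters")

    with _stage("bundle"):
        bundle_dir = out / "bundle"
        write_bundle(bundle_dir, trees, annotations, family_map)
        for path in sorted(bundle_dir.rglob("*")):
            if path.is_file():
                register(path)
        truth_path = register(out / "truth.json")
        truth_payload = {
            "clusters": sorted(sorted(c) for c in truth_clusters),
            "events": {fam: {"duplications": truths[fam].duplications,
                             "losses": truths[fam].losses}
                       for fam in sorted(truths)},
        }
        truth_path.write_text(json.dumps(truth_payload, indent=2,
                                         sort_keys=True) + "\n")

    summary: Dict[str, object] = {"mode": "simulate",
                                  "seed": config.seed,
                                  "n_families": config.n_families,
                                  "n_extinct": extinct}
    summary["complement_totals"] = _report_complement(complement, out,
                                                      register, log)
    summary["events"] = _report_events(matrix, species_tree, out, register,
                                       log)
    summary["true_total_events"] = true_events
    summary["clusters"] = _report_clusters(annotations, by_family, config,
                                           out, register, log)
    _report_enrichment(complement, config.correction, out, register, log)
    return summary


def _run_analyze(config: PipelineConfig, out: Path, register, log
                 ) -> Dict[str, object]:
    with _stage("inputs"):
        species_tree = SpeciesTree(config.species_tree)
        family_map = read_family_map(config.family_map_path)
        trees: Dict[str, Optional[GeneNode]] = {}
        for path in sorted(Path(config.gene_trees_dir).glob("*.nwk")):
            text = path.read_text().strip()
            trees[path.stem] = GeneNode.from_newick(text) if text else None
        if not trees:
            raise ValueError(f"no .nwk files in {config.gene_trees_dir}")
        log(f"inputs: {len(trees)} gene trees, "
            f"{len(family_map)} mapped genes")

    with _stage("curation"):
        if config.protein_table_path:
            records = cur.read_protein_table(config.protein_table_path)
            records, short_log = cur.filter_by_length(records,
                                                      config.min_length)
            records, iso_log = cur.select_longest_isoform(records)
            log(f"curation: {len(short_log)} too-short, "
                f"{len(iso_log)} shorter isoforms discarded, "
                f"{len(records)} proteins kept")
            if config.domain_table_path:
                domains = cur.read_domain_table(config.domain_table_path)
                records, dom_log, conflicts = cur.confirm_family_membership(
                    records, domains)
                log(f"curation: {len(dom_log)} without target domains "
                    f"discarded, {len(conflicts)} conflicts flagged")
            cur.write_discard_log(short_log + iso_log,
                                  register(out / "discards.tsv"))

    with _stage("complement"):
        counts: Dict[Tuple[str, str, str], int] = {}
        family_genes: Dict[Tuple[str, str], List[str]] = {}
        for gid, (species, fam) in sorted(family_map.items()):
            counts[(species, "detox", fam)] = counts.get(
                (species, "detox", fam), 0) + 1
            family_genes.setdefault((species, fam), []).append(gid)
        by_family = ComplementTable.from_counts(
            (sp, sf, gr, n) for (sp, sf, gr), n in sorted(counts.items()))

    with _stage("reconcile"):
        results = {fam: lca_reconcile(tree, species_tree)
                   for fam, tree in trees.items() if tree is not None}
        grouping = {fam: fam for fam in results}
        matrix = aggregate_event_matrix(results, grouping, species_tree)

    with _stage("annotations"):
        annotations = []
        missing_all: List[str] = []
        for species, gff in sorted(config.gff_paths.items()):
            ids = [g for g, (sp, _) in family_map.items() if sp == species]
            found, missing = read_gff_subset(gff, ids, family_map)
            annotations.extend(found)
            missing_all.extend(missing)
        if missing_all:
            log(f"annotations: {len(missing_all)} requested ids not found")

    summary: Dict[str, object] = {"mode": "analyze", "seed": config.seed}
    summary["complement_totals"] = _report_complement(by_family, out,
                                                      register, log)
    summary["events"] = _report_events(matrix, species_tree, out, register,
                                       log)
    if annotations:
        summary["clusters"] = _report_clusters(annotations, by_family,
                                               config, out, register, log)
    _report_enrichment(by_family, config.correction, out, register, log)
    return summary
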
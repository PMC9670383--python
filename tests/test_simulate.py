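import math

import numpy as np
import pytest

from detoxevol.simulate import (ScaffoldLayoutConfig, SimulationConfig,
                                simulate_families, simulate_family_evolution,
                                synthesize_gene_annotations)
from detoxevol.clusters import detect_clusters
from detoxevol.reconcile import lca_reconcile
from oracles import brute_force_clusters


class TestBirthDeathSimulation:
    def test_no_event_identity(self, species_tree):
        """With zero rates the gene tree is congruent with the species tree:
        one leaf per species and an all-zero truth log."""
        config = SimulationConfig(dup_rate=0.0, loss_prob=0.0)
        tree, truth = simulate_family_evolution(config, "fam", seed=11)
        assert sorted(tree.leaf_names()) == sorted(
            f"{sp}_fam_g1" for sp in species_tree.leaf_labels)
        assert truth.duplications == {} and truth.losses == {}
        assert lca_reconcile(tree, species_tree).cost == 0

    def test_forced_single_duplication(self, species_tree):
        config = SimulationConfig(dup_rate=0.0, loss_prob=0.0,
                                  fixed_duplications={"Hhal": 1})
        tree, truth = simulate_family_evolution(config, "fam", seed=5)
        counts = {}
        for leaf in tree.leaf_names():
            counts[leaf.split("_")[0]] = counts.get(leaf.split("_")[0], 0) + 1
        assert counts == {"Hhal": 2, "Clec": 1, "Rpro": 1, "Nvir": 1,
                          "Nlug": 1}
        assert truth.duplications == {"Hhal": 1}
        assert truth.losses == {}

    def test_leaf_count_conservation(self):
        """Gene-tree leaves per species equal the surviving-lineage counts
        of the truth log, including extinct families."""
        config = SimulationConfig(dup_rate=0.5, loss_prob=0.4, n_families=40,
                                  seed=23)
        trees, truths = simulate_families(config)
        for fam, tree in trees.items():
            truth = truths[fam]
            if tree is None:
                assert truth.extinct
                continue
            observed = {}
            for leaf in tree.leaf_names():
                sp = leaf.split("_")[0]
                observed[sp] = observed.get(sp, 0) + 1
            expected = {sp: n for sp, n in truth.surviving.items() if n > 0}
            assert observed == expected

    def test_extinct_family_keeps_truth(self):
        config = SimulationConfig(dup_rate=0.0, loss_prob=1.0)
        tree, truth = simulate_family_evolution(config, "doomed", seed=1)
        assert tree is None
        assert truth.extinct
        assert sum(truth.losses.values()) > 0

    def test_mean_copy_number_matches_closed_form(self, species_tree):
        """Monte-Carlo mean leaf count per species vs the closed-form
        expectation root_copies * prod (1+dup_rate)(1-loss_prob) over the
        root-to-leaf path, within 3 standard errors at 1,000 replicates."""
        dup, loss, reps = 0.3, 0.1, 1000
        config = SimulationConfig(dup_rate=dup, loss_prob=loss,
                                  n_families=reps, seed=2024)
        _, truths = simulate_families(config)
        for sp in species_tree.leaf_labels:
            n_branches = species_tree.distance_down(species_tree.root_label,
                                                    sp)
            expected = ((1 + dup) * (1 - loss)) ** n_branches
            samples = np.array([t.surviving.get(sp, 0)
                                for t in truths.values()])
            se = samples.std(ddof=1) / math.sqrt(reps)
            assert abs(samples.mean() - expected) < 3 * se + 1e-12

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dup_rate=-0.1).validate()
        with pytest.raises(ValueError):
            SimulationConfig(loss_prob=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(species_tree="((A,B;").validate()


class TestScaffoldLayout:
    @staticmethod
    def complement(n_per_family):
        return {(sp, fam): [f"{sp}_{fam}_g{i}" for i in range(1, n + 1)]
                for (sp, fam), n in n_per_family.items()}

    def test_zero_cluster_fraction_has_no_truth_clusters(self):
        comp = self.complement({("Hhal", "famA"): 6, ("Rpro", "famB"): 5})
        layout = ScaffoldLayoutConfig(cluster_fraction=0.0)
        annotations, truth = synthesize_gene_annotations(comp, layout, seed=1)
        assert truth == []
        assert len(annotations) == 11
        assert len(detect_clusters(annotations)) == 0

    def test_full_clustering_single_chain(self):
        comp = self.complement({("Hhal", "famA"): 4})
        layout = ScaffoldLayoutConfig(n_scaffolds=1, cluster_fraction=1.0,
                                      max_chain=4)
        annotations, truth = synthesize_gene_annotations(comp, layout, seed=2)
        assert len(truth) == 1 and len(truth[0]) == 4
        anns = sorted(annotations, key=lambda a: a.start)
        for left, right in zip(anns, anns[1:]):
            assert right.start - left.end - 1 < 35_000

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_detector_recovers_truth_partition(self, seed):
        """Round trip: cluster detection on the synthetic layout recovers
        exactly the generator's truth, verified against a brute-force
        all-pairs oracle as well."""
        rng = np.random.default_rng(seed)
        comp = self.complement({
            ("Hhal", "famA"): int(rng.integers(2, 10)),
            ("Hhal", "famB"): int(rng.integers(2, 10)),
            ("Clec", "famA"): int(rng.integers(2, 10)),
        })
        layout = ScaffoldLayoutConfig(cluster_fraction=float(rng.uniform()))
        annotations, truth = synthesize_gene_annotations(comp, layout,
                                                         seed=seed)
        detected = detect_clusters(annotations).partition()
        assert sorted(detected, key=sorted) == sorted(truth, key=sorted)
        assert sorted(detected, key=sorted) == brute_force_clusters(
            annotations, 35_000)

    def test_capacity_exceeded(self):
        comp = self.complement({("Hhal", "famA"): 50})
        layout = ScaffoldLayoutConfig(n_scaffolds=1, scaffold_length=100_000,
                                      cluster_fraction=0.0)
        with pytest.raises(ValueError, match="capacity"):
            synthesize_gene_annotations(comp, layout, seed=0)

    def test_gap_ranges_validated(self):
        with pytest.raises(ValueError):
            ScaffoldLayoutConfig(within_cluster_gap=(0, 35_000)).validate()
        with pytest.raises(ValueError):
            ScaffoldLayoutConfig(background_gap=(34_999, 50_000)).validate()
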
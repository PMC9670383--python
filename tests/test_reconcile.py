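import numpy as np
import pytest

from detoxevol.reconcile import (EventMatrix, aggregate_event_matrix,
                                 annotate_species_tree_with_events,
                                 lca_reconcile, root_by_min_dl)
from detoxevol.simulate import SimulationConfig, simulate_families
from detoxevol.trees import GeneNode, SpeciesTree, TreeError
from oracles import (OracleSpeciesTree, brute_force_min_dl,
                     enumerate_tuple_trees, tuple_tree_to_newick)

AB = SpeciesTree("(A,B)root;")
ABC = SpeciesTree("(A,(B,C)BC)R;")
ORACLE_ABC = OracleSpeciesTree.three_species()


def reconcile_abc(newick):
    tree = GeneNode.from_newick(newick)
    mapping = {leaf: leaf.split("_")[0] for leaf in tree.leaf_names()}
    return lca_reconcile(tree, ABC, mapping=mapping)


class TestLcaReconcile:
    def test_congruent_tree_costs_nothing(self, species_tree):
        tree = GeneNode.from_newick(
            "(Nlug_f_g1,((Clec_f_g1,Rpro_f_g1),(Hhal_f_g1,Nvir_f_g1)));")
        result = lca_reconcile(tree, species_tree)
        assert result.cost == 0
        assert result.duplications == {} and result.losses == {}

    def test_in_species_duplication(self):
        tree = GeneNode.from_newick("((A_1,A_2),B_1);")
        result = lca_reconcile(tree, AB,
                               mapping={"A_1": "A", "A_2": "A", "B_1": "B"})
        assert result.duplications == {"A": 1}
        assert result.losses == {}

    def test_root_duplication_with_loss(self):
        """((A1,B1),A2) on (A,B): one duplication predating the split plus
        one loss of the B copy - total cost 2, the brute-force minimum."""
        tree = GeneNode.from_newick("((A_1,B_1),A_2);")
        result = lca_reconcile(tree, AB,
                               mapping={"A_1": "A", "B_1": "B", "A_2": "A"})
        assert result.duplications == {"root": 1}
        assert result.losses == {"B": 1}
        assert result.cost == 2

    def test_loss_charged_to_skipped_branch(self, species_tree):
        # Hhal sister to (Clec,Rpro): the Nvir lineage was lost below HN
        tree = GeneNode.from_newick(
            "(Nlug_f_g1,((Clec_f_g1,Rpro_f_g1),Hhal_f_g1));")
        result = lca_reconcile(tree, species_tree)
        assert result.duplications == {}
        assert result.losses == {"Nvir": 1}

    def test_polytomy_rejected_then_resolved(self, species_tree):
        tree = GeneNode.from_newick("(Hhal_f_g1,Nvir_f_g1,Nlug_f_g1);")
        with pytest.raises(TreeError, match="polytom"):
            lca_reconcile(tree, species_tree)
        result = lca_reconcile(tree, species_tree, polytomies="resolve")
        assert result.n_duplications == 0

    def test_minimality_vs_brute_force_enumeration(self):
        """On every rooted binary gene tree with up to 5 leaves over a
        3-species tree, the LCA reconciliation cost equals the exhaustive
        minimum over all valid duplication-loss reconciliations."""
        for n in (2, 3, 4, 5):
            for tuple_tree in enumerate_tuple_trees(n, "ABC"):
                newick = tuple_tree_to_newick(tuple_tree)
                gene_tree = GeneNode.from_newick(newick)
                mapping = {leaf: leaf.split("_")[0]
                           for leaf in gene_tree.leaf_names()}
                got = lca_reconcile(gene_tree, ABC, mapping=mapping).cost
                expected = brute_force_min_dl(tuple_tree, ORACLE_ABC,
                                              {s: s for s in "ABC"})
                assert got == expected, newick


class TestMinDlRooting:
    def test_already_optimal_root_kept(self):
        tree = GeneNode.from_newick("(A_1,(B_1,C_1));")
        mapping = {l: l.split("_")[0] for l in tree.leaf_names()}
        rooted = root_by_min_dl(tree, ABC, mapping=mapping)
        assert lca_reconcile(rooted, ABC, mapping=mapping).cost == 0

    def test_congruent_unrooted_recovers_zero_cost(self, species_tree):
        tree = GeneNode.from_newick(
            "((Clec_f_g1,Rpro_f_g1),(Hhal_f_g1,Nvir_f_g1),Nlug_f_g1);")
        rooted = root_by_min_dl(tree, species_tree)
        assert lca_reconcile(rooted, species_tree).cost == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_all_rootings_oracle(self, seed):
        """Random 6-leaf instances: the chosen rooting attains the minimum
        cost over every possible rooting (checked exhaustively)."""
        rng = np.random.default_rng(seed)
        leaves = [f"{rng.choice(list('ABC'))}_{i}" for i in range(1, 7)]
        nodes = [GeneNode(name) for name in leaves]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = GeneNode(None, [nodes[i], nodes[j]])
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(merged)
        tree = nodes[0]
        mapping = {l: l.split("_")[0] for l in tree.leaf_names()}

        chosen = root_by_min_dl(tree, ABC, mapping=mapping)
        chosen_cost = lca_reconcile(chosen, ABC, mapping=mapping).cost

        # exhaustive oracle: reroot on every edge via the same adjacency
        # the implementation exposes, but score each candidate directly
        from detoxevol.reconcile import _unrooted_adjacency
        nodes_tbl, adj, _ = _unrooted_adjacency(tree)

        def subtree(at, came_from):
            nbrs = [n for n in adj[at] if n != came_from]
            if not nbrs:
                return GeneNode(nodes_tbl[at])
            return GeneNode(None, [subtree(n, at) for n in nbrs])

        costs = []
        seen = set()
        for u in range(len(nodes_tbl)):
            for v in adj[u]:
                if (v, u) in seen:
                    continue
                seen.add((u, v))
                candidate = GeneNode(None, [subtree(u, v), subtree(v, u)])
                costs.append(lca_reconcile(candidate, ABC,
                                           mapping=mapping).cost)
        assert chosen_cost == min(costs)


class TestSimulationRecovery:
    def test_lossless_simulation_recovered_exactly(self, species_tree):
        """With loss_prob=0, LCA reconciliation recovers the simulator's
        per-branch duplication counts exactly."""
        config = SimulationConfig(dup_rate=0.4, loss_prob=0.0, n_families=60,
                                  seed=99)
        trees, truths = simulate_families(config)
        for fam, tree in trees.items():
            result = lca_reconcile(tree, species_tree)
            assert result.duplications == truths[fam].duplications
            assert result.losses == {}

    def test_parsimony_lower_bound_with_losses(self, species_tree):
        """With losses the inferred cost never exceeds the true event
        count (parsimony is a lower bound on the true history)."""
        config = SimulationConfig(dup_rate=0.4, loss_prob=0.25,
                                  n_families=60, seed=100)
        trees, truths = simulate_families(config)
        checked = 0
        for fam, tree in trees.items():
            if tree is None:
                continue
            result = lca_reconcile(tree, species_tree)
            assert result.cost <= truths[fam].n_events
            checked += 1
        assert checked > 20


class TestAggregation:
    def test_empty_input_zero_matrix(self, species_tree):
        matrix = aggregate_event_matrix({}, {}, species_tree)
        assert matrix.total_events() == 0

    def test_additivity_family_by_family(self, species_tree):
        config = SimulationConfig(dup_rate=0.4, loss_prob=0.1, n_families=20,
                                  seed=7)
        trees, _ = simulate_families(config)
        results = {fam: lca_reconcile(tree, species_tree)
                   for fam, tree in trees.items() if tree is not None}
        grouping = {fam: "G1" if i % 2 else "G2"
                    for i, fam in enumerate(sorted(results))}
        whole = aggregate_event_matrix(results, grouping, species_tree,
                                       groups=["G1", "G2"])
        part_sum = 0
        for fam in results:
            single = aggregate_event_matrix({fam: results[fam]}, grouping,
                                            species_tree,
                                            groups=["G1", "G2"])
            part_sum += single.total_events()
        assert whole.total_events() == part_sum

    def test_unknown_group_rejected(self, species_tree):
        tree = GeneNode.from_newick("(Hhal_f_g1,Nvir_f_g1);")
        result = lca_reconcile(tree, species_tree)
        with pytest.raises(KeyError):
            aggregate_event_matrix({"f": result}, {}, species_tree)


class TestAnnotation:
    def test_zero_matrix_all_zero_labels(self, species_tree):
        matrix = EventMatrix.zeros(["Hhal", "Nvir"], ["G"])
        frame, newick = annotate_species_tree_with_events(matrix,
                                                          species_tree)
        assert set(frame["label"]) == {"+0/-0"}
        assert "[+0/-0]" in newick

    def test_single_event_passthrough(self, species_tree):
        matrix = EventMatrix.zeros(["Hhal"], ["G"])
        matrix.add("Hhal", "Duplications", "G", 2)
        frame, newick = annotate_species_tree_with_events(matrix,
                                                          species_tree)
        assert frame.loc["Hhal", "label"] == "+2/-0"
        assert "Hhal[+2/-0]" in newick

    def test_fixture_rpro_duplications(self, species_tree, table2):
        frame, _ = annotate_species_tree_with_events(table2, species_tree)
        assert frame.loc["Rpro", "gains"] == 113

    def test_unknown_branch_rejected(self, species_tree):
        matrix = EventMatrix.zeros(["NotABranch"], ["G"])
        with pytest.raises(TreeError):
            annotate_species_tree_with_events(matrix, species_tree)
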
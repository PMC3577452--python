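import random

import pytest
from hypothesis import given, strategies as st

import dtlslice as dl
from dtlslice.reconcile import ALL, ReconciliationError
from _oracles import dl_stem_cost, oracle_cost
from _util import random_costs, random_gene_tree, random_instance

BIG = 10**6


def applicable_rows(G, S0, costs, e, d):
    M = dl.compute_cost_matrix(G, S0, costs)
    return {c.row for c in M.cands[(e.index, d)]}


class TestApplicableEvents:
    def test_cohered_leaf_pair_has_fin(self, two_species_slices, default_costs):
        G = dl.parse_gene_tree("(A-1,B-2);")
        leaf_a = next(l for l in G.leaves() if l.species == "A")
        d = two_species_slices.terminal_tube["A"]
        rows = applicable_rows(G, two_species_slices, default_costs, leaf_a, d)
        assert rows == {0}

    def test_non_cohered_leaf_pair_has_tr_fin_not_fin(self, two_species_slices,
                                                      default_costs):
        G = dl.parse_gene_tree("(A-1,B-2);")
        leaf_a = next(l for l in G.leaves() if l.species == "A")
        d = two_species_slices.terminal_tube["B"]
        rows = applicable_rows(G, two_species_slices, default_costs, leaf_a, d)
        assert 1 in rows and 0 not in rows

    def test_root_tube_events(self, two_species_slices, default_costs):
        G = dl.parse_gene_tree("(A-1,B-2);")
        S0 = two_species_slices
        rows = applicable_rows(G, S0, default_costs, G.root, S0.d0)
        assert rows & {8, 9}  # gene present in the root
        assert rows & {10, 11}  # gene absent, leaves via the outgroup tube
        assert not rows & {6, 7}  # speciation-with-loss needs d != d_0
        assert {4, 5, 12, 13} <= rows  # forks and duplications at d_0


class TestWorkedExamples:
    """Hand-sized instances, each double-checked against the brute-force
    expansion of the event table."""

    def check(self, gene, species, costs, expected):
        G = dl.parse_gene_tree(gene)
        S0 = dl.slice_species_tree(species)
        got = dl.reconcile_cost(G, S0, costs)
        assert got == pytest.approx(expected)
        assert oracle_cost(G, S0, costs) == pytest.approx(expected)

    def test_congruent_pair_costs_zero(self, default_costs):
        self.check("(A-1,B-2);", "(A,B);", default_costs, 0.0)

    def test_single_loss(self, default_costs):
        # c_loss is the cheapest escape: fork at the root, then pass over C
        assert default_costs.loss <= default_costs.tr_without
        self.check("(A-1,B-1);", "((A,C),B);", default_costs,
                   default_costs.loss)

    def test_single_duplication(self, default_costs):
        self.check("((A-1,B-1),(A-2,B-2));", "(A,B);", default_costs,
                   default_costs.dupl)

    def test_transfer_beats_losses_when_cheap(self):
        costs = dl.EventCosts(loss=10.0, tr_with=1.0, tr_without=1.0)
        G = dl.parse_gene_tree("(A-1,D-1);")
        S0 = dl.slice_species_tree("((A,B),(C,D));")
        got = dl.reconcile_cost(G, S0, costs)
        assert got == pytest.approx(oracle_cost(G, S0, costs))
        assert got < 2 * costs.loss


class TestCostMatrix:
    def test_unsolvable_species_reported(self, two_species_slices):
        G = dl.parse_gene_tree("(A-1,Q-1);")
        with pytest.raises(ReconciliationError, match="Q"):
            dl.reconcile_cost(G, two_species_slices)

    def test_polytomy_rejected(self, two_species_slices):
        G = dl.parse_gene_tree("(A-1,A-2,B-1);")
        with pytest.raises(ReconciliationError, match="binar"):
            dl.reconcile_cost(G, two_species_slices)

    @given(st.integers(0, 10_000))
    def test_fast_and_full_paths_agree(self, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng, max_species=5, max_leaves=5)
        fast = dl.reconcile_cost(G, S0, costs)
        full = dl.compute_cost_matrix(G, S0, costs).cost
        assert fast == pytest.approx(full, abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce(self, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng)
        assert dl.reconcile_cost(G, S0, costs) == pytest.approx(
            oracle_cost(G, S0, costs), abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_monotone_in_each_cost(self, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng, max_species=3, max_leaves=3)
        base = dl.reconcile_cost(G, S0, costs)
        field = rng.choice(["loss", "dupl", "gain", "tr_with", "tr_without",
                            "sleep", "gain_big"])
        bumped = dl.EventCosts(**{**costs.__dict__, field:
                                  getattr(costs, field) + rng.uniform(0.1, 2)})
        assert dl.reconcile_cost(G, S0, bumped) >= base - 1e-9

    @given(st.integers(0, 10_000))
    def test_nonnegative(self, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng)
        assert dl.reconcile_cost(G, S0, costs) >= 0

    @given(st.integers(0, 3000))
    def test_classical_duplication_loss_limit(self, seed):
        """With transfers, gains and sleeps priced out, the tube model reduces
        to the classical LCA duplication-loss cost plus the stem losses."""
        rng = random.Random(seed)
        S, S0, forest = dl.simulate_forest(
            rng.choice([3, 4, 5]),
            dl.SimParams(0.15, 0.15, 0.0, n_trees=2, seed=seed))
        cd, cl = rng.uniform(0.5, 3), rng.uniform(0.5, 3)
        costs = dl.EventCosts(loss=cl, dupl=cd, gain=BIG, tr_with=BIG,
                              tr_without=BIG, sleep=BIG, gain_big=BIG)
        for G in forest:
            assert dl.reconcile_cost(G, S0, costs) == pytest.approx(
                dl_stem_cost(G, S.ingroup_root, cd, cl))


class TestTotalCost:
    def test_empty_forest(self, two_species_slices, default_costs):
        assert dl.total_cost(dl.Forest([]), two_species_slices,
                             default_costs) == 0.0

    def test_congruent_forest(self, two_species_slices, default_costs):
        forest = dl.parse_forest("(A-1,B-1);\n(A-2,B-2);\n")
        assert dl.total_cost(forest, two_species_slices, default_costs) == 0.0

    def test_weights(self, two_species_slices, default_costs):
        forest = dl.parse_forest("(A-1,B-1);\n((A-1,B-1),(A-2,B-2));\n")
        forest[1].weight = 2.0
        assert dl.total_cost(forest, two_species_slices, default_costs) == \
            pytest.approx(2 * default_costs.dupl)


class TestEventTree:
    def test_congruent_scenario_rows(self, two_species_slices, default_costs):
        G = dl.parse_gene_tree("(A-1,B-2);")
        M = dl.compute_cost_matrix(G, two_species_slices, default_costs)
        T = dl.build_event_tree(M)
        assert T.cost == 0.0
        assert {n.row for n in T.walk()} <= {8, 9, 3, 4, 5, 0}

    def test_one_duplication_tagged_once(self, one_dup_instance):
        _, _, M = one_dup_instance
        T = dl.build_event_tree(M)
        assert sum(1 for n in T.walk() if n.row == 12) == 1

    @given(st.integers(0, 5000))
    def test_event_tree_cost_identities(self, seed):
        """c(T) equals the matrix root cell and the sum of the local event
        increments along T."""
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng, max_species=5, max_leaves=5)
        M = dl.compute_cost_matrix(G, S0, costs)
        T = dl.build_event_tree(M)
        assert T.cost == M.cost
        assert T.local_cost() == pytest.approx(M.cost, abs=1e-9)


class TestBetaMapping:
    def test_leaf_edge_path_ends_in_terminal_tube(self, two_species_slices,
                                                  default_costs):
        G = dl.parse_gene_tree("(A-1,B-2);")
        M = dl.compute_cost_matrix(G, two_species_slices, default_costs)
        beta = dl.beta_mapping(dl.build_event_tree(M))
        leaf_a = next(l for l in G.leaves() if l.species == "A")
        tubes, final_row = beta[leaf_a]
        assert tubes[-1] == two_species_slices.terminal_tube["A"]
        assert final_row == 0  # ends with fin

    def test_duplication_can_terminate_a_path(self, one_dup_instance):
        G, S0, M = one_dup_instance
        beta = dl.beta_mapping(dl.build_event_tree(M))
        tubes, final_row = beta[G.root]
        assert final_row == 12  # the root edge's path ends with the duplication

    @given(st.integers(0, 5000))
    def test_paths_are_connected(self, seed):
        """Consecutive tubes of beta(e) are parent/child, same-slice partners
        (a transfer), or a child of the acceptor tube."""
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng, max_species=5, max_leaves=5)
        M = dl.compute_cost_matrix(G, S0, costs)
        beta = dl.beta_mapping(dl.build_event_tree(M))
        for tubes, _ in beta.values():
            for a, b in zip(tubes, tubes[1:]):
                same_slice = S0.slice_of[a] == S0.slice_of[b]
                parent_child = S0.parent[b] == a
                child_of_acceptor = (S0.parent[b] is not None
                                     and S0.slice_of[S0.parent[b]] == S0.slice_of[a])
                assert parent_child or same_slice or child_of_acceptor
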
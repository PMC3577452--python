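import random

import pytest
from hypothesis import given, strategies as st

import dtlslice as dl
from dtlslice.events import DEFAULT_SCENARIO_TAGS, TAG_TABLE
from dtlslice.scenario import count_in_tube, count_on_edges, iter_tagged
from _util import random_instance


def small_instances(seed, n=4):
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        G, S0, costs = random_instance(rng, max_species=4, max_leaves=4)
        out.append((G, S0, costs))
    return out


class TestBuildDag:
    def test_parameter_validation(self, two_species_slices, default_costs):
        G = dl.parse_gene_tree("(A-1,B-2);")
        with pytest.raises(ValueError):
            dl.build_dag(G, two_species_slices, default_costs, k=0)
        with pytest.raises(ValueError):
            dl.build_dag(G, two_species_slices, default_costs, k=1, tau=0.0)

    def test_k1_probabilities_are_zero_one(self, one_dup_instance):
        G, S0, _ = one_dup_instance
        dag = dl.propagate_mass(dl.build_dag(G, S0, k=1))
        for v in dag.vertices.values():
            for e in v.edges:
                assert e.p == 1.0

    def test_k1_edges_reproduce_the_event_tree(self, one_dup_instance):
        G, S0, M = one_dup_instance
        T = dl.build_event_tree(M)
        dag = dl.propagate_mass(dl.build_dag(G, S0, k=1))
        tree_events = sorted((n.e.index, n.d, n.row) for n in T.walk()
                             if n.children or n.row != 0)
        dag_events = sorted((v.e.index, v.d, e.row)
                            for v in dag.vertices.values() for e in v.edges)
        assert dag_events == tree_events
        assert all(e.mass == 1.0 for v in dag.vertices.values()
                   for e in v.edges)

    @given(st.integers(0, 3000))
    def test_large_k_keeps_every_applicable_alternative(self, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng)
        M = dl.compute_cost_matrix(G, S0, costs)
        dag = dl.build_dag(G, S0, costs, k=100, matrix=M)
        for (ei, d, mode), v in dag.vertices.items():
            cands = M.cands[(ei, d)]
            if mode == "all" and not (len(cands) == 1 and cands[0].row == 0):
                assert len(v.edges) == len(cands)

    @pytest.mark.parametrize("k", [1, 2, 5, 10])
    @given(st.integers(0, 2000))
    def test_probability_conservation(self, k, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng)
        dag = dl.build_dag(G, S0, costs, k=k)
        for v in dag.vertices.values():
            if v.edges:
                assert sum(e.p for e in v.edges) == pytest.approx(1.0, abs=1e-12)


class TestMassPropagation:
    def test_root_outgoing_masses_sum_to_one(self, one_dup_instance):
        G, S0, _ = one_dup_instance
        dag = dl.propagate_mass(dl.build_dag(G, S0, k=5))
        root = dag.vertices[dag.root_key]
        assert sum(e.mass for e in root.edges) == pytest.approx(1.0)

    @given(st.integers(0, 2000))
    def test_vertex_mass_is_sum_of_incoming(self, seed):
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng)
        dag = dl.propagate_mass(dl.build_dag(G, S0, costs, k=3))
        incoming = {key: 0.0 for key in dag.vertices}
        incoming[dag.root_key] = 1.0
        for v in dag.vertices.values():
            for e in v.edges:
                for t in e.termini:
                    incoming[t] += e.mass
        for key, v in dag.vertices.items():
            assert v.mass == pytest.approx(incoming[key], abs=1e-12)


class TestExpectations:
    def test_empty_tag_set_and_empty_marked_set(self, one_dup_instance):
        G, S0, _ = one_dup_instance
        dags = [dl.propagate_mass(dl.build_dag(G, S0, k=3))]
        assert dl.expect_in_tube(dags, frozenset(), 0) == 0.0
        assert dl.expect_on_edges(dags, {"dupl"}, frozenset()) == 0.0

    def test_unknown_tag_rejected(self, one_dup_instance):
        G, S0, _ = one_dup_instance
        dags = [dl.build_dag(G, S0, k=1)]
        with pytest.raises(ValueError, match="unknown"):
            dl.expect_in_tube(dags, {"quux"}, 0)

    def test_one_duplication_expectations_at_k1(self, one_dup_instance,
                                                default_costs):
        G, S0, M = one_dup_instance
        dags = [dl.propagate_mass(dl.build_dag(G, S0, k=1, matrix=M))]
        T = dl.build_event_tree(M)
        dup_tube = next(n.d for n in T.walk() if n.row == 12)
        assert dl.expect_in_tube(dags, {"dupl"}, dup_tube) == pytest.approx(1.0)
        assert dl.expect_costs(dags, {"dupl"}, u=dup_tube) == pytest.approx(
            default_costs.dupl)
        all_edges = frozenset(G.nodes)
        assert dl.expect_on_edges(dags, {"dupl"}, all_edges) == pytest.approx(1.0)
        assert dl.scenario_cost(dags) == pytest.approx(default_costs.dupl)

    def test_congruent_forest_scenario_cost_zero(self, two_species_slices):
        forest = dl.parse_forest("(A-1,B-1);\n(A-2,B-2);\n")
        dags = dl.forest_dags(forest, two_species_slices, k=1)
        assert dl.scenario_cost(dags) == 0.0

    def test_unit_costs_make_cf_equal_f(self, one_dup_instance):
        G, S0, _ = one_dup_instance
        unit = dl.EventCosts(loss=1, dupl=1, gain=1, tr_with=1, tr_without=1,
                             sleep=1, gain_big=1)
        dags = [dl.propagate_mass(dl.build_dag(G, S0, unit, k=4))]
        for u in range(S0.n_tubes):
            f = dl.expect_in_tube(dags, DEFAULT_SCENARIO_TAGS, u)
            cf = dl.expect_costs(dags, DEFAULT_SCENARIO_TAGS, u=u)
            assert cf == pytest.approx(f)

    @given(st.integers(0, 1500))
    def test_k1_collapse_to_event_tree_counts(self, seed):
        """At k = 1 every expectation equals the deterministic count/cost
        read off the first scenario."""
        for G, S0, costs in small_instances(seed, n=2):
            M = dl.compute_cost_matrix(G, S0, costs)
            T = dl.build_event_tree(M)
            dags = [dl.propagate_mass(dl.build_dag(G, S0, costs, k=1,
                                                   matrix=M))]
            I = DEFAULT_SCENARIO_TAGS
            for u in range(S0.n_tubes):
                assert dl.expect_in_tube(dags, I, u) == pytest.approx(
                    count_in_tube(T, I, u), abs=1e-12)
                assert dl.expect_costs(dags, I, u=u) == pytest.approx(
                    count_in_tube(T, I, u, weighted=True), abs=1e-12)
            edges = frozenset(G.nodes)
            assert dl.expect_on_edges(dags, I, edges) == pytest.approx(
                count_on_edges(T, I, edges), abs=1e-12)
            assert dl.expect_costs(dags, I, T=edges) == pytest.approx(
                count_on_edges(T, I, edges, weighted=True), abs=1e-12)

    @given(st.integers(0, 1500))
    def test_halving_is_consistent_with_totals(self, seed):
        """Summing f(I, u) over every tube must recover the full tagged mass:
        the d'&d'' halves of the double-transfer rows add back to a whole."""
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng)
        dags = [dl.propagate_mass(dl.build_dag(G, S0, costs, k=6))]
        I = dl.TAGS
        total_by_tube = sum(dl.expect_in_tube(dags, I, u)
                            for u in range(S0.n_tubes))
        total_mass = sum(mass for tag, _e, _d, mass, _c in iter_tagged(dags[0]))
        assert total_by_tube == pytest.approx(total_mass, abs=1e-9)

    def test_composite_edge_reference_halves(self):
        """A double-transfer edge with one marked child contributes half its
        mass per matching composite tag triplet."""
        from dtlslice.scenario import _edge_weight
        a, b = dl.GeneNode("A", "1"), dl.GeneNode("B", "1")
        assert _edge_weight((a, b), frozenset([a])) == 0.5
        assert _edge_weight((a, b), frozenset([a, b])) == 1.0
        assert _edge_weight(a, frozenset([a])) == 1.0
        # and the double-transfer rows do carry composite references
        assert any(eref == "e1&e2" for _t, eref, _d in TAG_TABLE[33])

    @given(st.integers(0, 800))
    def test_expectations_stable_in_k(self, seed):
        """Raising the ramification degree shifts expectations by no more
        than the mass routed through the newly admitted alternatives."""
        rng = random.Random(seed)
        G, S0, costs = random_instance(rng, max_species=3, max_leaves=3)
        for k in (1, 2, 4):
            d1 = [dl.propagate_mass(dl.build_dag(G, S0, costs, k=k))]
            d2 = [dl.propagate_mass(dl.build_dag(G, S0, costs, k=k + 1))]
            new_mass = 0.0
            for v in d2[0].vertices.values():
                if len(v.edges) == k + 1:
                    new_mass += v.edges[-1].mass
            f1 = sum(dl.expect_in_tube(d1, dl.TAGS, u)
                     for u in range(S0.n_tubes))
            f2 = sum(dl.expect_in_tube(d2, dl.TAGS, u)
                     for u in range(S0.n_tubes))
            if new_mass == 0.0:
                # no vertex gained an alternative, so the DAGs coincide
                assert f1 == pytest.approx(f2, abs=1e-9)
            else:
                # each event edge carries at most 5 tag triplets
                assert abs(f1 - f2) <= 5 * new_mass + 1e-9
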
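"""Density/enrichment predicates, pruning properties, and the enumerator."""

import itertools
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from qclique import (
    Graph,
    Module,
    Params,
    QuerySet,
    SearchState,
    brute_force_maximal,
    enumerate_dense,
    extension_feasible,
    initial_candidates,
    is_gamma_dense,
    is_mu_enriched,
    maximality_filter,
    prune_candidates_density,
    prune_enrichment,
    required_degree,
)

from conftest import (
    complete_graph,
    cycle_graph,
    er_graph,
    path_graph,
    random_query,
)


class TestParams:
    def test_gamma_range(self):
        with pytest.raises(ValueError, match=r"\(0.5, 1\]"):
            Params(0.5, 0.5)
        with pytest.raises(ValueError):
            Params(1.2, 0.5)
        assert Params(1.0, 0.5).gamma == 1

    def test_mu_range(self):
        with pytest.raises(ValueError):
            Params(0.75, 0)
        assert Params(0.75, 1).mu == 1

    def test_exact_rational_coercion(self):
        p = Params(0.75, 0.001)
        assert p.gamma == Fraction(3, 4)
        assert p.mu == Fraction(1, 1000)


class TestRequiredDegree:
    @pytest.mark.parametrize(
        "gamma,size,expected",
        [(0.75, 5, 3), (0.999, 4, 3), (1.0, 7, 6), (0.75, 1, 0), (0.51, 2, 1)],
    )
    def test_examples(self, gamma, size, expected):
        assert required_degree(gamma, size) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.fractions(min_value=Fraction(1, 2), max_value=1).filter(
            lambda f: f > Fraction(1, 2)
        ),
        st.integers(min_value=1, max_value=2000),
    )
    def test_is_exact_ceiling(self, gamma, size):
        r = required_degree(gamma, size)
        assert r >= gamma * (size - 1)
        assert r - 1 < gamma * (size - 1)

    def test_clique_behaviour_below_size_1001(self):
        # gamma=0.999 demands full adjacency for every size up to 1000
        for size in (2, 10, 500, 1000):
            assert required_degree(0.999, size) == size - 1
        assert required_degree(0.999, 1001) == 999


class TestDensityPredicate:
    def test_triangle_dense(self):
        assert is_gamma_dense(complete_graph(3), {0, 1, 2}, 0.75)

    def test_path_endpoints_fail(self):
        assert not is_gamma_dense(path_graph(3), {0, 1, 2}, 0.75)

    def test_four_cycle_at_low_gamma(self):
        assert is_gamma_dense(cycle_graph(4), {0, 1, 2, 3}, 0.6)

    def test_singleton_vacuous(self):
        assert is_gamma_dense(path_graph(3), {0}, 0.999)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            is_gamma_dense(path_graph(3), set(), 0.75)


class TestEnrichmentPredicate:
    def test_exact_boundary(self):
        S = set(range(5))
        assert is_mu_enriched(S, {0, 1}, 0.4)
        assert not is_mu_enriched(S, {0, 1}, 0.5)

    def test_tiny_mu_means_one_query_vertex(self):
        # mu=0.001: any set up to 1000 vertices needs exactly one query member
        S = set(range(1000))
        assert is_mu_enriched(S, {999}, 0.001)
        assert not is_mu_enriched(S, {1000}, 0.001)

    def test_no_query_member_never_enriched(self):
        for mu in (0.001, 0.5, 1.0):
            assert not is_mu_enriched({0, 1}, {5}, mu)


class TestInitialCandidates:
    def test_star(self):
        g = Graph.from_edges([("c", "a"), ("c", "b"), ("c", "d")])
        assert initial_candidates(g, g.index_of("c")) == sorted(
            g.index_of(x) for x in "abd"
        )

    def test_path_distance_two(self):
        g = path_graph(4)
        assert initial_candidates(g, 0) == [1, 2]

    def test_isolated_vertex(self):
        g = Graph.from_edges([("a", "b")], extra_vertices=["z"])
        assert initial_candidates(g, g.index_of("z")) == []


class TestSearchState:
    def test_incremental_counts_match_recomputation(self):
        rng = random.Random(3)
        for _ in range(20):
            g = er_graph(10, 0.4, rng)
            S = {0} | set(rng.sample(range(10), rng.randint(0, 3)))
            C = set(rng.sample(range(10), rng.randint(0, 6))) - S
            st_ = SearchState.from_sets(g, S, C, 0)
            s_a, c_a = st_.recompute_counts()
            assert st_.s_a == s_a and st_.c_a == c_a
            assert not (set(st_.C) & st_.S)


class TestExtensionFeasible:
    def test_empty_candidates_reduce_to_density(self):
        g = complete_graph(3)
        st_full = SearchState.from_sets(g, {0, 1, 2}, set(), 0)
        assert extension_feasible(st_full, 0.75) == is_gamma_dense(g, {0, 1, 2}, 0.75)
        gp = path_graph(3)
        st_path = SearchState.from_sets(gp, {0, 1, 2}, set(), 0)
        assert extension_feasible(st_path, 0.75) == is_gamma_dense(gp, {0, 1, 2}, 0.75)

    def test_candidate_adjacent_to_both_members(self):
        g = complete_graph(3)  # S={0,1}, C={2} adjacent to both
        assert extension_feasible(SearchState.from_sets(g, {0, 1}, {2}, 0), 0.75)

    def test_candidate_adjacent_to_one_member(self):
        """A candidate adjacent to only one of two members cannot produce a
        dense supergraph: brute force confirms none exists, and the density
        prune (not the expansion bound, which is a sound relaxation and
        still holds here) removes the candidate, leaving nothing to expand.
        """
        g = Graph.from_edges([("a", "b"), ("a", "c")])
        a, b, c = (g.index_of(x) for x in "abc")
        st_ = SearchState.from_sets(g, {a, b}, {c}, a)
        # no gamma-dense strict supergraph of {a,b} inside {a,b,c}
        assert not is_gamma_dense(g, {a, b, c}, 0.75)
        assert prune_candidates_density(st_, 0.75).C == []
        # with the candidate gone the bound reduces to density of S itself
        pruned = SearchState.from_sets(g, {a, b}, set(), a)
        assert extension_feasible(pruned, 0.75) == is_gamma_dense(g, {a, b}, 0.75)


class TestPruneCandidatesDensity:
    def test_fully_connected_candidate_retained(self):
        g = complete_graph(6)
        st_ = SearchState.from_sets(g, {0, 1}, {2, 3, 4, 5}, 0)
        assert prune_candidates_density(st_, 0.999).C == [2, 3, 4, 5]

    def test_unconnected_candidate_removed(self):
        g = Graph.from_edges([("a", "b"), ("b", "x"), ("x", "z")])
        a, b, z = g.index_of("a"), g.index_of("b"), g.index_of("z")
        st_ = SearchState.from_sets(g, {a, b}, {z}, a)
        assert prune_candidates_density(st_, 0.75).C == []

    def test_pruning_never_removes_module_vertices(self):
        """Fixed-point pruning keeps every vertex of every maximal module
        extending S — checked against brute force on random graphs."""
        rng = random.Random(11)
        for _ in range(200):
            g = er_graph(9, rng.choice([0.3, 0.5]), rng)
            gamma = rng.choice([0.55, 0.75, 0.999])
            seed = rng.randrange(9)
            S = {seed}
            C = set(initial_candidates(g, seed))
            st_ = SearchState.from_sets(g, S, C, seed)
            kept = set(prune_candidates_density(st_, gamma).C)
            params = Params(gamma, 0.001)
            oracle = brute_force_maximal(g, QuerySet(frozenset({seed})), params)
            for mod in oracle:
                if S <= mod.vertices and mod.vertices <= S | C:
                    assert mod.vertices <= S | kept


class TestPruneEnrichment:
    def test_query_covering_everything(self):
        g = complete_graph(5)
        st_ = SearchState.from_sets(g, {0}, {1, 2, 3, 4}, 0)
        assert prune_enrichment(st_, set(range(5)), 1.0)

    def test_branch_dead_without_query_member(self):
        g = complete_graph(3)
        st_ = SearchState.from_sets(g, {0}, {1}, 0)
        assert not prune_enrichment(st_, {2}, 0.001)

    def test_arithmetic_boundary(self):
        # |S|=3 with 2 query members, one query candidate: 3 < 0.9*4
        g = complete_graph(5)
        st_ = SearchState.from_sets(g, {0, 1, 2}, {3, 4}, 0)
        assert not prune_enrichment(st_, {0, 1, 3}, 0.9)

    def test_nonquery_candidates_removed_when_unaffordable(self):
        g = complete_graph(4)
        st_ = SearchState.from_sets(g, {0}, {1, 2, 3}, 0)
        assert prune_enrichment(st_, {0, 1}, 0.9)
        assert st_.C == [1]  # only the query candidate survives


class TestEnumerate:
    def params(self, gamma=0.75, mu=0.001, min_size=2):
        return Params(gamma, mu, min_size)

    def test_complete_graph_single_module(self):
        g = complete_graph(4)
        mods = enumerate_dense(g, QuerySet(frozenset({2})), self.params())
        assert [sorted(m.vertices) for m in mods] == [[0, 1, 2, 3]]

    def test_two_triangles_overlap(self, two_triangles):
        g = two_triangles
        hub = g.index_of("hub")
        mods = enumerate_dense(g, QuerySet(frozenset({hub})), self.params())
        got = {frozenset(g.labels[v] for v in m.vertices) for m in mods}
        assert got == {
            frozenset({"hub", "a1", "a2"}),
            frozenset({"hub", "b1", "b2"}),
        }

    def test_path_yields_each_edge(self):
        g = path_graph(4)
        mods = enumerate_dense(
            g, QuerySet(frozenset(range(4))), self.params()
        )
        assert {tuple(sorted(m.vertices)) for m in mods} == {(0, 1), (1, 2), (2, 3)}

    def test_invalid_inputs(self):
        g = complete_graph(3)
        with pytest.raises(ValueError):
            enumerate_dense(g, QuerySet(frozenset()), self.params())
        with pytest.raises(ValueError):
            enumerate_dense(g, QuerySet(frozenset({7})), self.params())

    def test_determinism(self):
        rng = random.Random(7)
        g = er_graph(14, 0.4, rng)
        Q = random_query(g, rng)
        p = self.params(0.75, 0.5)
        first = enumerate_dense(g, Q, p)
        second = enumerate_dense(g, Q, p)
        assert first == second  # same sets in the same order

    def test_modules_have_diameter_two_in_host_graph(self):
        rng = random.Random(13)
        for _ in range(20):
            g = er_graph(12, 0.45, rng)
            Q = random_query(g, rng)
            for m in enumerate_dense(g, Q, self.params(0.6, 0.001)):
                for u, v in itertools.combinations(m.vertices, 2):
                    assert (
                        v in g.adjacency[u]
                        or g.adjacency[u] & g.adjacency[v]
                    ), "members farther than two edges apart"

    def test_every_module_contains_a_query_vertex(self):
        rng = random.Random(17)
        for _ in range(20):
            g = er_graph(12, 0.5, rng)
            Q = random_query(g, rng, k=3)
            for mu in (0.001, 0.5):
                for m in enumerate_dense(g, Q, self.params(0.75, mu)):
                    assert m.vertices & Q.members

    def test_relaxation_monotonicity(self):
        """Tightening mu (or gamma) only shrinks modules into ones found at
        the looser setting."""
        rng = random.Random(19)
        for _ in range(15):
            g = er_graph(12, 0.5, rng)
            Q = random_query(g, rng)
            for g1, g2, m1, m2 in [
                (0.75, 0.75, 0.9, 0.5),
                (0.75, 0.75, 0.5, 0.001),
                (0.999, 0.75, 0.5, 0.5),
                (0.75, 0.55, 0.5, 0.5),
            ]:
                tight = enumerate_dense(g, Q, self.params(g1, m1))
                loose = enumerate_dense(g, Q, self.params(g2, m2))
                for mt in tight:
                    assert any(
                        mt.vertices <= ml.vertices for ml in loose
                    ), (g1, g2, m1, m2, sorted(mt.vertices))


class TestMaximalityFilter:
    def params(self):
        return Params(0.75, 0.001)

    def test_subset_removed(self):
        g = complete_graph(3)
        out = maximality_filter(
            [{0, 1}, {0, 1, 2}], g, QuerySet(frozenset({0})), self.params()
        )
        assert [sorted(m.vertices) for m in out] == [[0, 1, 2]]

    def test_incomparable_retained(self):
        g = complete_graph(3)
        out = maximality_filter(
            [{0, 1}, {1, 2}], g, QuerySet(frozenset({0})), self.params()
        )
        assert {tuple(sorted(m.vertices)) for m in out} == {(0, 1), (1, 2)}

    def test_empty_input(self):
        g = complete_graph(3)
        assert maximality_filter([], g, QuerySet(frozenset({0})), self.params()) == []

    def test_result_mutually_incomparable(self):
        rng = random.Random(23)
        sets = [frozenset(rng.sample(range(12), rng.randint(1, 6))) for _ in range(40)]
        g = complete_graph(12)
        out = maximality_filter(sets, g, QuerySet(frozenset({0})), self.params())
        for a, b in itertools.combinations([m.vertices for m in out], 2):
            assert not (a < b or b < a)
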
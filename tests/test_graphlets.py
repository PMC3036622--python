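import math

import networkx as nx
import numpy as np
import pytest

from orbitkit.graphlets import (
    N_GRAPHLETS,
    N_ORBITS,
    compute_gdv,
    count_graphlets,
    count_graphlets_oracle,
    orbit_weights,
    signature_similarity,
)

from .conftest import graphlet_index


class TestCatalog:
    def test_thirty_graphlets_seventy_three_orbits(self, catalog):
        assert catalog.n_graphlets == 30
        assert catalog.n_orbits == 73

    def test_graphlets_connected_and_pairwise_nonisomorphic(self, catalog):
        gs = catalog.graphlets
        assert all(nx.is_connected(g) for g in gs)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                if gs[i].number_of_nodes() == gs[j].number_of_nodes():
                    assert not nx.is_isomorphic(gs[i], gs[j])

    def test_ordering_edge_first_then_by_size(self, catalog):
        assert nx.is_isomorphic(catalog.graphlets[0], nx.path_graph(2))
        sizes = [(g.number_of_nodes(), g.number_of_edges())
                 for g in catalog.graphlets]
        assert sizes == sorted(sizes)

    def test_path3_has_two_orbits(self, catalog):
        gid = graphlet_index(catalog, nx.path_graph(3))
        orbits = catalog.orbits_of_graphlet(gid)
        assert len(orbits) == 2
        # the end-node orbit has two members, the middle one
        assert sorted(catalog.orbit_multiplicity(j) for j in orbits) == [1, 2]

    def test_orbits_partition_each_graphlet(self, catalog):
        for gid, g in enumerate(catalog.graphlets):
            members = [
                pos
                for j in catalog.orbits_of_graphlet(gid)
                for pos in catalog.orbits[j][1]
            ]
            assert sorted(members) == list(range(g.number_of_nodes()))


class TestCounting:
    def test_triangle(self, catalog):
        c = count_graphlets(nx.complete_graph(3))
        expect = np.zeros(N_GRAPHLETS, dtype=int)
        expect[graphlet_index(catalog, nx.path_graph(2))] = 3
        expect[graphlet_index(catalog, nx.complete_graph(3))] = 1
        assert (c.counts == expect).all()

    def test_path3(self, catalog):
        c = count_graphlets(nx.path_graph(3))
        assert c[graphlet_index(catalog, nx.path_graph(2))] == 2
        assert c[graphlet_index(catalog, nx.path_graph(3))] == 1
        assert c[graphlet_index(catalog, nx.complete_graph(3))] == 0

    def test_five_cycle(self, catalog):
        c = count_graphlets(nx.cycle_graph(5))
        nonzero = {i: c[i] for i in range(N_GRAPHLETS) if c[i]}
        assert nonzero == {
            graphlet_index(catalog, nx.path_graph(2)): 5,
            graphlet_index(catalog, nx.path_graph(3)): 5,
            graphlet_index(catalog, nx.path_graph(4)): 5,
            graphlet_index(catalog, nx.cycle_graph(5)): 1,
        }

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_clique_closed_forms(self, catalog, n):
        c = count_graphlets(nx.complete_graph(n))
        for k in (2, 3, 4, 5):
            gid = graphlet_index(catalog, nx.complete_graph(k))
            assert c[gid] == math.comb(n, k)
        assert c.total == sum(math.comb(n, k) for k in (2, 3, 4, 5))

    def test_edge_count_is_graphlet_zero(self):
        g = nx.gnm_random_graph(20, 50, seed=4)
        assert count_graphlets(g)[0] == 50

    def test_small_and_empty_graphs(self):
        assert count_graphlets(nx.Graph()).total == 0
        assert count_graphlets(nx.path_graph(2)).total == 1

    def test_oracle_on_k4(self, catalog):
        c = count_graphlets_oracle(nx.complete_graph(4))
        assert c[graphlet_index(catalog, nx.path_graph(2))] == 6
        assert c[graphlet_index(catalog, nx.complete_graph(3))] == 4
        assert c[graphlet_index(catalog, nx.complete_graph(4))] == 1
        assert c.total == 11


class TestGDV:
    def test_component_zero_is_degree(self):
        g = nx.gnm_random_graph(15, 40, seed=2)
        gdv = compute_gdv(g)
        for i, u in enumerate(gdv.nodes):
            assert gdv.matrix[i, 0] == g.degree(u)

    def test_star_centre(self, catalog):
        g = nx.star_graph(3)  # K1,3; node 0 is the centre
        gdv = compute_gdv(g)
        centre = gdv.row(0)
        p3_gid = graphlet_index(catalog, nx.path_graph(3))
        p3_mid = [j for j in catalog.orbits_of_graphlet(p3_gid)
                  if catalog.orbit_multiplicity(j) == 1][0]
        star_gid = graphlet_index(catalog, nx.star_graph(3))
        star_centre = [j for j in catalog.orbits_of_graphlet(star_gid)
                       if catalog.orbit_multiplicity(j) == 1][0]
        expect = np.zeros(N_ORBITS, dtype=int)
        expect[0] = 3
        expect[p3_mid] = 3
        expect[star_centre] = 1
        assert (centre == expect).all()

    def test_k4_rows(self, catalog):
        gdv = compute_gdv(nx.complete_graph(4))
        tri = catalog.orbits_of_graphlet(graphlet_index(catalog, nx.complete_graph(3)))[0]
        k4 = catalog.orbits_of_graphlet(graphlet_index(catalog, nx.complete_graph(4)))[0]
        for row in gdv.matrix:
            assert row[0] == 3 and row[tri] == 3 and row[k4] == 1
            assert row.sum() == 7

    def test_orbit_sums_match_counts(self, catalog):
        g = nx.gnm_random_graph(14, 35, seed=9)
        gdv, counts = compute_gdv(g), count_graphlets(g)
        for j in range(N_ORBITS):
            gid = catalog.graphlet_of_orbit(j)
            assert gdv.matrix[:, j].sum() == catalog.orbit_multiplicity(j) * counts[gid]


class TestOracleEquivalence:
    def test_fast_counter_matches_oracle(self, random_graphs):
        assert len(random_graphs) >= 200
        for g in random_graphs:
            fast = count_graphlets(g).counts
            slow = count_graphlets_oracle(g).counts
            assert (fast == slow).all(), nx.to_dict_of_lists(g)


class TestSignatureSimilarity:
    def test_weights_positive_and_bounded(self):
        w = orbit_weights()
        assert (w.o >= 1).all() and (w.o <= 73).all()
        assert (w.w > 0).all() and (w.w <= 1).all()
        assert w.o[0] == 1 and w.w[0] == 1.0  # the edge orbit depends only on itself

    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(5)
        u = rng.integers(0, 50, N_ORBITS)
        v = rng.integers(0, 50, N_ORBITS)
        assert signature_similarity(u, u) == pytest.approx(1.0)
        assert signature_similarity(u, v) == pytest.approx(signature_similarity(v, u))

    def test_zero_vectors_identical(self):
        z = np.zeros(N_ORBITS, dtype=int)
        assert signature_similarity(z, z) == pytest.approx(1.0)

    def test_bounded_and_discriminative(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            u = rng.integers(0, 30, N_ORBITS)
            v = rng.integers(0, 30, N_ORBITS)
            s = signature_similarity(u, v)
            assert 0.0 <= s <= 1.0
            if not (u == v).all():
                assert s < 1.0  # strictly positive weights separate unequal vectors
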
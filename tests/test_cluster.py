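import networkx as nx
import numpy as np
import pytest

from orbitkit.cluster import (
    DistanceMatrix,
    kmedoids,
    random_partition,
    read_distance_matrix,
    similarity_matrix,
    write_distance_matrix,
)
from orbitkit.graphlets import compute_gdv


@pytest.fixture(scope="module")
def two_block_dm():
    """Signature distances of a clique and a cycle joined by one bridge.

    Signatures encode local topological role, so the two blocks must be
    structurally different to be separable (two identical cliques have
    identical signatures).
    """
    g = nx.disjoint_union(nx.complete_graph(8), nx.cycle_graph(8))
    g.add_edge(0, 8)
    return g, similarity_matrix(compute_gdv(g))


class TestSimilarityMatrix:
    def test_square_symmetric_zero_diagonal(self):
        g = nx.gnm_random_graph(12, 25, seed=1)
        dm = similarity_matrix(compute_gdv(g))
        assert dm.is_square
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert dm.values.min() >= 0 and dm.values.max() <= 1

    def test_cross_network_diagonal_zero_for_copies(self):
        g = nx.gnm_random_graph(10, 20, seed=2)
        dm = similarity_matrix(compute_gdv(g), compute_gdv(g.copy()))
        assert not dm.is_square or True
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_rectangular_shape(self):
        a = compute_gdv(nx.path_graph(4))
        b = compute_gdv(nx.cycle_graph(6))
        dm = similarity_matrix(a, b)
        assert dm.values.shape == (4, 6)


class TestKMedoids:
    def test_k_equals_n_all_singletons(self):
        g = nx.gnm_random_graph(8, 14, seed=3)
        dm = similarity_matrix(compute_gdv(g))
        res = kmedoids(dm, k=8, seed=0)
        assert res.objective == pytest.approx(0.0)
        assert sorted(res.medoids) == sorted(dm.row_labels)

    def test_k1_matches_brute_force(self):
        g = nx.gnm_random_graph(12, 30, seed=4)
        dm = similarity_matrix(compute_gdv(g))
        res = kmedoids(dm, k=1, seed=5)
        brute = dm.row_labels[int(np.argmin(dm.values.sum(axis=1)))]
        assert res.medoids == (brute,)
        assert res.objective == pytest.approx(dm.values.sum(axis=1).min())

    def test_two_block_structure_recovered(self, two_block_dm):
        g, dm = two_block_dm
        for seed in range(5):
            res = kmedoids(dm, k=2, seed=seed)
            # bridge endpoints 0 and 8 have hybrid signatures; skip them
            left = {res.assignment[i] for i in range(1, 8)}
            right = {res.assignment[i] for i in range(9, 16)}
            assert len(left) == 1 and len(right) == 1 and left != right

    def test_every_node_assigned_and_medoids_self_assigned(self):
        g = nx.gnm_random_graph(15, 35, seed=6)
        dm = similarity_matrix(compute_gdv(g))
        res = kmedoids(dm, k=4, seed=7)
        assert set(res.assignment) == set(dm.row_labels)
        for ci, med in enumerate(res.medoids):
            assert res.assignment[med] == ci

    def test_k_out_of_range_rejected(self):
        dm = DistanceMatrix(("a", "b"), ("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            kmedoids(dm, k=3)

    def test_rectangular_matrix_rejected(self):
        dm = DistanceMatrix(("a",), ("x", "y"), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            kmedoids(dm, k=1)

    def test_permutation_invariance_up_to_relabelling(self):
        g = nx.gnm_random_graph(12, 28, seed=8)
        dm = similarity_matrix(compute_gdv(g))
        perm = np.random.default_rng(9).permutation(12)
        dm2 = DistanceMatrix(
            tuple(dm.row_labels[i] for i in perm),
            tuple(dm.col_labels[i] for i in perm),
            dm.values[np.ix_(perm, perm)],
        )
        r1 = kmedoids(dm, k=3, seed=10)
        # same medoid set reachable: check objective equality from the same start
        start = [list(dm2.row_labels).index(m) for m in r1.medoids]
        # run with medoids forced by constructing a k=|start| run from same seed is
        # not exposed; instead verify objective is permutation-consistent
        r2 = kmedoids(dm2, k=3, seed=10)
        obj_cross = 0.0
        for node, c in r1.assignment.items():
            i = list(dm2.row_labels).index(node)
            j = list(dm2.row_labels).index(r1.medoids[c])
            obj_cross += dm2.values[i, j]
        assert obj_cross == pytest.approx(r1.objective)


class TestRandomPartition:
    def test_k_equals_n_is_permutation(self):
        res = random_partition(list("abcdef"), k=6, seed=1)
        assert sorted(res.assignment.values()) == list(range(6))

    def test_all_clusters_nonempty(self):
        for seed in range(100):
            res = random_partition(range(17), k=5, seed=seed)
            assert set(res.assignment.values()) == set(range(5))

    def test_fixed_seed_reproducible(self):
        a = random_partition(range(20), k=4, seed=3)
        b = random_partition(range(20), k=4, seed=3)
        assert a.assignment == b.assignment


class TestMatrixIO:
    def test_square_round_trip(self):
        g = nx.path_graph(3)
        dm = similarity_matrix(compute_gdv(g))
        back = read_distance_matrix(write_distance_matrix(dm, "csv"))
        assert tuple(map(str, dm.row_labels)) == back.row_labels
        assert np.allclose(dm.values, back.values)

    def test_rectangular_round_trip_tsv(self):
        a = compute_gdv(nx.path_graph(4))
        b = compute_gdv(nx.cycle_graph(5))
        dm = similarity_matrix(a, b)
        back = read_distance_matrix(write_distance_matrix(dm, "tsv"))
        assert back.values.shape == (4, 5)
        assert np.allclose(dm.values, back.values)

    def test_bad_matrices_rejected(self):
        with pytest.raises(ValueError):
            read_distance_matrix("node,a\nx,0.1,0.2\n")  # ragged
        with pytest.raises(ValueError):
            read_distance_matrix("node,a\nx,frog\n")  # non-numeric
        with pytest.raises(ValueError):
            read_distance_matrix("node,a\nx,-0.5\n")  # negative entry
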
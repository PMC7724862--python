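import numpy as np
import pytest

from basinselect import (ValidationError, assign_basins, build_nn_graph,
                         find_local_minima, pairwise_distance)
from basinselect.landscape import (NNGraph, distance_matrix, pose_common_frame,
                                   superpose)
from conftest import make_ensemble, random_ensemble


# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)


def brute_force_minima(graph, energies):
    out = []
    for u in range(graph.n_vertices):
        if all(energies[u] <= energies[v] for v in graph.adjacency[u]):
            out.append(u)
    return sorted(out)


def brute_force_descend(graph, energies, u):
    """Follow the maximal-ratio gradient one vertex at a time (recursive)."""
    nbrs = list(graph.adjacency[u])
    if all(energies[u] <= energies[v] for v in nbrs):
        return u
    best_v, best_ratio = None, -np.inf
    for v in nbrs:
        d = graph.dist[u, v]
        if d == 0:
            ratio = np.inf if energies[v] < energies[u] else -np.inf
        else:
            ratio = (energies[u] - energies[v]) / d
        if ratio > best_ratio:  # strict: first max wins -> smallest index
            best_ratio, best_v = ratio, v
    return brute_force_descend(graph, energies, best_v)


def kabsch_oracle_rmsd(A, B):
    """Independent optimal-superposition RMSD via scipy's rotation solver."""
    from scipy.spatial.transform import Rotation
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    rot, _ = Rotation.align_vectors(B, A)
    return float(np.sqrt(np.mean(np.sum((rot.apply(A) - B) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# distances


def test_identical_structures_have_zero_distance(rng):
    ens = random_ensemble(rng, n=3)
    ens.coords[1] = ens.coords[0]
    assert pairwise_distance(ens, 0, 1) == 0.0
    assert pairwise_distance(ens, 2, 2) == 0.0


def test_single_atom_euclidean_345():
    ens = make_ensemble(np.array([[0.0, 0.0], [3.0, 4.0]]), [0.0, 1.0])
    assert pairwise_distance(ens, 0, 1) == pytest.approx(5.0)


def test_common_frame_matches_superposition_oracle(rng):
    """Posing every structure onto decoy 0 reproduces the independent
    optimal-superposition RMSD against that reference."""
    n_atoms = 10
    coords = rng.normal(scale=5, size=(6, n_atoms, 3))
    ens = make_ensemble(np.zeros((6, 1)), np.zeros(6))
    ens.coords = coords
    ens.distance_spec = "common-frame-rmsd"
    for i in range(1, 6):
        d = pairwise_distance(ens, 0, i)
        assert d == pytest.approx(kabsch_oracle_rmsd(coords[i], coords[0]), abs=1e-6)
    # full-matrix path agrees with the pairwise path
    D = distance_matrix(ens)
    ens2 = make_ensemble(np.zeros((6, 1)), np.zeros(6))
    ens2.coords = coords
    ens2.distance_spec = "common-frame-rmsd"
    for i in range(6):
        for j in range(6):
            assert D[i, j] == pytest.approx(pairwise_distance(ens2, i, j), abs=1e-9)


def test_superpose_is_rigid_motion_invariant(rng):
    from scipy.spatial.transform import Rotation
    A = rng.normal(size=(12, 3))
    R = Rotation.random(random_state=4).as_matrix()
    moved = A @ R.T + np.array([5.0, -3.0, 1.0])
    posed = superpose(moved, A)
    np.testing.assert_allclose(posed, A, atol=1e-9)


def test_precomputed_matrix_lookup():
    D = np.array([[0.0, 2.0, 7.0], [2.0, 0.0, 3.0], [7.0, 3.0, 0.0]])
    ens = make_ensemble(np.zeros((3, 1)), [0, 1, 2])
    ens.coords = None
    ens.distance_spec = "matrix"
    ens.dist_matrix = D
    assert pairwise_distance(ens, 0, 2) == 7.0


# ---------------------------------------------------------------------------
# graph construction


def test_two_decoys_within_initial_cutoff():
    ens = make_ensemble(np.array([[0.0], [0.5]]), [0.0, 1.0])
    g = build_nn_graph(ens, epsilon0=1.0)
    assert g.epsilon == 1.0
    assert g.n_edges == 1


def test_epsilon_escalates_until_connected():
    ens = make_ensemble(np.array([0.0, 1.0, 2.0, 10.0]), [0, 1, 2, 3])
    g = build_nn_graph(ens, epsilon0=1.0, step=0.5)
    assert g.epsilon == pytest.approx(8.0)
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    adj = np.zeros((4, 4), dtype=bool)
    for u, v in g.edges():
        adj[u, v] = adj[v, u] = True
    assert connected_components(csr_matrix(adj), directed=False)[0] == 1


@pytest.mark.parametrize("seed", range(10))
def test_graph_connected_and_consistent_with_epsilon(seed):
    rng = np.random.default_rng(seed)
    ens = random_ensemble(rng)
    g = build_nn_graph(ens)
    D = g.dist
    for u in range(g.n_vertices):
        expected = np.flatnonzero((D[u] <= g.epsilon)
                                  & (np.arange(g.n_vertices) != u))
        np.testing.assert_array_equal(g.adjacency[u], expected)
    assert g.epsilon <= D.max() + 1e-12 or g.epsilon == 1.0


def test_k_cap_keeps_graph_connected_and_sparser(rng):
    ens = random_ensemble(rng, n=30)
    full = build_nn_graph(ens)
    capped = build_nn_graph(ens, k_cap=3)
    assert capped.n_edges <= full.n_edges
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    n = capped.n_vertices
    adj = np.zeros((n, n), dtype=bool)
    for u, v in capped.edges():
        adj[u, v] = adj[v, u] = True
    assert connected_components(csr_matrix(adj), directed=False)[0] == 1


def test_duplicate_points_are_legal():
    ens = make_ensemble(np.zeros((3, 1)), [0.0, 1.0, 2.0])
    g = build_nn_graph(ens)
    assert g.n_edges == 3  # complete graph on equal points


def test_non_finite_distance_rejected():
    ens = make_ensemble(np.zeros((2, 1)), [0.0, 1.0])
    ens.coords[1, 0, 0] = np.nan
    with pytest.raises(ValidationError):
        build_nn_graph(ens)


# ---------------------------------------------------------------------------
# local minima and basins


def _graph_from_points(points, epsilon0=1.0):
    ens = make_ensemble(points, np.zeros(len(points)))
    return build_nn_graph(ens, epsilon0=epsilon0)


def test_path_graph_single_minimum():
    g = _graph_from_points(np.array([0.0, 1.0, 2.0]))
    minima = find_local_minima(g, np.array([3.0, 1.0, 2.0]))
    np.testing.assert_array_equal(minima, [1])


def test_equal_energy_neighbors_are_both_minima():
    g = _graph_from_points(np.array([0.0, 1.0]))
    minima = find_local_minima(g, np.array([2.0, 2.0]))
    np.testing.assert_array_equal(minima, [0, 1])


def test_descent_chain_single_basin():
    g = _graph_from_points(np.array([0.0, 1.0, 2.0]))
    decomp = assign_basins(g, np.array([3.0, 2.0, 1.0]))
    assert decomp.n_basins == 1
    assert decomp.basins[0].focal_minimum == 2
    np.testing.assert_array_equal(decomp.basins[0].members, [0, 1, 2])


def test_descent_follows_maximal_ratio_not_steepest_drop():
    # u at 0 with v1 at distance 2 (f=1, ratio 1.0) and v2 at 0.5 (f=2, ratio 2.0)
    ens = make_ensemble(np.array([0.0, 2.0, -0.5]), [3.0, 1.0, 2.0])
    g = build_nn_graph(ens, epsilon0=2.5)
    from basinselect.landscape import _descent_successor
    assert _descent_successor(g, np.array([3.0, 1.0, 2.0]), 0) == 2


@pytest.mark.parametrize("seed", range(15))
def test_basin_oracle_equivalence_random_landscapes(seed):
    """assign_basins matches the naive recursive descent, and the partition
    invariants hold, on random landscapes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 120))
    ens = make_ensemble(rng.normal(scale=2.0, size=(n, 2)), rng.normal(size=n))
    g = build_nn_graph(ens)
    energies = ens.energies
    decomp = assign_basins(g, energies)
    minima = brute_force_minima(g, energies)
    assert sorted(b.focal_minimum for b in decomp.basins) == minima
    assert decomp.n_basins == len(minima)
    # exhaustive per-vertex oracle
    for u in range(n):
        target = brute_force_descend(g, energies, u)
        assert decomp.basins[decomp.assignment[u]].focal_minimum == target
    # partition invariants
    sizes = sum(b.size for b in decomp.basins)
    assert sizes == n
    for b in decomp.basins:
        assert b.focal_minimum in b.members
        assert b.focal_energy == pytest.approx(energies[b.members].min())


def test_zero_distance_descent_uses_infinite_ratio():
    # duplicate points: strictly lower duplicate wins over any finite ratio
    ens = make_ensemble(np.array([0.0, 0.0, 5.0]), [3.0, 1.0, 0.0])
    g = build_nn_graph(ens, epsilon0=6.0)
    decomp = assign_basins(g, ens.energies)
    # vertex 0 jumps to its zero-distance twin (f=1), not the distant f=0
    assert decomp.assignment[0] == decomp.assignment[1]
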
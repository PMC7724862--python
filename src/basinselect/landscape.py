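"""Nearest-neighbor-graph view of a decoy ensemble and its basin decomposition.

A decoy ensemble Ω with an energy (fitness) f and a pairwise distance d is
embedded in a graph G=(V,E): vertices are decoys and (u,v) is an edge iff
d(u,v) ≤ ε.  The cutoff starts at 1 Å and is raised on a fixed ladder until
the graph is connected, since sparse sampling at small ε can disconnect it.
A vertex u is a local minimum iff f(u) ≤ f(v) for every neighbor v.  Every
other vertex follows its steepest negative gradient — the edge maximizing
[f(u)−f(v)]/d(u,v) — until a local minimum is reached; vertices draining to
the same minimum form that minimum's basin of attraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io_formats import ConfigurationError, Ensemble, ValidationError


# ---------------------------------------------------------------------------
# distances


def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix R minimizing ||P@R - Q|| for centered P, Q (Kabsch)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimally superpose ``mobile`` onto ``reference`` (rotation+translation
    minimizing RMSD) and return the posed copy."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    R = _kabsch_rotation(mobile - mc, reference - rc)
    return (mobile - mc) @ R + rc


def _coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def pose_common_frame(coords: np.ndarray) -> np.ndarray:
    """Superpose every structure onto the first in the ensemble (the common
    reference frame) and return the posed stack."""
    posed = np.empty_like(coords)
    posed[0] = coords[0]
    for i in range(1, coords.shape[0]):
        posed[i] = superpose(coords[i], coords[0])
    return posed


def distance_matrix(ensemble: Ensemble) -> np.ndarray:
    """Full symmetric pairwise-distance matrix under the ensemble's
    distance_spec. Cached on the ensemble after first computation."""
    if ensemble.dist_matrix is not None:
        return ensemble.dist_matrix
    if ensemble.coords is None:
        raise ConfigurationError(
            f"distance_spec={ensemble.distance_spec!r} requires coordinates")
    n, m, _ = ensemble.coords.shape
    if ensemble.distance_spec == "euclidean":
        flat = ensemble.coords.reshape(n, 3 * m)
        D = squareform(pdist(flat) / np.sqrt(m))
    elif ensemble.distance_spec == "common-frame-rmsd":
        posed = pose_common_frame(ensemble.coords).reshape(n, 3 * m)
        D = squareform(pdist(posed) / np.sqrt(m))
    else:  # pragma: no cover - post_init guarantees matrix present
        raise ConfigurationError(f"unresolvable distance_spec {ensemble.distance_spec!r}")
    ensemble.dist_matrix = D
    return D


def pairwise_distance(ensemble: Ensemble, u: int, v: int) -> float:
    """Distance between decoys u and v. Euclidean mode is per-atom RMS of the
    raw coordinates; common-frame mode superposes each structure onto decoy 0
    first; matrix mode is a lookup."""
    if u == v:
        return 0.0
    if ensemble.dist_matrix is not None:
        return float(ensemble.dist_matrix[u, v])
    if ensemble.coords is None:
        raise ConfigurationError("no coordinates or distance matrix available")
    if ensemble.distance_spec == "euclidean":
        return _coord_rmsd(ensemble.coords[u], ensemble.coords[v])
    if ensemble.distance_spec == "common-frame-rmsd":
        ref = ensemble.coords[0]
        pu = ensemble.coords[u] if u == 0 else superpose(ensemble.coords[u], ref)
        pv = ensemble.coords[v] if v == 0 else superpose(ensemble.coords[v], ref)
        return _coord_rmsd(pu, pv)
    raise ConfigurationError(f"unresolvable distance_spec {ensemble.distance_spec!r}")


# ---------------------------------------------------------------------------
# graph construction


@dataclass
class NNGraph:
    """ε-nearest-neighbor graph over a decoy ensemble.

    ``adjacency[u]`` is the sorted array of neighbors N(u); ``dist`` the full
    pairwise matrix the graph was thresholded from.
    """

    n_vertices: int
    epsilon: float
    dist: np.ndarray
    adjacency: list[np.ndarray]

    def neighbors(self, u: int) -> np.ndarray:
        return self.adjacency[u]

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def edges(self):
        """Iterate undirected edges (u, v), u < v."""
        for u, nbrs in enumerate(self.adjacency):
            for v in nbrs[nbrs > u]:
                yield u, int(v)


def _is_connected(adjacency_bool: np.ndarray) -> bool:
    ncomp, _ = connected_components(csr_matrix(adjacency_bool), directed=False)
    return ncomp == 1


def _minimax_connectivity_eps(D: np.ndarray) -> float:
    """Largest MST edge = smallest cutoff at which the ε-graph is connected
    (minimax path property). Dense Prim scan: O(n²) and allocation-free per
    step, much faster than sparse MST routines on a full matrix."""
    n = D.shape[0]
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    min_edge = D[0].copy()
    min_edge[0] = np.inf
    bottleneck = 0.0
    for _ in range(n - 1):
        j = int(np.argmin(min_edge))
        bottleneck = max(bottleneck, float(min_edge[j]))
        in_tree[j] = True
        np.minimum(min_edge, D[j], out=min_edge)
        min_edge[in_tree] = np.inf
    return bottleneck


def _cap_adjacency(D: np.ndarray, eps: float, k_cap: int) -> np.ndarray:
    """Boolean adjacency at cutoff eps where each vertex keeps at most its
    k_cap nearest neighbors; an edge survives if either endpoint keeps it."""
    n = D.shape[0]
    within = (D <= eps)
    np.fill_diagonal(within, False)
    keep = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for u in range(n):
        nbrs = np.flatnonzero(within[u])
        if len(nbrs) > k_cap:
            order = np.lexsort((nbrs, D[u, nbrs]))  # distance, then index
            nbrs = nbrs[order[:k_cap]]
        keep[u, nbrs] = True
    return keep | keep.T


def build_nn_graph(ensemble: Ensemble, epsilon0: float = 1.0, step: float = 0.5,
                   k_cap: Optional[int] = None) -> NNGraph:
    """Build the ε-graph at the smallest cutoff in the ladder epsilon0,
    epsilon0+step, … for which the graph is connected.

    With ``k_cap`` set, each vertex keeps only its k_cap nearest neighbors
    (an edge is kept if either endpoint selects it) and connectivity is
    re-checked on the capped graph, escalating further if capping
    disconnected it.
    """
    if ensemble.size < 2:
        raise ValidationError("need at least 2 decoys")
    if epsilon0 <= 0 or step <= 0:
        raise ConfigurationError("epsilon0 and step must be positive")
    D = distance_matrix(ensemble)
    if not np.all(np.isfinite(D)):
        raise ValidationError("non-finite pairwise distance")
    eps_needed = _minimax_connectivity_eps(D)
    n_steps = max(0, int(np.ceil((eps_needed - epsilon0) / step - 1e-12)))
    eps = epsilon0 + n_steps * step
    if k_cap is not None:
        while True:
            adj = _cap_adjacency(D, eps, int(k_cap))
            if _is_connected(adj):
                break
            eps += step
    else:
        adj = (D <= eps)
        np.fill_diagonal(adj, False)
    adjacency = [np.flatnonzero(adj[u]) for u in range(ensemble.size)]
    return NNGraph(n_vertices=ensemble.size, epsilon=float(eps), dist=D,
                   adjacency=adjacency)


# ---------------------------------------------------------------------------
# local minima and basins


def find_local_minima(graph: NNGraph, energies: np.ndarray) -> np.ndarray:
    """Indices u with f(u) ≤ f(v) for every neighbor v (≤ admits ties, so
    adjacent equal-energy vertices are each a minimum)."""
    energies = np.asarray(energies, dtype=float)
    if len(energies) != graph.n_vertices:
        raise ValidationError("energies length does not match graph")
    out = []
    for u in range(graph.n_vertices):
        nbrs = graph.adjacency[u]
        if len(nbrs) == 0 or np.all(energies[u] <= energies[nbrs]):
            out.append(u)
    return np.asarray(out, dtype=int)


@dataclass
class Basin:
    """A basin of attraction: the vertices whose gradient descent reaches the
    basin's focal (local) minimum."""

    basin_id: int
    focal_minimum: int
    members: np.ndarray
    focal_energy: float

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class BasinDecomposition:
    basins: list[Basin]
    assignment: np.ndarray  # decoy index -> basin_id

    @property
    def n_basins(self) -> int:
        return len(self.basins)

    def basin(self, basin_id: int) -> Basin:
        return self.basins[basin_id]


def _descent_successor(graph: NNGraph, energies: np.ndarray, u: int) -> int:
    """Neighbor maximizing [f(u)−f(v)]/d(u,v); ties to the smallest index.
    Zero-distance edges count as ratio +inf toward strictly lower energy and
    are skipped otherwise."""
    nbrs = graph.adjacency[u]
    drop = energies[u] - energies[nbrs]
    d = graph.dist[u, nbrs]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, drop / np.where(d > 0, d, 1.0),
                         np.where(drop > 0, np.inf, -np.inf))
    best = int(np.argmax(ratio))  # first occurrence = smallest neighbor index
    return int(nbrs[best])


def assign_basins(graph: NNGraph, energies: np.ndarray) -> BasinDecomposition:
    """Partition all vertices into basins by maximal-ratio gradient descent.

    Every non-minimum has a strictly lower neighbor, so f strictly decreases
    along each descent step and paths terminate; this is asserted per step.
    """
    energies = np.asarray(energies, dtype=float)
    if len(energies) != graph.n_vertices:
        raise ValidationError("energies length does not match graph")
    n = graph.n_vertices
    minima = find_local_minima(graph, energies)
    is_min = np.zeros(n, dtype=bool)
    is_min[minima] = True
    succ = np.full(n, -1, dtype=int)
    for u in range(n):
        if not is_min[u]:
            v = _descent_successor(graph, energies, u)
            if energies[v] >= energies[u]:  # termination guard; impossible
                raise RuntimeError("descent step did not strictly decrease f")
            succ[u] = v
    # resolve descent paths by pointer jumping
    root = np.where(is_min, np.arange(n), succ)
    while True:
        nxt = np.where(is_min[root], root, root[root])
        if np.array_equal(nxt, root):
            break
        root = nxt
    # number basins by ascending focal-minimum index
    minima_sorted = np.sort(minima)
    basin_of_min = {int(m): i for i, m in enumerate(minima_sorted)}
    assignment = np.array([basin_of_min[int(r)] for r in root], dtype=int)
    basins = []
    for bid, m in enumerate(minima_sorted):
        members = np.flatnonzero(assignment == bid)
        basins.append(Basin(basin_id=bid, focal_minimum=int(m), members=members,
                            focal_energy=float(energies[m])))
    return BasinDecomposition(basins=basins, assignment=assignment)
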
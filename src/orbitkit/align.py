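"""Seed-and-extend global network alignment (GRAAL).

GRAAL aligns two networks using topology alone.  Every node of the smaller
network G is mapped injectively to a node of the larger network H, so the
alignment is an embedding of G into H.  Node pairs are scored by the cost

    C(u, v) = 2 - [(1 - alpha) * (deg(u) + deg(v)) / (maxdeg(G) + maxdeg(H))
                   + alpha * S(u, v)]

where S(u, v) is the graphlet signature similarity and alpha (default 0.8)
weights signature against degree information; lower cost means a better
match.

The algorithm repeatedly (1) seeds with the cheapest unaligned pair and
(2) extends outward breadth-first around the seed: spheres of radius
r = 1, 2, 3 are grown simultaneously in both networks, and within each
radius the unaligned neighbours of each already-aligned pair are matched
greedily in ascending cost order, so the extension walks both networks in
lock-step and tends to map edges onto edges.  When a pass leaves G-nodes
unaligned, seeding and extension are retried on the power graphs G^p, H^p
(edges join nodes within distance <= p) for p = 1, 2, 3 cyclically, which
lets the alignment jump over structural mismatches; every round aligns at
least the seed pair, so the alignment is always total.  Signatures and
degrees are always taken from the original graphs; power graphs only guide
the traversal.

Alignment quality is reported as *edge correctness*: the percentage of
G's edges mapped onto edges of H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graphlets import compute_gdv, orbit_weights, N_ORBITS

__all__ = ["AlignmentParams", "Alignment", "alignment_cost_matrix", "graal_align",
           "edge_correctness"]


@dataclass(frozen=True)
class AlignmentParams:
    alpha: float = 0.8       # weight of the signature term vs the degree term
    seed: int = 0            # RNG seed for tie-breaking
    max_radius: int = 3      # BFS sphere radius per seed round
    max_power: int = 3       # largest power graph used for re-seeding

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class Alignment:
    mapping: dict            # node of G -> node of H, total and injective
    edge_correctness: float  # percentage in [0, 100]
    swapped: bool = field(default=False)  # True if inputs were swapped so |G| <= |H|


def _similarity_matrix(gdv_g: np.ndarray, gdv_h: np.ndarray) -> np.ndarray:
    """All-to-all signature similarity, vectorised over node pairs."""
    w = orbit_weights().w
    lg = np.log(gdv_g + 1.0)  # (nG, 73)
    lh = np.log(gdv_h + 1.0)  # (nH, 73)
    num = np.abs(lg[:, None, :] - lh[None, :, :])
    den = np.log(np.maximum(gdv_g[:, None, :], gdv_h[None, :, :]) + 2.0)
    d = np.tensordot(num / den, w, axes=([2], [0])) / w.sum()
    return 1.0 - d


def alignment_cost_matrix(g: nx.Graph, h: nx.Graph,
                          params: AlignmentParams = AlignmentParams()) -> np.ndarray:
    """Cost C(u, v) for every node pair, rows = G nodes, cols = H nodes."""
    gdv_g = compute_gdv(g).matrix.astype(float)
    gdv_h = compute_gdv(h).matrix.astype(float)
    sim = _similarity_matrix(gdv_g, gdv_h)
    deg_g = np.array([d for _, d in g.degree()], dtype=float)
    deg_h = np.array([d for _, d in h.degree()], dtype=float)
    max_sum = max(deg_g.max(initial=0.0) + deg_h.max(initial=0.0), 1.0)
    deg_term = (deg_g[:, None] + deg_h[None, :]) / max_sum
    return 2.0 - ((1.0 - params.alpha) * deg_term + params.alpha * sim)


def _power_adjacency(g: nx.Graph, nodes: list, p: int) -> list[set[int]]:
    """Index-based adjacency of g^p (nodes within distance <= p)."""
    index = {u: i for i, u in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in nodes]
    for u in nodes:
        lengths = nx.single_source_shortest_path_length(g, u, cutoff=p)
        ui = index[u]
        for v, d in lengths.items():
            if 0 < d <= p:
                adj[ui].add(index[v])
    return adj


def graal_align(g: nx.Graph, h: nx.Graph,
                params: AlignmentParams = AlignmentParams()) -> Alignment:
    """Globally align the smaller of (g, h) into the larger one."""
    if g.number_of_nodes() == 0 or h.number_of_nodes() == 0:
        raise ValueError("cannot align an empty network")
    swapped = g.number_of_nodes() > h.number_of_nodes()
    if swapped:
        g, h = h, g
    nodes_g, nodes_h = list(g.nodes()), list(h.nodes())
    n_g, n_h = len(nodes_g), len(nodes_h)
    cost = alignment_cost_matrix(g, h, params)
    rng = np.random.default_rng(int(params.seed))
    # fixed random priorities give deterministic, seed-controlled tie-breaks
    tie = rng.random((n_g, n_h))

    aligned_g: dict[int, int] = {}   # G index -> H index
    used_h: set[int] = set()
    power = 0
    while len(aligned_g) < n_g:
        p = power % params.max_power + 1
        power += 1
        adj_g = _power_adjacency(g, nodes_g, p)
        adj_h = _power_adjacency(h, nodes_h, p)

        free_g = [i for i in range(n_g) if i not in aligned_g]
        free_h = [j for j in range(n_h) if j not in used_h]
        sub = cost[np.ix_(free_g, free_h)] + 1e-9 * tie[np.ix_(free_g, free_h)]
        si, sj = np.unravel_index(np.argmin(sub), sub.shape)
        seed_pair = (free_g[si], free_h[sj])
        aligned_g[seed_pair[0]] = seed_pair[1]
        used_h.add(seed_pair[1])

        # breadth-first extension: match unaligned neighbours of each
        # aligned pair, radius by radius around the seed
        frontier = [seed_pair]
        for _radius in range(params.max_radius):
            next_frontier: list[tuple[int, int]] = []
            for (a, b) in frontier:
                cand_g = [x for x in adj_g[a] if x not in aligned_g]
                cand_h = [y for y in adj_h[b] if y not in used_h]
                if not cand_g or not cand_h:
                    continue
                pairs = sorted(
                    ((cost[x, y] + 1e-9 * tie[x, y], x, y)
                     for x in cand_g for y in cand_h),
                )
                for _, x, y in pairs:
                    if x in aligned_g or y in used_h:
                        continue
                    aligned_g[x] = y
                    used_h.add(y)
                    next_frontier.append((x, y))
            frontier = next_frontier
            if not frontier:
                break

    mapping = {nodes_g[i]: nodes_h[j] for i, j in aligned_g.items()}
    ec = edge_correctness(g, h, mapping)
    return Alignment(mapping=mapping, edge_correctness=ec, swapped=swapped)


def edge_correctness(g: nx.Graph, h: nx.Graph, mapping: dict) -> float:
    """Percentage of g's edges whose images under *mapping* are edges of h."""
    missing = [u for u in g.nodes() if u not in mapping]
    if missing:
        raise ValueError(f"mapping is not total on G ({len(missing)} nodes unmapped)")
    images = list(mapping.values())
    if len(set(images)) != len(images):
        raise ValueError("mapping is not injective")
    if g.number_of_edges() == 0:
        return 100.0
    kept = sum(1 for u, v in g.edges() if h.has_edge(mapping[u], mapping[v]))
    return 100.0 * kept / g.number_of_edges()
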
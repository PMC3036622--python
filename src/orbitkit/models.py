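"""Random network model generators for fitting protein-interaction data.

Seven models, each producing a simple undirected graph matched to a target
size (n nodes, m edges) so that model instances are directly comparable to
a data network of the same size:

* ``ER`` -- uniform random graph with exactly n nodes and m edges.
* ``ER_DD`` -- random graph with a prescribed degree sequence, built by the
  stubs method (each node gets deg stubs; random stub pairs become edges).
* ``SF`` -- scale-free Barabasi-Albert preferential attachment, adjusted
  to exactly m edges.
* ``GEO`` -- geometric random graph: uniform points in the unit d-cube,
  edges between the m closest pairs (radius = m-th smallest distance).
* ``STICKY`` -- stickiness model: node i gets index theta_i = d_i/sqrt(sum d);
  pair {i,j} is an edge independently with probability theta_i*theta_j.
  The edge count is random with expectation ~ sum(d)/2.
* ``SF_GD`` -- scale-free gene duplication and divergence: grow by
  duplicating a random node's neighbourhood, then randomly losing one of
  each duplicated pair's common-neighbour edges with probability q;
  adjusted to exactly m edges.
* ``GEO_GD`` -- geometric gene duplication: points are added near a random
  parent point (probability p) or uniformly (probability 1-p); edges as in
  GEO.

Every generator takes an integer seed and is bit-reproducible.  Generators
whose natural output size is random (SF, SF_GD) are adjusted to exactly m
by uniform random edge insertions/deletions; STICKY is deliberately left at
its natural random size because its defining property is the per-pair edge
probability.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "MODELS",
    "generate",
    "generate_er",
    "generate_er_dd",
    "generate_sf",
    "generate_geo",
    "generate_sticky",
    "generate_sf_gd",
    "generate_geo_gd",
]

MODELS = ("ER", "ER_DD", "SF", "GEO", "STICKY", "SF_GD", "GEO_GD")


def _check_size(n: int, m: int) -> None:
    if n < 0 or m < 0 or m > n * (n - 1) // 2:
        raise ValueError(f"infeasible size: n={n}, m={m}")


def _adjust_edge_count(g: nx.Graph, m: int, rng: np.random.Generator) -> nx.Graph:
    """Uniform random edge insertions/deletions until g has exactly m edges."""
    n = g.number_of_nodes()
    _check_size(n, m)
    nodes = list(g.nodes())
    while g.number_of_edges() > m:
        edges = list(g.edges())
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
    while g.number_of_edges() < m:
        u, v = (nodes[i] for i in rng.choice(n, size=2, replace=False))
        if not g.has_edge(u, v):
            g.add_edge(u, v)
    return g


def generate_er(n: int, m: int, seed: int) -> nx.Graph:
    """Uniform simple graph with exactly n nodes and m edges."""
    _check_size(n, m)
    g = nx.gnm_random_graph(n, m, seed=int(seed))
    g.name = f"ER_n{n}_m{m}_s{seed}"
    return g


def generate_er_dd(degree_sequence: Sequence[int], seed: int,
                   max_restarts: int = 100) -> nx.Graph:
    """Stub-matching random graph with the given degree sequence.

    Stubs are paired uniformly at random; self-loops and duplicate edges
    are rejected and retried.  A dead end (only infeasible stub pairs
    remain) triggers a restart; after ``max_restarts`` dead ends the best
    effort so far is returned, so the realised edge count can fall short of
    sum(d)/2 for hard sequences.
    """
    degrees = [int(d) for d in degree_sequence]
    if any(d < 0 for d in degrees):
        raise ValueError("degrees must be non-negative")
    if sum(degrees) % 2:
        raise ValueError("degree sequence must have even sum")
    rng = np.random.default_rng(int(seed))
    n = len(degrees)
    target_m = sum(degrees) // 2
    best: nx.Graph | None = None
    for _ in range(max_restarts + 1):
        g = nx.Graph(name=f"ER-DD_n{n}_s{seed}")
        g.add_nodes_from(range(n))
        stubs = [i for i, d in enumerate(degrees) for _ in range(d)]
        rejects = 0
        limit = 50 * (len(stubs) + 10)  # bounded dead-end retries
        while len(stubs) >= 2 and rejects < limit:
            a, b = rng.choice(len(stubs), size=2, replace=False)
            u, v = stubs[int(a)], stubs[int(b)]
            if u == v or g.has_edge(u, v):
                rejects += 1
                continue
            g.add_edge(u, v)
            for idx in sorted((int(a), int(b)), reverse=True):
                stubs.pop(idx)
        if best is None or g.number_of_edges() > best.number_of_edges():
            best = g
        if g.number_of_edges() == target_m:
            return g
    assert best is not None
    return best


def generate_sf(n: int, m: int, seed: int) -> nx.Graph:
    """Scale-free preferential-attachment graph with exactly n nodes, m edges."""
    _check_size(n, m)
    if n < 2:
        raise ValueError("SF model needs n >= 2")
    rng = np.random.default_rng(int(seed))
    d = max(1, round(m / n))
    d = min(d, n - 1)
    g = nx.barabasi_albert_graph(n, d, seed=int(seed))
    g = _adjust_edge_count(g, m, rng)
    g.name = f"SF_n{n}_m{m}_s{seed}"
    return g


def _threshold_edges(points: np.ndarray, m: int) -> list[tuple[int, int]]:
    """The m closest point pairs (Euclidean), ties broken by pair index."""
    n = len(points)
    iu, ju = np.triu_indices(n, k=1)
    d2 = np.sum((points[iu] - points[ju]) ** 2, axis=1)
    # lexsort: primary key distance, then (i, j) for deterministic ties
    order = np.lexsort((ju, iu, d2))[:m]
    return [(int(iu[t]), int(ju[t])) for t in order]


def generate_geo(n: int, m: int, dim: int = 3, seed: int = 0) -> nx.Graph:
    """Geometric random graph: uniform points in the unit cube, m closest pairs."""
    _check_size(n, m)
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(int(seed))
    points = rng.random((n, dim))
    g = nx.Graph(name=f"GEO_n{n}_m{m}_d{dim}_s{seed}")
    g.add_nodes_from((i, {"pos": tuple(points[i])}) for i in range(n))
    g.add_edges_from(_threshold_edges(points, m))
    return g


def generate_sticky(degree_sequence: Sequence[int], seed: int) -> nx.Graph:
    """Stickiness-index random graph.

    theta_i = d_i / sqrt(sum_j d_j); pair {i, j} is an edge with
    probability min(1, theta_i * theta_j), independently.  The expected
    degree of node i approximates d_i; the edge count is random.
    """
    degrees = np.asarray(degree_sequence, dtype=float)
    if (degrees < 0).any():
        raise ValueError("degrees must be non-negative")
    n = len(degrees)
    rng = np.random.default_rng(int(seed))
    g = nx.Graph(name=f"STICKY_n{n}_s{seed}")
    g.add_nodes_from(range(n))
    total = degrees.sum()
    if total > 0:
        theta = degrees / np.sqrt(total)
        iu, ju = np.triu_indices(n, k=1)
        p = np.minimum(1.0, theta[iu] * theta[ju])
        hit = rng.random(len(p)) < p
        g.add_edges_from(zip(iu[hit].tolist(), ju[hit].tolist()))
    return g


def generate_sf_gd(n: int, m: int, q: float = 0.5, seed: int = 0,
                   p_link: float = 0.1, adjust: bool = True) -> nx.Graph:
    """Scale-free gene duplication / divergence model.

    Growth starts from a single edge.  Each step duplicates a uniformly
    random node u: the copy v inherits all of u's neighbours, gains the
    edge {u, v} with probability ``p_link``, and then, for every common
    neighbour w, one of the two edges {u, w} / {v, w} (chosen uniformly)
    is deleted with probability q (divergence).  The grown graph is
    finally adjusted to exactly m edges by uniform insertions/deletions.
    """
    if n < 2:
        raise ValueError("SF-GD model needs n >= 2")
    _check_size(n, m)
    if not (0.0 <= q <= 1.0 and 0.0 <= p_link <= 1.0):
        raise ValueError("q and p_link must be probabilities")
    rng = np.random.default_rng(int(seed))
    g = nx.Graph(name=f"SF-GD_n{n}_m{m}_q{q}_s{seed}")
    g.add_edge(0, 1)
    while g.number_of_nodes() < n:
        u = int(rng.integers(g.number_of_nodes()))
        v = g.number_of_nodes()
        neighbours = list(g.neighbors(u))
        g.add_node(v)
        g.add_edges_from((v, w) for w in neighbours)
        if rng.random() < p_link:
            g.add_edge(u, v)
        for w in neighbours:
            if rng.random() < q:
                g.remove_edge(u if rng.random() < 0.5 else v, w)
    if adjust:
        g = _adjust_edge_count(g, m, rng)
    return g


def generate_geo_gd(n: int, m: int, p: float = 0.5, dim: int = 3,
                    seed: int = 0, n_seed_points: int = 5) -> nx.Graph:
    """Geometric gene duplication model (probability-cutoff variant).

    A seed set of uniform points grows one point at a time: a uniformly
    random parent is picked, and with probability p the child is placed
    uniformly inside a small ball around the parent (duplication stays
    local in expression space), otherwise uniformly in the unit cube.  The
    ball radius is twice an a-priori estimate of the connection radius
    needed for m edges.  Edges connect the m closest pairs, as in GEO.
    """
    if n < 2 or dim < 1:
        raise ValueError("GEO-GD model needs n >= 2 and dim >= 1")
    _check_size(n, m)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    rng = np.random.default_rng(int(seed))
    # expected pairs within radius r: C(n,2) * vol(ball_dim(r)) for uniform
    # points; solve for r at the target edge count
    from scipy.special import gamma

    unit_ball = np.pi ** (dim / 2) / gamma(dim / 2 + 1)
    pairs = n * (n - 1) / 2
    r_est = (m / (pairs * unit_ball)) ** (1.0 / dim) if m > 0 else 0.0
    eps = 2.0 * r_est
    s0 = min(n_seed_points, n)
    points = [rng.random(dim) for _ in range(s0)]
    while len(points) < n:
        parent = points[int(rng.integers(len(points)))]
        if rng.random() < p:
            # uniform in the ball of radius eps around the parent, clipped
            # to the unit cube
            direction = rng.normal(size=dim)
            direction /= np.linalg.norm(direction)
            radius = eps * rng.random() ** (1.0 / dim)
            child = np.clip(parent + radius * direction, 0.0, 1.0)
        else:
            child = rng.random(dim)
        points.append(child)
    pts = np.asarray(points)
    g = nx.Graph(name=f"GEO-GD_n{n}_m{m}_p{p}_d{dim}_s{seed}")
    g.add_nodes_from((i, {"pos": tuple(pts[i])}) for i in range(n))
    g.add_edges_from(_threshold_edges(pts, m))
    return g


def generate(model: str, n: int | None = None, m: int | None = None, *,
             degree_sequence: Sequence[int] | None = None, dim: int = 3,
             p: float = 0.5, q: float = 0.5, seed: int = 0) -> nx.Graph:
    """Dispatch to one of the seven model generators by name.

    ER_DD and STICKY are driven by a degree sequence; when only (n, m) is
    given for them, the degree sequence of an ER graph of that size is
    used as the target.
    """
    model = model.upper().replace("-", "_")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model in ("ER_DD", "STICKY"):
        if degree_sequence is None:
            if n is None or m is None:
                raise ValueError(f"{model} needs a degree_sequence or (n, m)")
            template = generate_er(n, m, seed=int(seed) + 1)
            degree_sequence = [template.degree(u) for u in template.nodes()]
            if model == "ER_DD" and sum(degree_sequence) % 2:
                degree_sequence[0] += 1
        if model == "ER_DD":
            return generate_er_dd(degree_sequence, seed)
        return generate_sticky(degree_sequence, seed)
    if n is None or m is None:
        raise ValueError(f"{model} needs n and m")
    if model == "ER":
        return generate_er(n, m, seed)
    if model == "SF":
        return generate_sf(n, m, seed)
    if model == "GEO":
        return generate_geo(n, m, dim=dim, seed=seed)
    if model == "SF_GD":
        return generate_sf_gd(n, m, q=q, seed=seed)
    return generate_geo_gd(n, m, p=p, dim=dim, seed=seed)
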
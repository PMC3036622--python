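"""Graphlet catalog, counting, node signatures and signature similarity.

Graphlets are the small connected induced non-isomorphic subgraphs on 2-5
nodes; there are 30 of them, carrying 73 automorphism orbits in total.  A
node's *signature* (graphlet degree vector, GDV) is the 73-component vector
whose j-th entry counts how many graphlet occurrences touch the node at a
position belonging to orbit j.  Orbit 0 is the edge, so component 0 of any
signature equals the node's degree.

Orbit numbering here is fixed by a deterministic canonical order (node
count, then edge count, then canonical adjacency code; orbits within a
graphlet ordered by their smallest node index in the canonical
representative).  The full catalog can be dumped with
:func:`GraphletCatalog.describe`.

Counting uses ESU-style enumeration of connected induced subgraphs (each
occurrence visited exactly once) with O(1) classification through a
precomputed adjacency-code table; a naive subset-enumeration oracle is
provided for validation on small graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphletCatalog",
    "GraphletCounts",
    "GDVMatrix",
    "OrbitWeights",
    "build_catalog",
    "orbit_weights",
    "count_graphlets",
    "count_graphlets_oracle",
    "compute_gdv",
    "signature_similarity",
]

MAX_GRAPHLET_NODES = 5
N_GRAPHLETS = 30
N_ORBITS = 73


def _pair_bits(k: int) -> dict[tuple[int, int], int]:
    """Bit index for each unordered node-index pair of a k-node graph."""
    return {pair: b for b, pair in enumerate(combinations(range(k), 2))}


def _code_edges(code: int, k: int) -> list[tuple[int, int]]:
    return [pair for pair, b in _pair_bits(k).items() if code >> b & 1]


def _recode(code: int, k: int, perm: Sequence[int]) -> int:
    """Adjacency code after relabelling node i -> perm[i]."""
    bits = _pair_bits(k)
    out = 0
    for (i, j), b in bits.items():
        if code >> b & 1:
            a, c = perm[i], perm[j]
            out |= 1 << bits[(a, c) if a < c else (c, a)]
    return out


def _is_connected_code(code: int, k: int) -> bool:
    adj: list[set[int]] = [set() for _ in range(k)]
    for i, j in _code_edges(code, k):
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for w in adj[u] - seen:
            seen.add(w)
            stack.append(w)
    return len(seen) == k


@dataclass(frozen=True)
class GraphletCatalog:
    """The 30 canonical graphlets on 2-5 nodes and their 73 orbits."""

    graphlets: tuple[nx.Graph, ...]
    #: (graphlet index, node position in canonical representative) -> orbit id
    orbit_of: dict[tuple[int, int], int]
    #: orbit id -> (graphlet index, sorted tuple of member positions)
    orbits: tuple[tuple[int, tuple[int, ...]], ...]
    #: per node count k: adjacency code -> (graphlet id, orbit id per position)
    _lookup: dict[int, dict[int, tuple[int, tuple[int, ...]]]] = field(repr=False)

    @property
    def n_graphlets(self) -> int:
        return len(self.graphlets)

    @property
    def n_orbits(self) -> int:
        return len(self.orbits)

    def orbits_of_graphlet(self, gid: int) -> list[int]:
        return [j for j, (g, _) in enumerate(self.orbits) if g == gid]

    def orbit_multiplicity(self, orbit: int) -> int:
        """Number of nodes per occurrence sitting in this orbit class."""
        return len(self.orbits[orbit][1])

    def graphlet_of_orbit(self, orbit: int) -> int:
        return self.orbits[orbit][0]

    def classify(self, code: int, k: int) -> tuple[int, tuple[int, ...]]:
        """Graphlet id and per-position orbit ids for an adjacency code."""
        return self._lookup[k][code]

    def describe(self) -> str:
        """Human-readable catalog dump (one line per graphlet)."""
        lines = []
        for gid, g in enumerate(self.graphlets):
            orbs = self.orbits_of_graphlet(gid)
            edges = sorted(tuple(sorted(e)) for e in g.edges())
            lines.append(
                f"G{gid}: n={g.number_of_nodes()} m={g.number_of_edges()} "
                f"edges={edges} orbits={orbs}"
            )
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GraphletCounts:
    """Occurrence counts N_i of the 30 graphlets in one network."""

    counts: np.ndarray  # shape (30,), int64

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, i: int) -> int:
        return int(self.counts[i])


@dataclass(frozen=True)
class GDVMatrix:
    """Per-node 73-component graphlet degree vectors (signatures)."""

    nodes: tuple
    matrix: np.ndarray  # shape (n, 73), int64

    def row(self, node) -> np.ndarray:
        return self.matrix[self.nodes.index(node)]


@dataclass(frozen=True)
class OrbitWeights:
    """Orbit dependency counts o_i and weights w_i = 1 - log(o_i)/log(73)."""

    o: np.ndarray
    w: np.ndarray


def _build_catalog() -> GraphletCatalog:
    graphlets: list[nx.Graph] = []
    orbit_of: dict[tuple[int, int], int] = {}
    orbits: list[tuple[int, tuple[int, ...]]] = []
    lookup: dict[int, dict[int, tuple[int, tuple[int, ...]]]] = {}

    # canonical code -> (k, map original code -> isomorphism perm) per class
    entries: list[tuple[int, int, int, dict[int, tuple[int, ...]]]] = []
    for k in range(2, MAX_GRAPHLET_NODES + 1):
        n_pairs = k * (k - 1) // 2
        perms = list(permutations(range(k)))
        classes: dict[int, dict[int, tuple[int, ...]]] = {}
        for code in range(1, 1 << n_pairs):
            if not _is_connected_code(code, k):
                continue
            canon = None
            canon_perm = None
            for perm in perms:
                rc = _recode(code, k, perm)
                if canon is None or rc < canon:
                    canon, canon_perm = rc, perm
            classes.setdefault(canon, {})[code] = canon_perm
        for canon, members in classes.items():
            entries.append((k, bin(canon).count("1"), canon, members))

    entries.sort(key=lambda e: (e[0], e[1], e[2]))
    for gid, (k, _m, canon, members) in enumerate(entries):
        g = nx.Graph()
        g.add_nodes_from(range(k))
        g.add_edges_from(_code_edges(canon, k))
        graphlets.append(g)

        # automorphism orbits of the canonical representative
        autos = [p for p in permutations(range(k)) if _recode(canon, k, p) == canon]
        unassigned = set(range(k))
        while unassigned:
            rep = min(unassigned)
            members_cls = tuple(sorted({p[rep] for p in autos}))
            oid = len(orbits)
            orbits.append((gid, members_cls))
            for pos in members_cls:
                orbit_of[(gid, pos)] = oid
                unassigned.discard(pos)

        table = lookup.setdefault(k, {})
        for code, perm in members.items():
            table[code] = (gid, tuple(orbit_of[(gid, perm[p])] for p in range(k)))

    cat = GraphletCatalog(
        graphlets=tuple(graphlets),
        orbit_of=orbit_of,
        orbits=tuple(orbits),
        _lookup=lookup,
    )
    return cat


@lru_cache(maxsize=1)
def build_catalog() -> GraphletCatalog:
    """Build (once per process) the canonical graphlet/orbit catalog."""
    return _build_catalog()


def _index_graph(g: nx.Graph) -> tuple[list, list[set[int]]]:
    nodes = list(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    adj: list[set[int]] = [set() for _ in nodes]
    for u, v in g.edges():
        if u == v:
            continue
        adj[index[u]].add(index[v])
        adj[index[v]].add(index[u])
    return nodes, adj


def _scan(g: nx.Graph, want_gdv: bool) -> tuple[np.ndarray, np.ndarray]:
    """One ESU pass over all connected induced subgraphs on 2-5 nodes.

    Returns (counts over 30 graphlets, n x 73 orbit-touch matrix); the
    matrix is empty when not requested.
    """
    cat = build_catalog()
    nodes, adj = _index_graph(g)
    n = len(nodes)
    counts = np.zeros(N_GRAPHLETS, dtype=np.int64)
    gdv = np.zeros((n, N_ORBITS) if want_gdv else (0, 0), dtype=np.int64)
    lookup = cat._lookup

    def record(sub: tuple[int, ...]) -> None:
        k = len(sub)
        code = 0
        b = 0
        for a_i in range(k):
            na = adj[sub[a_i]]
            for b_i in range(a_i + 1, k):
                if sub[b_i] in na:
                    code |= 1 << b
                b += 1
        gid, orbs = lookup[k][code]
        counts[gid] += 1
        if want_gdv:
            for pos, node in enumerate(sub):
                gdv[node, orbs[pos]] += 1

    def extend(sub: list[int], ext: set[int], v: int, excluded: set[int]) -> None:
        if len(sub) >= 2:
            record(tuple(sorted(sub)))
        if len(sub) == MAX_GRAPHLET_NODES:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u for u in adj[w] if u > v and u not in excluded
            }
            sub.append(w)
            extend(sub, new_ext, v, excluded | adj[w])
            sub.pop()

    for v in range(n):
        ext0 = {u for u in adj[v] if u > v}
        extend([v], ext0, v, adj[v] | {v})

    return counts, gdv


def count_graphlets(g: nx.Graph) -> GraphletCounts:
    """Count induced occurrences of every 2-5-node graphlet in *g*.

    Each occurrence (vertex subset) is counted once; N_0 equals the edge
    count.  Graphs with fewer than 5 nodes simply have zero counts for the
    larger graphlets.
    """
    counts, _ = _scan(g, want_gdv=False)
    return GraphletCounts(counts=counts)


def compute_gdv(g: nx.Graph) -> GDVMatrix:
    """Compute the 73-component signature of every node of *g*."""
    counts, gdv = _scan(g, want_gdv=True)
    del counts
    return GDVMatrix(nodes=tuple(g.nodes()), matrix=gdv)


def count_graphlets_oracle(g: nx.Graph) -> GraphletCounts:
    """Brute-force graphlet counter for validation (n up to ~30).

    Enumerates every vertex subset of size 2-5 and classifies the induced
    subgraph by direct isomorphism tests against the catalog.
    """
    cat = build_catalog()
    counts = np.zeros(N_GRAPHLETS, dtype=np.int64)
    nodes = list(g.nodes())
    by_size: dict[int, list[int]] = {}
    for gid, gl in enumerate(cat.graphlets):
        by_size.setdefault(gl.number_of_nodes(), []).append(gid)
    for k in range(2, MAX_GRAPHLET_NODES + 1):
        for subset in combinations(nodes, k):
            sub = g.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            for gid in by_size[k]:
                if (
                    sub.number_of_edges() == cat.graphlets[gid].number_of_edges()
                    and nx.is_isomorphic(sub, cat.graphlets[gid])
                ):
                    counts[gid] += 1
                    break
    return GraphletCounts(counts=counts)


@lru_cache(maxsize=1)
def orbit_weights() -> OrbitWeights:
    """Orbit weights correcting for dependencies among orbits.

    An orbit depends on every orbit its representative node necessarily
    touches inside the orbit's own graphlet (e.g. a node at the centre of a
    small star also touches path-middle and edge orbits).  o_i is the number
    of such orbits (counting orbit i itself, so o_0 = 1 for the edge) and
    the weight w_i = 1 - log(o_i)/log(73) downweights heavily dependent,
    redundant orbits.  All weights are strictly positive.
    """
    cat = build_catalog()
    o = np.zeros(N_ORBITS, dtype=np.int64)
    for oid, (gid, members) in enumerate(cat.orbits):
        gdv = compute_gdv(cat.graphlets[gid])
        row = gdv.matrix[list(gdv.nodes).index(members[0])]
        o[oid] = int(np.count_nonzero(row))
    w = 1.0 - np.log(o) / math.log(N_ORBITS)
    return OrbitWeights(o=o, w=w)


def signature_similarity(
    gdv_u: np.ndarray, gdv_v: np.ndarray, weights: OrbitWeights | None = None
) -> float:
    """Signature similarity S(u, v) in [0, 1] between two 73-vectors.

    The per-orbit distance compares log-scaled orbit counts, normalised so
    each orbit contributes at most its weight:

        D(u,v) = sum_i w_i |log(u_i+1) - log(v_i+1)| / log(max(u_i,v_i)+2)
                 / sum_i w_i

    and S = 1 - D.  S is symmetric, S(u, u) = 1, and with the strictly
    positive default weights S = 1 only for identical vectors.
    """
    if weights is None:
        weights = orbit_weights()
    u = np.asarray(gdv_u, dtype=float)
    v = np.asarray(gdv_v, dtype=float)
    if u.shape != (N_ORBITS,) or v.shape != (N_ORBITS,):
        raise ValueError("signatures must be 73-component vectors")
    num = weights.w * np.abs(np.log(u + 1.0) - np.log(v + 1.0))
    den = np.log(np.maximum(u, v) + 2.0)
    d = float(np.sum(num / den) / np.sum(weights.w))
    return 1.0 - d
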
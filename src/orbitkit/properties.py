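"""Basic network properties: degrees, clustering, eccentricity, spectra.

The clustering coefficient of node u is c(u) = 2*E_u / (deg(u)(deg(u)-1))
with E_u the number of edges among u's neighbours; nodes of degree <= 1 get
c(u) = 0.  Eccentricity is the longest shortest path from a node, taken
within its connected component (0 for an isolated node).  Average
pathlength and diameter are computed over connected node pairs only, so
disconnected graphs stay finite.

Spectra are scalar series indexed by degree k: the degree distribution
P(k), and the mean clustering coefficient / mean eccentricity over nodes of
degree k.  Two spectra are correlated (Pearson and Spearman) after
truncating the longer series by dropping its smallest-degree points.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "SpectrumSeries",
    "GlobalProperties",
    "clustering_coefficient",
    "eccentricity",
    "global_properties",
    "spectra",
    "spectrum_correlation",
]


@dataclass(frozen=True)
class SpectrumSeries:
    """A per-degree scalar series (degree distribution or a spectrum)."""

    kind: str  # degree_distribution | clustering_spectrum | eccentricity_spectrum
    points: tuple[tuple[int, float], ...]  # (degree k, value), ascending k

    @property
    def degrees(self) -> list[int]:
        return [k for k, _ in self.points]

    @property
    def values(self) -> list[float]:
        return [v for _, v in self.points]


@dataclass(frozen=True)
class GlobalProperties:
    n: int
    m: int
    avg_clustering: float
    avg_pathlength: float
    diameter: int


def clustering_coefficient(g: nx.Graph, u) -> float:
    if u not in g:
        raise KeyError(f"node {u!r} not in graph")
    if g.degree(u) <= 1:
        return 0.0
    return float(nx.clustering(g, u))


def eccentricity(g: nx.Graph, u) -> int:
    if u not in g:
        raise KeyError(f"node {u!r} not in graph")
    lengths = nx.single_source_shortest_path_length(g, u)
    return max(lengths.values())  # 0 for isolated u (only itself reachable)


def _all_eccentricities(g: nx.Graph) -> dict:
    ecc = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            ecc[next(iter(comp))] = 0
        else:
            ecc.update(nx.eccentricity(sub))
    return ecc


def global_properties(g: nx.Graph) -> GlobalProperties:
    """Average clustering, average pathlength and diameter of *g*.

    Path statistics average over connected unordered pairs only; an
    edgeless or empty graph reports pathlength and diameter 0.
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return GlobalProperties(0, 0, 0.0, 0.0, 0)
    clust = [clustering_coefficient(g, u) for u in g.nodes()]
    total, pairs, diam = 0, 0, 0
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, d in lengths.items():
            if d > 0:
                total += d
                pairs += 1
                diam = max(diam, d)
    avg_path = total / pairs if pairs else 0.0  # each pair counted twice; ratio unchanged
    return GlobalProperties(n, m, float(np.mean(clust)), avg_path, diam)


def spectra(g: nx.Graph) -> tuple[SpectrumSeries, SpectrumSeries, SpectrumSeries]:
    """Degree distribution P(k), clustering spectrum, eccentricity spectrum."""
    n = g.number_of_nodes()
    ecc = _all_eccentricities(g)
    by_degree: dict[int, list] = {}
    for u in g.nodes():
        by_degree.setdefault(g.degree(u), []).append(u)
    ks = sorted(by_degree)
    pk = tuple((k, len(by_degree[k]) / n) for k in ks)
    cs = tuple(
        (k, float(np.mean([clustering_coefficient(g, u) for u in by_degree[k]])))
        for k in ks
    )
    es = tuple((k, float(np.mean([ecc[u] for u in by_degree[k]]))) for k in ks)
    return (
        SpectrumSeries("degree_distribution", pk),
        SpectrumSeries("clustering_spectrum", cs),
        SpectrumSeries("eccentricity_spectrum", es),
    )


def spectrum_correlation(
    a: SpectrumSeries, b: SpectrumSeries
) -> tuple[float, float]:
    """Pearson and Spearman correlation between two per-degree series.

    When the series differ in length, points with the smallest degrees are
    dropped from the longer one until lengths match; the value sequences
    are then paired in ascending-degree order.  Returns (nan, nan) when
    fewer than 2 points remain or a sequence is constant.
    """
    if not a.points or not b.points:
        raise ValueError("cannot correlate an empty spectrum")
    va, vb = list(a.values), list(b.values)
    if len(va) > len(vb):
        va = va[len(va) - len(vb):]
    elif len(vb) > len(va):
        vb = vb[len(vb) - len(va):]
    if len(va) < 2:
        return (float("nan"), float("nan"))
    x, y = np.asarray(va, dtype=float), np.asarray(vb, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return (pearson, spearman)
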
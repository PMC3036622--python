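"""Whole-network comparison: RGF-distance and GDD-agreement.

Both measures summarise how similar the local wiring of two networks is,
using the 30-graphlet / 73-orbit machinery from :mod:`orbitkit.graphlets`.

*Relative graphlet frequency (RGF) distance* compares the frequency
profile of the 30 graphlets: with N_i occurrences of graphlet i and
T = sum_i N_i,

    F_i = -ln(N_i / T),    RGF(G, H) = sum_i |F_i(G) - F_i(H)|.

Zero counts are smoothed so F_i stays finite: graphlets absent from both
networks are skipped, and a count that is zero in exactly one network is
replaced by a pseudo-count of 1 (the measure reduces to the pure
definition on strictly positive counts).  Smaller distance = more similar.

*Graphlet degree distribution (GDD) agreement* compares, orbit by orbit,
the distribution of how many times nodes touch the orbit.  For orbit j let
d_G^j(k) be the number of nodes touching it exactly k >= 1 times; each
distribution is scaled by 1/k, normalised to total 1, and the two
normalised distributions are compared with a Euclidean distance capped at
1 by the 1/sqrt(2) factor:

    A_j = 1 - (1/sqrt(2)) * sqrt(sum_k (N_G^j(k) - N_H^j(k))^2)

The agreement is the arithmetic (default) or geometric mean of the 73
A_j's, a number in [0, 1]; identical networks score 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graphlets import GDVMatrix, GraphletCounts, N_GRAPHLETS, N_ORBITS

__all__ = ["RGFResult", "GDDResult", "rgf_distance", "gdd_agreement"]


@dataclass(frozen=True)
class RGFResult:
    f_g: np.ndarray  # F_i of the first network (nan where skipped)
    f_h: np.ndarray
    included: np.ndarray  # bool mask of graphlets entering the sum
    smoothed: np.ndarray  # bool mask of graphlets given a pseudo-count
    distance: float


@dataclass(frozen=True)
class GDDResult:
    per_orbit_agreement: np.ndarray  # shape (73,)
    agreement: float
    mean: str


def rgf_distance(cg: GraphletCounts, ch: GraphletCounts) -> RGFResult:
    """RGF-distance between two networks' graphlet count vectors."""
    ng = cg.counts.astype(float)
    nh = ch.counts.astype(float)
    tg, th = ng.sum(), nh.sum()
    if tg == 0 or th == 0:
        raise ValueError("RGF-distance is undefined for an empty graph (T = 0)")
    included = (ng > 0) | (nh > 0)
    smoothed = included & ((ng == 0) | (nh == 0))
    ng_s = np.where(included & (ng == 0), 1.0, ng)
    nh_s = np.where(included & (nh == 0), 1.0, nh)
    f_g = np.full(N_GRAPHLETS, np.nan)
    f_h = np.full(N_GRAPHLETS, np.nan)
    f_g[included] = -np.log(ng_s[included] / tg)
    f_h[included] = -np.log(nh_s[included] / th)
    distance = float(np.abs(f_g[included] - f_h[included]).sum())
    return RGFResult(f_g=f_g, f_h=f_h, included=included, smoothed=smoothed,
                     distance=distance)


def _orbit_distribution(column: np.ndarray) -> dict[int, float]:
    """Scaled, normalised touch-count distribution N^j(k) of one orbit."""
    ks, counts = np.unique(column[column >= 1], return_counts=True)
    if ks.size == 0:
        return {}
    scaled = counts / ks  # S^j(k) = d^j(k)/k; drops the k=0 bin
    scaled = scaled / scaled.sum()
    return {int(k): float(s) for k, s in zip(ks, scaled)}


def gdd_agreement(dg: GDVMatrix, dh: GDVMatrix, mean: str = "arithmetic") -> GDDResult:
    """GDD-agreement between two networks from their signature matrices."""
    if mean not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown mean {mean!r}")
    if dg.matrix.shape[0] == 0 or dh.matrix.shape[0] == 0:
        raise ValueError("GDD-agreement is undefined for an empty graph")
    per_orbit = np.zeros(N_ORBITS)
    for j in range(N_ORBITS):
        ng = _orbit_distribution(dg.matrix[:, j])
        nh = _orbit_distribution(dh.matrix[:, j])
        if not ng and not nh:
            per_orbit[j] = 1.0  # orbit absent from both: identical distributions
            continue
        ks = set(ng) | set(nh)
        sq = sum((ng.get(k, 0.0) - nh.get(k, 0.0)) ** 2 for k in ks)
        per_orbit[j] = 1.0 - math.sqrt(sq) / math.sqrt(2.0)
    if mean == "arithmetic":
        agreement = float(per_orbit.mean())
    else:
        agreement = float(np.exp(np.log(np.clip(per_orbit, 1e-300, None)).mean()))
    return GDDResult(per_orbit_agreement=per_orbit, agreement=agreement, mean=mean)
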
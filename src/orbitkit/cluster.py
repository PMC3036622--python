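"""Signature-similarity distance matrices and k-medoids node clustering.

Nodes with similar graphlet signatures tend to play similar functional
roles, so clustering nodes by signature distance D(u, v) = 1 - S(u, v)
groups topologically (and often biologically) similar nodes.  k-medoids is
used because it only needs a distance matrix: cluster centres are existing
nodes, so no vector-space embedding of the nodes is required, and any
user-provided distance matrix can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphlets import GDVMatrix, OrbitWeights, orbit_weights

__all__ = [
    "DistanceMatrix",
    "ClusterAssignment",
    "similarity_matrix",
    "kmedoids",
    "random_partition",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled matrix of signature distances, entries in [0, 1].

    Square and symmetric with a zero diagonal for a single network;
    rectangular for cross-network similarity.
    """

    row_labels: tuple
    col_labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels


@dataclass(frozen=True)
class ClusterAssignment:
    k: int
    medoids: tuple            # node labels of the k cluster centres
    assignment: dict          # node label -> cluster index
    objective: float          # total within-cluster distance to medoid


def similarity_matrix(gdv_a: GDVMatrix, gdv_b: GDVMatrix | None = None,
                      weights: OrbitWeights | None = None) -> DistanceMatrix:
    """All-to-all signature distance matrix D = 1 - S.

    With one signature matrix the result is square (nodes of one network
    against themselves); with two it is the rectangular cross-network
    matrix.
    """
    if weights is None:
        weights = orbit_weights()
    a = gdv_a.matrix.astype(float)
    b = a if gdv_b is None else gdv_b.matrix.astype(float)
    w = weights.w
    num = np.abs(np.log(a[:, None, :] + 1.0) - np.log(b[None, :, :] + 1.0))
    den = np.log(np.maximum(a[:, None, :], b[None, :, :]) + 2.0)
    d = np.tensordot(num / den, w, axes=([2], [0])) / w.sum()
    d = np.clip(d, 0.0, 1.0)
    cols = gdv_a.nodes if gdv_b is None else gdv_b.nodes
    if gdv_b is None:
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(row_labels=gdv_a.nodes, col_labels=cols, values=d)


def kmedoids(dm: DistanceMatrix, k: int, seed: int = 0,
             max_iter: int = 300) -> ClusterAssignment:
    """Cluster nodes with k-medoids on a precomputed distance matrix.

    k medoids are initialised uniformly at random; nodes are assigned to
    their nearest medoid (ties to the lowest cluster index), then each
    medoid is recomputed as the cluster member minimising the summed
    distance to its co-members (ties to the lowest node index).  Iteration
    stops when the medoid set is unchanged or after ``max_iter`` rounds;
    the objective never increases between rounds.  A cluster emptied during
    assignment is repaired by reseeding its medoid at the node farthest
    from its current medoid.
    """
    if not dm.is_square:
        raise ValueError("k-medoids needs a square distance matrix")
    n = len(dm.row_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    d = dm.values
    rng = np.random.default_rng(int(seed))
    medoids = sorted(rng.choice(n, size=k, replace=False).tolist())

    def assign(meds: list[int]) -> np.ndarray:
        sub = d[:, meds]                      # (n, k)
        labels = np.argmin(sub, axis=1)       # argmin takes the first (lowest
        for ci, mi in enumerate(meds):        # cluster index) on ties
            labels[mi] = ci                   # a medoid stays in its own cluster
        return labels

    def objective(meds: list[int], labels: np.ndarray) -> float:
        return float(d[np.arange(n), np.asarray(meds)[labels]].sum())

    labels = assign(medoids)
    prev_obj = objective(medoids, labels)
    for _ in range(max_iter):
        # repair empty clusters before the medoid update
        for ci in range(k):
            if not np.any(labels == ci):
                far = int(np.argmax(d[np.arange(n), np.asarray(medoids)[labels]]))
                labels[far] = ci
                medoids[ci] = far
        new_medoids = list(medoids)
        for ci in range(k):
            members = np.flatnonzero(labels == ci)
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[ci] = int(members[np.argmin(within)])  # first = lowest index
        new_labels = assign(new_medoids)
        new_obj = objective(new_medoids, new_labels)
        if new_obj > prev_obj + 1e-12:
            raise AssertionError("k-medoids objective increased")
        converged = new_medoids == medoids
        medoids, labels, prev_obj = new_medoids, new_labels, new_obj
        if converged:
            break
    assignment = {dm.row_labels[i]: int(labels[i]) for i in range(n)}
    return ClusterAssignment(
        k=k,
        medoids=tuple(dm.row_labels[m] for m in medoids),
        assignment=assignment,
        objective=prev_obj,
    )


def random_partition(nodes, k: int, seed: int = 0) -> ClusterAssignment:
    """Uniform random clustering with every cluster non-empty.

    Null-model control: comparing enrichment of k-medoids clusters against
    random clusters of the same sizes separates topological signal from
    chance.
    """
    nodes = list(nodes)
    n = len(nodes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(int(seed))
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[perm[:k]] = np.arange(k)           # one guaranteed member per cluster
    labels[perm[k:]] = rng.integers(0, k, size=n - k)
    assignment = {nodes[i]: int(labels[i]) for i in range(n)}
    return ClusterAssignment(k=k, medoids=(), assignment=assignment,
                             objective=float("nan"))


def write_distance_matrix(dm: DistanceMatrix, format: str = "csv") -> str:
    """Serialise a labelled distance matrix (header row + label column)."""
    sep = "," if format == "csv" else "\t"
    lines = [sep.join(["node", *map(str, dm.col_labels)])]
    for label, row in zip(dm.row_labels, dm.values):
        lines.append(sep.join([str(label), *(repr(float(x)) for x in row)]))
    return "\n".join(lines) + "\n"


def read_distance_matrix(text: str) -> DistanceMatrix:
    """Parse a labelled distance matrix written by :func:`write_distance_matrix`.

    The delimiter (comma or tab) is sniffed from the header line.  Entries
    must be numeric and in [0, 1]; ragged rows are rejected.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty distance-matrix text")
    sep = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(sep)
    col_labels = tuple(header[1:])
    row_labels = []
    rows = []
    for ln in lines[1:]:
        parts = ln.split(sep)
        if len(parts) != len(col_labels) + 1:
            raise ValueError(f"ragged row: {ln!r}")
        row_labels.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in row {parts[0]!r}") from exc
    return DistanceMatrix(row_labels=tuple(row_labels), col_labels=col_labels,
                          values=np.asarray(rows, dtype=float))
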
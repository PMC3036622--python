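"""Readers and writers for the two supported graph formats.

Networks are undirected, simple (no self-loops or parallel edges) and
unweighted.  Both readers normalise their input: self-loops, duplicate
edges (in either orientation) and edge directions are stripped, so the
returned :class:`networkx.Graph` always satisfies that contract.

Supported formats:

* edge list (``.txt`` / ``.edgeLst``): one edge per line, two node labels
  separated by tabs or spaces; blank lines and ``#`` comments are skipped.
* LEDA graph format (``.gw``): the free-LEDA parameterised header
  (``LEDA.GRAPH`` / type / type / directedness flag) followed by node and
  edge records.  Node payloads between ``|{`` and ``}|`` are used as labels
  when non-empty, otherwise the 1-based position index is used.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "ParseError",
    "read_edge_list",
    "read_leda_gw",
    "read_graph",
    "write_edge_list",
    "write_leda_gw",
    "write_graph",
    "write_results_table",
]


class ParseError(ValueError):
    """Raised when a graph or matrix file is malformed."""


def _normalized(name: str, nodes: Iterable[str], raw_edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Assemble a simple undirected graph, dropping loops and duplicates."""
    g = nx.Graph(name=name)
    g.add_nodes_from(nodes)
    for u, v in raw_edges:
        if u == v:
            continue  # self-loop
        g.add_node(u)
        g.add_node(v)
        g.add_edge(u, v)  # re-adding an existing or reversed edge is a no-op
    return g


def read_edge_list(text: str, name: str = "") -> nx.Graph:
    """Parse whitespace-separated edge-list text into a normalised graph.

    Each non-empty, non-comment line must contain exactly two tokens.
    Node order follows first appearance in the file.
    """
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 2:
            raise ParseError(
                f"line {lineno}: expected 2 tokens, found {len(tokens)}: {line!r}"
            )
        edges.append((tokens[0], tokens[1]))
    return _normalized(name, (), edges)


def read_leda_gw(text: str, name: str = "") -> nx.Graph:
    """Parse LEDA ``.gw`` text into a normalised graph.

    Isolated nodes declared in the node section are preserved.  The
    directedness flag is read but ignored: directions are always stripped.
    """
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    # skip blank/comment lines before the header
    idx = 0
    while idx < len(lines) and (not lines[idx].strip() or lines[idx].startswith("#")):
        idx += 1
    if idx >= len(lines) or not lines[idx].startswith("LEDA.GRAPH"):
        raise ParseError("missing LEDA.GRAPH header")
    idx += 1  # header
    idx += 2  # two type lines (node/edge payload types)
    if idx >= len(lines):
        raise ParseError("truncated header block")
    try:
        int(lines[idx].split()[0])  # directedness flag (-1/-2), ignored
        idx += 1
    except (ValueError, IndexError):
        # some dialects omit the directedness line; tolerate that
        pass

    def _next_count(pos: int, what: str) -> tuple[int, int]:
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            raise ParseError(f"missing {what} count")
        try:
            return int(lines[pos].strip()), pos + 1
        except ValueError as exc:
            raise ParseError(f"bad {what} count: {lines[pos]!r}") from exc

    n, idx = _next_count(idx, "node")
    labels: list[str] = []
    for i in range(n):
        if idx >= len(lines):
            raise ParseError(f"declared {n} nodes, file ends after {i}")
        record = lines[idx].strip()
        idx += 1
        label = ""
        if "|{" in record and "}|" in record:
            label = record.split("|{", 1)[1].split("}|", 1)[0].strip()
        labels.append(label if label else str(i + 1))
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate node labels in .gw file")

    m, idx = _next_count(idx, "edge")
    edges: list[tuple[str, str]] = []
    for i in range(m):
        if idx >= len(lines):
            raise ParseError(f"declared {m} edges, file ends after {i}")
        tokens = lines[idx].strip().split()
        idx += 1
        if len(tokens) < 2:
            raise ParseError(f"edge record {i + 1}: {lines[idx - 1]!r}")
        try:
            s, t = int(tokens[0]), int(tokens[1])
        except ValueError as exc:
            raise ParseError(f"edge record {i + 1}: non-integer endpoint") from exc
        if not (1 <= s <= n and 1 <= t <= n):
            raise ParseError(f"edge record {i + 1}: endpoint out of range")
        edges.append((labels[s - 1], labels[t - 1]))
    return _normalized(name, labels, edges)


def write_edge_list(g: nx.Graph) -> str:
    return "".join(f"{u} {v}\n" for u, v in g.edges())


def write_leda_gw(g: nx.Graph) -> str:
    nodes = list(g.nodes())
    index = {u: i + 1 for i, u in enumerate(nodes)}
    buf = _io.StringIO()
    buf.write("LEDA.GRAPH\nstring\nshort\n-2\n")
    buf.write(f"{g.number_of_nodes()}\n")
    for u in nodes:
        buf.write(f"|{{{u}}}|\n")
    buf.write(f"{g.number_of_edges()}\n")
    for u, v in g.edges():
        buf.write(f"{index[u]} {index[v]} 0 |{{}}|\n")
    return buf.getvalue()


def write_graph(g: nx.Graph, format: str = "edge_list") -> str:
    """Serialise *g*; ``format`` is ``edge_list`` or ``leda_gw``."""
    if format == "edge_list":
        return write_edge_list(g)
    if format == "leda_gw":
        return write_leda_gw(g)
    raise ValueError(f"unknown format {format!r}")


def read_graph(path: str | Path, name: str | None = None) -> nx.Graph:
    """Load a graph from a file, choosing the parser by extension."""
    path = Path(path)
    text = path.read_text()
    graph_name = name if name is not None else path.stem
    if path.suffix.lower() == ".gw":
        return read_leda_gw(text, name=graph_name)
    return read_edge_list(text, name=graph_name)


def write_results_table(rows: Sequence[Mapping[str, object]], format: str = "csv") -> str:
    """Render records with a shared schema as delimited text.

    All records must expose the same keys; key order of the first record
    fixes the column order.
    """
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    if not rows:
        return ""
    header = list(rows[0].keys())
    schema = set(header)
    out = [sep.join(header)]
    for i, row in enumerate(rows):
        if set(row.keys()) != schema:
            raise ValueError(f"record {i} does not match header schema {header}")
        out.append(sep.join(str(row[k]) for k in header))
    return "\n".join(out) + "\n"
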
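"""Weighted undirected graphs: data model, random ensembles, and edge-list I/O.

Nodes are dense integers ``0..n-1`` internally; external labels (e.g. from a
GML file) are kept in a side map.  Graphs are simple: no self-loops, no
multi-edges, strictly positive symmetric weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp


class GraphFormatError(ValueError):
    """Raised for malformed edge-list input (message carries the line number)."""


class ParameterError(ValueError):
    """Raised for invalid generator or algorithm parameters."""


@dataclass
class WeightedGraph:
    """Simple undirected weighted graph on nodes ``0..n-1``.

    Parameters
    ----------
    n : int
        Number of nodes.
    edges : list of (u, v, w)
        One entry per undirected edge, ``u != v``, ``w > 0``.
    labels : list, optional
        External label of each internal node id (defaults to the identity).
    """

    n: int
    edges: list[tuple[int, int, float]]
    labels: list | None = None
    _adj: sp.csr_array | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int], float] = {}
        for u, v, w in self.edges:
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise GraphFormatError(f"edge ({u},{v}) out of range for n={self.n}")
            if u == v:
                raise GraphFormatError(f"self-loop on node {u}")
            if w <= 0:
                raise GraphFormatError(f"non-positive weight {w} on edge ({u},{v})")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise GraphFormatError(f"duplicate edge {key}")
            seen[key] = float(w)
        self.edges = [(u, v, w) for (u, v), w in sorted(seen.items())]

    # -- derived quantities -------------------------------------------------

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return len(self.edges)

    @property
    def adjacency(self) -> sp.csr_array:
        """Symmetric sparse weight matrix w_ij (CSR)."""
        if self._adj is None:
            if self.edges:
                u, v, w = (np.asarray(a) for a in zip(*self.edges))
            else:
                u = v = np.empty(0, dtype=int)
                w = np.empty(0)
            a = sp.coo_array(
                (np.r_[w, w], (np.r_[u, v], np.r_[v, u])), shape=(self.n, self.n)
            )
            self._adj = a.tocsr()
        return self._adj

    @property
    def degrees(self) -> np.ndarray:
        """Neighbour counts k_i."""
        a = self.adjacency
        return np.diff(a.indptr)

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths W_i = sum_k w_ik (equal to k_i when unweighted)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.m / self.n if self.n else 0.0

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[i] : a.indptr[i + 1]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from(self.edges)
        return g

    # -- I/O ----------------------------------------------------------------

    def write_edgelist(self, path: str | Path) -> None:
        """Write as TSV ``u<TAB>v<TAB>w``, one undirected edge per line."""
        with open(path, "w") as fh:
            fh.write(f"# nodes {self.n}\n")
            for u, v, w in self.edges:
                fh.write(f"{u}\t{v}\t{w!r}\n")


def read_edgelist(path: str | Path) -> WeightedGraph:
    """Parse a whitespace-separated edge list ``u v [w]`` (default w = 1).

    Lines starting with ``#`` are comments; ``# nodes N`` fixes the node
    count (otherwise it is ``max id + 1``).  Duplicate pairs must agree on
    the weight or a :class:`GraphFormatError` is raised.
    """
    edges: dict[tuple[int, int], float] = {}
    n_declared = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "nodes":
                    n_declared = int(parts[1])
                continue
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(f"line {lineno}: expected 'u v [w]', got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise GraphFormatError(f"line {lineno}: {exc}") from exc
            if u == v:
                raise GraphFormatError(f"line {lineno}: self-loop on node {u}")
            if w <= 0:
                raise GraphFormatError(f"line {lineno}: non-positive weight {w}")
            key = (min(u, v), max(u, v))
            if key in edges and edges[key] != w:
                raise GraphFormatError(
                    f"line {lineno}: conflicting weights for edge {key}: "
                    f"{edges[key]} vs {w}"
                )
            edges[key] = w
    n = max(n_declared, max((max(u, v) for u, v in edges), default=-1) + 1)
    return WeightedGraph(n, [(u, v, w) for (u, v), w in edges.items()])


def read_gml(path: str | Path) -> WeightedGraph:
    """Load a GML file (e.g. the 2004 political-blogs network).

    Directed edges are kept as directed weights and must be symmetrized
    (:func:`symmetrize_max`) downstream; here reciprocal directed edges are
    merged with the max rule so the result is a valid undirected graph.
    """
    g = nx.read_gml(str(path), label="id")
    labels = list(g.nodes())
    index = {lab: i for i, lab in enumerate(labels)}
    directed = [
        (index[u], index[v], float(d.get("weight", 1.0) or 1.0))
        for u, v, d in g.edges(data=True)
        if u != v
    ]
    out = symmetrize_max(directed)
    if out.n < len(labels):
        out = WeightedGraph(len(labels), out.edges)
    out.labels = labels
    return out


# -- generators -------------------------------------------------------------


def generate_er(n: int, mean_degree: float, seed: int) -> WeightedGraph:
    """Erdős–Rényi G(n, p) with p = mean_degree/(n-1); all weights 1."""
    if not 0 <= mean_degree < n:
        raise ParameterError(f"mean_degree must be in [0, n); got {mean_degree}")
    p = mean_degree / (n - 1) if n > 1 else 0.0
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    return WeightedGraph(n, [(u, v, 1.0) for u, v in g.edges()])


def generate_ba(n: int, edges_per_new_node: int, seed: int) -> WeightedGraph:
    """Barabási–Albert preferential attachment, seeded with an (m+1)-clique.

    Each of the remaining ``n - m - 1`` nodes attaches to ``m`` distinct
    existing nodes chosen with probability proportional to degree.  The
    asymptotic mean degree is 2m and the degree tail follows P(k) ~ k^-3.
    """
    m = int(edges_per_new_node)
    if not 1 <= m < n:
        raise ParameterError(f"edges_per_new_node must be in [1, n); got {m}")
    rng = np.random.default_rng(seed)
    edges = [(u, v, 1.0) for u in range(m + 1) for v in range(u + 1, m + 1)]
    # one entry per edge endpoint => sampling from this list is degree-biased
    repeated: list[int] = [u for u in range(m + 1) for _ in range(m)]
    for v in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            edges.append((t, v, 1.0))
            repeated.append(t)
            repeated.append(v)
    return WeightedGraph(n, edges)


# -- transforms -------------------------------------------------------------


def symmetrize_max(directed_edges: Iterable[tuple[int, int, float]]) -> WeightedGraph:
    """Undirect a weighted edge list with w_uv = max(w_uv, w_vu).

    A missing reverse direction counts as weight 0, so a one-way edge keeps
    its weight.  Idempotent on already-symmetric input.
    """
    best: dict[tuple[int, int], float] = {}
    n = 0
    for u, v, w in directed_edges:
        if w < 0:
            raise ParameterError(f"negative weight {w} on edge ({u},{v})")
        if u == v:
            continue
        n = max(n, u + 1, v + 1)
        key = (min(u, v), max(u, v))
        best[key] = max(best.get(key, 0.0), float(w))
    return WeightedGraph(n, [(u, v, w) for (u, v), w in best.items() if w > 0])


def largest_component(g: WeightedGraph) -> tuple[WeightedGraph, np.ndarray]:
    """Induced subgraph on the largest connected component.

    Returns the relabelled subgraph (nodes ``0..n'-1`` in increasing order of
    original id) and the array of original node ids.  Ties between equally
    large components are broken towards the one containing the smallest
    original id.
    """
    if g.n == 0:
        raise ParameterError("empty graph has no components")
    n_comp, member = sp.csgraph.connected_components(g.adjacency, directed=False)
    sizes = np.bincount(member, minlength=n_comp)
    best = int(np.argmax(sizes))  # argmax ties -> lowest label = smallest first id
    keep = np.flatnonzero(member == best)
    index = {int(old): new for new, old in enumerate(keep)}
    edges = [
        (index[u], index[v], w)
        for u, v, w in g.edges
        if u in index and v in index
    ]
    sub = WeightedGraph(len(keep), edges)
    if g.labels is not None:
        sub.labels = [g.labels[i] for i in keep]
    return sub, keep


def connected_components(g: WeightedGraph) -> np.ndarray:
    """Component label of every node."""
    _, member = sp.csgraph.connected_components(g.adjacency, directed=False)
    return member
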
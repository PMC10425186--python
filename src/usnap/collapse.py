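"""The weighted collapsed graph and the density / exclusivity measures.

Given T snapshot graphs and a target snapshot u, the collapsed graph Gc
has exactly the edges of snapshot u. Each edge carries NoCond — the number
of snapshots whose edge set contains that vertex pair — and an inverse
document frequency style weight that rewards rarity across snapshots:

    w(e) = 2 * (1 + log(T / NoCond))   if NoCond == 1   (u-specific)
    w(e) = 1 + log(T / NoCond)         if NoCond  > 1

so an edge present in every snapshot has weight 1 and an edge unique to u
has the strictly largest weight 2*(1 + log T). The density of a subgraph
is its total edge weight (mass) divided by its vertex count, and the
exclusive fraction is the share of its edges that are u-specific
(NoCond == 1). The log base defaults to natural log and is configurable;
every monotonicity property below holds in any base.

Storage: a graph built edge-by-edge (:meth:`CollapsedGraph.add_edge`)
keeps dict-of-dict adjacency plus per-vertex caches throughout.
:func:`build_collapsed_graph` instead collapses in bulk into flat numpy
arrays — NoCond is counted by sorted-key membership across snapshots —
and the dict structures are materialised lazily on first use, so the hot
path (collapse then peel) never pays for them on large inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .exceptions import ConfigError
from .io import SnapshotGraphSet

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "CollapsedGraph",
    "no_cond",
    "edge_weight",
    "build_collapsed_graph",
    "density",
    "exclusive_fraction",
]

_LOG_FNS = {"e": math.log, "2": math.log2, "10": math.log10}


def _logfn(log_base: str):
    try:
        return _LOG_FNS[str(log_base)]
    except KeyError:
        raise ConfigError(f"log base must be one of {sorted(_LOG_FNS)}, got {log_base!r}")


@dataclass(frozen=True, slots=True)
class EdgeRecord:
    """Annotation of one collapsed-graph edge."""

    no_cond: int
    weight: float
    u_specific: bool


def no_cond(pair: tuple[str, str], snapshots: SnapshotGraphSet) -> int:
    """Number of snapshots whose edge set contains this (unordered) vertex pair."""
    a, b = pair
    return sum(1 for g in snapshots.snapshots if g.has_edge(a, b))


def edge_weight(no_cond: int, T: int, in_u: bool = True, log_base: str = "e") -> float:
    """Weight of a collapsed edge from its snapshot count.

    Only edges of snapshot u are weighted (they are the only edges of Gc),
    so ``in_u`` must be true and ``1 <= no_cond <= T``.
    """
    if not in_u:
        raise ValueError("only edges present in snapshot u belong to Gc and get a weight")
    if T < 1:
        raise ValueError(f"T must be positive, got {T}")
    if not 1 <= no_cond <= T:
        raise ValueError(f"NoCond must lie in [1, T={T}], got {no_cond}")
    log = _logfn(log_base)
    if no_cond == 1:
        return 2.0 * (1.0 + log(T))
    return 1.0 + log(T / no_cond)


def _record_cache(T: int, log_base: str) -> dict[int, EdgeRecord]:
    """One shared immutable record per possible NoCond value."""
    return {
        c: EdgeRecord(c, edge_weight(c, T, log_base=log_base), c == 1)
        for c in range(1, T + 1)
    }


class CollapsedGraph:
    """Weighted undirected graph Gc with per-edge records and vertex caches.

    Vertices are string labels. Per-vertex caches d(v) (degree), du(v)
    (number of incident u-specific edges) and dw(v) (weighted degree) are
    kept consistent with the edge set at all times; ``mass`` is the total
    edge weight. Bulk-built graphs hold the edge list as flat arrays and
    materialise the dict views on demand; such graphs are immutable.
    """

    __slots__ = ("u", "T", "log_base", "_adj", "_edges", "_du", "_dw",
                 "_mass", "_n_u", "_labels", "_index", "_ia", "_ib", "_nc", "_w")

    def __init__(self, u: int, T: int, log_base: str = "e") -> None:
        self.u = u
        self.T = T
        self.log_base = log_base
        self._adj: dict[str, dict[str, EdgeRecord]] | None = {}
        self._edges: dict[tuple[str, str], EdgeRecord] | None = {}
        self._du: dict[str, int] | None = {}
        self._dw: dict[str, float] | None = {}
        self._mass = 0.0
        self._n_u = 0
        self._labels: list[str] | None = None  # array mode only, sorted
        self._index: dict[str, int] | None = None
        self._ia = self._ib = self._nc = self._w = None

    @classmethod
    def _from_arrays(cls, u, T, log_base, labels, index, ia, ib, nc, w) -> "CollapsedGraph":
        """Bulk constructor: ``labels`` sorted; ia <= ib index-wise per edge."""
        gc = cls(u, T, log_base)
        gc._adj = gc._edges = gc._du = gc._dw = None
        gc._labels = labels
        gc._index = index
        gc._ia, gc._ib, gc._nc, gc._w = ia, ib, nc, w
        gc._mass = float(w.sum())
        gc._n_u = int((nc == 1).sum())
        return gc

    def _ensure_dicts(self) -> None:
        if self._adj is not None:
            return
        adj: dict[str, dict[str, EdgeRecord]] = {v: {} for v in self._labels}
        dwd = {v: 0.0 for v in self._labels}
        dud = {v: 0 for v in self._labels}
        edges: dict[tuple[str, str], EdgeRecord] = {}
        cache = _record_cache(self.T, self.log_base)
        labels = self._labels
        for i, j, c in zip(self._ia.tolist(), self._ib.tolist(), self._nc.tolist()):
            a, b = labels[i], labels[j]
            rec = cache[c]
            edges[(a, b)] = rec
            adj[a][b] = rec
            adj[b][a] = rec
            dwd[a] += rec.weight
            dwd[b] += rec.weight
            if c == 1:
                dud[a] += 1
                dud[b] += 1
        self._adj, self._edges, self._dw, self._du = adj, edges, dwd, dud

    # -- construction (edge-by-edge mode) ------------------------------

    def add_vertex(self, v: str) -> None:
        if self._labels is not None:
            raise ValueError("bulk-built collapsed graphs are immutable")
        if v not in self._adj:
            self._adj[v] = {}
            self._du[v] = 0
            self._dw[v] = 0.0

    def add_edge(self, a: str, b: str, record: EdgeRecord) -> None:
        if self._labels is not None:
            raise ValueError("bulk-built collapsed graphs are immutable")
        if a == b:
            raise ValueError(f"self-loop {a!r} not allowed in Gc")
        key = (a, b) if a <= b else (b, a)
        if key in self._edges:
            raise ValueError(f"duplicate edge {key}")
        self.add_vertex(a)
        self.add_vertex(b)
        self._edges[key] = record
        self._adj[a][b] = record
        self._adj[b][a] = record
        self._dw[a] += record.weight
        self._dw[b] += record.weight
        if record.u_specific:
            self._du[a] += 1
            self._du[b] += 1
            self._n_u += 1
        self._mass += record.weight

    # -- views ---------------------------------------------------------

    @property
    def vertices(self) -> Iterable[str]:
        if self._adj is not None:
            return self._adj.keys()
        return self._labels

    @property
    def n_vertices(self) -> int:
        return len(self._adj) if self._adj is not None else len(self._labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges) if self._edges is not None else len(self._ia)

    @property
    def edges(self) -> dict[tuple[str, str], EdgeRecord]:
        self._ensure_dicts()
        return self._edges

    @property
    def mass(self) -> float:
        """Sum of all edge weights."""
        return self._mass

    @property
    def u_specific_edge_count(self) -> int:
        return self._n_u

    def degree(self, v: str) -> int:
        self._ensure_dicts()
        return len(self._adj[v])

    def u_degree(self, v: str) -> int:
        self._ensure_dicts()
        return self._du[v]

    def weighted_degree(self, v: str) -> float:
        self._ensure_dicts()
        return self._dw[v]

    def neighbors(self, v: str) -> Iterable[str]:
        self._ensure_dicts()
        return self._adj[v].keys()

    def adjacency(self) -> Iterator[tuple[str, dict[str, EdgeRecord]]]:
        self._ensure_dicts()
        return iter(self._adj.items())

    def has_edge(self, a: str, b: str) -> bool:
        self._ensure_dicts()
        return b in self._adj.get(a, ())

    # -- derived graphs ------------------------------------------------

    def subgraph(self, vertices: Iterable[str]) -> "CollapsedGraph":
        """Induced subgraph on the given vertices (kept even if isolated)."""
        vs = set(vertices)
        sub = CollapsedGraph(self.u, self.T, self.log_base)
        if self._adj is None:
            # array mode: select edges by membership without building dicts
            index = self._index
            idxs = np.fromiter(
                (index[v] for v in vs if v in index), dtype=np.int64,
            )
            for v in vs:
                if v in index:
                    sub.add_vertex(v)
            if len(self._ia):
                mask = np.isin(self._ia, idxs) & np.isin(self._ib, idxs)
                cache = _record_cache(self.T, self.log_base)
                labels = self._labels
                for p in np.nonzero(mask)[0].tolist():
                    sub.add_edge(labels[self._ia[p]], labels[self._ib[p]],
                                 cache[int(self._nc[p])])
            return sub
        for v in vs:
            if v in self._adj:
                sub.add_vertex(v)
        for v in sub._adj:
            for w, rec in self._adj[v].items():
                if w in vs and v < w:
                    sub.add_edge(v, w, rec)
        return sub

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (a, b), rec in self.edges.items():
            g.add_edge(a, b, weight=rec.weight, no_cond=rec.no_cond,
                       u_specific=bool(rec.u_specific))
        return g

    def __repr__(self) -> str:  # pragma: no cover
        return (f"CollapsedGraph(u={self.u}, T={self.T}, nc={self.n_vertices}, "
                f"mc={self.n_edges}, mass={self._mass:.4g})")


def build_collapsed_graph(
    snapshots: SnapshotGraphSet, u: int, log_base: str = "e"
) -> CollapsedGraph:
    """Collapse a snapshot set onto target snapshot ``u`` (1-based).

    The edges of Gc are exactly the edges of snapshot u; each is annotated
    with NoCond, its weight, and the u-specificity flag. Vertices of Gc are
    exactly the endpoints of those edges. NoCond is counted in bulk: every
    edge of snapshot u is encoded as an integer pair key and matched
    against the (sorted, unique) key sets of the other snapshots.
    """
    T = snapshots.T
    if not 1 <= u <= T:
        raise ConfigError(f"target snapshot u={u} out of range [1, T={T}]")
    gu = snapshots.snapshots[u - 1]
    if gu.number_of_edges() == 0:
        logger.warning("snapshot u=%d is empty: collapsed graph has no edges", u)
        return CollapsedGraph(u, T, log_base)

    import pandas as pd

    a_list: list[str] = []
    b_list: list[str] = []
    for a, b in gu.edges():
        a_list.append(str(a))
        b_list.append(str(b))
    labels = sorted(set(a_list).union(b_list))
    index = {v: i for i, v in enumerate(labels)}
    pd_index = pd.Index(labels)  # C hash table for bulk label -> int mapping
    n = len(labels)
    ia = pd_index.get_indexer(a_list).astype(np.int64)
    ib = pd_index.get_indexer(b_list).astype(np.int64)
    lo = np.minimum(ia, ib)
    hi = np.maximum(ia, ib)
    keys = lo * n + hi

    nc = np.ones(len(keys), dtype=np.int64)
    members: dict[int, np.ndarray] = {}  # per snapshot object (may be shared)
    for i, g in enumerate(snapshots.snapshots, 1):
        if i == u:
            continue
        gid = id(g)
        if gid not in members:
            oa: list[str] = []
            ob: list[str] = []
            for a, b in g.edges():
                oa.append(str(a))
                ob.append(str(b))
            if oa:
                xa = pd_index.get_indexer(oa).astype(np.int64)
                yb = pd_index.get_indexer(ob).astype(np.int64)
                valid = (xa >= 0) & (yb >= 0)
                xa, yb = xa[valid], yb[valid]
                ok = np.unique(np.minimum(xa, yb) * n + np.maximum(xa, yb))
            else:
                ok = np.empty(0, dtype=np.int64)
            if ok.size:
                pos = np.minimum(np.searchsorted(ok, keys), ok.size - 1)
                members[gid] = (ok[pos] == keys).astype(np.int64)
            else:
                members[gid] = np.zeros(len(keys), dtype=np.int64)
        nc += members[gid]

    # exact same scalar weight per NoCond as edge_weight()
    table = np.empty(T + 1, dtype=np.float64)
    for c in range(1, T + 1):
        table[c] = edge_weight(c, T, log_base=log_base)
    w = table[nc]
    return CollapsedGraph._from_arrays(u, T, log_base, labels, index, lo, hi, nc, w)


def density(subgraph: CollapsedGraph) -> float:
    """Weighted density: total edge weight divided by vertex count."""
    n = subgraph.n_vertices
    if n == 0:
        raise ValueError("density is undefined for an empty vertex set")
    return subgraph.mass / n


def exclusive_fraction(subgraph: CollapsedGraph) -> float:
    """Fraction of the subgraph's edges that are u-specific (NoCond == 1)."""
    ne = subgraph.n_edges
    if ne == 0:
        raise ValueError("exclusive fraction is undefined for an edgeless subgraph")
    return subgraph.u_specific_edge_count / ne
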
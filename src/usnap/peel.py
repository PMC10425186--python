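"""Greedy vertex peeling and the outer loop extracting k usnaps.

The peeler starts from the full collapsed graph and repeatedly deletes one
vertex: an isolated vertex if any exists (it can never improve density),
otherwise the vertex minimising the selection score

    score(v) = dw(v) * (1 + du(v) / d(v))

where dw(v) is the weighted degree, d(v) the degree and du(v) the number
of incident u-specific edges. The first factor steers the peel toward
dense remainders; the second discourages deleting vertices that carry
u-specific edges. Every visited configuration is recorded; the result is
the configuration of maximum density among those meeting the exclusive
threshold gamma and the minimum size.

For the score-minimising choice the density after the removal is provably
bracketed per step:

    (mass - 2*dw_min)/(|V|-1)  <=  density(after)  <=  (mass - dw_min)/(|V|-1)

with mass and dw_min = min_v dw(v) taken before the removal: the chosen
vertex v* satisfies dw(v*) <= score(v*) <= score(argmin dw) <= 2*dw_min.
The bracket is recorded in the trace (instrumentation only — it never
influences a removal) and can be switched off for timing runs.

The outer loop (:func:`find_usnaps`) peels, deletes the accepted usnap's
vertices and incident edges from the residual collapsed graph, and repeats
up to k times; results are vertex-disjoint and relabelled d0, d1, ...
densest-first.

Complexity: each edge of the collapsed graph is touched O(1) times during
a peel and each touch costs one lazy-heap operation, giving
O(m + mc log nc + nc log nc) per extraction (m to build Gc, the heap
terms to peel it). The sequential inner loop is compiled with numba
(:mod:`usnap._peelcore`); a pure-Python twin of the same loop is kept as
a reference implementation and the tests assert both produce identical
traces.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._peelcore import peel_core
from .collapse import (
    CollapsedGraph,
    EdgeRecord,
    build_collapsed_graph,
    density,
    exclusive_fraction,
)
from .exceptions import ConfigError
from .io import SnapshotGraphSet

logger = logging.getLogger(__name__)

__all__ = [
    "UsnapConfig",
    "PeelStep",
    "PeelTrace",
    "Usnap",
    "selection_score",
    "select_removal_vertex",
    "lemma1_bounds",
    "peel",
    "find_usnaps",
]

# tolerance when comparing an exclusive fraction against gamma; both sides
# are short float computations, so this only absorbs representation error
_GAMMA_EPS = 1e-12

# relative tolerance for density ties during best-configuration selection:
# wide enough to absorb running-mass round-off over any realistic peel,
# narrow enough never to blur genuinely different densities
_DENSITY_RTOL = 1e-9


@dataclass(frozen=True)
class UsnapConfig:
    """Run parameters for one usnap extraction.

    Parameters
    ----------
    u:
        Target snapshot (1-based).
    k:
        Number of subgraphs to extract.
    gamma:
        Exclusive threshold in (0, 1]: minimum fraction of a result's edges
        that must be u-specific. Default 1.0 (every edge unique to u).
    restart:
        When true, each accepted configuration is refined by a second peel
        pass seeded from the configuration plus its residual-graph
        neighbourhood. Experimental; the default (false) reproduces the
        plain single-pass peel.
    fraction_to_remain:
        Peeling stops once fewer than this fraction of the starting
        vertices remains; 0 peels to exhaustion.
    log_base:
        Base of the logarithm in the edge-weight function: "e", "2" or "10".
    min_vertices:
        Smallest subgraph size ever reported (default 3: results must have
        more than two nodes).
    seed:
        Reserved for randomised tie-breaking; the default path is fully
        deterministic (ties break on the lexicographically smallest label).
    """

    u: int
    k: int = 1
    gamma: float = 1.0
    restart: bool = False
    fraction_to_remain: float = 0.0
    log_base: str = "e"
    min_vertices: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.u < 1:
            raise ConfigError(f"u must be a 1-based snapshot index, got {self.u}")
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigError(f"gamma must lie in (0, 1], got {self.gamma}")
        if not 0.0 <= self.fraction_to_remain < 1.0:
            raise ConfigError(
                f"fraction_to_remain must lie in [0, 1), got {self.fraction_to_remain}"
            )
        if self.min_vertices < 2:
            raise ConfigError(f"min_vertices must be >= 2, got {self.min_vertices}")
        if str(self.log_base) not in ("e", "2", "10"):
            raise ConfigError(f"log_base must be 'e', '2' or '10', got {self.log_base!r}")


@dataclass(slots=True)
class PeelStep:
    """One visited configuration; step 0 is the untouched starting graph."""

    step: int
    removed: str | None
    n_vertices: int
    n_edges: int
    n_u_edges: int
    mass: float
    density: float
    exclusive_fraction: float | None
    bound_lower: float | None  # density bracket for this step's removal,
    bound_upper: float | None  # computed from the state before the removal


class PeelTrace:
    """Sequence of configurations visited by one peel pass."""

    def __init__(self, initial_vertices: Iterable[str]) -> None:
        self.initial_vertices: frozenset[str] = frozenset(initial_vertices)
        self.steps: list[PeelStep] = []

    def vertices_at(self, step_index: int) -> set[str]:
        """Vertex set of the configuration recorded at ``step_index``."""
        removed = {s.removed for s in self.steps[1 : step_index + 1]}
        return set(self.initial_vertices) - removed

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": s.step,
                "removed_vertex": s.removed if s.removed is not None else "",
                "n_vertices": s.n_vertices,
                "n_edges": s.n_edges,
                "mass": s.mass,
                "density": s.density,
                "exclusive_fraction": s.exclusive_fraction,
                "lemma1_lower": s.bound_lower,
                "lemma1_upper": s.bound_upper,
            }
            for s in self.steps
        ]

    def write_tsv(self, path) -> None:
        def f(x):
            return "" if x is None else (f"{x:.6g}" if isinstance(x, float) else str(x))

        with open(path, "wt", encoding="utf-8") as fh:
            fh.write(
                "#step\tremoved_vertex\tn_vertices\tn_edges\tmass\tdensity"
                "\texclusive_fraction\tlemma1_lower\tlemma1_upper\n"
            )
            for row in self.to_rows():
                fh.write("\t".join(f(row[k]) for k in (
                    "step", "removed_vertex", "n_vertices", "n_edges", "mass",
                    "density", "exclusive_fraction", "lemma1_lower", "lemma1_upper",
                )) + "\n")


@dataclass(frozen=True)
class Usnap:
    """One extracted unique dense subgraph."""

    rank: str
    vertices: frozenset[str]
    edges: dict[tuple[str, str], EdgeRecord]
    density: float
    exclusive_fraction: float

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# selection rule and bounds (reference forms, used directly on small graphs)


def selection_score(v: str, gc: CollapsedGraph) -> float:
    """Greedy removal score dw(v) * (1 + du(v)/d(v)); lower is removed first."""
    d = gc.degree(v)
    if d == 0:
        raise ValueError(
            f"selection score undefined for isolated vertex {v!r}; "
            "isolated vertices are removed first, unscored"
        )
    return gc.weighted_degree(v) * (1.0 + gc.u_degree(v) / d)


def select_removal_vertex(gc: CollapsedGraph) -> str:
    """Vertex the greedy peel deletes next.

    An isolated vertex (smallest label) if any exists; otherwise the vertex
    minimising :func:`selection_score`, ties broken toward the
    lexicographically smallest label.
    """
    if gc.n_vertices == 0:
        raise ValueError("cannot select a removal vertex from an empty graph")
    isolated = [v for v in gc.vertices if gc.degree(v) == 0]
    if isolated:
        return min(isolated)
    return min(gc.vertices, key=lambda v: (selection_score(v, gc), v))


def lemma1_bounds(gc: CollapsedGraph) -> tuple[float, float]:
    """Per-step density bracket for a score-minimising removal.

    Returns ``((mass - 2*dw_min)/(|V|-1), (mass - dw_min)/(|V|-1))`` with
    dw_min the minimum weighted degree over the current vertices.
    """
    n = gc.n_vertices
    if n < 2:
        raise ValueError(f"bounds need at least 2 vertices, got {n}")
    dw_min = min(gc.weighted_degree(v) for v in gc.vertices)
    mass = gc.mass
    return (mass - 2.0 * dw_min) / (n - 1), (mass - dw_min) / (n - 1)


# ---------------------------------------------------------------------------
# the peel engine


class _PeelEngine:
    """Int-indexed peeling state shared by the k extractions of one run.

    Vertices are renumbered by sorted label, so comparing indices is
    comparing labels and heap ties break lexicographically for free. The
    adjacency is a flat CSR layout; an edge is processed exactly once,
    when its first endpoint dies. ``dead`` marks vertices of already
    accepted usnaps so later extractions run on the residual graph
    without copying it.
    """

    __slots__ = ("verts", "indptr", "nbrs", "wts", "usp", "dead", "_index")

    def __init__(self, gc: CollapsedGraph) -> None:
        if gc._labels is not None:
            # bulk-built graph: CSR assembled fully vectorised; labels are
            # already sorted, so index order is label order
            self.verts = gc._labels
            self._index = gc._index
            n = len(self.verts)
            uniq = (gc._nc == 1)
            src = np.concatenate([gc._ia, gc._ib])
            dst = np.concatenate([gc._ib, gc._ia])
            w2 = np.concatenate([gc._w, gc._w])
            u2 = np.concatenate([uniq, uniq])
            perm = np.argsort(src, kind="stable")
            counts = np.bincount(src, minlength=n)
            self.indptr = np.concatenate(
                [np.zeros(1, dtype=np.int64), np.cumsum(counts, dtype=np.int64)]
            )
            self.nbrs = np.ascontiguousarray(dst[perm]).astype(np.int32)
            self.wts = np.ascontiguousarray(w2[perm])
            self.usp = np.ascontiguousarray(u2[perm]).astype(np.uint8)
            self.dead = np.zeros(n, dtype=np.uint8)
            return
        self.verts = sorted(gc.vertices)
        self._index = {v: i for i, v in enumerate(self.verts)}
        indptr = [0]
        nbrs: list[int] = []
        wts: list[float] = []
        usp: list[bool] = []
        index = self._index
        for v in self.verts:
            for w, rec in gc._adj[v].items():
                nbrs.append(index[w])
                wts.append(rec.weight)
                usp.append(rec.u_specific)
            indptr.append(len(nbrs))
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.nbrs = np.asarray(nbrs, dtype=np.int32)
        self.wts = np.asarray(wts, dtype=np.float64)
        self.usp = np.asarray(usp, dtype=np.uint8)
        self.dead = np.zeros(len(self.verts), dtype=np.uint8)

    def mark_dead(self, labels: Iterable[str]) -> None:
        for v in labels:
            self.dead[self._index[v]] = 1

    def n_alive(self) -> int:
        return int(len(self.verts) - int(self.dead.sum()))

    def run(
        self, config: UsnapConfig, with_bounds: bool = True, compiled: bool = True
    ) -> tuple[set[str] | None, PeelTrace]:
        """One full peel of the current residual; returns the best feasible
        configuration's vertex labels (or None) and the trace."""
        alive0 = self.n_alive()
        trace = PeelTrace(
            v for v, dd in zip(self.verts, self.dead) if not dd
        )
        if alive0 == 0:
            return None, trace
        stop_floor = max(
            config.min_vertices, math.ceil(config.fraction_to_remain * alive0)
        )
        runner = self._run_compiled if compiled else self._run_python
        removed, nv, ne, nu, mass, lo, hi = runner(stop_floor, with_bounds)

        verts = self.verts
        for s in range(len(nv)):
            n_edges = int(ne[s])
            n_vert = int(nv[s])
            trace.steps.append(
                PeelStep(
                    step=s,
                    removed=None if removed[s] < 0 else verts[int(removed[s])],
                    n_vertices=n_vert,
                    n_edges=n_edges,
                    n_u_edges=int(nu[s]),
                    mass=float(mass[s]),
                    density=float(mass[s]) / n_vert if n_vert else 0.0,
                    exclusive_fraction=(int(nu[s]) / n_edges) if n_edges else None,
                    bound_lower=None if math.isnan(lo[s]) else float(lo[s]),
                    bound_upper=None if math.isnan(hi[s]) else float(hi[s]),
                )
            )

        # best feasible configuration: max density, then fewer vertices,
        # then earlier visit. Densities are compared with a tiny relative
        # tolerance: the running mass accumulates subtraction round-off,
        # so mathematically tied configurations (e.g. one planted clique
        # vs two disjoint copies of it) may differ in the last few ulps,
        # and the tie must still resolve toward the smaller configuration.
        best: PeelStep | None = None
        for st in trace.steps:
            if st.n_edges < 1 or st.n_vertices < config.min_vertices:
                continue
            if st.exclusive_fraction is None or st.exclusive_fraction < config.gamma - _GAMMA_EPS:
                continue
            if best is None:
                best = st
                continue
            tol = _DENSITY_RTOL * max(abs(st.density), abs(best.density))
            if st.density > best.density + tol:
                best = st
            elif st.density > best.density - tol and st.n_vertices < best.n_vertices:
                best = st
        if best is None:
            return None, trace
        return trace.vertices_at(best.step), trace

    def _run_compiled(self, stop_floor: int, with_bounds: bool):
        return peel_core(
            self.indptr, self.nbrs, self.wts, self.usp, self.dead.copy(),
            stop_floor, with_bounds,
        )

    def _run_python(self, stop_floor: int, with_bounds: bool):
        """Reference twin of :func:`usnap._peelcore.peel_core`.

        Same arithmetic, same tie-breaks, same lazy-heap discipline —
        kept readable and used by the tests to cross-check the compiled
        path on small instances.
        """
        indptr = self.indptr.tolist()
        nbrs = self.nbrs.tolist()
        wts = self.wts.tolist()
        usp = self.usp.tolist()
        dead = bytearray(self.dead.tolist())
        n = len(dead)
        heappush, heappop = heapq.heappush, heapq.heappop

        dw = [0.0] * n
        du = [0] * n
        d = [0] * n
        mass = 0.0
        n_edges = 0
        n_u = 0
        alive = 0
        for i in range(n):
            if dead[i]:
                continue
            alive += 1
            s = 0.0
            c = 0
            cu = 0
            for p in range(indptr[i], indptr[i + 1]):
                if dead[nbrs[p]]:
                    continue
                s += wts[p]
                c += 1
                if usp[p]:
                    cu += 1
            dw[i] = s
            d[i] = c
            du[i] = cu
            mass += s
            n_edges += c
            n_u += cu
        mass /= 2.0
        n_edges //= 2
        n_u //= 2

        out = [(-1, alive, n_edges, n_u, mass, math.nan, math.nan)]
        if alive == 0:
            return tuple(zip(*out))

        score = [0.0] * n
        heap: list[tuple[float, int]] = []
        dw_heap: list[tuple[float, int]] = []
        iso_heap: list[int] = []
        for i in range(n):
            if dead[i]:
                continue
            if d[i] == 0:
                iso_heap.append(i)
            else:
                s = dw[i] * (1.0 + du[i] / d[i])
                score[i] = s
                heap.append((s, i))
            if with_bounds:
                dw_heap.append((dw[i], i))
        heapq.heapify(heap)
        heapq.heapify(dw_heap)
        heapq.heapify(iso_heap)

        while alive >= stop_floor and alive >= 2:
            if with_bounds:
                while dw_heap:
                    val, i = dw_heap[0]
                    if not dead[i] and dw[i] == val:
                        break
                    heappop(dw_heap)
                dw_min = dw_heap[0][0] if dw_heap else 0.0
                denom = alive - 1
                lo = (mass - 2.0 * dw_min) / denom
                hi = (mass - dw_min) / denom
            else:
                lo = hi = math.nan

            victim = -1
            while iso_heap:
                i = heappop(iso_heap)
                if not dead[i] and d[i] == 0:
                    victim = i
                    break
            if victim < 0:
                while heap:
                    s, i = heappop(heap)
                    if not dead[i] and d[i] > 0 and score[i] == s:
                        victim = i
                        break
            if victim < 0:  # pragma: no cover - alive implies a pickable vertex
                break

            dead[victim] = 1
            for p in range(indptr[victim], indptr[victim + 1]):
                j = nbrs[p]
                if dead[j]:
                    continue
                w = wts[p]
                dw[j] -= w
                d[j] -= 1
                mass -= w
                n_edges -= 1
                if usp[p]:
                    du[j] -= 1
                    n_u -= 1
                if d[j] == 0:
                    heappush(iso_heap, j)
                else:
                    s = dw[j] * (1.0 + du[j] / d[j])
                    score[j] = s
                    heappush(heap, (s, j))
                if with_bounds:
                    heappush(dw_heap, (dw[j], j))
            alive -= 1
            out.append((victim, alive, n_edges, n_u, mass, lo, hi))
        return tuple(zip(*out))


def peel(
    gc: CollapsedGraph,
    config: UsnapConfig,
    with_bounds: bool = True,
    compiled: bool = True,
) -> tuple[CollapsedGraph | None, PeelTrace]:
    """One full greedy peel of ``gc``.

    Records every configuration from the untouched graph down to the stop
    floor and returns the induced subgraph of the best feasible
    configuration (maximum density subject to at least one edge,
    exclusive fraction >= gamma and at least ``min_vertices`` vertices),
    or ``None`` if no configuration qualifies. Density ties prefer fewer
    vertices, then the earlier-visited configuration.
    """
    if gc.n_vertices == 0:
        return None, PeelTrace(())
    best_vs, trace = _PeelEngine(gc).run(config, with_bounds=with_bounds,
                                         compiled=compiled)
    if best_vs is None:
        return None, trace
    return gc.subgraph(best_vs), trace


def _refine(residual: CollapsedGraph, best: CollapsedGraph, config: UsnapConfig) -> CollapsedGraph:
    """Restart pass: re-peel the best configuration plus its neighbourhood."""
    seed_vs = set(best.vertices)
    for v in best.vertices:
        seed_vs.update(residual.neighbors(v))
    sub = residual.subgraph(seed_vs)
    cand, _ = peel(sub, config)
    if cand is not None and density(cand) > density(best):
        return cand
    return best


def find_usnaps(
    snapshots: SnapshotGraphSet | None,
    config: UsnapConfig,
    collapsed: CollapsedGraph | None = None,
    with_traces: bool = False,
    with_bounds: bool = True,
):
    """Extract up to k vertex-disjoint usnaps for target snapshot config.u.

    Builds the collapsed graph once (or reuses ``collapsed``), then
    alternates peeling and deleting the accepted usnap's vertices and all
    their incident edges from the residual graph. Stops early, with a
    logged notice, when no qualifying configuration remains. Results are
    relabelled d0, d1, ... in decreasing order of density.

    Returns the list of :class:`Usnap`; with ``with_traces=True`` also the
    per-extraction :class:`PeelTrace` list (in the same order).
    """
    if collapsed is None:
        if snapshots is None:
            raise ConfigError("either a snapshot set or a prebuilt collapsed graph is required")
        collapsed = build_collapsed_graph(snapshots, config.u, config.log_base)
    engine = _PeelEngine(collapsed)
    found: list[CollapsedGraph] = []
    traces: list[PeelTrace] = []
    for _ in range(config.k):
        if engine.n_alive() == 0:
            break
        best_vs, trace = engine.run(config, with_bounds=with_bounds)
        best = collapsed.subgraph(best_vs) if best_vs is not None else None
        if best is not None and config.restart:
            residual = collapsed.subgraph(trace.initial_vertices)
            best = _refine(residual, best, config)
        if best is None:
            logger.info(
                "stopping after %d usnap(s): no qualifying configuration remains",
                len(found),
            )
            break
        found.append(best)
        traces.append(trace)
        engine.mark_dead(best.vertices)
    if len(found) < config.k:
        logger.info("found %d of the requested k=%d usnaps", len(found), config.k)

    order = sorted(range(len(found)), key=lambda i: (-density(found[i]), i))
    results = []
    for rank, i in enumerate(order):
        sub = found[i]
        results.append(
            Usnap(
                rank=f"d{rank}",
                vertices=frozenset(sub.vertices),
                edges=dict(sub.edges),
                density=density(sub),
                exclusive_fraction=exclusive_fraction(sub),
            )
        )
    if with_traces:
        return results, [traces[i] for i in order]
    return results
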
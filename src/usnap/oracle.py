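"""Exhaustive reference search for small collapsed graphs.

Enumerates every vertex subset (induced-subgraph semantics: at a fixed
vertex set, adding edges can only raise density, so induced subgraphs
dominate) and returns the feasible subset of maximum density. Used in
tests to certify expected values and to bound the greedy peel.
"""

from __future__ import annotations

from itertools import combinations

from .collapse import CollapsedGraph

__all__ = ["brute_force_best", "MAX_ORACLE_VERTICES"]

MAX_ORACLE_VERTICES = 20

_GAMMA_EPS = 1e-12


def brute_force_best(
    gc: CollapsedGraph, gamma: float, min_vertices: int = 3
) -> CollapsedGraph | None:
    """Best induced subgraph by exhaustive enumeration.

    Feasibility: at least ``min_vertices`` vertices, at least one edge and
    an exclusive fraction of at least ``gamma``. Ties on density prefer
    fewer vertices, then the lexicographically smallest vertex tuple
    (guaranteed by enumeration order: sizes ascending, subsets in lexical
    order, and only strictly denser subsets replace the incumbent).
    Refuses graphs above ``MAX_ORACLE_VERTICES`` vertices.
    """
    n = gc.n_vertices
    if n > MAX_ORACLE_VERTICES:
        raise ValueError(
            f"brute-force oracle is guarded at {MAX_ORACLE_VERTICES} vertices, got {n}"
        )
    verts = sorted(gc.vertices)
    edges = [(a, b, rec) for (a, b), rec in gc.edges.items()]
    best_set: tuple[str, ...] | None = None
    best_density = float("-inf")
    for size in range(max(min_vertices, 1), n + 1):
        for combo in combinations(verts, size):
            s = set(combo)
            mass = 0.0
            ne = 0
            nu = 0
            for a, b, rec in edges:
                if a in s and b in s:
                    mass += rec.weight
                    ne += 1
                    nu += rec.u_specific
            if ne == 0:
                continue
            if nu / ne < gamma - _GAMMA_EPS:
                continue
            dens = mass / size
            if dens > best_density:
                best_density = dens
                best_set = combo
    if best_set is None:
        return None
    return gc.subgraph(best_set)
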
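"""Synthetic snapshot sets with planted unique dense regions.

The generator emulates the structure the algorithm is designed to detect:
a background of interactions shared by every snapshot (maximally
non-unique, weight 1 after collapsing) plus one or more planted dense
regions whose edges exist only in the target snapshot u. ``cross_leak``
lets a planted edge additionally appear in one random other snapshot, to
exercise exclusive thresholds below 1; ``background_mode="resampled"``
draws the background independently per snapshot, which scatters
incidental u-specific edges through the background.

Defaults mirror a stage-modelled study: T=4 snapshots (four disease
stages), one planted 6-vertex clique, and a shared sparse background.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import ConfigError
from .io import SnapshotGraphSet

__all__ = ["SyntheticSpec", "generate", "generate_scaling_set"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one planted-region snapshot set.

    ``n_planted`` may be a single size shared by all regions or one size
    per region. Planted vertex sets are fresh labels, disjoint from the
    background and from each other.
    """

    T: int = 4
    u: int = 1
    n_background: int = 40
    p_background: float = 0.1
    n_planted: int | Sequence[int] = 6
    planted_density: float = 1.0
    n_planted_regions: int = 1
    cross_leak: float = 0.0
    background_mode: str = "shared"  # or "resampled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ConfigError(f"T must be >= 2, got {self.T}")
        if not 1 <= self.u <= self.T:
            raise ConfigError(f"u={self.u} out of range [1, {self.T}]")
        for name in ("p_background", "planted_density", "cross_leak"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {val}")
        if self.n_planted_regions < 0:
            raise ConfigError("n_planted_regions must be >= 0")
        if self.background_mode not in ("shared", "resampled"):
            raise ConfigError(
                f"background_mode must be 'shared' or 'resampled', got {self.background_mode!r}"
            )
        sizes = self.region_sizes()
        if any(s < 2 for s in sizes):
            raise ConfigError("each planted region needs at least 2 vertices")

    def region_sizes(self) -> list[int]:
        if isinstance(self.n_planted, int):
            return [self.n_planted] * self.n_planted_regions
        sizes = list(self.n_planted)
        if len(sizes) != self.n_planted_regions:
            raise ConfigError(
                f"{len(sizes)} planted sizes given for {self.n_planted_regions} regions"
            )
        return sizes


def generate(spec: SyntheticSpec) -> tuple[SnapshotGraphSet, list[frozenset[str]]]:
    """Generate a snapshot set and the ground-truth planted vertex sets.

    Background edges appear in all T snapshots (shared mode) or are drawn
    independently per snapshot (resampled mode). Planted edges always
    appear in snapshot u and, with probability ``cross_leak`` each, in one
    uniformly chosen other snapshot. Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    bg_vertices = [f"b{i:04d}" for i in range(spec.n_background)]
    bg_pairs = list(combinations(bg_vertices, 2))

    snapshots = [nx.Graph() for _ in range(spec.T)]
    if bg_pairs:
        if spec.background_mode == "shared":
            mask = rng.random(len(bg_pairs)) < spec.p_background
            shared = [p for p, keep in zip(bg_pairs, mask) if keep]
            for g in snapshots:
                g.add_edges_from(shared)
        else:
            for g in snapshots:
                mask = rng.random(len(bg_pairs)) < spec.p_background
                g.add_edges_from(p for p, keep in zip(bg_pairs, mask) if keep)

    gu = snapshots[spec.u - 1]
    other_idx = [i for i in range(spec.T) if i != spec.u - 1]
    ground_truth: list[frozenset[str]] = []
    for r, size in enumerate(spec.region_sizes()):
        verts = [f"u{r}_{j:02d}" for j in range(size)]
        ground_truth.append(frozenset(verts))
        for a, b in combinations(verts, 2):
            if spec.planted_density < 1.0 and rng.random() >= spec.planted_density:
                continue
            gu.add_edge(a, b)
            if spec.cross_leak > 0.0 and rng.random() < spec.cross_leak:
                leak_to = other_idx[rng.integers(len(other_idx))]
                snapshots[leak_to].add_edge(a, b)

    labels = [f"s{i}" for i in range(1, spec.T + 1)]
    return SnapshotGraphSet(snapshots, labels), ground_truth


def generate_scaling_set(
    mc: int,
    T: int = 3,
    u: int = 1,
    unique_fraction: float = 0.1,
    n_cliques: int = 5,
    clique_size: int = 8,
    seed: int = 0,
) -> SnapshotGraphSet:
    """Large snapshot set whose collapsed graph has about ``mc`` edges.

    Built for runtime measurements: snapshot u carries ~mc random edges
    over mc/10 vertices (average degree ~20), a fraction of which are
    unique to u while the rest are shared by every snapshot, plus
    ``n_cliques`` small u-only cliques so that multiple usnaps exist. The
    non-u snapshots share one graph object (their edge sets are identical
    by construction), keeping memory linear in mc.
    """
    if mc < 100:
        raise ConfigError(f"mc too small for a scaling instance: {mc}")
    rng = np.random.default_rng(seed)
    n = max(20, mc // 10)
    # rejection-sample distinct unordered pairs
    draw = int(mc * 1.4) + 100
    i = rng.integers(0, n, size=draw)
    j = rng.integers(0, n, size=draw)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    keep = lo != hi
    codes = np.unique(lo[keep].astype(np.int64) * n + hi[keep])
    rng.shuffle(codes)
    codes = codes[:mc]
    a_idx, b_idx = codes // n, codes % n
    uniq_mask = rng.random(len(codes)) < unique_fraction

    gu = nx.Graph()
    shared = nx.Graph()
    labels = [f"v{int(x)}" for x in range(n)]
    for a, b, uniq in zip(a_idx, b_idx, uniq_mask):
        va, vb = labels[a], labels[b]
        gu.add_edge(va, vb)
        if not uniq:
            shared.add_edge(va, vb)
    for c in range(n_cliques):
        cv = [f"q{c}_{j:02d}" for j in range(clique_size)]
        for x, y in combinations(cv, 2):
            gu.add_edge(x, y)

    snapshots = [shared] * T
    snapshots[u - 1] = gu
    return SnapshotGraphSet(list(snapshots), [f"s{i}" for i in range(1, T + 1)])
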
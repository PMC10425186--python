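"""Runtime scaling measurements for the peeler.

The peel is designed to run in O(m + mc log nc + nc log nc): each edge of
the collapsed graph is touched a constant number of times and each touch
costs one heap operation. :func:`measure_scaling` times complete
extractions (collapse + k peels) on synthetic sets of increasing edge
count and reports wall-clock seconds per size, from which a per-doubling
growth ratio can be checked against quasilinear expectations. Absolute
seconds are machine-dependent and are never asserted; only ratios are.
"""

from __future__ import annotations

import time

from .collapse import build_collapsed_graph
from .peel import UsnapConfig, find_usnaps
from .synthetic import generate_scaling_set

__all__ = ["measure_scaling", "per_doubling_ratio"]


def measure_scaling(
    sizes: list[int],
    seed: int = 0,
    k: int = 5,
    T: int = 3,
    u: int = 1,
    repeats: int = 3,
) -> list[tuple[int, float]]:
    """Time one k-usnap extraction per collapsed-graph size in ``sizes``.

    Generation is excluded from the timing; collapsing and peeling are
    included. A small warm-up extraction runs first so one-off costs
    (JIT compilation, imports) never land inside a timed run, and each
    size is timed ``repeats`` times with the fastest run kept. Returns
    (requested mc, seconds) pairs in input order.
    """
    config = UsnapConfig(u=u, k=k, gamma=1.0)
    warm = generate_scaling_set(1000, T=T, u=u, seed=seed)
    find_usnaps(None, config, collapsed=build_collapsed_graph(warm, u),
                with_bounds=False)
    results = []
    for mc in sizes:
        snapshots = generate_scaling_set(mc, T=T, u=u, seed=seed)
        best = float("inf")
        for _ in range(max(1, repeats)):
            t0 = time.perf_counter()
            gc = build_collapsed_graph(snapshots, u)
            find_usnaps(None, config, collapsed=gc, with_bounds=False)
            best = min(best, time.perf_counter() - t0)
        results.append((mc, best))
    return results


def per_doubling_ratio(size_a: int, time_a: float, size_b: int, time_b: float) -> float:
    """Observed runtime growth factor per doubling of the input size.

    For sizes differing by factor f, the raw time ratio r is normalised to
    r ** (1 / log2(f)), the growth per size doubling; quasilinear
    algorithms stay near 2, quadratic ones near 4.
    """
    import math

    if size_b <= size_a or time_a <= 0:
        raise ValueError("sizes must increase and times must be positive")
    doublings = math.log2(size_b / size_a)
    return (time_b / time_a) ** (1.0 / doublings)
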
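"""Greedy peeling: selection rule, density bracket, best configuration, k-loop."""

import logging
import math

import pytest

from usnap import (
    CollapsedGraph,
    EdgeRecord,
    SyntheticSpec,
    UsnapConfig,
    brute_force_best,
    build_collapsed_graph,
    density,
    edge_weight,
    exclusive_fraction,
    find_usnaps,
    generate,
    lemma1_bounds,
    peel,
    select_removal_vertex,
    selection_score,
)
from usnap.exceptions import ConfigError
from usnap.peel import _PeelEngine

from conftest import make_set


def graph_from_records(edges):
    """CollapsedGraph from {(a, b): (weight, u_specific)} for unit tests."""
    gc = CollapsedGraph(1, 4)
    for (a, b), (w, uspec) in edges.items():
        gc.add_edge(a, b, EdgeRecord(1 if uspec else 2, w, uspec))
    return gc


def unit_clique(vertices, shared=True):
    """Clique with weight-1 edges (shared=True) or u-specific flag set."""
    edges = {}
    vs = list(vertices)
    for i, a in enumerate(vs):
        for b in vs[i + 1:]:
            edges[(a, b)] = (1.0, not shared)
    return graph_from_records(edges)


# -- config validation -----------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(u=0),
        dict(u=1, k=0),
        dict(u=1, gamma=0.0),
        dict(u=1, gamma=1.2),
        dict(u=1, fraction_to_remain=1.0),
        dict(u=1, min_vertices=1),
        dict(u=1, log_base="3"),
    ],
)
def test_config_rejects_invalid_parameters(kwargs):
    with pytest.raises(ConfigError):
        UsnapConfig(**kwargs)


# -- selection score and vertex choice ------------------------------------


def test_selection_score_hand_values():
    # dw=2, d=4, du=0 -> 2; dw=2, d=4, du=4 -> 4; dw=3, d=3, du=1 -> 4
    gc = graph_from_records({
        ("v", f"n{i}"): (0.5, False) for i in range(4)
    })
    assert selection_score("v", gc) == pytest.approx(2.0)
    gc2 = graph_from_records({
        ("v", f"n{i}"): (0.5, True) for i in range(4)
    })
    assert selection_score("v", gc2) == pytest.approx(4.0)
    gc3 = graph_from_records({
        ("v", "a"): (1.0, True), ("v", "b"): (1.0, False), ("v", "c"): (1.0, False)
    })
    assert selection_score("v", gc3) == pytest.approx(4.0)


def test_selection_score_isolated_vertex_is_contract_error():
    gc = CollapsedGraph(1, 2)
    gc.add_vertex("x")
    with pytest.raises(ValueError):
        selection_score("x", gc)


def test_select_removal_vertex_path_breaks_tie_lexically():
    # path A-B-C, unit weights, nothing u-specific: scores A=1, B=2, C=1
    path = [("A", "B"), ("B", "C")]
    gc = build_collapsed_graph(make_set(path, path), 1)
    assert selection_score("A", gc) == pytest.approx(1.0)
    assert selection_score("B", gc) == pytest.approx(2.0)
    assert select_removal_vertex(gc) == "A"


def test_select_removal_vertex_prefers_isolated():
    gc = unit_clique("ABC")
    gc.add_vertex("X")
    assert select_removal_vertex(gc) == "X"


def test_select_removal_vertex_matches_exhaustive_scan():
    snaps, _ = generate(SyntheticSpec(seed=1, cross_leak=0.3, n_background=15))
    gc = build_collapsed_graph(snaps, 1)
    brute = min(gc.vertices, key=lambda v: (selection_score(v, gc), v))
    assert select_removal_vertex(gc) == brute


def test_select_removal_vertex_empty_graph_is_contract_error():
    with pytest.raises(ValueError):
        select_removal_vertex(CollapsedGraph(1, 2))


# -- density bracket -------------------------------------------------------


def test_bracket_unit_triangle():
    gc = unit_clique("ABC")
    lo, hi = lemma1_bounds(gc)
    assert (lo, hi) == pytest.approx((-0.5, 0.5))
    # removing any vertex of a unit triangle leaves density 1/2 = upper bound
    sub = gc.subgraph({"B", "C"})
    assert density(sub) == pytest.approx(hi)


def test_bracket_unit_star():
    gc = graph_from_records({("h", leaf): (1.0, False) for leaf in "abc"})
    lo, hi = lemma1_bounds(gc)
    assert (lo, hi) == pytest.approx((1 / 3, 2 / 3))
    leaf = select_removal_vertex(gc)
    assert leaf in "abc"  # the hub has the largest score
    after = gc.subgraph(set("habc") - {leaf})
    assert density(after) == pytest.approx(hi)


def test_bracket_needs_two_vertices():
    gc = CollapsedGraph(1, 2)
    gc.add_vertex("a")
    with pytest.raises(ValueError):
        lemma1_bounds(gc)


def test_bracket_contains_observed_density_on_random_graphs():
    # re-simulate peels on random instances and check every recorded step
    checked = 0
    for seed in range(10):
        snaps, _ = generate(
            SyntheticSpec(seed=seed, T=2 + seed % 4, n_background=18,
                          p_background=0.25, background_mode="resampled",
                          n_planted_regions=0)
        )
        gc = build_collapsed_graph(snaps, 1)
        if gc.n_vertices == 0:
            continue
        _, trace = peel(gc, UsnapConfig(u=1, min_vertices=2))
        for step in trace.steps[1:]:
            assert step.bound_lower - 1e-9 <= step.density <= step.bound_upper + 1e-9
            checked += 1
    assert checked > 50


# -- peel ------------------------------------------------------------------


def test_peel_single_unique_triangle_returns_it_whole():
    tri = [("A", "B"), ("B", "C"), ("A", "C")]
    snaps = make_set(tri, [])
    gc = build_collapsed_graph(snaps, 1)
    best, trace = peel(gc, UsnapConfig(u=1, gamma=1.0))
    assert set(best.vertices) == {"A", "B", "C"}
    assert density(best) == pytest.approx(2 * (1 + math.log(2)))
    assert trace.steps[0].n_vertices == 3


def test_peel_identical_snapshots_returns_none():
    tri = [("A", "B"), ("B", "C"), ("A", "C")]
    gc = build_collapsed_graph(make_set(tri, tri), 1)
    best, _ = peel(gc, UsnapConfig(u=1, gamma=1.0))
    assert best is None


def test_peel_recovers_planted_clique_and_matches_oracle():
    spec = SyntheticSpec(seed=1, n_background=8, p_background=0.4, n_planted=6)
    snaps, truth = generate(spec)
    gc = build_collapsed_graph(snaps, 1)
    assert gc.n_vertices <= 14
    cfg = UsnapConfig(u=1, gamma=1.0)
    best, _ = peel(gc, cfg)
    oracle = brute_force_best(gc, cfg.gamma, cfg.min_vertices)
    assert set(best.vertices) == set(oracle.vertices) == set(truth[0])


def test_peel_trace_agrees_with_independent_resimulation():
    snaps, _ = generate(SyntheticSpec(seed=3, cross_leak=0.4, n_background=14,
                                      p_background=0.3))
    gc = build_collapsed_graph(snaps, 1)
    _, trace = peel(gc, UsnapConfig(u=1, min_vertices=2))
    remaining = set(trace.initial_vertices)
    for step in trace.steps[1:]:
        state = gc.subgraph(remaining)
        # the removed vertex must be a score minimiser; exact-symmetry ties
        # may resolve differently between incremental and fresh summation,
        # so compare scores, not labels
        isolated = sorted(v for v in state.vertices if state.degree(v) == 0)
        if isolated:
            assert step.removed == isolated[0]
        else:
            scores = {v: selection_score(v, state) for v in state.vertices}
            min_score = min(scores.values())
            assert scores[step.removed] <= min_score + 1e-9
            near_ties = [v for v, s in scores.items() if s <= min_score + 1e-9]
            if len(near_ties) == 1:
                assert step.removed == select_removal_vertex(state)
        lo, hi = lemma1_bounds(state)
        assert step.bound_lower == pytest.approx(lo, rel=1e-9, abs=1e-12)
        assert step.bound_upper == pytest.approx(hi, rel=1e-9, abs=1e-12)
        remaining.discard(step.removed)
        after = gc.subgraph(remaining)
        assert step.n_vertices == len(remaining)
        if remaining:
            assert step.density == pytest.approx(density(after), rel=1e-9, abs=1e-12)


def test_peel_vertex_count_decrements_and_mass_never_increases():
    snaps, _ = generate(SyntheticSpec(seed=5, n_background=25, p_background=0.2))
    gc = build_collapsed_graph(snaps, 1)
    _, trace = peel(gc, UsnapConfig(u=1, min_vertices=2))
    for before, after in zip(trace.steps, trace.steps[1:]):
        assert after.n_vertices == before.n_vertices - 1
        assert after.mass <= before.mass + 1e-12


def test_peel_fraction_to_remain_stops_early():
    snaps, _ = generate(SyntheticSpec(seed=2, n_background=20, p_background=0.5,
                                      n_planted_regions=0))
    gc = build_collapsed_graph(snaps, 1)
    nc = gc.n_vertices
    _, trace = peel(gc, UsnapConfig(u=1, fraction_to_remain=0.5, min_vertices=2))
    floor = max(2, math.ceil(0.5 * nc))
    assert trace.steps[-1].n_vertices == floor - 1


def test_peel_compiled_and_reference_paths_agree():
    for seed in range(8):
        snaps, _ = generate(
            SyntheticSpec(seed=seed, cross_leak=0.3, n_background=20,
                          p_background=0.3, background_mode="resampled")
        )
        gc = build_collapsed_graph(snaps, 1)
        cfg = UsnapConfig(u=1, min_vertices=2)
        vs_c, tr_c = _PeelEngine(gc).run(cfg, compiled=True)
        vs_p, tr_p = _PeelEngine(gc).run(cfg, compiled=False)
        assert vs_c == vs_p
        key = lambda t: [
            (s.removed, s.mass, s.density, s.bound_lower, s.bound_upper)
            for s in t.steps
        ]
        assert key(tr_c) == key(tr_p)


def test_peel_is_deterministic():
    snaps, _ = generate(SyntheticSpec(seed=9, cross_leak=0.5))
    cfg = UsnapConfig(u=1, k=3, gamma=0.5)
    a = find_usnaps(snaps, cfg)
    b = find_usnaps(snaps, cfg)
    assert [(r.rank, r.vertices, r.density) for r in a] == [
        (r.rank, r.vertices, r.density) for r in b
    ]


# -- find_usnaps -----------------------------------------------------------


def test_two_disjoint_unique_cliques_ranked_by_density():
    # two u-specific cliques of different sizes: distinct masses, k=2
    big = [("B1", "B2"), ("B1", "B3"), ("B1", "B4"), ("B2", "B3"), ("B2", "B4"),
           ("B3", "B4")]
    small = [("A1", "A2"), ("A2", "A3"), ("A1", "A3")]
    snaps = make_set(big + small, [])
    res = find_usnaps(snaps, UsnapConfig(u=1, k=2, gamma=1.0))
    assert len(res) == 2
    assert res[0].vertices == frozenset(["B1", "B2", "B3", "B4"])
    assert res[1].vertices == frozenset(["A1", "A2", "A3"])
    assert res[0].density > res[1].density
    assert not (res[0].vertices & res[1].vertices)


def test_equal_size_planted_regions_are_returned_separately():
    # two 6-cliques tie a 12-vertex union on density exactly; the tie must
    # resolve toward the smaller configuration, so k=2 recovers both
    snaps, truth = generate(SyntheticSpec(seed=1, n_planted_regions=2,
                                          n_planted=6, n_background=40))
    res = find_usnaps(snaps, UsnapConfig(u=1, k=2, gamma=1.0))
    assert {r.vertices for r in res} == {frozenset(t) for t in truth}


def test_find_usnaps_k1_equals_single_peel(planted_two_regions):
    snaps, _ = planted_two_regions
    cfg = UsnapConfig(u=1, k=1)
    res = find_usnaps(snaps, cfg)
    best, _ = peel(build_collapsed_graph(snaps, 1), cfg)
    assert len(res) == 1
    assert res[0].vertices == frozenset(best.vertices)


def test_find_usnaps_stops_early_with_notice(caplog):
    snaps, _ = generate(SyntheticSpec(seed=1))  # one planted region
    with caplog.at_level(logging.INFO, logger="usnap.peel"):
        res = find_usnaps(snaps, UsnapConfig(u=1, k=5, gamma=1.0))
    assert len(res) == 1
    assert any("no qualifying configuration" in r.message for r in caplog.records)


def test_find_usnaps_results_satisfy_contracts(planted_two_regions):
    snaps, _ = planted_two_regions
    cfg = UsnapConfig(u=1, k=4, gamma=1.0)
    res = find_usnaps(snaps, cfg)
    seen = set()
    for r in res:
        assert r.exclusive_fraction >= cfg.gamma
        assert r.n_vertices >= cfg.min_vertices
        assert not (r.vertices & seen)
        seen |= r.vertices
    assert [r.rank for r in res] == [f"d{i}" for i in range(len(res))]
    assert all(a.density >= b.density for a, b in zip(res, res[1:]))


def test_restart_refinement_never_worsens_density(planted_two_regions):
    snaps, _ = planted_two_regions
    base = find_usnaps(snaps, UsnapConfig(u=1, k=2))
    refined = find_usnaps(snaps, UsnapConfig(u=1, k=2, restart=True))
    assert len(refined) == len(base)
    for b, r in zip(base, refined):
        assert r.density >= b.density - 1e-12
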
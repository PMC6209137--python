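"""Pareto dominance, archive behaviour, SMPSO search and the grid oracle."""

import numpy as np
import pytest

from fluxdesign.moo import (
    FunctionProblem,
    ParetoArchive,
    SnappedProblem,
    SwarmParams,
    crowding_distances,
    dominates,
    exhaustive_front,
    hypervolume_2d,
    pareto_filter,
    smpso_optimize,
)


def test_dominance_definition():
    assert dominates((2, 3), (1, 3))
    assert not dominates((2, 1), (1, 2))
    assert not dominates((1, 2), (2, 1))
    assert not dominates((1, 1), (1, 1))  # needs one strict improvement


def test_dominance_requires_matching_objective_sets():
    with pytest.raises(ValueError):
        dominates((1, 2), (1, 2, 3))


def test_pareto_filter_brute_force_example():
    pts = [(1, 1), (2, 3), (3, 2), (2, 2)]
    keep = pareto_filter(pts)
    assert [pts[i] for i in keep] == [(2, 3), (3, 2)]


def test_pareto_filter_keeps_identical_points():
    pts = [(1, 2)] * 4
    assert pareto_filter(pts) == [0, 1, 2, 3]


def test_pareto_filter_totally_ordered_chain():
    pts = [(i, i) for i in range(5)]
    assert pareto_filter(pts) == [4]


def test_archive_maintains_internal_non_domination(rng):
    archive = ParetoArchive(capacity=50)
    for _ in range(300):
        archive.add(rng.uniform(0, 1, size=2))
        objs = archive.objectives
        assert len(pareto_filter(objs)) == len(archive)


def test_archive_capacity_truncation_preserves_boundaries():
    archive = ParetoArchive(capacity=20)
    xs = np.linspace(0, 1, 200)
    for x in xs:
        archive.add(np.array([x, 1 - x]))
    assert len(archive) == 20
    objs = archive.objectives
    # crowding truncation never drops the extreme points
    assert objs[:, 0].max() == pytest.approx(1.0)
    assert objs[:, 1].max() == pytest.approx(1.0)


def test_crowding_boundary_points_infinite():
    objs = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
    dist = crowding_distances(objs)
    assert np.isinf(dist[0]) and np.isinf(dist[2])
    assert np.isfinite(dist[1])


TOY = FunctionProblem([0.0], [1.0], lambda x: np.array([x[0], 1 - x[0] ** 2]))


def test_smpso_reaches_the_analytic_front():
    params = SwarmParams(swarm_size=40, iterations=60, archive_capacity=80, seed=42)
    archive, log = smpso_optimize(TOY, params)
    objs = archive.objectives
    # every archive point lies on the curve y = 1 - x^2 within 1e-3
    assert np.abs(objs[:, 1] - (1 - objs[:, 0] ** 2)).max() < 1e-3
    assert log[-1]["archive_size"] == len(archive)


def test_smpso_is_bitwise_reproducible():
    params = SwarmParams(swarm_size=30, iterations=40, archive_capacity=50, seed=7)
    a1, _ = smpso_optimize(TOY, params)
    a2, _ = smpso_optimize(TOY, params)
    np.testing.assert_array_equal(a1.objectives, a2.objectives)


def test_archive_capacity_is_respected_on_dense_front():
    params = SwarmParams(swarm_size=40, iterations=60, archive_capacity=20, seed=3)
    archive, _ = smpso_optimize(TOY, params)
    assert len(archive) == 20


def test_archive_hypervolume_monotone_over_iterations():
    """Without truncation pressure the archive only ever gains front mass."""
    ref = np.array([-0.1, -0.1])
    hvs = []

    def track(record, archive):
        hvs.append(hypervolume_2d(archive.objectives, ref))

    params = SwarmParams(swarm_size=30, iterations=30, archive_capacity=2000, seed=11)
    smpso_optimize(TOY, params, callback=track)
    assert all(a <= b + 1e-12 for a, b in zip(hvs, hvs[1:]))


def test_exhaustive_front_equals_brute_force_filter():
    grid = [np.linspace(0, 1, 11)]
    front = exhaustive_front(TOY, grid)
    evals = [TOY.evaluate(np.array([x]))[0] for x in grid[0]]
    keep = pareto_filter(evals)
    assert len(front) == len(keep)
    got = sorted(map(tuple, front.objectives.tolist()))
    expected = sorted(tuple(evals[i]) for i in keep)
    np.testing.assert_allclose(got, expected)


def test_exhaustive_front_degenerate_objectives_single_point():
    prob = FunctionProblem([0.0], [1.0], lambda x: np.array([x[0], x[0]]))
    front = exhaustive_front(prob, [np.linspace(0, 1, 5)])
    assert len(front) == 1
    np.testing.assert_allclose(front.objectives[0], [1.0, 1.0])


def test_exhaustive_front_guard_refuses_large_grids():
    from fluxdesign.errors import ConfigurationError

    with pytest.raises(ConfigurationError, match="guard"):
        exhaustive_front(
            FunctionProblem([0, 0, 0], [1, 1, 1], lambda x: x),
            [np.linspace(0, 1, 101)] * 3,
            guard=10_000,
        )


def test_two_variable_toy_front_matches_hand_enumeration():
    """2 mixture levels x 11 replicate levels, objectives known by hand."""

    def fn(x):
        # info grows with tracer share and replicates; cost likewise
        info = x[0] * (1 + x[1])
        cost = 10 * x[0] + x[1]
        return np.array([info, -cost])

    prob = FunctionProblem([0, 0], [1, 10], fn)
    grids = [np.array([0.0, 1.0]), np.arange(11.0)]
    front = exhaustive_front(prob, grids)
    combos = [(a, b) for a in grids[0] for b in grids[1]]
    objs = [fn(np.array(c)) for c in combos]
    keep = pareto_filter(objs)
    assert sorted(map(tuple, front.objectives.tolist())) == sorted(
        tuple(objs[i]) for i in keep
    )


def test_smpso_recovers_snapped_grid_front():
    grid = [np.linspace(0, 1, 11)]
    snapped = SnappedProblem(TOY, grid)
    exact = exhaustive_front(snapped, grid)
    params = SwarmParams(swarm_size=40, iterations=60, archive_capacity=100, seed=1)
    archive, _ = smpso_optimize(snapped, params)
    exact_set = {tuple(np.round(o, 9)) for o in exact.objectives}
    got = {tuple(np.round(o, 9)) for o in archive.objectives}
    # every archive point is an exact front point, and coverage >= 90%
    assert got <= exact_set
    assert len(exact_set & got) / len(exact_set) >= 0.9
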
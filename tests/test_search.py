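"""NSGA-II machinery against brute-force oracles, and whole searches."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcdesign import (
    DesignEvaluator,
    SearchConfig,
    build_search_space,
    crowding_distance,
    dominates,
    exhaustive_front,
    hypervolume,
    non_dominated_sort,
    run_search,
)
from gcdesign.fixtures import toy_redox_model
from gcdesign.search import decode, vary


# -- dominance ---------------------------------------------------------------

def test_dominates_tradeoff_incomparable():
    a, b = (10, 0, -0.5), (6, 4, 0.267)
    assert not dominates(a, b) and not dominates(b, a)


def test_dominates_single_improvement():
    assert dominates((6, 4, 0.3), (6, 4, 0.267))


def test_dominates_irreflexive():
    assert not dominates((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))


def _brute_force_fronts(fitnesses):
    remaining = list(range(len(fitnesses)))
    fronts = []
    while remaining:
        front = [
            i for i in remaining
            if not any(dominates(fitnesses[j], fitnesses[i]) for j in remaining)
        ]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


def test_sort_matches_brute_force_200_random():
    rng = np.random.default_rng(42)
    fits = [tuple(v) for v in rng.random((200, 3))]
    got = non_dominated_sort(fits)
    assert [sorted(f) for f in got] == _brute_force_fronts(fits)
    assert sorted(i for f in got for i in f) == list(range(200))


@given(
    st.lists(
        st.tuples(st.integers(0, 4), st.integers(0, 4), st.integers(0, 4)),
        min_size=1,
        max_size=30,
    )
)
def test_sort_matches_brute_force_property(fits):
    fits = [tuple(map(float, f)) for f in fits]
    assert [sorted(f) for f in non_dominated_sort(fits)] == _brute_force_fronts(fits)


def test_sort_identical_points_single_front():
    fits = [(1.0, 1.0, 1.0)] * 5
    assert non_dominated_sort(fits) == [[0, 1, 2, 3, 4]]


def test_sort_chain_gives_singletons():
    fits = [(3, 3, 3), (2, 2, 2), (1, 1, 1)]
    assert non_dominated_sort(fits) == [[0], [1], [2]]


# -- crowding ---------------------------------------------------------------

def test_crowding_two_members_infinite():
    d = crowding_distance([(0, 0, 0), (1, 1, 1)])
    assert np.all(np.isinf(d))


def test_crowding_collinear_middle_finite():
    d = crowding_distance([(0, 0, 0), (1, 1, 1), (2, 2, 2)])
    assert np.isinf(d[0]) and np.isinf(d[2])
    assert d[1] == pytest.approx(3.0)  # one full-range gap per objective


def test_crowding_empty():
    assert crowding_distance([]).size == 0


# -- hypervolume --------------------------------------------------------------

def test_hypervolume_single_box():
    assert hypervolume([(2.0, 3.0, 0.0)], ref=(0, 0, -1)) == pytest.approx(6.0)


def test_hypervolume_union_of_boxes():
    pts = [(2.0, 1.0, 0.0), (1.0, 2.0, 0.0)]
    assert hypervolume(pts, ref=(0, 0, -1)) == pytest.approx(3.0)


def test_hypervolume_dominated_point_adds_nothing():
    base = hypervolume([(2.0, 2.0, 0.5)], ref=(0, 0, -1))
    more = hypervolume([(2.0, 2.0, 0.5), (1.0, 1.0, 0.0)], ref=(0, 0, -1))
    assert more == pytest.approx(base)


# -- variation ----------------------------------------------------------------

def test_vary_identity_without_operators():
    rng = np.random.default_rng(0)
    parents = np.array([[0, -1, 1], [1, 1, -1]])
    children = vary(parents, rng, 3, crossover_prob=0.0, mutation_rate=0.0)
    assert np.array_equal(children, parents)


def test_vary_full_mutation_redraws_everything():
    rng = np.random.default_rng(1)
    parents = np.full((4, 5), -1)
    children = vary(parents, rng, 50, crossover_prob=0.0, mutation_rate=1.0)
    assert children.min() >= -1 and children.max() < 50
    assert not np.array_equal(children, parents)  # astronomically unlikely


def test_vary_deterministic_under_seed():
    parents = np.array([[0, 1], [2, -1], [1, 1], [-1, 0]])
    a = vary(np.copy(parents), np.random.default_rng(7), 3, 0.8, 0.5)
    b = vary(np.copy(parents), np.random.default_rng(7), 3, 0.8, 0.5)
    assert np.array_equal(a, b)


def test_decode_drops_none_and_duplicates():
    assert decode(np.array([-1, 2, 2, 0, -1])) == frozenset({0, 2})


# -- whole searches ------------------------------------------------------------

def _toy_search_space(cfg):
    model = toy_redox_model()
    reduced, cands, _ = build_search_space(model)
    return DesignEvaluator(reduced, cfg, cands), cands


@pytest.mark.parametrize("seed", range(10))
def test_search_recovers_exhaustive_front(seed):
    cfg = SearchConfig(
        k_max=2, pop_size=20, max_generations=50, tau=0.0, n_env=50, seed=seed
    )
    ev, cands = _toy_search_space(cfg)
    archive = run_search(ev, len(cands), cfg)
    got = {
        (round(f.growth, 6), round(f.product, 6), round(f.coupling, 3))
        for f in archive.fitnesses()
    }
    assert got == {(10.0, 0.0, -0.5), (6.0, 4.0, 0.267), (5.0, 5.0, 0.5)}


def test_search_matches_oracle_on_random_family():
    from gcdesign.fixtures import random_coupling_family

    model = random_coupling_family(n_branches=2, cofactor_ratio=1.0, seed=5)
    reduced, cands, _ = build_search_space(model)
    cfg = SearchConfig(
        k_max=3, pop_size=24, max_generations=60, tau=0.0, n_env=20, seed=11
    )
    ev = DesignEvaluator(reduced, cfg, cands)
    archive = run_search(ev, len(cands), cfg)
    oracle = exhaustive_front(ev, len(cands), cfg.k_max)
    got = {tuple(np.round(f.as_tuple(), 6)) for f in archive.fitnesses()}
    want = {tuple(np.round(f.as_tuple(), 6)) for f in oracle.fitnesses()}
    assert got == want


def test_search_time_limit_zero_returns_initial_archive():
    cfg = SearchConfig(
        k_max=2, pop_size=20, max_generations=50, time_limit=0.0, seed=0
    )
    ev, cands = _toy_search_space(cfg)
    archive = run_search(ev, len(cands), cfg)
    # only the initial population was evaluated; wild type is seeded
    assert ev.cache_size <= cfg.pop_size
    assert any(d == frozenset() for d, _ in archive.entries)


def test_search_deterministic_under_seed():
    cfg = SearchConfig(k_max=2, pop_size=20, max_generations=30, seed=9)
    runs = []
    for _ in range(2):
        ev, cands = _toy_search_space(cfg)
        archive = run_search(ev, len(cands), cfg)
        runs.append(
            sorted((tuple(sorted(d)), f.as_tuple()) for d, f in archive.entries)
        )
    assert runs[0] == runs[1]


def test_search_rejects_empty_candidates(toy_evaluator):
    with pytest.raises(ValueError):
        run_search(toy_evaluator, 0, SearchConfig(k_max=2, pop_size=4))


def test_archive_mutually_non_dominated_and_reevaluable():
    cfg = SearchConfig(
        k_max=2, pop_size=20, max_generations=30, tau=0.0, n_env=50, seed=4
    )
    ev, cands = _toy_search_space(cfg)
    archive = run_search(ev, len(cands), cfg)
    fits = archive.fitnesses()
    for i, (d, f) in enumerate(archive.entries):
        fresh = DesignEvaluator(ev.model, cfg, cands).evaluate(d)
        assert fresh.as_tuple() == pytest.approx(f.as_tuple(), abs=1e-9)
        for j, g in enumerate(fits):
            if i != j:
                assert not dominates(g, f)
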
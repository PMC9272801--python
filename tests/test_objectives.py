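"""Coupling strength, classification and full design fitness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gcdesign import classify_coupling, coupling_strength
from gcdesign.flux import ProductionEnvelope
from gcdesign.objectives import DesignEvaluator


def _envelope(mu_grid, p_lo, p_hi, p_max=None, mu_apex=None):
    mu_grid = np.asarray(mu_grid, dtype=float)
    p_lo = np.asarray(p_lo, dtype=float)
    p_hi = np.asarray(p_hi, dtype=float)
    if p_max is None:
        p_max = float(p_hi.max())
    if mu_apex is None:
        attains = np.flatnonzero(p_hi >= p_max * (1 - 1e-6))
        mu_apex = float(mu_grid[attains[-1]]) if attains.size else float(
            mu_grid[int(np.argmax(p_hi))]
        )
    return ProductionEnvelope(
        mu_grid=mu_grid, p_lo=p_lo, p_hi=p_hi,
        mu_star=float(mu_grid[-1]), p_max=p_max, mu_apex=mu_apex,
    )


# -- guaranteed synthesis (tau = 0, exact hand LPs) -------------------------

@pytest.mark.parametrize(
    "kos, expected",
    [(("RSP",), 4.0), (("RSP", "ALT"), 5.0), ((), 0.0)],
)
def test_guaranteed_synthesis(toy_evaluator, rid, kos, expected):
    p = toy_evaluator.guaranteed_synthesis([rid[r] for r in kos])
    assert p == pytest.approx(expected, abs=1e-6)


# -- coupling strength on computed and constructed envelopes ----------------

def test_cs_wild_type(toy_flux):
    env = toy_flux.production_envelope([], n=10)
    assert coupling_strength(env) == pytest.approx(-0.5, abs=1e-6)


def test_cs_strong(toy_flux, rid):
    env = toy_flux.production_envelope([rid["RSP"], rid["ALT"]], n=10)
    assert coupling_strength(env) == pytest.approx(0.5, abs=1e-6)


def test_cs_weak_grid_and_fine(toy_flux, rid):
    cs10 = coupling_strength(toy_flux.production_envelope([rid["RSP"]], n=10))
    cs_fine = coupling_strength(toy_flux.production_envelope([rid["RSP"]], n=600))
    assert cs10 == pytest.approx(0.268, abs=1e-3)
    assert cs_fine == pytest.approx(4.0 / 15.0, abs=1e-4)


def test_cs_no_synthesis(toy_flux, rid):
    env = toy_flux.production_envelope([rid["PRD"]], n=10)
    assert coupling_strength(env) == -1.0
    assert classify_coupling(env) == "no-synthesis"


def test_cs_sign_law():
    """coupled <=> CS > 0; uncoupled <=> CS in [-1, 0] (given synthesis
    is possible at all)."""
    mu = np.linspace(0, 10, 11)
    coupled = _envelope(mu, np.maximum(0, mu - 1), np.minimum(mu + 1, 10))
    uncoupled = _envelope(mu, np.zeros_like(mu), np.minimum(mu, 10 - mu))
    assert coupling_strength(coupled) > 0
    assert classify_coupling(coupled) in ("weak", "strong")
    assert -1 <= coupling_strength(uncoupled) <= 0
    assert classify_coupling(uncoupled) == "uncoupled"


@given(st.floats(0.1, 100.0))
def test_cs_scale_invariance(c):
    mu = np.linspace(0, 8, 17)
    p_lo = np.maximum(0.0, mu - 3.0)
    p_hi = np.maximum(p_lo, np.minimum(mu, 8 - 0.5 * mu))
    base = coupling_strength(_envelope(mu, p_lo, p_hi))
    scaled = coupling_strength(_envelope(c * mu, c * p_lo, c * p_hi))
    assert scaled == pytest.approx(base, rel=1e-9)


def test_cs_uncoupled_monotone_in_apex():
    """Among uncoupled envelopes with equal mu*, CS strictly increases
    as the apex moves toward maximum growth."""
    mu = np.linspace(0, 10, 101)
    scores = []
    for apex in (2.0, 5.0, 8.0, 10.0):
        width = 10.0 - apex
        p_hi = np.where(
            mu <= apex, 5 * mu / apex if apex else 5.0,
            5 * (10 - mu) / width if width else 5.0,
        )
        env = _envelope(mu, np.zeros_like(mu), p_hi)
        scores.append(coupling_strength(env))
    assert scores == sorted(scores)
    assert all(a < b for a, b in zip(scores, scores[1:]))


def test_classification_examples(toy_flux, rid):
    weak = toy_flux.production_envelope([rid["RSP"]], n=10)
    strong = toy_flux.production_envelope([rid["RSP"], rid["ALT"]], n=10)
    wt = toy_flux.production_envelope([], n=10)
    assert classify_coupling(weak, f_min=0.1) == "weak"
    assert classify_coupling(strong, f_min=0.1) == "strong"
    assert classify_coupling(wt) == "uncoupled"


# -- full design evaluation --------------------------------------------------

def test_evaluate_design_weak(toy_evaluator, rid):
    f = toy_evaluator.evaluate(frozenset({rid["RSP"]}))
    assert f.viable
    assert f.growth == pytest.approx(6.0, abs=1e-6)
    assert f.product == pytest.approx(4.0, abs=1e-6)
    assert f.coupling == pytest.approx(4.0 / 15.0, abs=1e-3)
    assert f.coupling_class == "weak"


def test_evaluate_design_nonviable(toy_evaluator, rid):
    f = toy_evaluator.evaluate(frozenset({rid["GRW"], rid["ALT"]}))
    assert not f.viable
    assert f.as_tuple() == (0.0, 0.0, -1.0)


def test_evaluate_design_wild_type(toy_evaluator):
    f = toy_evaluator.evaluate(frozenset())
    assert f.as_tuple() == pytest.approx((10.0, 0.0, -0.5), abs=1e-6)
    assert f.coupling_class == "uncoupled"


def test_memoization_transparent(toy, exact_cfg, rid):
    ev = DesignEvaluator(toy, exact_cfg)
    d = frozenset({rid["RSP"]})
    first = ev.evaluate(d)
    assert ev.cache_size == 1
    again = ev.evaluate(d)
    assert again is first  # cached
    fresh = DesignEvaluator(toy, exact_cfg).evaluate(d)
    assert fresh.as_tuple() == first.as_tuple()


def test_fitness_invariants_over_design_space(toy_evaluator, rid):
    """CS bounded, sentinel well-formed, class/product consistency."""
    pool = [rid[r] for r in ("GRW", "ALT", "RSP", "PRD")]
    from itertools import combinations

    for size in range(3):
        for combo in combinations(pool, size):
            f = toy_evaluator.evaluate(frozenset(combo))
            assert -1.0 <= f.coupling <= 1.0
            assert f.growth >= 0 and f.product >= 0
            if not f.viable:
                assert f.as_tuple() == (0.0, 0.0, -1.0)
            elif f.coupling_class in ("weak", "strong"):
                assert f.product > toy_evaluator.cfg.eps_p
                assert f.coupling > 0
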
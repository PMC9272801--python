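"""Search-space reduction: dead removal, lumping, essentiality screens."""

import numpy as np
import pytest

from gcdesign import (
    DesignEvaluator,
    ReductionOptions,
    SearchConfig,
    build_search_space,
    find_dead_reactions,
    lump_unbranched,
    screen_essentials,
)
from gcdesign.fixtures import toy_redox_model, toy_variant
from gcdesign.io import ConfigurationError
from gcdesign.model import MetabolicModel
import scipy.sparse as sp


def _ids(model, indices):
    return {model.reaction_ids[j] for j in indices}


def test_dead_reactions_toy_variant():
    m = toy_variant("dead")
    assert _ids(m, find_dead_reactions(m)) == {"DED"}


def test_dead_reactions_none_in_toy(toy):
    assert find_dead_reactions(toy) == set()


def test_zero_bounded_reaction_is_dead(toy):
    m = toy.copy()
    j = m.reaction_index("ALT")
    m.lb[j] = m.ub[j] = 0.0
    assert j in find_dead_reactions(m)


def test_lump_unbranched_merges_split_pathway():
    m = toy_variant("lumpable")
    reduced, groups, membership = lump_unbranched(m)
    assert groups == [["GRW1", "GRW2"]]
    assert reduced.n_reactions == m.n_reactions - 1
    # M is internal to the composite and disappears
    assert "M" not in reduced.metabolite_ids
    # composite stoichiometry equals the original fused reaction
    from gcdesign import FluxEvaluator

    assert FluxEvaluator(reduced).fba_max_growth() == pytest.approx(10.0)


def test_lump_nothing_in_toy(toy):
    reduced, groups, _ = lump_unbranched(toy)
    assert groups == []
    assert reduced.reaction_ids == toy.reaction_ids


def test_lump_chain_of_three():
    # A -> X -> Y -> B chain collapses into a single composite
    m = MetabolicModel(
        metabolite_ids=["A", "X", "Y", "B"],
        reaction_ids=["SRC", "R1", "R2", "R3", "BIO"],
        stoich=sp.csc_matrix(
            np.array(
                [
                    [1, -1, 0, 0, 0],
                    [0, 1, -1, 0, 0],
                    [0, 0, 1, -1, 0],
                    [0, 0, 0, 1, -1],
                ],
                dtype=float,
            )
        ),
        lb=np.zeros(5),
        ub=np.full(5, 1000.0),
        objective_index=4,
    )
    reduced, groups, _ = lump_unbranched(m)
    assert groups == [["R1", "R2", "R3"]]


def test_lump_preserves_objectives_for_all_designs():
    """Any design expressible on both models evaluates identically."""
    m = toy_variant("lumpable")
    cfg = SearchConfig(k_max=2, pop_size=4, tau=0.0, n_env=20)
    reduced, cands, rmap = build_search_space(m, ReductionOptions())
    base = toy_redox_model()
    _, cands0, _ = build_search_space(base, ReductionOptions())
    ev_red = DesignEvaluator(reduced, cfg, cands)
    ev_base = DesignEvaluator(base, cfg, cands0)
    assert cands.labels() == cands0.labels() == ["ALT", "RSP"]
    for design in [frozenset(), {0}, {1}, {0, 1}]:
        fa = ev_red.evaluate(frozenset(design)).as_tuple()
        fb = ev_base.evaluate(frozenset(design)).as_tuple()
        assert fa == pytest.approx(fb, abs=1e-6)


def test_screen_essentials_toy(toy):
    cands = screen_essentials(toy)
    assert cands.labels() == ["ALT", "RSP"]
    reasons = dict(cands.excluded)
    assert reasons["GRW"] == "synthesis-essential"
    assert reasons["PRD"] == "synthesis-essential"
    assert reasons["SRC"] == "exchange"
    assert reasons["BIO"] == "objective"
    assert reasons["EXP"] == "target"


def test_screen_essentials_growth_threshold(toy):
    # at 70% of wild-type growth, KO{RSP} (mu*=6 < 7) becomes essential
    cands = screen_essentials(toy, options=ReductionOptions(min_growth_frac=0.7))
    assert cands.labels() == ["ALT"]
    assert ("RSP", "growth-essential") in cands.excluded


def test_screen_essentials_requires_viable_wild_type(toy):
    m = toy.copy()
    m.ub[m.reaction_index("SRC")] = 0.0
    with pytest.raises(ConfigurationError):
        screen_essentials(m)


def test_build_search_space_combined_variant():
    m = toy_variant("combined")
    reduced, cands, rmap = build_search_space(m)
    assert rmap.dropped == ["DED"]
    assert rmap.lump_groups == [["GRW1", "GRW2"]]
    assert cands.labels() == ["ALT", "RSP"]
    # the lumped composite was screened out as synthesis-essential
    reasons = dict(cands.excluded)
    assert reasons["GRW1+GRW2"] == "synthesis-essential"


def test_user_exclusion(toy):
    _, cands, _ = build_search_space(
        toy, ReductionOptions(user_exclude=frozenset({"ALT"}))
    )
    assert cands.labels() == ["RSP"]
    assert ("ALT", "user") in cands.excluded


def test_gene_assoc_only(toy):
    m = toy.copy()
    m.gene_associated[m.reaction_index("ALT")] = False
    _, cands, _ = build_search_space(m, ReductionOptions(gene_assoc_only=True))
    assert cands.labels() == ["RSP"]
    assert ("ALT", "no-gene") in cands.excluded


def test_maintenance_reactions_never_candidates(toy):
    m = toy.copy()
    j = m.reaction_index("ALT")
    m.lb[j] = 0.5  # forced positive flux: an assay constraint, not genetics
    cands = screen_essentials(m)
    assert ("ALT", "maintenance") in cands.excluded


def test_reduction_idempotent():
    m = toy_variant("combined")
    reduced1, cands1, _ = build_search_space(m)
    reduced2, cands2, rmap2 = build_search_space(reduced1)
    assert rmap2.dropped == [] and rmap2.lump_groups == []
    assert reduced2.reaction_ids == reduced1.reaction_ids
    assert cands2.labels() == cands1.labels()
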
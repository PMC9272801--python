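"""Small synthetic metabolic models with known coupling structure.

These fixtures make every stage of the pipeline testable by hand.  The
canonical ``toy_redox_model`` embodies the classic growth-coupling
mechanism: product synthesis is the only alternative sink for a redox
cofactor, so knocking out respiration forces synthesis whenever the
cell grows.  All fluxes are round numbers so the expected LP optima
can be derived with pencil and paper.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .model import MetabolicModel


def _build(metabolites, reactions, objective, target) -> MetabolicModel:
    """reactions: list of (id, {met: coeff}, lb, ub, gene_associated)."""
    met_pos = {m: i for i, m in enumerate(metabolites)}
    rows, cols, vals = [], [], []
    ids, lb, ub, gene = [], [], [], []
    for j, (rid, stoich, lo, hi, g) in enumerate(reactions):
        ids.append(rid)
        lb.append(lo)
        ub.append(hi)
        gene.append(g)
        for mid, coeff in stoich.items():
            rows.append(met_pos[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sp.csc_matrix((vals, (rows, cols)), shape=(len(metabolites), len(ids)))
    return MetabolicModel(
        metabolite_ids=list(metabolites),
        reaction_ids=ids,
        stoich=S,
        lb=np.array(lb, dtype=float),
        ub=np.array(ub, dtype=float),
        objective_index=ids.index(objective),
        target_index=ids.index(target) if target is not None else None,
        gene_associated=np.array(gene),
    )


def toy_redox_model() -> MetabolicModel:
    """Four metabolites, seven reactions, hand-solvable optima.

    A is the substrate, B the biomass precursor, N a redox cofactor and
    P the product.  Growth (GRW) produces N which must be drained by
    respiration (RSP) or by synthesis (PRD); knocking out RSP therefore
    growth-couples P, and additionally knocking out the redox-neutral
    bypass (ALT) makes the coupling strong.

    Wild type: mu* = 10 with no guaranteed synthesis.
    KO {RSP}: (growth 6, product 4, weak coupling).
    KO {RSP, ALT}: (growth 5, product 5, strong coupling).
    """
    return _build(
        ["A", "B", "N", "P"],
        [
            ("SRC", {"A": 1}, 0, 10, False),
            ("GRW", {"A": -1, "B": 1, "N": 1}, 0, 1000, True),
            ("ALT", {"A": -1, "B": 1}, 0, 2, True),
            ("BIO", {"B": -1}, 0, 1000, False),
            ("RSP", {"N": -1}, 0, 1000, True),
            ("PRD", {"A": -1, "N": -1, "P": 1}, 0, 1000, True),
            ("EXP", {"P": -1}, 0, 1000, False),
        ],
        objective="BIO",
        target="EXP",
    )


def toy_variant(which: str) -> MetabolicModel:
    """Reduction-rule exercisers derived from the toy model.

    ``dead``     adds DED: X -> Y with X and Y otherwise unused, so DED
                 can never carry flux;
    ``lumpable`` splits GRW into GRW1: A -> M + N and GRW2: M -> B with
                 M unique to the pair, so the two lump back into GRW;
    ``combined`` applies both edits.
    """
    if which not in ("dead", "lumpable", "combined"):
        raise ValueError(f"unknown variant {which!r}")
    metabolites = ["A", "B", "N", "P"]
    reactions = [
        ("SRC", {"A": 1}, 0, 10, False),
        ("GRW", {"A": -1, "B": 1, "N": 1}, 0, 1000, True),
        ("ALT", {"A": -1, "B": 1}, 0, 2, True),
        ("BIO", {"B": -1}, 0, 1000, False),
        ("RSP", {"N": -1}, 0, 1000, True),
        ("PRD", {"A": -1, "N": -1, "P": 1}, 0, 1000, True),
        ("EXP", {"P": -1}, 0, 1000, False),
    ]
    if which in ("lumpable", "combined"):
        metabolites = metabolites + ["M"]
        reactions = [r for r in reactions if r[0] != "GRW"]
        reactions.insert(1, ("GRW1", {"A": -1, "M": 1, "N": 1}, 0, 1000, True))
        reactions.insert(2, ("GRW2", {"M": -1, "B": 1}, 0, 1000, True))
    if which in ("dead", "combined"):
        metabolites = metabolites + ["X", "Y"]
        reactions = reactions + [("DED", {"X": -1, "Y": 1}, 0, 1000, True)]
    return _build(metabolites, reactions, objective="BIO", target="EXP")


def random_coupling_family(
    n_branches: int = 2, cofactor_ratio: float = 1.0, seed: int = 0
) -> MetabolicModel:
    """Seeded family of branched toy-like networks for search stress tests.

    ``n_branches`` growth routes share substrate A; each branch i has a
    cofactor-producing route GRW_i: A -> B + a_i N and a redox-neutral
    bypass ALT_i: A -> B with a small capacity.  Synthesis PRD consumes
    A plus ``cofactor_ratio`` N per product, so with ratio 0 no
    knockout set can ever force synthesis (the cofactor never ties
    product to growth), while with ratio > 0 closing the cofactor sink
    RSP couples synthesis.  The candidate space stays small enough for
    exhaustive enumeration (<= 2*n_branches + 1 targets).
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    metabolites = ["A", "B", "N", "P"]
    reactions = [("SRC", {"A": 1}, 0, 10, False)]
    for i in range(1, n_branches + 1):
        a_i = int(rng.integers(1, 3))  # cofactor yield of branch i
        cap = int(rng.integers(1, 4))  # bypass capacity
        reactions.append((f"GRW{i}", {"A": -1, "B": 1, "N": a_i}, 0, 1000, True))
        reactions.append((f"ALT{i}", {"A": -1, "B": 1}, 0, cap, True))
    stoich_prd = {"A": -1, "P": 1}
    if cofactor_ratio > 0:
        stoich_prd["N"] = -float(cofactor_ratio)
    reactions += [
        ("BIO", {"B": -1}, 0, 1000, False),
        ("RSP", {"N": -1}, 0, 1000, True),
        ("PRD", stoich_prd, 0, 1000, True),
        ("EXP", {"P": -1}, 0, 1000, False),
    ]
    return _build(metabolites, reactions, objective="BIO", target="EXP")
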
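"""Search-space reduction: dead reactions, lumping, essentiality screens.

The knockout design space of a genome-scale model is pruned in three
steps before the search:

1. *dead reactions* — reactions whose flux variability interval under
   the configured medium is {0}; they can never carry flux, so
   knocking them out is a no-op and they are removed outright;
2. *unbranched lumping* — two irreversible reactions coupled through a
   metabolite that appears nowhere else carry proportional fluxes at
   steady state, so they are merged into one composite column whose
   knockout means knocking out every member;
3. *essentiality screen* — single knockouts that abolish growth (below
   a configured fraction of wild type) or abolish synthesis entirely
   can never be part of a useful design and are excluded, along with
   boundary source reactions (the medium), the biomass and target
   columns, maintenance reactions with a positive lower bound, and
   optionally reactions without gene association.

Reduction preserves the objectives: any design expressible on the
reduced model evaluates identically (to LP tolerance) on the original.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .flux import ZERO_TOL, FluxEvaluator
from .io import ConfigurationError
from .model import MetabolicModel


@dataclass(frozen=True)
class KnockoutTarget:
    """One knockout candidate: a single reaction or a lumped composite."""

    label: str
    members: tuple[int, ...]  # reaction column indices in the reduced model
    original_ids: tuple[str, ...]  # reaction ids in the *original* model
    provenance: str  # "single" | "lumped"


@dataclass
class CandidateSet:
    """Knockout targets surviving reduction, plus the exclusion record."""

    targets: list[KnockoutTarget]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    # reasons: dead, growth-essential, synthesis-essential, exchange,
    # objective, target, no-gene, maintenance, user

    def __len__(self) -> int:
        return len(self.targets)

    def labels(self) -> list[str]:
        return [t.label for t in self.targets]

    def to_dict(self) -> dict:
        return {
            "targets": [
                {
                    "label": t.label,
                    "members": list(t.members),
                    "original_ids": list(t.original_ids),
                    "provenance": t.provenance,
                }
                for t in self.targets
            ],
            "excluded": [list(e) for e in self.excluded],
        }


@dataclass
class ReductionMap:
    """Record of what reduction did, for provenance and expansion."""

    lump_groups: list[list[str]] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"lump_groups": self.lump_groups, "dropped": self.dropped}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class ReductionOptions:
    min_growth_frac: float = 0.01
    gene_assoc_only: bool = False
    user_exclude: frozenset[str] = frozenset()
    lump: bool = True
    solver: str = "highs"


# ---------------------------------------------------------------------------
# Step 1: dead reactions
# ---------------------------------------------------------------------------

def find_dead_reactions(model: MetabolicModel, solver: str = "highs") -> set[int]:
    """Reactions whose FVA interval is within 1e-6 of {0} under the medium."""
    ev = FluxEvaluator(model, solver=solver)
    dead: set[int] = set()
    for j in range(model.n_reactions):
        if model.lb[j] == 0.0 and model.ub[j] == 0.0:
            dead.add(j)
            continue
        lo, hi = ev.flux_range(j)
        if abs(lo) <= ZERO_TOL and abs(hi) <= ZERO_TOL:
            dead.add(j)
    return dead


def drop_reactions(model: MetabolicModel, drop: set[int]) -> MetabolicModel:
    """Remove columns (and any rows left empty) from the model."""
    keep = [j for j in range(model.n_reactions) if j not in drop]
    if model.objective_index in drop:
        raise ConfigurationError("cannot drop the objective reaction")
    if model.target_index is not None and model.target_index in drop:
        raise ConfigurationError("cannot drop the target reaction")
    S = model.stoich[:, keep]
    row_nnz = S.getnnz(axis=1)
    keep_rows = np.flatnonzero(row_nnz > 0)
    S = S[keep_rows, :]
    old_to_new = {j: k for k, j in enumerate(keep)}
    return MetabolicModel(
        metabolite_ids=[model.metabolite_ids[i] for i in keep_rows],
        reaction_ids=[model.reaction_ids[j] for j in keep],
        stoich=sp.csc_matrix(S),
        lb=model.lb[keep],
        ub=model.ub[keep],
        objective_index=old_to_new[model.objective_index],
        target_index=(
            old_to_new[model.target_index] if model.target_index is not None else None
        ),
        gene_associated=model.gene_associated[keep],
    )


# ---------------------------------------------------------------------------
# Step 2: unbranched lumping
# ---------------------------------------------------------------------------

def lump_unbranched(
    model: MetabolicModel,
) -> tuple[MetabolicModel, list[list[str]], dict[str, list[str]]]:
    """Merge reaction pairs coupled through a two-participant metabolite.

    Returns the lumped model, the list of merged groups (original ids)
    and a membership map {reduced reaction id: [original ids]}.
    Only strictly unbranched, irreversible (lb >= 0) internal pairs with
    one producer and one consumer are merged; the biomass and target
    columns are never absorbed.
    """
    # working copies; composites tracked via membership lists
    S = sp.lil_matrix(model.stoich)
    lb = model.lb.copy()
    ub = model.ub.copy()
    ids = list(model.reaction_ids)
    gene = list(model.gene_associated)
    members: list[list[str]] = [[r] for r in model.reaction_ids]
    alive_rxn = np.ones(len(ids), dtype=bool)
    alive_met = np.ones(model.n_metabolites, dtype=bool)
    # never absorb the biomass/target columns or boundary reactions:
    # a composite knockout target must be purely internal pathway
    protected = {model.objective_index}
    if model.target_index is not None:
        protected.add(model.target_index)
    protected.update(np.flatnonzero(model.exchange_flags).tolist())

    changed = True
    while changed:
        changed = False
        Sc = sp.csr_matrix(S)
        for i in range(model.n_metabolites):
            if not alive_met[i]:
                continue
            row = Sc.getrow(i)
            cols = [j for j, v in zip(row.indices, row.data)
                    if alive_rxn[j] and v != 0.0]
            if len(cols) != 2:
                continue
            j1, j2 = cols
            if j1 in protected or j2 in protected:
                continue
            s1, s2 = Sc[i, j1], Sc[i, j2]
            # need one producer, one consumer, both irreversible
            if s1 * s2 >= 0 or lb[j1] < 0 or lb[j2] < 0:
                continue
            prod, cons = (j1, j2) if s1 > 0 else (j2, j1)
            a, b = abs(Sc[i, prod]), abs(Sc[i, cons])
            # steady state at metabolite i: a v_prod = b v_cons
            r = a / b  # v_cons = r * v_prod
            new_lb = max(lb[prod], lb[cons] / r if r > 0 else lb[cons])
            new_ub = min(ub[prod], ub[cons] / r if r > 0 else ub[cons])
            if new_lb > new_ub:
                continue  # bound directions conflict; skip
            # composite column expressed in units of the producer flux
            S[:, prod] = S[:, prod] + r * S[:, cons]
            S[i, prod] = 0.0
            lb[prod], ub[prod] = new_lb, new_ub
            gene[prod] = gene[prod] or gene[cons]
            members[prod] = members[prod] + members[cons]
            alive_rxn[cons] = False
            alive_met[i] = False
            changed = True
            break  # Sc is stale after a merge; rescan

    keep = np.flatnonzero(alive_rxn)
    keep_set = set(keep.tolist())
    Sf = sp.csc_matrix(S)[:, keep]
    row_nnz = Sf.getnnz(axis=1)
    keep_rows = np.flatnonzero(row_nnz > 0)
    Sf = Sf[keep_rows, :]
    old_to_new = {j: k for k, j in enumerate(keep)}
    new_ids = []
    membership: dict[str, list[str]] = {}
    groups: list[list[str]] = []
    for j in keep:
        if len(members[j]) > 1:
            rid = "+".join(sorted(members[j]))
            groups.append(sorted(members[j]))
        else:
            rid = ids[j]
        new_ids.append(rid)
        membership[rid] = sorted(members[j])
    assert model.objective_index in keep_set
    reduced = MetabolicModel(
        metabolite_ids=[model.metabolite_ids[i] for i in keep_rows],
        reaction_ids=new_ids,
        stoich=Sf,
        lb=lb[keep],
        ub=ub[keep],
        objective_index=old_to_new[model.objective_index],
        target_index=(
            old_to_new[model.target_index] if model.target_index is not None else None
        ),
        gene_associated=np.array([gene[j] for j in keep]),
    )
    return reduced, groups, membership


# ---------------------------------------------------------------------------
# Step 3: essentiality and role screens
# ---------------------------------------------------------------------------

def screen_essentials(
    model: MetabolicModel,
    membership: dict[str, list[str]] | None = None,
    options: ReductionOptions | None = None,
) -> CandidateSet:
    """Build the candidate set by single-knockout screening.

    Excluded with a recorded reason: the objective and target columns,
    import-capable boundary sources (they encode the medium, not
    genetics), maintenance reactions with lb > 0, user-listed ids,
    gene-less reactions under ``gene_assoc_only``, and reactions whose
    lone knockout drops growth below ``min_growth_frac`` of wild type
    (growth-essential) or zeroes the maximum product flux
    (synthesis-essential).
    """
    opts = options or ReductionOptions()
    if membership is None:
        membership = {r: [r] for r in model.reaction_ids}
    ev = FluxEvaluator(model, solver=opts.solver)
    wt_mu = ev.fba_max_growth(())
    if wt_mu <= 0:
        raise ConfigurationError("wild-type model infeasible or cannot grow")
    uptake = model.uptake_capable()
    targets: list[KnockoutTarget] = []
    excluded: list[tuple[str, str]] = []
    for j, rid in enumerate(model.reaction_ids):
        origin = membership.get(rid, [rid])
        if j == model.objective_index:
            excluded.append((rid, "objective"))
            continue
        if j == model.target_index:
            excluded.append((rid, "target"))
            continue
        if uptake[j]:
            excluded.append((rid, "exchange"))
            continue
        if model.lb[j] > 0:
            excluded.append((rid, "maintenance"))
            continue
        if any(o in opts.user_exclude for o in origin) or rid in opts.user_exclude:
            excluded.append((rid, "user"))
            continue
        if opts.gene_assoc_only and not model.gene_associated[j]:
            excluded.append((rid, "no-gene"))
            continue
        mu = ev.fba_max_growth([j])
        if mu < opts.min_growth_frac * wt_mu:
            excluded.append((rid, "growth-essential"))
            continue
        if model.target_index is not None:
            p = ev.max_product([j])
            if p <= ZERO_TOL:
                excluded.append((rid, "synthesis-essential"))
                continue
        targets.append(
            KnockoutTarget(
                label=rid,
                members=(j,),
                original_ids=tuple(sorted(origin)),
                provenance="lumped" if len(origin) > 1 else "single",
            )
        )
    return CandidateSet(targets=targets, excluded=excluded)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def build_search_space(
    model: MetabolicModel, options: ReductionOptions | None = None
) -> tuple[MetabolicModel, CandidateSet, ReductionMap]:
    """dead -> lump -> essentials, producing the reduced search space."""
    opts = options or ReductionOptions()
    rmap = ReductionMap()
    dead = find_dead_reactions(model, solver=opts.solver)
    dead -= {model.objective_index}
    if model.target_index is not None:
        dead -= {model.target_index}
    rmap.dropped = sorted(model.reaction_ids[j] for j in dead)
    reduced = drop_reactions(model, dead) if dead else model.copy()
    if opts.lump:
        reduced, groups, membership = lump_unbranched(reduced)
        rmap.lump_groups = groups
    else:
        membership = {r: [r] for r in reduced.reaction_ids}
    candidates = screen_essentials(reduced, membership, opts)
    for rid in rmap.dropped:
        candidates.excluded.append((rid, "dead"))
    return reduced, candidates, rmap


def read_exclusion_list(path: str | Path) -> frozenset[str]:
    """Newline-delimited reaction ids; blank lines and '#' comments skipped."""
    lines = Path(path).read_text().splitlines()
    return frozenset(
        s.strip() for s in lines if s.strip() and not s.strip().startswith("#")
    )
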
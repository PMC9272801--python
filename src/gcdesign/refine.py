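"""Post-processing: strip redundant knockouts and re-filter the front.

The search may archive designs carrying knockouts that contribute
nothing — for instance a knockout of a reaction that is already
flux-less in every optimum.  Each archived design is reduced to a
fixed point under single-knockout removal: a knockout is dropped
whenever re-evaluation without it is at least as good in all three
objectives.  The surviving designs are de-duplicated and Pareto
filtered once more.
"""

from __future__ import annotations

from .objectives import DesignEvaluator, FitnessTriple
from .search import ParetoArchive, dominates

#: Objective tolerance when deciding that a removal loses nothing.
REMOVAL_TOL = 1e-6


def _at_least_as_good(new: FitnessTriple, old: FitnessTriple) -> bool:
    return all(
        n >= o - REMOVAL_TOL for n, o in zip(new.as_tuple(), old.as_tuple())
    )


def remove_redundant_kos(
    evaluator: DesignEvaluator,
    design: frozenset[int],
    fitness: FitnessTriple | None = None,
) -> tuple[frozenset[int], FitnessTriple]:
    """Minimal design under single-knockout removal.

    Deterministic order: candidates are tried in ascending target
    index; after any successful removal the scan restarts against the
    improved incumbent.  Never lowers any objective, never grows the
    design.
    """
    incumbent = fitness if fitness is not None else evaluator.evaluate(design)
    current = set(design)
    changed = True
    while changed:
        changed = False
        for t in sorted(current):
            trial = frozenset(current - {t})
            fit = evaluator.evaluate(trial)
            if fit.viable and _at_least_as_good(fit, incumbent):
                current = set(trial)
                incumbent = fit
                changed = True
                break
    return frozenset(current), incumbent


def pareto_filter(
    entries: list[tuple[frozenset[int], FitnessTriple]]
) -> ParetoArchive:
    """Drop dominated entries and duplicate designs (first kept)."""
    seen: set[frozenset[int]] = set()
    unique: list[tuple[frozenset[int], FitnessTriple]] = []
    for d, f in entries:
        if d in seen:
            continue
        seen.add(d)
        unique.append((d, f))
    kept = [
        (d, f)
        for d, f in unique
        if not any(dominates(g, f) for _, g in unique)
    ]
    return ParetoArchive(entries=kept)


def refine_archive(
    evaluator: DesignEvaluator, archive: ParetoArchive
) -> ParetoArchive:
    """remove_redundant_kos on every entry, then de-dup + Pareto filter."""
    refined = [
        remove_redundant_kos(evaluator, d, f) for d, f in archive.entries
    ]
    return pareto_filter(refined)


def expand_design(design: frozenset[int], candidates) -> list[str]:
    """Original-model reaction ids of a design, composites expanded."""
    ids: list[str] = []
    for t in design:
        if not 0 <= t < len(candidates.targets):
            raise IndexError(f"unknown candidate target index {t}")
        ids.extend(candidates.targets[t].original_ids)
    return sorted(ids)
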
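"""NSGA-II search over knockout designs.

Designs are encoded as fixed-length genomes of ``k_max`` slots, each
holding a candidate-target index or -1 (empty).  A genome decodes to
the set of its non-empty, de-duplicated slots, so the decoded design
has at most ``k_max`` knockouts.  The loop is the controlled-elitist
NSGA-II: binary tournament on (rank, crowding), uniform crossover,
per-slot reset mutation, and environmental selection from the merged
parent+child population.  An unbounded external archive keeps every
non-dominated design seen; termination is wall-clock, generation
count, or stagnation of the archive hypervolume.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import SearchConfig
from .objectives import DesignEvaluator, FitnessTriple

logger = logging.getLogger(__name__)

NONE_SLOT = -1

#: Reference point for hypervolume: the non-viable sentinel fitness.
HV_REFERENCE = (0.0, 0.0, -1.0)


# ---------------------------------------------------------------------------
# Dominance machinery
# ---------------------------------------------------------------------------

def dominates(a: FitnessTriple | tuple, b: FitnessTriple | tuple) -> bool:
    """Pareto dominance under maximization of all three objectives."""
    ta = a.as_tuple() if isinstance(a, FitnessTriple) else tuple(a)
    tb = b.as_tuple() if isinstance(b, FitnessTriple) else tuple(b)
    return all(x >= y for x, y in zip(ta, tb)) and any(
        x > y for x, y in zip(ta, tb)
    )


def non_dominated_sort(fitnesses: list) -> list[list[int]]:
    """Fast non-dominated sort (Deb et al. bookkeeping); returns fronts."""
    n = len(fitnesses)
    tuples = [
        f.as_tuple() if isinstance(f, FitnessTriple) else tuple(f)
        for f in fitnesses
    ]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(tuples[i], tuples[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(tuples[j], tuples[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if domination_count[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    nxt.append(j)
        current = sorted(nxt)
    return fronts


def crowding_distance(front: list) -> np.ndarray:
    """Per-member crowding distance; boundary members get +inf."""
    n = len(front)
    if n == 0:
        return np.zeros(0)
    tuples = np.array(
        [f.as_tuple() if isinstance(f, FitnessTriple) else tuple(f) for f in front]
    )
    dist = np.zeros(n)
    for m in range(tuples.shape[1]):
        order = np.argsort(tuples[:, m], kind="stable")
        lo, hi = tuples[order[0], m], tuples[order[-1], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if hi - lo <= 0 or n < 3:
            continue
        gaps = (tuples[order[2:], m] - tuples[order[:-2], m]) / (hi - lo)
        dist[order[1:-1]] += gaps
    return dist


# ---------------------------------------------------------------------------
# Hypervolume (3 objectives, maximization, small point sets)
# ---------------------------------------------------------------------------

def _area_2d(points: list[tuple[float, float]], rx: float, ry: float) -> float:
    """Dominated area above (rx, ry) for 2-D maximization points."""
    pts = sorted((p for p in points if p[0] > rx and p[1] > ry), reverse=True)
    area = 0.0
    best_y = ry
    for x, y in pts:
        if y > best_y:
            area += (x - rx) * (y - best_y)
            best_y = y
    return area


def hypervolume(fitnesses: list, ref: tuple[float, float, float] = HV_REFERENCE
                ) -> float:
    """Volume dominated by the point set, above the reference point.

    Computed by sweeping the third objective and accumulating 2-D
    slice areas — quadratic in the number of points, which is ample
    for archive-sized sets.
    """
    pts = [
        f.as_tuple() if isinstance(f, FitnessTriple) else tuple(f)
        for f in fitnesses
    ]
    pts = [p for p in pts if all(v > r for v, r in zip(p, ref))]
    if not pts:
        return 0.0
    zs = sorted({p[2] for p in pts}, reverse=True)
    zs.append(ref[2])
    vol = 0.0
    for k in range(len(zs) - 1):
        z = zs[k]
        slab = zs[k] - zs[k + 1]
        slice_pts = [(p[0], p[1]) for p in pts if p[2] >= z]
        vol += slab * _area_2d(slice_pts, ref[0], ref[1])
    return vol


# ---------------------------------------------------------------------------
# Genome handling
# ---------------------------------------------------------------------------

def decode(genome: np.ndarray) -> frozenset[int]:
    return frozenset(int(g) for g in genome if g != NONE_SLOT)


def vary(
    parents: np.ndarray,
    rng: np.random.Generator,
    n_targets: int,
    crossover_prob: float,
    mutation_rate: float,
) -> np.ndarray:
    """Uniform crossover on consecutive pairs, then per-slot reset mutation."""
    children = parents.copy()
    n, k = children.shape
    for i in range(0, n - 1, 2):
        if rng.random() < crossover_prob:
            mask = rng.random(k) < 0.5
            a = children[i].copy()
            children[i, mask] = children[i + 1, mask]
            children[i + 1, mask] = a[mask]
    # mutation: redraw slot uniformly from {none} + targets
    mut = rng.random(children.shape) < mutation_rate
    draws = rng.integers(-1, n_targets, size=children.shape)
    children[mut] = draws[mut]
    return children


# ---------------------------------------------------------------------------
# Archive
# ---------------------------------------------------------------------------

@dataclass
class ParetoArchive:
    """All mutually non-dominated (design, fitness) pairs seen so far."""

    entries: list[tuple[frozenset[int], FitnessTriple]] = field(default_factory=list)

    def update(self, design: frozenset[int], fit: FitnessTriple) -> None:
        if not fit.viable:
            return
        # equal-fitness distinct designs are alternatives and all kept;
        # only strict dominance evicts
        for d, f in self.entries:
            if d == design or dominates(f, fit):
                return
        self.entries = [
            (d, f) for d, f in self.entries if not dominates(fit, f)
        ]
        self.entries.append((design, fit))

    def fitnesses(self) -> list[FitnessTriple]:
        return [f for _, f in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def run_search(
    evaluator: DesignEvaluator,
    n_targets: int,
    cfg: SearchConfig,
) -> ParetoArchive:
    """NSGA-II over designs drawn from ``n_targets`` knockout candidates.

    The initial population contains the empty design (wild type is on
    the Pareto front by construction) plus uniform random genomes.
    Returns the external archive of all non-dominated designs.
    """
    if n_targets < 1:
        raise ValueError("empty candidate set: nothing to search")
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_max
    pop = rng.integers(-1, n_targets, size=(cfg.pop_size, k))
    pop[0, :] = NONE_SLOT  # seed the wild type
    archive = ParetoArchive()
    t0 = time.monotonic()
    hv_history: list[float] = []

    def evaluate_pop(genomes: np.ndarray) -> list[FitnessTriple]:
        fits = []
        for g in genomes:
            d = decode(g)
            f = evaluator.evaluate(d)
            archive.update(d, f)
            fits.append(f)
        return fits

    fits = evaluate_pop(pop)
    generation = 0
    reason = "generations"
    while True:
        hv = hypervolume(archive.fitnesses())
        hv_history.append(hv)
        best = _best_per_objective(fits)
        logger.info(
            "generation=%d evaluations=%d archive=%d hypervolume=%.6g "
            "best_growth=%.6g best_product=%.6g best_coupling=%.6g",
            generation, evaluator.cache_size, len(archive), hv, *best,
        )
        if generation >= cfg.max_generations:
            reason = "generations"
            break
        if time.monotonic() - t0 >= cfg.time_limit:
            reason = "time"
            break
        if len(hv_history) > cfg.stall_generations:
            past = hv_history[-cfg.stall_generations - 1]
            if abs(hv - past) <= cfg.stall_tol * max(abs(past), 1e-12):
                reason = "stall"
                break

        # selection: binary tournament on (rank, crowding)
        fronts = non_dominated_sort(fits)
        rank = np.empty(len(fits), dtype=int)
        crowd = np.empty(len(fits))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = crowding_distance([fits[i] for i in front])
        parents_idx = []
        for _ in range(cfg.pop_size):
            i, j = rng.integers(0, cfg.pop_size, size=2)
            if rank[i] < rank[j] or (rank[i] == rank[j] and crowd[i] > crowd[j]):
                parents_idx.append(i)
            else:
                parents_idx.append(j)
        children = vary(
            pop[parents_idx], rng, n_targets, cfg.crossover_prob,
            cfg.mutation_rate,
        )
        child_fits = evaluate_pop(children)

        # elitist environmental selection from merged population
        merged = np.vstack([pop, children])
        merged_fits = fits + child_fits
        fronts = non_dominated_sort(merged_fits)
        new_idx: list[int] = []
        for front in fronts:
            if len(new_idx) + len(front) <= cfg.pop_size:
                new_idx.extend(front)
            else:
                cd = crowding_distance([merged_fits[i] for i in front])
                order = sorted(
                    range(len(front)), key=lambda t: (-cd[t], front[t])
                )
                need = cfg.pop_size - len(new_idx)
                new_idx.extend(front[t] for t in order[:need])
                break
        pop = merged[new_idx]
        fits = [merged_fits[i] for i in new_idx]
        generation += 1

    logger.info(
        "terminated reason=%s generations=%d evaluations=%d archive=%d",
        reason, generation, evaluator.cache_size, len(archive),
    )
    return archive


def exhaustive_front(
    evaluator: DesignEvaluator, n_targets: int, k_max: int
) -> ParetoArchive:
    """Brute-force Pareto front over all designs of size <= k_max.

    Independent of the GA loop; tractable only for small candidate
    sets, where it serves as the reference the search must match.
    """
    from itertools import combinations

    archive = ParetoArchive()
    for size in range(k_max + 1):
        for combo in combinations(range(n_targets), size):
            d = frozenset(combo)
            archive.update(d, evaluator.evaluate(d))
    return archive


def _best_per_objective(fits: list[FitnessTriple]) -> tuple[float, float, float]:
    if not fits:
        return (0.0, 0.0, -1.0)
    arr = np.array([f.as_tuple() for f in fits])
    return tuple(arr.max(axis=0))
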
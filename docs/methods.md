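# Methods

## Model and evaluation

A model is a sparse stoichiometric matrix S (metabolites × reactions)
with per-reaction flux bounds, a biomass objective column and a product
exchange column. Every quantity the search optimizes is a flux balance
analysis LP: optimize one flux subject to S·v = 0 and lb ≤ v ≤ ub, with
knocked-out reactions pinned to lb = ub = 0 (reaction-deletion
semantics). LPs are solved with HiGHS dual simplex through scipy on the
matrix directly; HiGHS is deterministic, so re-evaluating a design
reproduces its fitness bit-for-bit, which the memoization cache and the
reproducibility contract (same invocation ⇒ byte-identical CSV) rely
on. Plain FBA only: loopless constraints are not imposed, so
thermodynamically infeasible cycles can inflate upper envelope bounds
in models that contain them — a known caveat of envelope-based scores.

Numerical conventions: all bounds are capped to ±1000 mmol·gDW⁻¹·h⁻¹ so
every LP is bounded; fluxes below 1e−6 are treated as zero; envelope
grid points fix the biomass flux two-sidedly with a ±1e−9·max(μ\*, 1)
slack, the top grid point backed off to μ\*(1 − 1e−9) to avoid vertex
infeasibility, with one retry at 1e−6 slack before an evaluation is
declared failed. LP failures during the search degrade the design to
the non-viable sentinel (0, 0, −1) rather than aborting the run.

## Production envelope and coupling strength

The envelope is computed on n + 1 evenly spaced growth values spanning
[0, μ\*] (default n = 10; a config knob, since a finer grid buys
integration accuracy with ~2n more LPs per design). The maximum
attainable synthesis p_max can fall strictly between grid points, so it
comes from its own growth-unconstrained LP rather than the grid maximum;
μ_apex is the largest grid growth attaining p_max within relative 1e−6,
falling back to the grid argmax when no grid point attains it.

Coupling strength CS is a piecewise functional of the envelope:

* p_max ≤ ε_p → CS = −1 (synthesis impossible);
* p_lo(μ\*) > ε_p (coupled) → CS = ∫ p_lo dμ / (μ\*·p_max), trapezoidal
  on the grid, in (0, 1];
* otherwise (uncoupled) → CS = −(μ\* − μ_apex)/μ\*, in [−1, 0].

The functional is continuous across the coupled/uncoupled boundary,
invariant to rescaling all fluxes, and — crucially for the genetic
algorithm — it grades *uncoupled* designs by how close the synthesis
apex sits to maximum growth, so the search landscape has a slope toward
coupling instead of a flat plateau. It is registered by name
(`envelope-area`) and pluggable, so an alternative score can be swapped
in without touching the search. Classification: `no-synthesis` if
p_max ≤ ε_p; `uncoupled` if p_lo(μ\*) ≤ ε_p; `strong` if p_lo > ε_p at
every grid growth above f_min·μ\*; else `weak`.

The product objective is the *minimum* product flux with biomass
constrained to at least (1 − τ)·μ\* — the synthesis the design
guarantees at maximal growth. The minimum (not the maximum) is the only
reading consistent with synthesis being obligatory.

## Parameters

| name | default | meaning |
|---|---|---|
| τ (`tau`) | 1e−3 | relative growth slack for the guarantee; 0 gives the exact-vertex guarantee used in the worked example |
| ε_p (`eps_p`) | 1e−4 | product flux treated as "no synthesis" (mmol·gDW⁻¹·h⁻¹) |
| f_min | 0.1 | growth fraction above which the lower envelope must stay positive for *strong* coupling |
| n_env | 10 | envelope grid resolution |
| min_growth_frac | 0.01 | viability threshold and growth-essentiality screen, as a fraction of wild-type μ\* |
| K_max | 3 | genome length / maximum knockouts per design |
| pop_size | 200 | NSGA-II population (even, ≥ 4) |
| crossover_prob | 0.8 | per-pair uniform crossover probability |
| mutation_rate | 1/K_max | per-slot reset probability |
| stall_generations / stall_tol | 50 / 1e−4 | archive-hypervolume stagnation window |

## Search-space reduction

Order: dead → lump → essentials, which minimizes LP count (dead removal
shrinks the FVA set lumping and screening operate on).

*Dead reactions* are those whose FVA interval under the configured
medium lies within 1e−6 of zero — medium-conditional deadness, since
the search operates under one condition.

*Lumping* merges two irreversible internal reactions coupled through a
metabolite that participates in exactly those two (one producer, one
consumer): steady state forces their fluxes proportional, so they form
one composite column (member bounds intersected after ratio scaling)
whose knockout means knocking out all members. Boundary, biomass and
target columns are never absorbed: a composite knockout target must be
purely internal pathway. Restricting lumping to strictly unbranched,
sign-compatible pairs is what makes objective preservation provable —
every design expressible on both models evaluates identically to 1e−6,
and the reduction pipeline is idempotent.

*Candidate screening* excludes, with a recorded reason: the biomass and
target columns; **import-capable boundary reactions** (they define the
medium — knocking one out changes the environment, not the genotype);
maintenance reactions with lb > 0 (assay constraints); user-listed ids;
optionally all gene-less reactions; and every reaction whose lone
knockout drops growth below min_growth_frac·μ\*(wild type) or zeroes the
maximum product flux. Export-only boundary sinks (e.g. an abstracted
respiration/dissipation reaction) *remain* candidates: closing a sink
is a meaningful intervention and is exactly the knockout that creates
coupling in the fixture networks; in genome-scale work the
gene-association filter removes the non-genetic ones.

## Search

NSGA-II with fixed-length genomes: K_max slots, each a candidate index
or empty; a genome decodes to the de-duplicated set of its non-empty
slots. Binary tournament on (non-domination rank, crowding distance),
uniform crossover, per-slot reset mutation, elitist environmental
selection on the merged parent+child population. The initial population
contains the all-empty genome, so the wild type sits in the archive
from generation zero. An unbounded external archive collects every
non-dominated viable design evaluated; equal-fitness distinct designs
are all kept as alternatives (dominance is strict). Termination:
generation cap, wall-clock limit, or relative change of the archive
hypervolume (reference point (0, 0, −1), the non-viable sentinel) below
stall_tol across stall_generations. With a fixed seed a run is fully
deterministic whenever termination is triggered by the generation or
stall condition; the wall-clock condition is inherently
machine-dependent and is meant as a budget, not a reproducibility
mechanism. Evaluations are memoized by canonical knockout-set key,
which on small design spaces collapses the cost of extra generations to
bookkeeping.

## Refinement and output

Each archived design is reduced to a fixed point under single-knockout
removal: scanning candidates in ascending index, a knockout is dropped
whenever re-evaluation without it is ≥ the incumbent in all three
objectives (tolerance 1e−6), restarting after every removal. This
accepts ties — "no loss in performance" — and deliberately does not
search for a globally minimum-cardinality subset. The refined designs
are de-duplicated (first kept) and Pareto-filtered once more.
Refinement never lowers an objective, never grows a design, and
`pareto_filter ∘ refine` is idempotent.

Output: a CSV (design id, pipe-separated knockouts with composites
expanded to original reaction ids, knockout count, the three
objectives at 6 significant digits, coupling class; rows sorted by
descending growth then product), the same table on the console, an
optional static scatter (growth vs product, colored by CS), and a
provenance JSON (config, seed, reduction map, versions).

## Fixtures: what they emulate, and what they don't

The toy redox network reproduces the canonical coupling mechanism —
growth emits a cofactor whose only sinks are respiration and synthesis
— with round-number bounds so every optimum is a pencil-and-paper LP.
`random_coupling_family` generates seeded bundles of parallel growth
branches sharing the substrate and cofactor, sized so the full design
space stays exhaustively enumerable (≤ ~11 targets), which is what lets
the NSGA-II archive be checked against a brute-force oracle. These
fixtures have none of the features that make genome-scale models hard:
no thermodynamically infeasible loops, no cofactor redundancy, no
isoenzymes or compartments, and candidate spaces the GA can cover
exhaustively. Passing tests therefore demonstrate correctness of the
machinery (LPs, reduction contracts, dominance logic, determinism), not
search performance on genome-scale instances — genome-scale behavior
depends on population size and time budget, which are user inputs.

## Open choices made here

* Envelope resolution vs exactness: defaults favor speed (n_env = 10);
  the worked example and the reproduction script use n_env = 50 and
  τ = 0, where the toy front's objective values are exact.
* Whether "product synthesis" means the minimum or maximum flux at
  maximum growth: the minimum (the guarantee), as argued above.
* Equal-fitness alternative designs are all reported rather than
  merged; users pick among alternatives in the lab.
* The coupling-strength functional above is this package's default
  definition of the score; it is deliberately pluggable.
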
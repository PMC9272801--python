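# gcdesign

Multi-objective search for **growth-coupled knockout designs** in
constraint-based metabolic models.

## The problem

A robust way to build a microbial cell factory is to delete reactions so
that making the product becomes *obligatory* whenever the cell grows: the
product pathway is the only remaining way to balance some internal
resource (typically a redox cofactor), so faster-growing mutants are
automatically better producers and adaptive laboratory evolution works
*for* you instead of against you. Good knockout sets are rare in the
combinatorial design space of a genome-scale model, and three things
matter at once:

* **growth rate** — the FBA optimum μ\* of the biomass flux,
* **guaranteed synthesis** — p_guar, the *minimum* product flux the
  network can be forced to while growing at (1 − τ)·μ\*; if it is
  positive, production at maximum growth is unavoidable,
* **coupling strength** — CS ∈ [−1, 1], a score of the production
  envelope's geometry. Writing p_lo(μ) for the envelope's lower
  boundary, p_max for the maximum attainable synthesis and μ_apex for
  the largest growth still attaining p_max:

  * CS = ∫₀^{μ\*} p_lo(μ) dμ / (μ\*·p_max) for coupled designs
    (p_lo(μ\*) > ε_p) — close to 1 when synthesis persists across the
    whole growth range (strong coupling), close to 0⁺ when it only
    appears near maximal growth (weak coupling);
  * CS = −(μ\* − μ_apex)/μ\* for uncoupled designs — grades even the
    uncoupled region of the design space by how cheaply the network
    *could* synthesize, giving the search a gradient toward coupling;
  * CS = −1 when synthesis is impossible.

These objectives trade off, so `gcdesign` runs an NSGA-II genetic
algorithm over knockout sets and returns the whole **Pareto front** of
designs, letting you pick the growth/production/robustness balance your
process needs.

The pipeline around the search: model loading (SBML L3+fbc via COBRApy,
or a small JSON dialect), medium application (minimal-medium semantics:
unlisted uptakes are closed), search-space reduction (dead-reaction
removal, lumping of unbranched pathway segments into composite targets,
exclusion of knockouts essential for growth or synthesis), redundant-
knockout minimization of every archived design, and CSV/plot/table
output. All LPs are solved with HiGHS (deterministic) on a sparse
stoichiometric matrix.

## Worked example

The built-in `toy_redox_model()` is a 7-reaction network in which growth
(`GRW: A → B + N`) produces a cofactor N that must be drained by
respiration (`RSP: N → ∅`) or by product synthesis (`PRD: A + N → P`).

```bash
python - <<'EOF'
from gcdesign.fixtures import toy_redox_model
from gcdesign.io import save_model
m = toy_redox_model(); m.target_index = None
save_model(m, "toy.json")
EOF
gcdesign --model toy.json --target EXP --max-kos 2 --pop 20 \
         --max-gens 50 --seed 1 --tau 0 --envelope-points 50 \
         --out front.csv --log-level WARNING
```

prints

```
id   knockouts                                 n    growth   product  coupling  class
-------------------------------------------------------------------------------------
D1                                             0        10         0      -0.5  uncoupled
D2   RSP                                       1         6         4   0.26672  weak
D3   ALT|RSP                                   2         5         5       0.5  strong
```

Read it as: the wild type grows at 10 h⁻¹ but guarantees no product.
Deleting respiration (`RSP`) forces the cofactor through synthesis —
growth drops to 6, but 4 mmol·gDW⁻¹·h⁻¹ of product become obligatory at
maximum growth (weak coupling: production vanishes if growth falls below
a third of maximum). Additionally deleting the redox-neutral bypass
(`ALT`) makes production proportional to growth at *every* growth rate
(strong coupling, CS = 0.5) at the price of one more unit of growth.
No design improves one objective without sacrificing another — that is
the Pareto front.

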
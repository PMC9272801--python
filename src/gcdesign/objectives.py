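"""The three maximized objectives of a knockout design.

For a design d the search maximizes

* growth      — mu*(d), the FBA optimum of the biomass flux;
* product     — p_guar(d), the *minimum* product flux attainable while
  the cell grows at (1 - tau) of mu*(d): the synthesis the design
  guarantees when growth is maximal, hence what adaptive evolution
  selects for;
* coupling    — CS(d), a dimensionless score in [-1, 1] of how tightly
  the production envelope ties synthesis to growth.

The default coupling-strength functional works on the envelope
geometry.  Writing p_lo/p_hi for the lower/upper envelope over growth
mu in [0, mu*], p_max for the envelope's maximum product flux and
mu_apex for the largest growth still attaining p_max:

* no synthesis possible (p_max <= eps_p):           CS = -1
* coupled (p_lo(mu*) > eps_p):
      CS = integral of p_lo over [0, mu*] / (mu* p_max)   in (0, 1]
  so designs whose guaranteed synthesis holds up over the whole growth
  range (strong coupling) score near 1, while designs that only
  synthesize near maximal growth (weak coupling) score near 0+.
* uncoupled:  CS = -(mu* - mu_apex)/mu*                   in [-1, 0]
  so flat envelopes — maximum synthesis cheap in growth — score near
  0, grading the uncoupled region of the design space and giving the
  genetic algorithm a gradient toward coupled designs.

The functional is continuous across the coupled/uncoupled boundary,
scale-invariant in flux units, and pluggable: alternative functionals
can be registered by name and selected via ``SearchConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .config import SearchConfig
from .flux import EvaluationError, FluxEvaluator, ProductionEnvelope

#: Sentinel fitness of a non-viable design.
NONVIABLE = (0.0, 0.0, -1.0)


@dataclass(frozen=True)
class FitnessTriple:
    """(growth, guaranteed product at max growth, coupling strength)."""

    growth: float
    product: float
    coupling: float
    viable: bool = True
    coupling_class: str = "uncoupled"  # uncoupled | weak | strong | no-synthesis

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.growth, self.product, self.coupling)


def nonviable_fitness() -> FitnessTriple:
    return FitnessTriple(*NONVIABLE, viable=False, coupling_class="no-synthesis")


# ---------------------------------------------------------------------------
# Coupling strength and classification
# ---------------------------------------------------------------------------

def _cs_envelope_area(env: ProductionEnvelope, eps_p: float) -> float:
    if env.p_max <= eps_p:
        return -1.0
    if env.p_lo[-1] > eps_p:  # coupled: guaranteed synthesis at max growth
        area = float(np.trapezoid(env.p_lo, env.mu_grid))
        return area / (env.mu_star * env.p_max)
    return -(env.mu_star - env.mu_apex) / env.mu_star


CS_FUNCTIONALS: dict[str, Callable[[ProductionEnvelope, float], float]] = {
    "envelope-area": _cs_envelope_area,
}


def coupling_strength(
    env: ProductionEnvelope, eps_p: float = 1e-4, functional: str = "envelope-area"
) -> float:
    """Score the envelope's coupling geometry in [-1, 1]."""
    if env.mu_star <= 0:
        raise ValueError("coupling strength undefined at zero growth")
    cs = CS_FUNCTIONALS[functional](env, eps_p)
    return float(np.clip(cs, -1.0, 1.0))


def classify_coupling(
    env: ProductionEnvelope, eps_p: float = 1e-4, f_min: float = 0.1
) -> str:
    """Classify the envelope: no-synthesis / uncoupled / weak / strong.

    Strong coupling requires a positive lower envelope at every grid
    growth above ``f_min * mu_star`` — synthesis persists even at
    substantially suboptimal growth.  Weak coupling only guarantees
    synthesis at (near-)maximal growth.
    """
    if env.p_max <= eps_p:
        return "no-synthesis"
    if env.p_lo[-1] <= eps_p:
        return "uncoupled"
    mask = env.mu_grid >= f_min * env.mu_star
    if np.all(env.p_lo[mask] > eps_p):
        return "strong"
    return "weak"


# ---------------------------------------------------------------------------
# Design evaluation
# ---------------------------------------------------------------------------

class DesignEvaluator:
    """Memoized fitness evaluation of knockout designs on one model.

    A design is a set of knockout-target indices into ``candidates``
    (or raw reaction indices when ``candidates`` is None).  Results are
    cached by the canonical frozenset key; memoization is
    observationally transparent because evaluation is deterministic.
    """

    def __init__(self, model, cfg: SearchConfig | None = None, candidates=None):
        self.model = model
        self.cfg = cfg or SearchConfig()
        self.candidates = candidates
        self.flux = FluxEvaluator(model, solver=self.cfg.solver)
        self._cache: dict[frozenset[int], FitnessTriple] = {}
        self.n_lp_evaluations = 0
        self.wt_growth = self.flux.fba_max_growth(())
        if self.wt_growth <= 0:
            raise ValueError("wild-type model cannot grow; check medium")

    def reactions_of(self, design: Iterable[int]) -> list[int]:
        """Expand design (candidate-target indices) to reaction columns."""
        if self.candidates is None:
            return sorted(design)
        out: list[int] = []
        for t in design:
            out.extend(self.candidates.targets[t].members)
        return sorted(out)

    def guaranteed_synthesis(self, design: Iterable[int]) -> float:
        ko = self.reactions_of(design)
        mu = self.flux.fba_max_growth(ko)
        if mu <= 0:
            raise ValueError("guaranteed synthesis undefined at zero growth")
        floor = (1.0 - self.cfg.tau) * mu
        p_lo, _ = self.flux.product_range_at_growth(ko, floor)
        return p_lo

    def evaluate(self, design: Iterable[int]) -> FitnessTriple:
        key = frozenset(design)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        fit = self._evaluate_uncached(key)
        self._cache[key] = fit
        return fit

    def _evaluate_uncached(self, key: frozenset[int]) -> FitnessTriple:
        cfg = self.cfg
        ko = self.reactions_of(key)
        try:
            self.n_lp_evaluations += 1
            mu = self.flux.fba_max_growth(ko)
            if mu < cfg.min_growth_frac * self.wt_growth:
                return nonviable_fitness()
            floor = (1.0 - cfg.tau) * mu
            p_guar, _ = self.flux.product_range_at_growth(ko, floor)
            env = self.flux.production_envelope(ko, n=cfg.n_env)
            cs = coupling_strength(env, cfg.eps_p, cfg.cs_functional)
            klass = classify_coupling(env, cfg.eps_p, cfg.f_min)
        except EvaluationError:
            # solver hiccups must not kill the search
            return nonviable_fitness()
        return FitnessTriple(
            growth=mu,
            product=max(p_guar, 0.0),
            coupling=cs,
            viable=True,
            coupling_class=klass,
        )

    @property
    def cache_size(self) -> int:
        return len(self._cache)


def evaluate_design(model, design, cfg: SearchConfig | None = None,
                    candidates=None) -> FitnessTriple:
    """One-shot convenience wrapper around :class:`DesignEvaluator`."""
    return DesignEvaluator(model, cfg, candidates).evaluate(design)
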
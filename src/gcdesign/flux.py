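"""Linear-program evaluations on a metabolic model under knockouts.

Every quantity the search optimizes reduces to flux balance analysis:
maximize (or minimize) one flux subject to steady state ``S v = 0`` and
bounds ``lb <= v <= ub``, with knocked-out reactions pinned to zero.
The solver is HiGHS (dual simplex) through scipy, which is
deterministic: re-evaluating a design reproduces values to well below
1e-9.

A knockout design is any iterable of reaction column indices; members
get ``lb = ub = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

#: Fluxes below this magnitude are treated as zero.
ZERO_TOL = 1e-6
#: Two-sided slack used when fixing the biomass flux on an envelope grid.
GRID_TOL = 1e-9


class EvaluationError(RuntimeError):
    """An LP that should be feasible failed; carries the design."""

    def __init__(self, message: str, design: frozenset[int] | None = None):
        super().__init__(message)
        self.design = design


@dataclass
class ProductionEnvelope:
    """Feasible (growth, product flux) region of a design.

    ``mu_grid`` spans [0, mu_star]; ``p_lo``/``p_hi`` are the minimum
    and maximum product flux with biomass fixed at each grid value.
    ``p_max`` is the grid maximum of ``p_hi`` and ``mu_apex`` the
    largest grid growth still attaining it (within relative 1e-6).
    """

    mu_grid: np.ndarray
    p_lo: np.ndarray
    p_hi: np.ndarray
    mu_star: float
    p_max: float
    mu_apex: float

    def validate(self) -> None:
        assert np.all(self.p_lo <= self.p_hi + 1e-9)
        assert self.mu_grid[0] == 0.0
        assert np.all(np.diff(self.mu_grid) > 0)
        assert 0.0 <= self.mu_apex <= self.mu_star + 1e-12


class FluxEvaluator:
    """Shared LP machinery for one model (matrix built once)."""

    def __init__(self, model, solver: str = "highs"):
        self.model = model
        self.solver = solver
        self._A = sp.csc_matrix(model.stoich)
        self._b = np.zeros(model.n_metabolites)
        self._base_bounds = np.column_stack([model.lb, model.ub])

    # -- primitive LP ------------------------------------------------------

    def _solve(
        self,
        objective_col: int,
        maximize: bool,
        ko: Iterable[int] = (),
        overrides: dict[int, tuple[float, float]] | None = None,
    ) -> float | None:
        """Optimize one flux; returns the optimum or None if infeasible."""
        bounds = self._base_bounds.copy()
        for j in ko:
            bounds[j] = (0.0, 0.0)
        if overrides:
            for j, (lo, hi) in overrides.items():
                bounds[j] = (lo, hi)
        c = np.zeros(self.model.n_reactions)
        c[objective_col] = -1.0 if maximize else 1.0
        res = linprog(
            c,
            A_eq=self._A,
            b_eq=self._b,
            bounds=bounds,
            method=self.solver,
        )
        if res.status == 2:  # infeasible
            return None
        if not res.success:
            raise EvaluationError(
                f"LP failed (status {res.status}): {res.message}",
                frozenset(ko),
            )
        return -res.fun if maximize else res.fun

    # -- public operations -------------------------------------------------

    def fba_max_growth(self, ko: Iterable[int] = ()) -> float:
        """Maximum biomass flux under the knockout; 0 if infeasible."""
        mu = self._solve(self.model.objective_index, maximize=True, ko=ko)
        return mu if mu is not None and mu > 0 else 0.0

    def product_range_at_growth(
        self, ko: Iterable[int], growth_floor: float
    ) -> tuple[float, float]:
        """Min/max product flux subject to biomass >= growth_floor."""
        ko = list(ko)
        j_bio = self.model.objective_index
        j_tgt = self._target()
        overrides = {
            j_bio: (max(self.model.lb[j_bio], growth_floor), self.model.ub[j_bio])
        }
        lo = self._solve(j_tgt, maximize=False, ko=ko, overrides=overrides)
        hi = self._solve(j_tgt, maximize=True, ko=ko, overrides=overrides)
        if lo is None or hi is None:
            raise EvaluationError(
                f"infeasible growth floor {growth_floor}", frozenset(ko)
            )
        if abs(lo) < ZERO_TOL:
            lo = 0.0
        if abs(hi) < ZERO_TOL:
            hi = 0.0
        return lo, max(hi, lo)

    def max_product(self, ko: Iterable[int] = ()) -> float:
        """Maximum product flux with growth unconstrained; 0 if infeasible."""
        p = self._solve(self._target(), maximize=True, ko=ko)
        return p if p is not None and p > 0 else 0.0

    def flux_range(self, j: int, ko: Iterable[int] = ()) -> tuple[float, float]:
        """FVA interval of reaction ``j`` (growth unconstrained)."""
        lo = self._solve(j, maximize=False, ko=ko)
        hi = self._solve(j, maximize=True, ko=ko)
        if lo is None or hi is None:
            raise EvaluationError("model infeasible during FVA", frozenset(ko))
        return lo, hi

    def production_envelope(
        self, ko: Iterable[int] = (), n: int = 10
    ) -> ProductionEnvelope:
        """Product flux range at n+1 evenly spaced growth levels on [0, mu*]."""
        if n < 2:
            raise ValueError("envelope grid needs n >= 2")
        ko = list(ko)
        mu_star = self.fba_max_growth(ko)
        if mu_star <= 0:
            raise EvaluationError("cannot build envelope: max growth is 0",
                                  frozenset(ko))
        grid = np.linspace(0.0, mu_star, n + 1)
        j_bio = self.model.objective_index
        j_tgt = self._target()
        p_lo = np.empty(n + 1)
        p_hi = np.empty(n + 1)
        slack = GRID_TOL * max(mu_star, 1.0)
        for k, mu in enumerate(grid):
            # back the vertex off the boundary to dodge infeasibility
            mu_fix = mu_star * (1.0 - GRID_TOL) if k == n else mu
            for width in (slack, ZERO_TOL * max(mu_star, 1.0)):
                overrides = {j_bio: (mu_fix - width, mu_fix + width)}
                lo = self._solve(j_tgt, maximize=False, ko=ko, overrides=overrides)
                hi = self._solve(j_tgt, maximize=True, ko=ko, overrides=overrides)
                if lo is not None and hi is not None:
                    break
            if lo is None or hi is None:
                raise EvaluationError(
                    f"envelope LP infeasible at growth {mu}", frozenset(ko)
                )
            p_lo[k] = 0.0 if abs(lo) < ZERO_TOL else lo
            p_hi[k] = 0.0 if abs(hi) < ZERO_TOL else hi
        p_lo = np.minimum(p_lo, p_hi)
        # the true maximum synthesis can fall between grid points, so it
        # comes from its own growth-unconstrained LP
        p_max = max(self.max_product(ko), float(p_hi.max()))
        attains = np.flatnonzero(p_hi >= p_max * (1.0 - 1e-6))
        if attains.size:
            mu_apex = float(grid[attains[-1]])
        else:  # apex lies between grid points: take the nearest grid proxy
            mu_apex = float(grid[int(np.argmax(p_hi))])
        env = ProductionEnvelope(
            mu_grid=grid,
            p_lo=p_lo,
            p_hi=p_hi,
            mu_star=mu_star,
            p_max=p_max,
            mu_apex=mu_apex,
        )
        env.validate()
        return env

    # -- helpers -----------------------------------------------------------

    def _target(self) -> int:
        if self.model.target_index is None:
            raise EvaluationError("model has no resolved target reaction")
        return self.model.target_index


# Convenience functional wrappers -------------------------------------------

def fba_max_growth(model, ko: Sequence[int] = (), solver: str = "highs") -> float:
    return FluxEvaluator(model, solver).fba_max_growth(ko)


def product_range_at_growth(model, ko: Sequence[int], growth_floor: float,
                            solver: str = "highs") -> tuple[float, float]:
    return FluxEvaluator(model, solver).product_range_at_growth(ko, growth_floor)


def max_product(model, ko: Sequence[int] = (), solver: str = "highs") -> float:
    return FluxEvaluator(model, solver).max_product(ko)


def production_envelope(model, ko: Sequence[int] = (), n: int = 10,
                        solver: str = "highs") -> ProductionEnvelope:
    return FluxEvaluator(model, solver).production_envelope(ko, n)
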
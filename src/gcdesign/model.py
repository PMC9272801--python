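"""In-memory representation of a constraint-based metabolic model.

The model is the substrate for every linear-program evaluation in the
package: a sparse stoichiometric matrix S (metabolites x reactions),
per-reaction flux bounds, a biomass objective column and a product
exchange column.  Fluxes are in mmol/gDW/h; the biomass flux is the
specific growth rate in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

#: All bounds are capped to this magnitude so every LP is bounded.
BOUND_CAP = 1000.0


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class MetabolicModel:
    """A stoichiometric network with flux bounds and an objective.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Identifiers; row/column order of ``stoich``.
    stoich
        Sparse CSC matrix, ``len(metabolite_ids)`` rows by
        ``len(reaction_ids)`` columns.
    lb, ub
        Per-reaction flux bounds, finite after capping to ``BOUND_CAP``.
    objective_index
        Column of the biomass reaction.
    target_index
        Column of the product exchange reaction, or ``None`` until a
        target has been resolved.
    gene_associated
        Per-reaction flag: the reaction carries a gene association and
        is therefore a plausible genetic intervention.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    stoich: sp.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    objective_index: int
    target_index: int | None = None
    gene_associated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.stoich = sp.csc_matrix(self.stoich, dtype=float)
        self.lb = np.clip(np.asarray(self.lb, dtype=float), -BOUND_CAP, BOUND_CAP)
        self.ub = np.clip(np.asarray(self.ub, dtype=float), -BOUND_CAP, BOUND_CAP)
        if self.gene_associated is None:
            self.gene_associated = np.ones(self.n_reactions, dtype=bool)
        else:
            self.gene_associated = np.asarray(self.gene_associated, dtype=bool)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def exchange_flags(self) -> np.ndarray:
        """Boolean per reaction: column touches exactly one metabolite."""
        counts = self.stoich.getnnz(axis=0)
        return counts == 1

    def uptake_capable(self) -> np.ndarray:
        """Exchanges that can *import* their metabolite from the boundary.

        A boundary column with coefficient ``s`` imports when ``s * v > 0``
        is feasible, i.e. ``s > 0`` with ``ub > 0`` or ``s < 0`` with
        ``lb < 0``.  These reactions define the medium.
        """
        out = np.zeros(self.n_reactions, dtype=bool)
        for j in np.flatnonzero(self.exchange_flags):
            s = self.stoich[:, j].data[0]
            if (s > 0 and self.ub[j] > 0) or (s < 0 and self.lb[j] < 0):
                out[j] = True
        return out

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id: {rid!r}") from None

    def metabolite_index(self, mid: str) -> int:
        try:
            return self.metabolite_ids.index(mid)
        except ValueError:
            raise KeyError(f"unknown metabolite id: {mid!r}") from None

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        m, n = self.stoich.shape
        if m != self.n_metabolites or n != self.n_reactions:
            raise ModelValidationError(
                f"stoichiometry is {m}x{n} but model declares "
                f"{self.n_metabolites} metabolites / {self.n_reactions} reactions"
            )
        if len(self.lb) != n or len(self.ub) != n:
            raise ModelValidationError("bound vectors do not match reaction count")
        bad = np.flatnonzero(self.lb > self.ub)
        if bad.size:
            raise ModelValidationError(
                f"lb > ub for reactions: {[self.reaction_ids[j] for j in bad]}"
            )
        if not (np.isfinite(self.lb).all() and np.isfinite(self.ub).all()):
            raise ModelValidationError("non-finite bounds after capping")
        if not 0 <= self.objective_index < n:
            raise ModelValidationError("objective_index out of range")
        if self.target_index is not None:
            if not 0 <= self.target_index < n:
                raise ModelValidationError("target_index out of range")
            if self.target_index == self.objective_index:
                raise ModelValidationError("objective and target must differ")
        if len(self.gene_associated) != n:
            raise ModelValidationError("gene_associated does not match reaction count")

    # -- convenience -------------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            stoich=self.stoich.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gene_associated=self.gene_associated.copy(),
        )

    def equals(self, other: "MetabolicModel") -> bool:
        """Field-for-field equality (used by round-trip contracts)."""
        return (
            self.metabolite_ids == other.metabolite_ids
            and self.reaction_ids == other.reaction_ids
            and self.objective_index == other.objective_index
            and self.target_index == other.target_index
            and np.array_equal(self.lb, other.lb)
            and np.array_equal(self.ub, other.ub)
            and np.array_equal(self.gene_associated, other.gene_associated)
            and (self.stoich != other.stoich).nnz == 0
        )
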
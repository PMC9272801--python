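"""Model input/output, medium application and target resolution.

Two on-disk formats are supported: SBML Level 3 with the fbc extension
(read/written through COBRApy) and a small JSON dialect used for
fixtures and provenance.  The JSON dialect stores ids, stoichiometry as
``{metabolite_id: coefficient}`` per reaction, bounds, the objective
reaction id and optionally the target reaction id.

A medium is a headered TSV with columns ``exchange_id``, ``lb``, ``ub``.
Applying it sets the listed exchange bounds and, by default, closes the
import direction of every unlisted uptake-capable exchange — minimal
medium semantics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import BOUND_CAP, MetabolicModel, ModelValidationError


class FormatError(ValueError):
    """The input file does not parse as a model."""


class ConfigurationError(ValueError):
    """The input parses but describes an unusable configuration."""


class ResolutionError(ValueError):
    """A target id could not be resolved to an exchange reaction."""


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def model_to_dict(model: MetabolicModel) -> dict:
    reactions = []
    S = model.stoich.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j)
        mets = {
            model.metabolite_ids[i]: float(v)
            for i, v in zip(col.indices, col.data)
        }
        reactions.append(
            {
                "id": rid,
                "lb": float(model.lb[j]),
                "ub": float(model.ub[j]),
                "metabolites": mets,
                "gene_associated": bool(model.gene_associated[j]),
            }
        )
    out = {
        "metabolites": [{"id": m} for m in model.metabolite_ids],
        "reactions": reactions,
        "objective": model.reaction_ids[model.objective_index],
    }
    if model.target_index is not None:
        out["target"] = model.reaction_ids[model.target_index]
    return out


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolite_ids = [m["id"] for m in data["metabolites"]]
        reactions = data["reactions"]
        objective = data["objective"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed model JSON: missing {exc}") from exc
    met_pos = {m: i for i, m in enumerate(metabolite_ids)}
    reaction_ids, lb, ub, gene = [], [], [], []
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(reactions):
        try:
            reaction_ids.append(rxn["id"])
            lb.append(float(rxn["lb"]))
            ub.append(float(rxn["ub"]))
            gene.append(bool(rxn.get("gene_associated", True)))
            for mid, coeff in rxn["metabolites"].items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(float(coeff))
        except KeyError as exc:
            raise FormatError(
                f"malformed reaction entry {rxn.get('id', j)!r}: missing {exc}"
            ) from exc
    stoich = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    if objective not in reaction_ids:
        raise ConfigurationError(f"declared objective {objective!r} not a reaction")
    target = data.get("target")
    if target is not None and target not in reaction_ids:
        raise ConfigurationError(f"declared target {target!r} not a reaction")
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        stoich=stoich,
        lb=np.array(lb),
        ub=np.array(ub),
        objective_index=reaction_ids.index(objective),
        target_index=reaction_ids.index(target) if target is not None else None,
        gene_associated=np.array(gene),
    )


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def _from_cobra(cmodel) -> MetabolicModel:
    metabolite_ids = [m.id for m in cmodel.metabolites]
    reaction_ids = [r.id for r in cmodel.reactions]
    met_pos = {m: i for i, m in enumerate(metabolite_ids)}
    rows, cols, vals = [], [], []
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    gene = np.zeros(len(reaction_ids), dtype=bool)
    objective = None
    for j, rxn in enumerate(cmodel.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        gene[j] = len(rxn.genes) > 0
        if rxn.objective_coefficient:
            objective = j
        for met, coeff in rxn.metabolites.items():
            rows.append(met_pos[met.id])
            cols.append(j)
            vals.append(float(coeff))
    if objective is None:
        raise ConfigurationError("model declares no objective reaction")
    stoich = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        stoich=stoich,
        lb=lb,
        ub=ub,
        objective_index=objective,
        gene_associated=gene,
    )


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model("gcdesign")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolite_ids}
    S = model.stoich.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        cmodel.add_reactions([rxn])
        col = S.getcol(j)
        rxn.add_metabolites(
            {mets[model.metabolite_ids[i]]: float(v) for i, v in zip(col.indices, col.data)}
        )
        if model.gene_associated[j]:
            rxn.gene_reaction_rule = f"g_{rid}"
    cmodel.objective = model.reaction_ids[model.objective_index]
    return cmodel


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from SBML or the JSON dialect.

    ``format`` is ``"sbml"`` or ``"json"``; when omitted it is inferred
    from the file suffix.  Bounds are capped to +/-1000 on load.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        return model_from_dict(data)
    if format == "sbml":
        import cobra.io

        try:
            cmodel = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises a zoo of types
            raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
        return _from_cobra(cmodel)
    raise ValueError(f"unknown format {format!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as the JSON dialect or SBML L3+fbc."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    if format == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1, sort_keys=True))
    elif format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_medium(path: str | Path) -> pd.DataFrame:
    """Read a medium TSV with columns exchange_id, lb, ub."""
    df = pd.read_csv(path, sep="\t")
    required = {"exchange_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"medium file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def apply_medium(
    model: MetabolicModel,
    medium: pd.DataFrame,
    close_unlisted_uptakes: bool = True,
) -> MetabolicModel:
    """Apply exchange bounds from a medium table.

    Listed exchanges receive the given bounds verbatim.  Unless
    ``close_unlisted_uptakes`` is False, every unlisted uptake-capable
    exchange has its import direction closed; secretion directions are
    untouched.
    """
    out = model.copy()
    exchange = out.exchange_flags
    listed: set[int] = set()
    for row in medium.itertuples(index=False):
        try:
            j = out.reaction_index(str(row.exchange_id))
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        if not exchange[j]:
            raise ConfigurationError(
                f"{row.exchange_id!r} is not an exchange reaction"
            )
        lo, hi = float(row.lb), float(row.ub)
        if lo > hi:
            raise ConfigurationError(f"{row.exchange_id!r}: lb > ub in medium")
        out.lb[j] = max(lo, -BOUND_CAP)
        out.ub[j] = min(hi, BOUND_CAP)
        listed.add(j)
    if close_unlisted_uptakes:
        for j in np.flatnonzero(model.uptake_capable()):
            if j in listed:
                continue
            s = out.stoich[:, j].data[0]
            if s > 0:  # imports when flux positive
                out.ub[j] = min(out.ub[j], 0.0)
                out.lb[j] = min(out.lb[j], 0.0)
            else:  # conventional exchange: imports when flux negative
                out.lb[j] = max(out.lb[j], 0.0)
                out.ub[j] = max(out.ub[j], 0.0)
    out.validate()
    return out


def resolve_target(
    model: MetabolicModel, identifier: str, add_demand: bool = False
) -> tuple[MetabolicModel, int]:
    """Resolve a metabolite or reaction id to a product exchange column.

    Returns a (model, index) pair: the model is unchanged unless a
    demand reaction was appended (``add_demand``).  A reaction id must
    name an exchange/demand; a metabolite id resolves to the unique
    exchange able to export it.
    """
    if identifier in model.reaction_ids:
        j = model.reaction_index(identifier)
        if not model.exchange_flags[j]:
            raise ResolutionError(
                f"{identifier!r} is a reaction but not an exchange/demand"
            )
        out = model.copy()
        out.target_index = j
        out.validate()
        return out, j
    if identifier not in model.metabolite_ids:
        raise ResolutionError(f"{identifier!r} matches no reaction or metabolite")
    i = model.metabolite_index(identifier)
    # exporting exchanges: single-metabolite columns consuming the metabolite
    candidates = []
    S = model.stoich.tocsr()
    exchange = model.exchange_flags
    for j in range(model.n_reactions):
        if not exchange[j] or j == model.objective_index:
            continue
        s = model.stoich[:, j].data[0]
        row = model.stoich[:, j].indices[0]
        if row != i:
            continue
        if (s < 0 and model.ub[j] > 0) or (s > 0 and model.lb[j] < 0):
            candidates.append(j)
    _ = S
    if len(candidates) == 1:
        out = model.copy()
        out.target_index = candidates[0]
        out.validate()
        return out, candidates[0]
    if len(candidates) > 1:
        names = [model.reaction_ids[j] for j in candidates]
        raise ResolutionError(
            f"metabolite {identifier!r} has multiple exporting exchanges: {names}"
        )
    if not add_demand:
        raise ResolutionError(
            f"metabolite {identifier!r} has no exporting exchange; "
            "pass add_demand to append one"
        )
    out = _append_demand(model, i, identifier)
    return out, out.n_reactions - 1


def _append_demand(model: MetabolicModel, met_index: int, mid: str) -> MetabolicModel:
    rid = f"DM_{mid}"
    if rid in model.reaction_ids:
        raise ConfigurationError(f"demand id {rid!r} already exists")
    col = sp.csc_matrix(
        ([-1.0], ([met_index], [0])), shape=(model.n_metabolites, 1)
    )
    stoich = sp.hstack([model.stoich, col], format="csc")
    out = MetabolicModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=list(model.reaction_ids) + [rid],
        stoich=stoich,
        lb=np.append(model.lb, 0.0),
        ub=np.append(model.ub, BOUND_CAP),
        objective_index=model.objective_index,
        target_index=model.n_reactions,
        gene_associated=np.append(model.gene_associated, False),
    )
    return out


__all__ = [
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "read_medium",
    "apply_medium",
    "resolve_target",
    "FormatError",
    "ConfigurationError",
    "ResolutionError",
    "ModelValidationError",
]
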
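"""Model I/O: a JSON dialect (full fidelity) and SBML Level 3 via cobrapy.

The JSON dialect stores compartments, metabolites, reactions (with optional
bounds), coupling constraints, the accumulation right-hand side ``b`` and the
component/condition labels.  JSON output is bit-stable for identical input
(sorted keys, fixed float formatting via ``repr``).  SBML export goes through
cobrapy and is interoperable but lossy with respect to coupling constraints
and ``b``; the JSON dialect is the authoritative on-disk form.
"""

from __future__ import annotations

import json
from pathlib import Path

from .model import (
    DEFAULT_BOUND,
    CouplingConstraint,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed as a model."""


def _reaction_from_dict(entry: dict) -> Reaction:
    try:
        rid = entry["id"]
        stoich = {k: float(v) for k, v in entry["stoichiometry"].items()}
    except KeyError as exc:
        raise ModelFormatError(f"reaction entry missing field {exc}") from None
    lb = entry.get("lower_bound")
    ub = entry.get("upper_bound")
    if lb is None or ub is None:
        # Unspecified bounds default to the generic ±1000 μmol/gDW/h;
        # irreversible (declared) reactions get [0, 1000].
        reversible = entry.get("reversible", True)
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        lower_bound=float(lb),
        upper_bound=float(ub),
        subsystem=entry.get("subsystem", ""),
        name=entry.get("name", ""),
        is_exchange=entry.get("is_exchange"),
    )


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "labels": dict(sorted(model.labels.items())),
        "compartments": dict(sorted(model.compartments.items())),
        "atpm_id": model.atpm_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": float(r.lower_bound),
                "upper_bound": float(r.upper_bound),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "couplings": [
            {"coefficients": dict(sorted(c.coefficients.items())), "rhs": c.rhs}
            for c in model.couplings
        ],
        "b": {k: v for k, v in sorted(model.b.items()) if v != 0.0},
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
            )
            for m in data["metabolites"]
        ]
        rxns = [_reaction_from_dict(r) for r in data["reactions"]]
    except (KeyError, TypeError) as exc:
        raise ModelFormatError(f"malformed model document: {exc}") from None
    coups = [
        CouplingConstraint(
            coefficients={k: float(v) for k, v in c["coefficients"].items()},
            rhs=float(c["rhs"]),
        )
        for c in data.get("couplings", [])
    ]
    return MetabolicModel(
        model_id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        couplings=coups,
        b={k: float(v) for k, v in data.get("b", {}).items()},
        labels=data.get("labels", {}),
        compartments=data.get("compartments", {}),
        atpm_id=data.get("atpm_id", "ATPM"),
    )


def load_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Load a model from ``path`` in the named format ('json' or 'sbml')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(
                f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: "
                f"{exc.msg}"
            ) from None
        try:
            return model_from_dict(data)
        except ModelValidationError:
            raise
    if format == "sbml":
        return _load_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def save_model(model: MetabolicModel, path: str | Path, format: str = "json") -> Path:
    """Serialize ``model`` so that :func:`load_model` restores an equivalent model."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        text = json.dumps(model_to_dict(model), indent=1, sort_keys=False)
        path.write_text(text + "\n")
        return path
    if format == "sbml":
        _save_sbml(model, path)
        return path
    raise ValueError(f"unknown model format {format!r}")


# -- SBML via cobrapy -------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    comps = dict(model.compartments)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment=m.compartment or "c"
        )
        cmets[m.id] = cmet
        comps.setdefault(m.compartment or "c", m.compartment or "c")
    cm.compartments = comps
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        cr.subsystem = r.subsystem
        rxns.append((cr, r.stoichiometry))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, stoich in rxns:
        cr.add_metabolites({cmets[k]: v for k, v in stoich.items()})
    return cm


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


def _load_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    cm = read_sbml_model(str(path))
    mets = [
        Metabolite(id=m.id, name=m.name or m.id, compartment=m.compartment or "")
        for m in cm.metabolites
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            subsystem=r.subsystem or "",
            name=r.name or r.id,
        )
        for r in cm.reactions
    ]
    return MetabolicModel(
        model_id=cm.id or path.stem,
        metabolites=mets,
        reactions=rxns,
        compartments=dict(cm.compartments),
    )
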
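"""Constraint-based metabolic model container.

Conventions follow the COBRA community standard: VMH-style identifiers with a
bracketed compartment suffix (``atp[m]``), fluxes in μmol/gDW/h, and for
exchange reactions negative flux = uptake, positive flux = secretion.  An
exchange reaction is any boundary column touching exactly one metabolite pool.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

#: Generic bound (μmol/gDW/h) applied when a file omits reaction bounds.
DEFAULT_BOUND = 1000.0

_COMPARTMENT_RE = re.compile(r"\[([a-zA-Z0-9]+)\]$")


class ModelValidationError(ValueError):
    """Raised when a model (or an edit to it) violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_atp_species: bool = False

    def __post_init__(self) -> None:
        if not self.compartment:
            m = _COMPARTMENT_RE.search(self.id)
            self.compartment = m.group(1) if m else ""
        if not self.name:
            self.name = self.id
        if self.id.split("[")[0].lower() == "atp":
            self.is_atp_species = True


@dataclass
class Reaction:
    """A stoichiometric column with box bounds.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed).  ``is_exchange`` is normally auto-detected from the number of
    metabolites in the column.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    name: str = ""
    is_exchange: bool | None = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.is_exchange is None:
            self.is_exchange = len(self.stoichiometry) == 1
        if not self.name:
            self.name = self.id

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class CouplingConstraint:
    """One row of C·v <= d coupling net internal fluxes."""

    coefficients: dict[str, float]
    rhs: float


@dataclass
class ConstraintOverlay:
    """Bound edits layered on a base model to produce a condition variant.

    ``bound_edits`` maps reaction id -> (new_lower, new_upper), either entry
    may be None (keep).  ``scale_edits`` maps reaction id -> dict with keys
    ``bound`` ("lower"|"upper"|"both") and ``factor``.
    """

    bound_edits: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    scale_edits: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bound_edits": {
                r: [lo, hi] for r, (lo, hi) in self.bound_edits.items()
            },
            "scale_edits": _copy.deepcopy(self.scale_edits),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintOverlay":
        return cls(
            bound_edits={
                r: (v[0], v[1]) for r, v in d.get("bound_edits", {}).items()
            },
            scale_edits=dict(d.get("scale_edits", {})),
        )


class MetabolicModel:
    """Stoichiometry, bounds and coupling constraints for one condition.

    ``labels`` carries the neuronal component (synaptic | nonsynaptic) and the
    condition (control | pd) when the model is one of the study variants.
    """

    def __init__(
        self,
        model_id: str,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        couplings: list[CouplingConstraint] | None = None,
        b: dict[str, float] | None = None,
        labels: dict[str, str] | None = None,
        compartments: dict[str, str] | None = None,
        atpm_id: str = "ATPM",
    ):
        self.id = model_id
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.couplings = list(couplings or [])
        self.b = dict(b or {})
        self.labels = dict(labels or {})
        self.compartments = dict(compartments or {})
        self.atpm_id = atpm_id
        self._index()
        self.validate()

    # -- indexing -----------------------------------------------------------

    def _index(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def internal_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if not r.is_exchange]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def atp_species(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_atp_species]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")
        dangling = sorted(
            {
                met
                for r in self.reactions
                for met in r.stoichiometry
                if met not in self._met_index
            }
        )
        if dangling:
            raise ModelValidationError(
                f"reactions reference unknown metabolites: {dangling}"
            )
        bad_b = sorted(set(self.b) - set(self._met_index))
        if bad_b:
            raise ModelValidationError(f"b entries for unknown metabolites: {bad_b}")
        for c in self.couplings:
            missing = sorted(set(c.coefficients) - set(self._rxn_index))
            if missing:
                raise ModelValidationError(
                    f"coupling references unknown reactions: {missing}"
                )
        if self.compartments:
            declared = set(self.compartments)
            for m in self.metabolites:
                if m.compartment and m.compartment not in declared:
                    raise ModelValidationError(
                        f"metabolite {m.id!r} uses undeclared compartment "
                        f"{m.compartment!r}"
                    )

    # -- copies and overlays ------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def apply_overlay(self, overlay: ConstraintOverlay) -> "MetabolicModel":
        """Return a new model with the overlay's bound edits applied.

        The original model is untouched.  Absolute edits are applied before
        scale edits.  An edit producing lower > upper raises
        :class:`ModelValidationError` naming the reaction.
        """
        new = self.copy()
        for rid, (lo, hi) in overlay.bound_edits.items():
            r = new.reaction(rid)
            if lo is not None:
                r.lower_bound = float(lo)
            if hi is not None:
                r.upper_bound = float(hi)
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"overlay leaves reaction {rid!r} with lower bound "
                    f"{r.lower_bound} > upper bound {r.upper_bound}"
                )
        for rid, edit in overlay.scale_edits.items():
            r = new.reaction(rid)
            factor = float(edit["factor"])
            which = edit.get("bound", "both")
            if which in ("lower", "both"):
                r.lower_bound *= factor
            if which in ("upper", "both"):
                r.upper_bound *= factor
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"overlay leaves reaction {rid!r} with lower bound "
                    f"{r.lower_bound} > upper bound {r.upper_bound}"
                )
        return new

    def bound_diff(self, other: "MetabolicModel") -> dict[str, tuple]:
        """Reactions whose bounds differ between self and other."""
        diff = {}
        for r in self.reactions:
            if not other.has_reaction(r.id):
                diff[r.id] = ((r.lower_bound, r.upper_bound), None)
                continue
            o = other.reaction(r.id)
            if (r.lower_bound, r.upper_bound) != (o.lower_bound, o.upper_bound):
                diff[r.id] = (
                    (r.lower_bound, r.upper_bound),
                    (o.lower_bound, o.upper_bound),
                )
        for o in other.reactions:
            if not self.has_reaction(o.id):
                diff[o.id] = (None, (o.lower_bound, o.upper_bound))
        return diff


@dataclass
class AssembledMatrices:
    """Partitioned problem data: N v + B w = b, C v <= d, box bounds."""

    metabolite_ids: list[str]
    internal_ids: list[str]
    exchange_ids: list[str]
    N: sparse.csr_matrix
    B: sparse.csr_matrix
    b: np.ndarray
    C: sparse.csr_matrix
    d: np.ndarray
    lb_internal: np.ndarray
    ub_internal: np.ndarray
    lb_exchange: np.ndarray
    ub_exchange: np.ndarray


def assemble_matrices(model: MetabolicModel) -> AssembledMatrices:
    """Assemble sparse stoichiometric partitions in model order.

    Column order is deterministic: internal reactions in model order form N,
    exchange reactions in model order form B.
    """
    model.validate()
    met_ids = [m.id for m in model.metabolites]
    met_pos = {m: i for i, m in enumerate(met_ids)}
    internal = model.internal_reactions
    exchanges = model.exchange_reactions

    def _mat(reactions: list[Reaction]) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for j, r in enumerate(reactions):
            for met, coef in r.stoichiometry.items():
                rows.append(met_pos[met])
                cols.append(j)
                vals.append(float(coef))
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(reactions))
        )

    int_pos = {r.id: j for j, r in enumerate(internal)}
    crow, ccol, cval = [], [], []
    d = []
    for i, c in enumerate(model.couplings):
        for rid, coef in c.coefficients.items():
            if rid not in int_pos:
                raise ModelValidationError(
                    f"coupling constraint references non-internal reaction {rid!r}"
                )
            crow.append(i)
            ccol.append(int_pos[rid])
            cval.append(float(coef))
        d.append(float(c.rhs))

    return AssembledMatrices(
        metabolite_ids=met_ids,
        internal_ids=[r.id for r in internal],
        exchange_ids=[r.id for r in exchanges],
        N=_mat(internal),
        B=_mat(exchanges),
        b=np.array([model.b.get(m, 0.0) for m in met_ids]),
        C=sparse.csr_matrix(
            (cval, (crow, ccol)), shape=(len(model.couplings), len(internal))
        ),
        d=np.asarray(d, dtype=float),
        lb_internal=np.array([r.lower_bound for r in internal]),
        ub_internal=np.array([r.upper_bound for r in internal]),
        lb_exchange=np.array([r.lower_bound for r in exchanges]),
        ub_exchange=np.array([r.upper_bound for r in exchanges]),
    )
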
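"""Linear-programming utilities on the net-flux polytope (HiGHS backend).

Used for feasibility screening, flux capacity questions and the basic
metabolic-function validity checks.  The entropic solver in
:mod:`dopaflux.efba` never routes through this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, assemble_matrices


@dataclass
class LpResult:
    status: str  # optimal | infeasible | unbounded
    objective: float | None
    fluxes: dict[str, float] | None


def solve_lp(
    model: MetabolicModel,
    objective: dict[str, float],
    sense: str = "max",
) -> LpResult:
    """Optimize a linear functional of net fluxes subject to the model polytope.

    ``objective`` maps reaction id -> coefficient; ``sense`` is 'max' or 'min'.
    """
    mats = assemble_matrices(model)
    ids = mats.internal_ids + mats.exchange_ids
    pos = {r: i for i, r in enumerate(ids)}
    n = len(ids)
    c = np.zeros(n)
    for rid, coef in objective.items():
        c[pos[rid]] = coef
    if sense == "max":
        c = -c
    elif sense != "min":
        raise ValueError("sense must be 'max' or 'min'")

    A_eq = sparse.hstack([mats.N, mats.B], format="csr")
    bounds = np.concatenate(
        [
            np.stack([mats.lb_internal, mats.ub_internal], axis=1)
            if mats.lb_internal.size
            else np.empty((0, 2)),
            np.stack([mats.lb_exchange, mats.ub_exchange], axis=1)
            if mats.lb_exchange.size
            else np.empty((0, 2)),
        ]
    )
    A_ub = b_ub = None
    if mats.C.shape[0]:
        A_ub = sparse.hstack(
            [mats.C, sparse.csr_matrix((mats.C.shape[0], len(mats.exchange_ids)))],
            format="csr",
        )
        b_ub = mats.d
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=mats.b,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        return LpResult("infeasible", None, None)
    if res.status == 3:
        return LpResult("unbounded", None, None)
    if not res.success:
        return LpResult("infeasible", None, None)
    obj = float(res.fun)
    if sense == "max":
        obj = -obj
    return LpResult("optimal", obj, dict(zip(ids, map(float, res.x))))


def is_feasible(model: MetabolicModel) -> bool:
    return solve_lp(model, {}, sense="min").status == "optimal"


def binding_bounds(model: MetabolicModel, tol: float = 1e-7) -> list[str]:
    """Heuristic infeasibility hint: forced-flux bounds (lb > 0 or ub < 0)."""
    hints = []
    for r in model.reactions:
        if r.lower_bound > tol:
            hints.append(f"{r.id}: lower bound {r.lower_bound} forces flux")
        if r.upper_bound < -tol:
            hints.append(f"{r.id}: upper bound {r.upper_bound} forces flux")
    return hints
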
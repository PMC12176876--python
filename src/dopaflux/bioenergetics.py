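"""ATP-contribution accounting, subsystem aggregation and energy-demand scans.

A reaction's net ATP production is its net flux times the summed
stoichiometric coefficients of all ATP species; transporters that move ATP
between compartments therefore net to zero and are excluded from both the
contributor and consumer sets.  Demand scans impose energy demand by raising
the lower bound of the ATP maintenance reaction (ATPM) and re-solving the
entropic flux program at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efba import EntropicObjective, EntropicSolution, SolverSettings, solve_entropic_fba
from .model import MetabolicModel

#: Net-flux magnitude below which a reaction is treated as carrying no flux.
FLUX_TOL = 1e-6

#: Default demand grid (μmol/gDW/h), minimum to maximum maintenance demand.
DEFAULT_DEMAND_GRID = tuple(float(d) for d in range(10, 601, 10))

#: Focused grid used in reports.
FOCUSED_DEMAND_GRID = tuple(float(d) for d in range(10, 101, 10))


@dataclass
class AtpAccounting:
    net_production: dict[str, float]
    contributors: set[str]
    consumers: set[str]


@dataclass
class DemandScanResult:
    demands: list[float]
    subsystem_flux: list[dict[str, float] | None]  # None for infeasible points
    subsystem_share: list[dict[str, float] | None]
    statuses: list[str]
    atps_flux: list[float | None] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Tidy (demand, subsystem, flux, share) table for plotting."""
        rows = []
        for d, fl, sh, st in zip(
            self.demands, self.subsystem_flux, self.subsystem_share, self.statuses
        ):
            if fl is None:
                rows.append(
                    {"demand": d, "subsystem": "", "flux": np.nan, "share": np.nan,
                     "status": st}
                )
                continue
            for sub, f in sorted(fl.items()):
                rows.append(
                    {"demand": d, "subsystem": sub, "flux": f,
                     "share": (sh or {}).get(sub, np.nan), "status": st}
                )
        return pd.DataFrame(rows)


def atp_accounting(
    model: MetabolicModel,
    solution: EntropicSolution,
    atp_species: set[str] | None = None,
    flux_tol: float = FLUX_TOL,
) -> AtpAccounting:
    """Classify reactions into net ATP contributors and consumers."""
    if solution.status != "optimal":
        raise ValueError("accounting requires an optimal solution")
    if atp_species is None:
        atp_species = set(model.atp_species)
    if not atp_species:
        raise ValueError("atp_species must not be empty")
    fluxes = solution.fluxes
    net = {}
    for r in model.reactions:
        coef = sum(c for m, c in r.stoichiometry.items() if m in atp_species)
        net[r.id] = coef * fluxes[r.id]
    contributors = {
        rid
        for rid, p in net.items()
        if p > flux_tol and abs(fluxes[rid]) > flux_tol
    }
    consumers = {
        rid
        for rid, p in net.items()
        if p < -flux_tol and abs(fluxes[rid]) > flux_tol
    }
    return AtpAccounting(net, contributors, consumers)


def subsystem_shares(
    accounting: AtpAccounting, model: MetabolicModel
) -> tuple[dict[str, tuple[float, float]], bool]:
    """Aggregate contributor ATP flux by subsystem.

    Returns (subsystem -> (flux, fraction), defined).  When there are no
    contributors the share map is empty and ``defined`` is False rather than
    raising a division error.
    """
    flux_by_sub: dict[str, float] = {}
    for rid in accounting.contributors:
        sub = model.reaction(rid).subsystem or "(unassigned)"
        flux_by_sub[sub] = flux_by_sub.get(sub, 0.0) + accounting.net_production[rid]
    total = sum(flux_by_sub.values())
    if total <= 0:
        return {}, False
    return {s: (f, f / total) for s, f in flux_by_sub.items()}, True


def demand_scan(
    model: MetabolicModel,
    demands: tuple[float, ...] = FOCUSED_DEMAND_GRID,
    objective: EntropicObjective | None = None,
    settings: SolverSettings | None = None,
    atps_id: str = "ATPS4mi",
) -> DemandScanResult:
    """Entropic solve + ATP accounting at each ATPM lower bound in ``demands``.

    Infeasible grid points are flagged in ``statuses``, never dropped.
    """
    atpm = model.reaction(model.atpm_id)
    result = DemandScanResult([], [], [], [], [])
    for d in demands:
        if d < 0 or d > atpm.upper_bound:
            result.demands.append(d)
            result.subsystem_flux.append(None)
            result.subsystem_share.append(None)
            result.statuses.append("out_of_range")
            result.atps_flux.append(None)
            continue
        mm = model.copy()
        mm.reaction(model.atpm_id).lower_bound = d
        sol = solve_entropic_fba(mm, objective, settings)
        result.demands.append(d)
        result.statuses.append(sol.status)
        if sol.status != "optimal":
            result.subsystem_flux.append(None)
            result.subsystem_share.append(None)
            result.atps_flux.append(None)
            continue
        acc = atp_accounting(mm, sol)
        shares, defined = subsystem_shares(acc, mm)
        result.subsystem_flux.append({s: f for s, (f, _) in shares.items()})
        result.subsystem_share.append(
            {s: frac for s, (_, frac) in shares.items()} if defined else None
        )
        result.atps_flux.append(sol.fluxes.get(atps_id))
    return result


def total_contribution(flux_by_sub: dict[str, float] | None) -> float:
    return sum(flux_by_sub.values()) if flux_by_sub else 0.0
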
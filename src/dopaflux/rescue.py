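"""Single-reaction bioenergetic rescue scans on a diseased (PD) model.

Two modes:

* **inhibition** — each internal reaction is knocked out (both bounds zero)
  in turn; a knockout is an energy rescue when ATP-synthase flux and the
  summed glycolytic ATP flux reach at least (1 − slack) of the matched
  control values at every demand in the grid.

* **increase** — each internal reaction with nonzero baseline flux is forced
  to 1.1× its baseline net flux in the baseline's active direction.  In the
  forced solve the exchange bounds are replaced by relaxed generic bounds and
  a diagonal quadratic penalty anchors exchange fluxes at their baseline
  values, so exchanges move only under stoichiometric compulsion.  Energy
  improvement is judged against the PD baseline (rescued ATP-synthase flux
  must exceed it by more than a tolerance).

Exchange improvements are judged by direction-of-control movement:
sign(rescued − pd) = sign(control − pd) with both magnitudes above tolerance
(overshoot past the control value still counts as improvement); a movement of
opposite sign is a worsening.  The composite "overall rescue" call — energy
improvement at every feasible demand, at least one evaluated exchange
improved and none worsened — operationalizes "improved bioenergetic
performance and metabolite exchanges" and is exposed through configurable
predicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .compare import CsfDirectionEntry
from .efba import (
    EntropicObjective,
    EntropicSolution,
    SolverSettings,
    solve_entropic_fba,
)
from .model import DEFAULT_BOUND, MetabolicModel


@dataclass
class RescueConfig:
    mode: str = "increase"  # increase | inhibit
    increase_factor: float = 1.1
    demand_grid: tuple[float, ...] = (10.62,)
    atps_id: str = "ATPS4mi"
    glycolysis_subsystem: str = "Glycolysis"
    energy_slack: float = 0.05  # fractional, inhibition mode
    energy_tol: float = 1e-3  # absolute ATP-synthase flux gain, increase mode
    exchange_tol: float = 0.01  # absolute exchange flux movement
    flux_tol: float = 1e-6
    exchange_entries: list[CsfDirectionEntry] = field(default_factory=list)
    penalty_weight: float = 100.0
    settings: SolverSettings | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("increase", "inhibit"):
            raise ValueError(f"unknown rescue mode {self.mode!r}")
        if self.mode == "increase" and self.increase_factor < 1.0:
            raise ValueError("increase factor must be >= 1 in increase mode")


@dataclass
class RescueResult:
    reaction_id: str
    statuses: dict[float, str]
    energy_improved: dict[float, bool]
    atps_flux: dict[float, float | None]
    glycolytic_atp: dict[float, float | None]
    exchange_calls: dict[str, str]  # improved | not_improved | worsened | not_evaluable
    rescued_exchanges: dict[str, float] = field(default_factory=dict)
    skipped_reason: str | None = None

    @property
    def overall(self) -> bool:
        """Energy improvement at all feasible demands, >=1 exchange improved,
        none worsened (the documented composite)."""
        if self.skipped_reason:
            return False
        feasible = [d for d, s in self.statuses.items() if s == "optimal"]
        if not feasible:
            return False
        if not all(self.energy_improved.get(d, False) for d in feasible):
            return False
        calls = list(self.exchange_calls.values())
        return calls.count("improved") >= 1 and calls.count("worsened") == 0


def classify_improvement(
    control_flux: float,
    pd_flux: float,
    rescued_flux: float,
    role: str,
    tol: float,
) -> str:
    """Improvement call for one flux triple (control, PD baseline, rescued).

    energy: improved iff the rescued flux exceeds the PD baseline by > tol.
    exchange: improved iff the rescued flux moved from the PD baseline in the
    direction of the control flux, both movements exceeding tol in magnitude
    (overshoot allowed).
    """
    if role == "energy":
        return "improved" if rescued_flux > pd_flux + tol else "not_improved"
    if role != "exchange":
        raise ValueError(f"unknown role {role!r}")
    d_res = rescued_flux - pd_flux
    d_ctrl = control_flux - pd_flux
    if abs(d_res) > tol and abs(d_ctrl) > tol and d_res * d_ctrl > 0:
        return "improved"
    return "not_improved"


def _exchange_call(control, pd, rescued, tol) -> str:
    d_res = rescued - pd
    d_ctrl = control - pd
    if abs(d_ctrl) <= tol:
        return "not_evaluable"
    if abs(d_res) <= tol:
        return "not_improved"
    return "improved" if d_res * d_ctrl > 0 else "worsened"


def glycolytic_atp(
    model: MetabolicModel, solution: EntropicSolution, subsystem: str
) -> float:
    """Summed net ATP production of the glycolytic subsystem."""
    atp = set(model.atp_species)
    fluxes = solution.fluxes
    total = 0.0
    for r in model.reactions:
        if r.subsystem != subsystem:
            continue
        coef = sum(c for m, c in r.stoichiometry.items() if m in atp)
        total += coef * fluxes[r.id]
    return total


def _solve_with_demand(model, demand, objective=None, settings=None):
    mm = model.copy()
    mm.reaction(model.atpm_id).lower_bound = demand
    return mm, solve_entropic_fba(mm, objective, settings)


def _reference_solutions(model, config):
    out = {}
    for d in config.demand_grid:
        _, sol = _solve_with_demand(model, d, settings=config.settings)
        out[d] = sol
    return out


def inhibition_scan(
    pd_model: MetabolicModel,
    control_model: MetabolicModel,
    config: RescueConfig,
    reactions: list[str] | None = None,
) -> list[RescueResult]:
    """Knock out each internal reaction of the PD model and re-solve.

    Each knockout starts from the pristine PD model (order-independent).
    Energy criterion: ATP-synthase flux and glycolytic ATP flux both at least
    (1 − slack) × control at the same demand.
    """
    control_ref = _reference_solutions(control_model, config)
    baseline_ref = _reference_solutions(pd_model, config)
    if reactions is None:
        reactions = [r.id for r in pd_model.internal_reactions]
    primary = config.demand_grid[0]
    results = []
    for rid in reactions:
        statuses, energy_ok, atps_f, glyc_f = {}, {}, {}, {}
        rescued_w: dict[str, float] = {}
        for d in config.demand_grid:
            mm = pd_model.copy()
            r = mm.reaction(rid)
            r.lower_bound = 0.0
            r.upper_bound = 0.0
            mm.reaction(pd_model.atpm_id).lower_bound = d
            sol = solve_entropic_fba(mm, settings=config.settings)
            statuses[d] = sol.status
            if sol.status != "optimal":
                atps_f[d] = glyc_f[d] = None
                energy_ok[d] = False
                continue
            ctrl = control_ref[d]
            atps = sol.fluxes[config.atps_id]
            glyc = glycolytic_atp(mm, sol, config.glycolysis_subsystem)
            atps_f[d], glyc_f[d] = atps, glyc
            if ctrl.status != "optimal":
                energy_ok[d] = False
            else:
                ctrl_atps = ctrl.fluxes[config.atps_id]
                ctrl_glyc = glycolytic_atp(
                    control_model, ctrl, config.glycolysis_subsystem
                )
                energy_ok[d] = (
                    atps >= (1.0 - config.energy_slack) * ctrl_atps
                    and glyc >= (1.0 - config.energy_slack) * ctrl_glyc
                )
            if d == primary:
                rescued_w = dict(sol.w)
        exchange_calls = _evaluate_exchanges(
            config, control_ref[primary], baseline_ref[primary], rescued_w
        )
        results.append(
            RescueResult(rid, statuses, energy_ok, atps_f, glyc_f,
                         exchange_calls, rescued_w)
        )
    return results


def _evaluate_exchanges(config, control_sol, baseline_sol, rescued_w):
    calls = {}
    if not rescued_w or control_sol.status != "optimal" or baseline_sol.status != "optimal":
        return calls
    for entry in config.exchange_entries:
        rid = entry.reaction_id
        if rid not in rescued_w or rid not in control_sol.w or rid not in baseline_sol.w:
            continue
        calls[rid] = _exchange_call(
            control_sol.w[rid], baseline_sol.w[rid], rescued_w[rid],
            config.exchange_tol,
        )
    return calls


def increase_scan(
    pd_model: MetabolicModel,
    control_model: MetabolicModel,
    config: RescueConfig,
    reactions: list[str] | None = None,
    generic_bound: float = DEFAULT_BOUND,
) -> list[RescueResult]:
    """Force each active internal reaction to ``increase_factor`` × its
    baseline net flux and re-solve with exchanges anchored at baseline.

    Reactions with |baseline net flux| <= flux tolerance are skipped with a
    reason.  A forcing that exceeds the reaction's own capacity is reported
    infeasible for that demand.  With increase factor exactly 1 the forcing
    is a no-op and results equal the baseline.
    """
    control_ref = _reference_solutions(control_model, config)
    baseline_ref = _reference_solutions(pd_model, config)
    if reactions is None:
        reactions = [r.id for r in pd_model.internal_reactions]
    primary = config.demand_grid[0]
    results = []
    for rid in reactions:
        base_primary = baseline_ref[primary]
        if base_primary.status != "optimal":
            results.append(
                RescueResult(rid, {}, {}, {}, {}, {},
                             skipped_reason="baseline not optimal")
            )
            continue
        v0 = base_primary.v[rid]
        if abs(v0) <= config.flux_tol:
            results.append(
                RescueResult(rid, {}, {}, {}, {}, {},
                             skipped_reason="zero baseline flux")
            )
            continue
        statuses, energy_ok, atps_f, glyc_f = {}, {}, {}, {}
        rescued_w: dict[str, float] = {}
        for d in config.demand_grid:
            base = baseline_ref[d]
            if base.status != "optimal":
                statuses[d] = "baseline_" + base.status
                energy_ok[d] = False
                atps_f[d] = glyc_f[d] = None
                continue
            if config.increase_factor == 1.0:
                sol, mm = base, pd_model
            else:
                mm = pd_model.copy()
                objective = EntropicObjective()
                for ex in mm.exchange_reactions:
                    ex.lower_bound = -generic_bound
                    ex.upper_bound = generic_bound
                    objective.h[ex.id] = base.w[ex.id]
                    objective.H[ex.id] = config.penalty_weight
                target = config.increase_factor * base.v[rid]
                r = mm.reaction(rid)
                if base.v[rid] > 0:
                    if target > r.upper_bound:
                        statuses[d] = "infeasible"
                        energy_ok[d] = False
                        atps_f[d] = glyc_f[d] = None
                        continue
                    r.lower_bound = target
                else:
                    if target < r.lower_bound:
                        statuses[d] = "infeasible"
                        energy_ok[d] = False
                        atps_f[d] = glyc_f[d] = None
                        continue
                    r.upper_bound = target
                mm.reaction(pd_model.atpm_id).lower_bound = d
                sol = solve_entropic_fba(mm, objective, config.settings)
            statuses[d] = sol.status
            if sol.status != "optimal":
                energy_ok[d] = False
                atps_f[d] = glyc_f[d] = None
                continue
            atps = sol.fluxes[config.atps_id]
            atps_f[d] = atps
            glyc_f[d] = glycolytic_atp(mm, sol, config.glycolysis_subsystem)
            energy_ok[d] = (
                classify_improvement(
                    float("nan"), base.fluxes[config.atps_id], atps,
                    "energy", config.energy_tol,
                )
                == "improved"
            )
            if d == primary:
                rescued_w = dict(sol.w)
        exchange_calls = _evaluate_exchanges(
            config, control_ref[primary], baseline_ref[primary], rescued_w
        )
        results.append(
            RescueResult(rid, statuses, energy_ok, atps_f, glyc_f,
                         exchange_calls, rescued_w)
        )
    return results


def potential_shift(
    baseline: EntropicSolution,
    perturbed: EntropicSolution,
    metabolite_ids: list[str] | None = None,
) -> dict[str, float]:
    """Change in chemical potential (mass-balance dual) per metabolite."""
    if baseline.status != "optimal" or perturbed.status != "optimal":
        raise ValueError("potential shifts require optimal solutions")
    if set(baseline.y_N) != set(perturbed.y_N):
        only_b = sorted(set(baseline.y_N) - set(perturbed.y_N))
        only_p = sorted(set(perturbed.y_N) - set(baseline.y_N))
        raise ValueError(
            f"metabolite sets differ: baseline-only {only_b}, perturbed-only {only_p}"
        )
    ids = metabolite_ids if metabolite_ids is not None else sorted(baseline.y_N)
    out = {}
    for m in ids:
        if m not in baseline.y_N:
            raise KeyError(f"unknown metabolite id {m!r}")
        out[m] = perturbed.y_N[m] - baseline.y_N[m]
    return out
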
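"""Complex I inhibition scans and substrate (oxygen/glucose) sensitivity scans.

Inhibition is implemented as capacity scaling: the bound limiting the
reaction's active direction is multiplied by (1 − α), so α = 1 forces zero
flux.  The reference capacity is the bound of the unperturbed model, not the
baseline flux.  Substrate scans tighten an exchange reaction's uptake
capacity from its current lower bound toward zero; where a forced minimum
uptake exceeds the scanned capacity, the minimum is reduced to the capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efba import EntropicObjective, SolverSettings, solve_entropic_fba
from .model import MetabolicModel


@dataclass
class InhibitionScanResult:
    demand: float
    alphas: list[float]
    complex1_flux: list[float | None]
    atps_flux: list[float | None]
    statuses: list[str]
    inflection_alpha: float | None = None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alphas,
                "complex1_flux": [np.nan if v is None else v for v in self.complex1_flux],
                "atps_flux": [np.nan if v is None else v for v in self.atps_flux],
                "status": self.statuses,
            }
        )


@dataclass
class SubstrateScanResult:
    demand: float
    exchange_id: str
    uptake_bounds: list[float]
    atps_flux: list[float | None]
    statuses: list[str]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "uptake_bound": self.uptake_bounds,
                "atps_flux": [np.nan if v is None else v for v in self.atps_flux],
                "status": self.statuses,
            }
        )


def _solve_at_demand(model, demand, objective, settings):
    mm = model.copy()
    mm.reaction(model.atpm_id).lower_bound = demand
    return mm, solve_entropic_fba(mm, objective, settings)


def complex1_scan(
    model: MetabolicModel,
    complex1_id: str,
    alphas: tuple[float, ...],
    demand: float,
    atps_id: str = "ATPS4mi",
    drop_threshold: float = 0.01,
    objective: EntropicObjective | None = None,
    settings: SolverSettings | None = None,
) -> InhibitionScanResult:
    """ATP-synthase response to graded Complex I inhibition at fixed demand.

    The inflection point is reported as the smallest α at which ATP-synthase
    flux drops more than ``drop_threshold`` (fractionally) below its α = 0
    value; None when no such α exists on the grid.
    """
    ref = model.reaction(complex1_id)  # raises on unknown id
    ref_upper, ref_lower = ref.upper_bound, ref.lower_bound
    result = InhibitionScanResult(demand, [], [], [], [])
    baseline_atps = None
    for alpha in alphas:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("inhibition fractions must lie in [0, 1]")
        mm = model.copy()
        r = mm.reaction(complex1_id)
        # scale the capacity of the active direction; keep zero crossing valid
        r.upper_bound = ref_upper * (1.0 - alpha) if ref_upper > 0 else ref_upper
        r.lower_bound = ref_lower * (1.0 - alpha) if ref_lower < 0 else ref_lower
        mm.reaction(model.atpm_id).lower_bound = demand
        sol = solve_entropic_fba(mm, objective, settings)
        result.alphas.append(alpha)
        result.statuses.append(sol.status)
        if sol.status != "optimal":
            result.complex1_flux.append(None)
            result.atps_flux.append(None)
            continue
        ci = sol.fluxes[complex1_id]
        atps = sol.fluxes[atps_id]
        result.complex1_flux.append(ci)
        result.atps_flux.append(atps)
        if alpha == 0.0:
            baseline_atps = atps
        if (
            result.inflection_alpha is None
            and baseline_atps is not None
            and atps < baseline_atps * (1.0 - drop_threshold)
        ):
            result.inflection_alpha = alpha
    return result


def substrate_scan(
    model: MetabolicModel,
    exchange_id: str,
    demand: float,
    grid: tuple[float, ...] | None = None,
    n_points: int = 9,
    atps_id: str = "ATPS4mi",
    objective: EntropicObjective | None = None,
    settings: SolverSettings | None = None,
) -> SubstrateScanResult:
    """ATP-synthase flux as an exchange's uptake capacity shrinks to zero."""
    ex = model.reaction(exchange_id)
    if not ex.is_exchange:
        raise ValueError(f"{exchange_id!r} is not an exchange reaction")
    if ex.lower_bound >= 0:
        raise ValueError(f"{exchange_id!r} does not admit uptake")
    if grid is None:
        grid = tuple(np.linspace(ex.lower_bound, 0.0, n_points))
    result = SubstrateScanResult(demand, exchange_id, [], [], [])
    for g in grid:
        mm = model.copy()
        r = mm.reaction(exchange_id)
        r.lower_bound = g
        # a forced minimum uptake cannot exceed the scanned capacity
        r.upper_bound = max(r.upper_bound, g)
        mm.reaction(model.atpm_id).lower_bound = demand
        sol = solve_entropic_fba(mm, objective, settings)
        result.uptake_bounds.append(float(g))
        result.statuses.append(sol.status)
        result.atps_flux.append(
            sol.fluxes[atps_id] if sol.status == "optimal" else None
        )
    return result
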
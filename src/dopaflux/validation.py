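"""Basic metabolic-function validity checks.

Each check opens a named set of carbon-source exchanges (optionally with
oxygen), relaxes every forced-flux minimum elsewhere, and maximizes the ATP
maintenance (ATPM) flux by linear programming.  A model "can generate ATP
from a source" when the maximal ATPM flux is positive.  These checks use LP
directly — the entropic solver plays no role here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lp import solve_lp
from .model import MetabolicModel

#: Exchanges treated as carbon sources in the default toy check battery.
DEFAULT_CARBON_SOURCES = (
    "EX_glc_D[e]",
    "EX_lac_L[e]",
    "EX_his_L[e]",
    "EX_lys_L[e]",
    "EX_met_L[e]",
    "EX_gln_L[e]",
    "EX_orn[e]",
)

GENERIC_UPTAKE = -1000.0


@dataclass
class FunctionCheck:
    name: str
    sources: tuple[str, ...]
    aerobic: bool
    max_atpm: float | None
    status: str  # ok | infeasible

    @property
    def passed(self) -> bool:
        return self.status == "ok" and (self.max_atpm or 0.0) > 1e-9


def _relaxed(model: MetabolicModel) -> MetabolicModel:
    """Copy with every forced-flux minimum relaxed (lb>0 -> 0, ub<0 -> 0)."""
    mm = model.copy()
    for r in mm.reactions:
        if r.lower_bound > 0:
            r.lower_bound = 0.0
        if r.upper_bound < 0:
            r.upper_bound = 0.0
    return mm


def max_atpm_with_sources(
    model: MetabolicModel,
    sources: tuple[str, ...],
    aerobic: bool,
    oxygen_exchange: str = "EX_o2[e]",
    carbon_sources: tuple[str, ...] = DEFAULT_CARBON_SOURCES,
) -> FunctionCheck:
    """Maximal ATPM flux with only the named carbon sources open."""
    mm = _relaxed(model)
    for rid in carbon_sources:
        if mm.has_reaction(rid):
            mm.reaction(rid).lower_bound = 0.0  # close all sources
    for rid in sources:
        r = mm.reaction(rid)
        r.lower_bound = (
            model.reaction(rid).lower_bound
            if model.reaction(rid).lower_bound < 0
            else GENERIC_UPTAKE
        )
    if mm.has_reaction(oxygen_exchange):
        ox = mm.reaction(oxygen_exchange)
        if aerobic:
            ox.lower_bound = model.reaction(oxygen_exchange).lower_bound
        else:
            ox.lower_bound = 0.0
    res = solve_lp(mm, {model.atpm_id: 1.0}, sense="max")
    name = "+".join(s.replace("EX_", "").replace("[e]", "") for s in sources) or "none"
    name += "_aerobic" if aerobic else "_anaerobic"
    if res.status != "optimal":
        return FunctionCheck(name, sources, aerobic, None, "infeasible")
    return FunctionCheck(name, sources, aerobic, res.objective, "ok")


def validate_core_functions(
    model: MetabolicModel,
    carbon_sources: tuple[str, ...] = DEFAULT_CARBON_SOURCES,
    oxygen_exchange: str = "EX_o2[e]",
) -> list[FunctionCheck]:
    """Battery of single-source ATP-generation checks plus the closed case.

    An infeasible base model yields checks with status 'infeasible' rather
    than an exception.
    """
    if not model.has_reaction(model.atpm_id):
        raise ValueError(f"model lacks an ATPM-role reaction {model.atpm_id!r}")
    checks = []
    for src in carbon_sources:
        if not model.has_reaction(src):
            continue
        checks.append(
            max_atpm_with_sources(
                model, (src,), aerobic=True,
                oxygen_exchange=oxygen_exchange, carbon_sources=carbon_sources,
            )
        )
    # glycolysis-only: glucose without oxygen
    if model.has_reaction("EX_glc_D[e]"):
        checks.append(
            max_atpm_with_sources(
                model, ("EX_glc_D[e]",), aerobic=False,
                oxygen_exchange=oxygen_exchange, carbon_sources=carbon_sources,
            )
        )
    # all carbon sources closed
    checks.append(
        max_atpm_with_sources(
            model, (), aerobic=True,
            oxygen_exchange=oxygen_exchange, carbon_sources=carbon_sources,
        )
    )
    return checks
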
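"""End-to-end orchestration of the condition-comparison workflow.

``run_full_analysis`` builds or loads the four condition variants, solves the
entropic flux program for each, runs the demand / Complex I / substrate
scans, builds the CSF comparison reports for both components, runs the
rescue scans on the PD variants, and writes deterministic tab-separated
tables plus a JSON run summary.  Identical configuration and seed produce an
identical bundle (timestamps excluded).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bioenergetics import demand_scan
from .compare import build_comparison_table, comparison_frame, load_csf_table
from .efba import SolverSettings, flux_table, solve_entropic_fba
from .io import load_model, save_model
from .perturbation import complex1_scan, substrate_scan
from .rescue import RescueConfig, increase_scan, inhibition_scan  # noqa: F401
from .toy import (
    ATP_SYNTHASE_ID,
    COMPLEX1_ID,
    STUDY_DEMANDS,
    ToySpec,
    build_toy_model,
)

logger = logging.getLogger("dopaflux")

VARIANTS = (
    ("synaptic", "control"),
    ("synaptic", "pd"),
    ("nonsynaptic", "control"),
    ("nonsynaptic", "pd"),
)


@dataclass
class RunConfig:
    output_dir: str | Path = "dopaflux_run"
    model_paths: dict[str, str] | None = None  # variant key -> model file
    demand_grid: tuple[float, ...] = tuple(float(d) for d in range(10, 101, 10))
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    csf_table_path: str | None = None  # None -> packaged table
    complex1_demand: float = STUDY_DEMANDS["complex1"]
    minimum_demand: float = STUDY_DEMANDS["minimum"]
    rescue_demands: tuple[float, ...] = STUDY_DEMANDS["increase_rescue"]
    rescue_penalty_weight: float = 1000.0
    run_rescue: bool = True
    seed: int = 0
    settings: SolverSettings = field(default_factory=SolverSettings)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg


def _load_variants(config: RunConfig):
    models = {}
    for component, condition in VARIANTS:
        key = f"{component}_{condition}"
        if config.model_paths and key in config.model_paths:
            models[key] = load_model(config.model_paths[key])
        else:
            models[key] = build_toy_model(ToySpec(component, condition))
    return models


def run_full_analysis(config: RunConfig) -> dict:
    """Run the full workflow; returns the JSON-serializable run summary."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "software": {"name": "dopaflux", "version": __version__},
        "seed": config.seed,
        "tolerances": {
            "feasibility": config.settings.feasibility_tol,
            "stationarity": config.settings.stationarity_tol,
        },
        "stages": {},
    }

    models = _load_variants(config)
    solutions = {}
    try:
        for key, model in models.items():
            save_model(model, out / f"model_{key}.json")
            mm = model.copy()
            mm.reaction(model.atpm_id).lower_bound = config.minimum_demand
            sol = solve_entropic_fba(mm, settings=config.settings)
            solutions[key] = sol
            if sol.status == "optimal":
                flux_table(sol, mm).to_csv(
                    out / f"fluxes_{key}.tsv", sep="\t", index=False
                )
            summary["stages"][f"solve_{key}"] = sol.status
            logger.info("solved %s: %s", key, sol.status)
    except Exception as exc:  # pragma: no cover - defensive
        (out / "FAILED").write_text(f"solve stage: {exc}\n")
        raise

    for key, model in models.items():
        scan = demand_scan(model, config.demand_grid, atps_id=ATP_SYNTHASE_ID)
        scan.table().to_csv(out / f"demand_scan_{key}.tsv", sep="\t", index=False)
        summary["stages"][f"demand_scan_{key}"] = "ok"

        c1 = complex1_scan(
            model, COMPLEX1_ID, config.alpha_grid, config.complex1_demand
        )
        c1.table().to_csv(out / f"complex1_scan_{key}.tsv", sep="\t", index=False)
        summary["stages"][f"complex1_scan_{key}"] = "ok"
        summary.setdefault("complex1_inflection", {})[key] = c1.inflection_alpha

        sub = substrate_scan(model, "EX_o2[e]", config.minimum_demand)
        sub.table().to_csv(out / f"oxygen_scan_{key}.tsv", sep="\t", index=False)
        summary["stages"][f"oxygen_scan_{key}"] = "ok"

    # CSF comparison reports (toy control vs PD per component)
    try:
        entries = load_csf_table(config.csf_table_path)
        for component in ("synaptic", "nonsynaptic"):
            c = solutions[f"{component}_control"]
            p = solutions[f"{component}_pd"]
            if c.status != "optimal" or p.status != "optimal":
                summary["stages"][f"csf_comparison_{component}"] = "skipped"
                continue
            rows, missing = build_comparison_table(c, p, entries)
            comparison_frame(rows).to_csv(
                out / f"csf_comparison_{component}.tsv", sep="\t", index=False
            )
            summary["stages"][f"csf_comparison_{component}"] = "ok"
            summary.setdefault("csf_missing", {})[component] = [
                e.reaction_id for e in missing
            ]
    except FileNotFoundError:
        logger.warning("CSF table missing; comparison stage skipped")
        summary["stages"]["csf_comparison"] = "skipped_missing_table"

    if config.run_rescue:
        entries = load_csf_table(config.csf_table_path)
        for component in ("synaptic", "nonsynaptic"):
            cfg = RescueConfig(
                mode="increase",
                demand_grid=config.rescue_demands,
                exchange_entries=entries,
                penalty_weight=config.rescue_penalty_weight,
            )
            results = increase_scan(
                models[f"{component}_pd"], models[f"{component}_control"], cfg
            )
            _rescue_table(results, cfg).to_csv(
                out / f"rescue_increase_{component}.tsv", sep="\t", index=False
            )
            summary["stages"][f"rescue_increase_{component}"] = "ok"
            summary.setdefault("rescue_overall", {})[component] = sorted(
                r.reaction_id for r in results if r.overall
            )

    summary["runtime_s"] = round(time.time() - t0, 2)
    text = json.dumps(summary, indent=1, sort_keys=True)
    (out / "run_summary.json").write_text(text + "\n")
    return summary


def _rescue_table(results, cfg):
    import pandas as pd

    rows = []
    for r in results:
        primary = cfg.demand_grid[0]
        rows.append(
            {
                "reaction": r.reaction_id,
                "status": r.statuses.get(primary, r.skipped_reason or "skipped"),
                "energy_improved_all": bool(r.energy_improved)
                and all(r.energy_improved.values()),
                "atps_flux": r.atps_flux.get(primary),
                "n_exchanges_improved": list(r.exchange_calls.values()).count(
                    "improved"
                ),
                "n_exchanges_worsened": list(r.exchange_calls.values()).count(
                    "worsened"
                ),
                "overall_rescue": r.overall,
            }
        )
    return pd.DataFrame(rows)


def run_inhibition_rescue(
    component: str,
    demand: float,
    reactions: list[str] | None = None,
    csf_table_path: str | None = None,
):
    """Convenience wrapper: knockout rescue scan on one PD variant."""
    entries = load_csf_table(csf_table_path)
    pd_model = build_toy_model(ToySpec(component, "pd"))
    control = build_toy_model(ToySpec(component, "control"))
    cfg = RescueConfig(
        mode="inhibit", demand_grid=(demand,), exchange_entries=entries
    )
    return inhibition_scan(pd_model, control, cfg, reactions=reactions), cfg
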
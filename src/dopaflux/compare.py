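"""Classification of control→PD exchange-flux changes and consistency calls
against cerebrospinal-fluid (CSF) metabolite directions.

Sign convention: exchange fluxes are negative for uptake and positive for
secretion.  A metabolite reported as increased in PD CSF is consistent with
lower uptake or higher excretion in the PD model; a decrease is consistent
with higher uptake or lower excretion.  Metabolites with conflicting CSF
reports carry both directions and a change is consistent if it matches any
reported direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .efba import EntropicSolution

#: Absolute flux tolerance for calling two fluxes "the same"
#: (published comparisons print four decimals).
SAME_TOL = 1e-4

CHANGE_CLASSES = (
    "same",
    "lower_uptake",
    "higher_uptake",
    "lower_excretion",
    "higher_excretion",
    "sign_change",
)

#: Model change classes consistent with each CSF direction.
_CONSISTENT_WITH = {
    "increased": {"lower_uptake", "higher_excretion"},
    "decreased": {"higher_uptake", "lower_excretion"},
}

#: Printed labels used in tabular reports.
PRINTED_LABEL = {
    "same": "Same",
    "lower_uptake": "Lower uptake",
    "higher_uptake": "Higher uptake",
    "lower_excretion": "Lower excrete",
    "higher_excretion": "Higher excrete",
    "sign_change": "Sign change",
}


@dataclass
class CsfDirectionEntry:
    metabolite: str
    reaction_id: str
    directions: frozenset[str]
    citations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError(f"{self.metabolite}: directions must be nonempty")
        bad = set(self.directions) - set(_CONSISTENT_WITH)
        if bad:
            raise ValueError(f"{self.metabolite}: unknown directions {sorted(bad)}")


@dataclass
class CsfComparisonRow:
    entry: CsfDirectionEntry
    control_flux: float
    pd_flux: float
    change_class: str
    consistency: str  # consistent | inconsistent | not_evaluable

    @property
    def printed_change(self) -> str:
        # a reaction carrying no flux in either condition is reported as
        # non-operating rather than "Same"
        if (
            self.change_class == "same"
            and abs(self.control_flux) <= SAME_TOL
            and abs(self.pd_flux) <= SAME_TOL
        ):
            return "No excrete"
        return PRINTED_LABEL[self.change_class]


def classify_exchange_change(
    control_flux: float, pd_flux: float, tol: float = SAME_TOL
) -> str:
    """Classify a control→PD exchange flux change."""
    if not (math.isfinite(control_flux) and math.isfinite(pd_flux)):
        raise ValueError("fluxes must be finite")
    if abs(pd_flux - control_flux) <= tol:
        return "same"
    if control_flux <= 0 and pd_flux <= 0:
        return "lower_uptake" if abs(pd_flux) < abs(control_flux) else "higher_uptake"
    if control_flux >= 0 and pd_flux >= 0:
        return "lower_excretion" if pd_flux < control_flux else "higher_excretion"
    return "sign_change"


def consistency_call(change_class: str, directions: frozenset[str] | set[str]) -> str:
    """Consistency of a model change with reported CSF directions.

    A conflicting-report entry (both directions) is consistent if any listed
    direction matches.  "same" cannot be evaluated; a sign change is checked
    against both the uptake and the excretion regime it spans.
    """
    if change_class not in CHANGE_CLASSES:
        raise ValueError(f"unknown change class {change_class!r}")
    if change_class == "same":
        return "not_evaluable"
    if change_class == "sign_change":
        # leaving uptake for excretion acts as lower uptake and higher
        # excretion at once (and conversely); match permissively
        effective = {"lower_uptake", "higher_excretion", "higher_uptake",
                     "lower_excretion"}
    else:
        effective = {change_class}
    for d in directions:
        if effective & _CONSISTENT_WITH[d]:
            return "consistent"
    return "inconsistent"


def load_csf_table(path: str | Path | None = None) -> list[CsfDirectionEntry]:
    """Load a direction-annotated CSF metabolite table (packaged by default)."""
    if path is None:
        src = resources.files("dopaflux.data") / "csf_pd_directions.tsv"
        df = pd.read_csv(src, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    entries = []
    for rec in df.itertuples(index=False):
        entries.append(
            CsfDirectionEntry(
                metabolite=rec.metabolite,
                reaction_id=rec.reaction_id,
                directions=frozenset(str(rec.directions).split(";")),
                citations=tuple(str(rec.citations).split(";")),
            )
        )
    return entries


def build_comparison_table(
    control_solution: EntropicSolution | dict[str, float],
    pd_solution: EntropicSolution | dict[str, float],
    csf_entries: list[CsfDirectionEntry],
    tol: float = SAME_TOL,
) -> tuple[list[CsfComparisonRow], list[CsfDirectionEntry]]:
    """One comparison row per CSF entry present in both flux maps.

    Returns (rows, missing) where ``missing`` lists entries whose exchange
    reaction is absent from either solution.
    """
    cf = control_solution.w if isinstance(control_solution, EntropicSolution) else control_solution
    pf = pd_solution.w if isinstance(pd_solution, EntropicSolution) else pd_solution
    rows, missing = [], []
    for entry in csf_entries:
        if entry.reaction_id not in cf or entry.reaction_id not in pf:
            missing.append(entry)
            continue
        c, p = cf[entry.reaction_id], pf[entry.reaction_id]
        change = classify_exchange_change(c, p, tol)
        rows.append(
            CsfComparisonRow(
                entry=entry,
                control_flux=c,
                pd_flux=p,
                change_class=change,
                consistency=consistency_call(change, entry.directions),
            )
        )
    return rows, missing


def comparison_frame(rows: list[CsfComparisonRow]) -> pd.DataFrame:
    """Report table mirroring the published column layout."""
    return pd.DataFrame(
        [
            {
                "reaction_id": r.entry.reaction_id,
                "metabolite": r.entry.metabolite,
                "csf_directions": ";".join(sorted(r.entry.directions)),
                "control_flux": r.control_flux,
                "pd_flux": r.pd_flux,
                "change": r.printed_change,
                "consistency": {
                    "consistent": "Yes",
                    "inconsistent": "No",
                    "not_evaluable": "-",
                }[r.consistency],
            }
            for r in rows
        ]
    )


def load_printed_fluxes(component: str) -> pd.DataFrame:
    """Packaged replica of the published control/PD exchange-flux columns."""
    name = f"exchange_fluxes_{component}.tsv"
    src = resources.files("dopaflux.data") / name
    return pd.read_csv(src, sep="\t")


def load_printed_rescue(component: str) -> pd.DataFrame:
    """Packaged replica of the published rescue flux triples."""
    name = f"rescue_fluxes_{component}.tsv"
    src = resources.files("dopaflux.data") / name
    return pd.read_csv(src, sep="\t")
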
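"""Deterministic toy dopaminergic-neuron network in four condition variants.

The generator emits a small (<60 reaction) mass-balanced network emulating the
structural features of condition-specific neuronal models: lumped glycolysis
with separate PGK/PYK ATP-producing steps, a lumped TCA cycle with one
substrate-level phosphorylation step, a Complex I → proton-motive force → ATP
synthase chain with a constitutive proton leak, an ornithine-transaminase /
urea fragment whose urea output stoichiometrically caps amino-acid nitrogen
disposal, amino-acid degradation lumps (lysine feeding electrons to the
quinone pool, flavoprotein-style), lactate exchange, and — in the synaptic
variants only — a dopamine synthesis/release branch with an ATP cost.

Variants: {synaptic, nonsynaptic} × {control, pd}.  A PD variant differs from
its control ONLY by the disease overlay: Complex I capacity ×0.82, dopamine
release minimum ×0.25 (synaptic only), and glucose/oxygen minimum uptake
relaxed to zero.

All capacity numbers are fixture parameters chosen so the network reproduces
the qualitative study phenomena at toy scale (oxidative-phosphorylation
plateau, PD/control and synaptic/non-synaptic orderings, rescue behavior);
they are NOT literature values.  The proton-motive force is a pseudo-
metabolite lumping the H+ gradient; the 4/6/3 pumping/synthesis
stoichiometries are round numbers giving an integer P/O-like ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constraints import ATPM_UPPER_BOUND
from .model import ConstraintOverlay, MetabolicModel, Metabolite, Reaction

#: Fixture capacity parameters (toy conventions, not literature values).
FIXTURE_PARAMS: dict = {
    "ci_cap": {"synaptic": 7.0, "nonsynaptic": 12.0},
    "pd_ci_factor": 0.82,
    "pd_dopa_factor": 0.25,
    "pmf_per_ci": 4.0,
    "pmf_per_ciii": 6.0,
    "pmf_per_atp": 3.0,
    "leak_min": 2.0,
    "atpm_bounds": (10.62, ATPM_UPPER_BOUND),
    "glc_bounds": {"synaptic": (-60.0, -0.7525), "nonsynaptic": (-40.0, -0.4825)},
    "o2_bounds": (-8.0, -2.0),
    "lac_bounds": (-6.48, 100.0),
    "orn_bounds": (-3.0, -0.3),
    "ureacyc_cap": 0.32,
    "his_bounds": (-27.05, 0.0),
    "lys_bounds": (-100.0, 0.0),
    "met_bounds": (-1.8909, 0.0),
    "gln_bounds": (-60.5564, 0.0),
    "tyr_bounds": (-5.0, 0.0),
    "dopa_release_min": 1.0,
}

#: Demands (μmol/gDW/h ATPM lower bound) at which the fixture analyses are
#: reported: the minimum maintenance demand, the plateau pair, the
#: share-comparison demand, the Complex I scan demand, and the demand at
#: which the PD proton-motive capacity is binding (used by the knockout
#: rescue fixture).
STUDY_DEMANDS: dict = {
    "minimum": 10.62,
    "plateau": (60.0, 100.0),
    "share": 60.0,
    "complex1": 20.0,
    "knockout_rescue": {"synaptic": 25.0, "nonsynaptic": 40.0},
    "increase_rescue": (10.62, 20.0),
}

COMPLEX1_ID = "NADH2_u10mi"
ATP_SYNTHASE_ID = "ATPS4mi"
ATPM_ID = "ATPM"
ORNT_ID = "ORNTArm"
LEAK_ID = "HLEAKm"


@dataclass
class ToySpec:
    component: str = "nonsynaptic"  # synaptic | nonsynaptic
    condition: str = "control"  # control | pd
    seed: int = 0
    params: dict = field(default_factory=lambda: dict(FIXTURE_PARAMS))

    def __post_init__(self) -> None:
        if self.component not in ("synaptic", "nonsynaptic"):
            raise ValueError(f"unknown component {self.component!r}")
        if self.condition not in ("control", "pd"):
            raise ValueError(f"unknown condition {self.condition!r}")


def _metabolites(synaptic: bool) -> list[Metabolite]:
    base = [
        "glc_D[e]", "glc_D[c]", "o2[e]", "o2[m]", "lac_L[e]", "lac_L[c]",
        "urea[e]", "orn[e]", "his_L[e]", "his_L[m]",
        "lys_L[e]", "lys_L[m]", "met_L[e]", "met_L[m]", "gln_L[e]", "gln_L[m]",
        "co2[e]", "co2[m]", "atp[c]", "adp[c]", "atp[m]", "adp[m]",
        "nad[c]", "nadh[c]", "nad[m]", "nadh[m]", "13dpg[c]", "pep[c]",
        "pyr[c]", "pyr[m]", "accoa[m]", "oaa[m]", "akg[m]", "glu_L[m]",
        "glu_L[e]", "glu5sa[m]", "nh4[m]", "q10[m]", "q10h2[m]", "pmf[m]", "pmfdiss[m]",
        "pro_L[m]", "pro_L[e]",
    ]
    if synaptic:
        base += ["tyr_L[e]", "tyr_L[c]", "dopa[e]", "dopa[c]"]
    return [Metabolite(mid) for mid in base]


def build_toy_model(spec: ToySpec) -> MetabolicModel:
    """Build one condition variant of the toy neuron network.

    PD variants are produced by applying :func:`pd_overlay` to the control
    model, guaranteeing that the bound difference is exactly the disease
    overlay.
    """
    p = spec.params
    syn = spec.component == "synaptic"
    ci_cap = p["ci_cap"][spec.component]
    glc_lb, glc_ub = p["glc_bounds"][spec.component]
    pmf_ci, pmf_ciii, pmf_atp = p["pmf_per_ci"], p["pmf_per_ciii"], p["pmf_per_atp"]

    R = Reaction
    rxns = [
        # boundary exchanges (negative flux = uptake)
        R("EX_glc_D[e]", {"glc_D[e]": -1}, glc_lb, glc_ub),
        R("EX_o2[e]", {"o2[e]": -1}, *p["o2_bounds"]),
        R("EX_lac_L[e]", {"lac_L[e]": -1}, *p["lac_bounds"]),
        R("EX_urea[e]", {"urea[e]": -1}, 0.0, 1000.0),
        R("EX_orn[e]", {"orn[e]": -1}, *p["orn_bounds"]),
        R("EX_his_L[e]", {"his_L[e]": -1}, *p["his_bounds"]),
        R("EX_lys_L[e]", {"lys_L[e]": -1}, *p["lys_bounds"]),
        R("EX_met_L[e]", {"met_L[e]": -1}, *p["met_bounds"]),
        R("EX_gln_L[e]", {"gln_L[e]": -1}, *p["gln_bounds"]),
        R("EX_co2[e]", {"co2[e]": -1}, 0.0, 1000.0),
        R("EX_pro_L[e]", {"pro_L[e]": -1}, 0.0, 1000.0),
        R("EX_glu_L[e]", {"glu_L[e]": -1}, 0.0, 1000.0),
        R("DM_pmfdiss[m]", {"pmfdiss[m]": -1}, 0.0, 1000.0),
        # transports
        R("GLCt1r", {"glc_D[e]": -1, "glc_D[c]": 1}, 0, 1000, "Transport, extracellular"),
        R("O2tm", {"o2[e]": -1, "o2[m]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("L_LACt2r", {"lac_L[e]": -1, "lac_L[c]": 1}, -1000, 1000, "Transport, extracellular"),
        R("HISt", {"his_L[e]": -1, "his_L[m]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("LYSt", {"lys_L[e]": -1, "lys_L[m]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("METt", {"met_L[e]": -1, "met_L[m]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("GLNt", {"gln_L[e]": -1, "gln_L[m]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("CO2t", {"co2[m]": -1, "co2[e]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("NADHSHm", {"nadh[c]": -1, "nad[m]": -1, "nad[c]": 1, "nadh[m]": 1},
          -1000, 1000, "Transport, mitochondrial"),
        R("PYRt2m", {"pyr[c]": -1, "pyr[m]": 1}, 0, 1000, "Transport, mitochondrial"),
        # reversible: the translocator runs backwards in de-energized mitochondria
        R("ATPtm", {"atp[m]": -1, "adp[c]": -1, "atp[c]": 1, "adp[m]": 1},
          -1000, 1000, "Transport, mitochondrial"),
        # glycolysis: lumped upper part, then PGK and PYK as separate
        # ATP-producing steps, and reversible lactate dehydrogenase
        R("HEX_PFK_GAPD",
          {"glc_D[c]": -1, "atp[c]": -2, "nad[c]": -2,
           "13dpg[c]": 2, "adp[c]": 2, "nadh[c]": 2},
          0, 1000, "Glycolysis"),
        R("PGK", {"13dpg[c]": -1, "adp[c]": -1, "pep[c]": 1, "atp[c]": 1},
          0, 1000, "Glycolysis"),
        R("PYK", {"pep[c]": -1, "adp[c]": -1, "pyr[c]": 1, "atp[c]": 1},
          0, 1000, "Glycolysis"),
        R("LDH_L", {"pyr[c]": -1, "nadh[c]": -1, "lac_L[c]": 1, "nad[c]": 1},
          -1000, 1000, "Glycolysis"),
        # anaplerosis: pyruvate carboxylase replenishes TCA intermediates
        R("PCm", {"pyr[m]": -1, "atp[m]": -1, "co2[m]": -1, "oaa[m]": 1, "adp[m]": 1},
          0, 1000, "Pyruvate metabolism"),
        # lumped citric acid cycle with one substrate-level (GTP->ATP proxy) step
        R("PDHm", {"pyr[m]": -1, "nad[m]": -1, "accoa[m]": 1, "nadh[m]": 1, "co2[m]": 1},
          0, 1000, "Citric acid cycle"),
        R("CS_ICDHxm",
          {"accoa[m]": -1, "oaa[m]": -1, "nad[m]": -1,
           "akg[m]": 1, "nadh[m]": 1, "co2[m]": 1},
          0, 1000, "Citric acid cycle"),
        R("AKGD_SUCOASm",
          {"akg[m]": -1, "nad[m]": -2, "adp[m]": -1,
           "oaa[m]": 1, "nadh[m]": 2, "atp[m]": 1, "co2[m]": 1},
          0, 1000, "Citric acid cycle"),
        # respiratory chain and phosphorylation
        R(COMPLEX1_ID,
          {"nadh[m]": -1, "q10[m]": -1, "nad[m]": 1, "q10h2[m]": 1, "pmf[m]": pmf_ci},
          0, ci_cap, "Oxidative phosphorylation"),
        R("CYOR_CYOOm",
          {"q10h2[m]": -1, "o2[m]": -0.5, "q10[m]": 1, "pmf[m]": pmf_ciii},
          0, 1000, "Oxidative phosphorylation"),
        # reversible: reverse mode is the proton-pumping ATPase
        R(ATP_SYNTHASE_ID,
          {"adp[m]": -1, "pmf[m]": -pmf_atp, "atp[m]": 1},
          -1000, 1000, "Oxidative phosphorylation"),
        R(LEAK_ID, {"pmf[m]": -3, "pmfdiss[m]": 1}, p["leak_min"], 1000, "Proton leak"),
        R(ATPM_ID, {"atp[c]": -1, "adp[c]": 1}, *p["atpm_bounds"], "ATP maintenance"),
        # ornithine transaminase / urea fragment: urea output (2 N per urea)
        # is the network's only nitrogen exit, coupling amino-acid catabolism
        # to ornithine transaminase flux; the urea-cycle lump has a capacity
        # slightly above its resting flux, with glutamate-5-semialdehyde
        # overflow reduced to proline (NADH-consuming) and surplus ornithine
        # decarboxylated to putrescine
        R(ORNT_ID, {"akg[m]": -1, "orn[e]": -1, "glu5sa[m]": 1, "glu_L[m]": 1},
          -1000, 1000, "Urea cycle"),
        R("GLUDym", {"glu_L[m]": -1, "nad[m]": -1, "akg[m]": 1, "nadh[m]": 1, "nh4[m]": 1},
          0, 1000, "Glutamate metabolism"),
        R("UREACYCm",
          {"glu5sa[m]": -1, "nh4[m]": -2, "atp[m]": -1, "urea[e]": 1, "adp[m]": 1},
          0, p["ureacyc_cap"], "Urea cycle"),
        R("GLUt", {"glu_L[m]": -1, "atp[c]": -1, "glu_L[e]": 1, "adp[c]": 1}, 0, 1000, "Transport, mitochondrial"),
        R("P5CRm", {"glu5sa[m]": -1, "nadh[m]": -1, "pro_L[m]": 1, "nad[m]": 1},
          0, 1000, "Arginine and proline metabolism"),
        R("PROt", {"pro_L[m]": -1, "pro_L[e]": 1}, 0, 1000, "Transport, mitochondrial"),
        # amino-acid degradation lumps; lysine feeds electrons to the quinone
        # pool (electron-transfer-flavoprotein style), bypassing Complex I
        R("HISDAm", {"his_L[m]": -1, "nad[m]": -1, "glu_L[m]": 1, "nadh[m]": 1},
          0, 1000, "Histidine metabolism"),
        R("LYSDAm",
          {"lys_L[m]": -1, "q10[m]": -2, "accoa[m]": 1, "q10h2[m]": 2, "nh4[m]": 1},
          0, 1000, "Lysine metabolism"),
        R("METDAm", {"met_L[m]": -1, "nad[m]": -1, "pyr[m]": 1, "nadh[m]": 1, "nh4[m]": 1},
          0, 1000, "Methionine metabolism"),
        R("GLNDAm", {"gln_L[m]": -1, "akg[m]": 1, "nh4[m]": 2},
          0, 1000, "Glutamine metabolism"),
    ]
    if syn:
        rxns += [
            R("EX_tyr_L[e]", {"tyr_L[e]": -1}, *p["tyr_bounds"]),
            R("EX_dopa[e]", {"dopa[e]": -1}, p["dopa_release_min"], 1000.0),
            R("TYRt", {"tyr_L[e]": -1, "tyr_L[c]": 1}, 0, 1000, "Transport, extracellular"),
            R("TYR_DOPA", {"tyr_L[c]": -1, "dopa[c]": 1}, 0, 1000, "Tyrosine metabolism"),
            R("DOPAVESr", {"dopa[c]": -1, "atp[c]": -1, "dopa[e]": 1, "adp[c]": 1},
              0, 1000, "Transport, vesicular"),
        ]

    model = MetabolicModel(
        model_id=f"toy_{spec.component}_{spec.condition}",
        metabolites=_metabolites(syn),
        reactions=rxns,
        labels={"component": spec.component, "condition": spec.condition},
        compartments={"c": "cytosol", "m": "mitochondrion", "e": "extracellular"},
        atpm_id=ATPM_ID,
    )
    if spec.condition == "pd":
        model = model.apply_overlay(pd_overlay(spec))
        model.id = f"toy_{spec.component}_pd"
        model.labels["condition"] = "pd"
    return model


def pd_overlay(spec: ToySpec) -> ConstraintOverlay:
    """Disease overlay: Complex I cap ×0.82, dopamine release minimum ×0.25
    (synaptic only), glucose and oxygen minimum uptake relaxed to zero."""
    p = spec.params
    scale = {
        COMPLEX1_ID: {"bound": "upper", "factor": p["pd_ci_factor"]},
    }
    if spec.component == "synaptic":
        scale["EX_dopa[e]"] = {"bound": "lower", "factor": p["pd_dopa_factor"]}
    return ConstraintOverlay(
        bound_edits={"EX_glc_D[e]": (None, 0.0), "EX_o2[e]": (None, 0.0)},
        scale_edits=scale,
    )


def build_variants(params: dict | None = None) -> dict[str, MetabolicModel]:
    """All four study variants keyed 'synaptic_control', 'synaptic_pd', ..."""
    out = {}
    for component in ("synaptic", "nonsynaptic"):
        for condition in ("control", "pd"):
            spec = ToySpec(component, condition)
            if params:
                spec.params.update(params)
            out[f"{component}_{condition}"] = build_toy_model(spec)
    return out


def jitter_instances(
    spec: ToySpec, n: int, seed: int, relative_amplitude: float
) -> list[MetabolicModel]:
    """Robustness fixtures: n copies with finite nonzero bounds multiplicatively
    perturbed by uniform noise in [1−a, 1+a].  One factor per reaction keeps
    lower ≤ upper; identical seeds give identical output."""
    if not 0.0 <= relative_amplitude < 0.5:
        raise ValueError("relative amplitude must lie in [0, 0.5)")
    if n < 0:
        raise ValueError("n must be nonnegative")
    base = build_toy_model(spec)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        m = base.copy()
        for r in m.reactions:
            factor = 1.0 + rng.uniform(-relative_amplitude, relative_amplitude)
            if np.isfinite(r.lower_bound) and r.lower_bound != 0.0:
                r.lower_bound *= factor
            if np.isfinite(r.upper_bound) and r.upper_bound != 0.0:
                r.upper_bound *= factor
        out.append(m)
    return out
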
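"""Rescue scans: improvement classification, knockout and flux-increase."""

import pytest

from dopaflux.compare import load_csf_table, load_printed_rescue
from dopaflux.efba import solve_entropic_fba
from dopaflux.rescue import (
    RescueConfig,
    classify_improvement,
    increase_scan,
    inhibition_scan,
    potential_shift,
)
from dopaflux.toy import ATP_SYNTHASE_ID, LEAK_ID, ORNT_ID, STUDY_DEMANDS


@pytest.mark.parametrize("component", ["synaptic", "nonsynaptic"])
def test_improvement_classifier_reproduces_printed_calls(component):
    """All published Yes/No improvement calls follow from the flux triples."""
    table = load_printed_rescue(component)
    for rec in table.itertuples(index=False):
        got = classify_improvement(
            rec.control_flux, rec.pd_flux, rec.rescued_flux, rec.role, tol=1e-4
        )
        expected = "improved" if rec.printed_improvement == "Yes" else "not_improved"
        assert got == expected, (component, rec.reaction_id)


def test_improvement_edge_cases():
    # energy judged against the diseased baseline, not control
    assert classify_improvement(10.0, 9.0, 9.5, "energy", 1e-4) == "improved"
    assert classify_improvement(10.0, 9.0, 9.0, "energy", 1e-4) == "not_improved"
    # exchange overshoot past control still counts
    assert classify_improvement(-16.6588, -16.6238, -17.5047, "exchange", 1e-4) == "improved"
    # unchanged rescued flux is no improvement
    assert classify_improvement(0.3131, 0.2876, 0.2876, "exchange", 1e-4) == "not_improved"
    with pytest.raises(ValueError):
        classify_improvement(1.0, 1.0, 1.0, "unknown", 1e-4)


@pytest.fixture(scope="module")
def csf_entries():
    return load_csf_table()


def _config(mode, demands, entries, **kw):
    return RescueConfig(
        mode=mode, demand_grid=demands, exchange_entries=entries,
        penalty_weight=1000.0, **kw,
    )


def test_empty_reaction_list_gives_empty_result(variants, csf_entries):
    cfg = _config("inhibit", (10.62,), csf_entries)
    assert inhibition_scan(
        variants["synaptic_pd"], variants["synaptic_control"], cfg, reactions=[]
    ) == []


def test_knockout_of_atp_synthase_is_never_a_rescue(variants, csf_entries):
    cfg = _config("inhibit", (STUDY_DEMANDS["knockout_rescue"]["synaptic"],), csf_entries)
    (res,) = inhibition_scan(
        variants["synaptic_pd"], variants["synaptic_control"], cfg,
        reactions=[ATP_SYNTHASE_ID],
    )
    assert not any(res.energy_improved.values())
    assert not res.overall


def test_knockout_of_proton_leak_rescues_energy(variants, csf_entries):
    """Removing the futile proton drain restores ATP-synthase and glycolytic
    fluxes to near-control levels at the demand where the PD proton-motive
    capacity binds."""
    for component in ("synaptic", "nonsynaptic"):
        d = STUDY_DEMANDS["knockout_rescue"][component]
        cfg = _config("inhibit", (d,), csf_entries)
        (res,) = inhibition_scan(
            variants[f"{component}_pd"], variants[f"{component}_control"], cfg,
            reactions=[LEAK_ID],
        )
        assert res.statuses[d] == "optimal", component
        assert res.energy_improved[d], component


def test_knockout_scan_order_independence(variants, csf_entries):
    cfg = _config("inhibit", (10.62,), csf_entries)
    pd_m, ctrl = variants["nonsynaptic_pd"], variants["nonsynaptic_control"]
    a = inhibition_scan(pd_m, ctrl, cfg, reactions=["PGK", "PYK"])
    b = inhibition_scan(pd_m, ctrl, cfg, reactions=["PYK", "PGK"])
    by_id_a = {r.reaction_id: r for r in a}
    by_id_b = {r.reaction_id: r for r in b}
    for rid in ("PGK", "PYK"):
        assert by_id_a[rid].atps_flux[10.62] == pytest.approx(
            by_id_b[rid].atps_flux[10.62], abs=1e-5
        )


def test_increase_factor_one_is_identity(variants, csf_entries):
    cfg = _config("increase", (10.62,), csf_entries, increase_factor=1.0)
    (res,) = increase_scan(
        variants["nonsynaptic_pd"], variants["nonsynaptic_control"], cfg,
        reactions=[ORNT_ID],
    )
    mm = variants["nonsynaptic_pd"].copy()
    mm.reaction(mm.atpm_id).lower_bound = 10.62
    base = solve_entropic_fba(mm)
    assert res.atps_flux[10.62] == pytest.approx(base.fluxes[ATP_SYNTHASE_ID])
    for rid, w in res.rescued_exchanges.items():
        assert w == pytest.approx(base.w[rid])


def test_zero_baseline_reactions_skipped(variants, csf_entries):
    cfg = _config("increase", (10.62,), csf_entries)
    (res,) = increase_scan(
        variants["nonsynaptic_pd"], variants["nonsynaptic_control"], cfg,
        reactions=["PCm"],  # anaplerosis carries no net flux at baseline
    )
    assert res.skipped_reason == "zero baseline flux"
    assert not res.overall


def test_increase_scan_does_not_mutate_models(variants, csf_entries):
    pd_m = variants["nonsynaptic_pd"]
    before = {r.id: (r.lower_bound, r.upper_bound) for r in pd_m.reactions}
    cfg = _config("increase", (10.62,), csf_entries)
    increase_scan(pd_m, variants["nonsynaptic_control"], cfg, reactions=["PGK"])
    after = {r.id: (r.lower_bound, r.upper_bound) for r in pd_m.reactions}
    assert before == after


def test_ornithine_transaminase_increase_raises_atps_and_urea(variants, csf_entries):
    """The designed rescue: forcing the ornithine transaminase analog 1.1x
    raises both ATP-synthase flux and urea excretion on both PD variants,
    moving urea toward its control value."""
    for component in ("synaptic", "nonsynaptic"):
        pd_m = variants[f"{component}_pd"]
        ctrl = variants[f"{component}_control"]
        cfg = _config("increase", STUDY_DEMANDS["increase_rescue"], csf_entries)
        (res,) = increase_scan(pd_m, ctrl, cfg, reactions=[ORNT_ID])
        primary = cfg.demand_grid[0]
        assert res.statuses[primary] == "optimal", component
        mm = pd_m.copy()
        mm.reaction(mm.atpm_id).lower_bound = primary
        base = solve_entropic_fba(mm)
        mc = ctrl.copy()
        mc.reaction(mc.atpm_id).lower_bound = primary
        cbase = solve_entropic_fba(mc)
        # ATP synthase rises
        assert res.atps_flux[primary] > base.fluxes[ATP_SYNTHASE_ID] + cfg.energy_tol
        # urea excretion rises toward the control value
        du = res.rescued_exchanges["EX_urea[e]"] - base.w["EX_urea[e]"]
        assert du > cfg.exchange_tol, component
        assert cbase.w["EX_urea[e]"] > base.w["EX_urea[e]"], component
        assert res.exchange_calls["EX_urea[e]"] == "improved", component


def test_potential_shift_basics(min_demand_solutions):
    _, sol = min_demand_solutions["nonsynaptic_pd"]
    assert all(v == 0.0 for v in potential_shift(sol, sol).values())
    subset = potential_shift(sol, sol, ["atp[c]", "adp[c]", "nadh[m]"])
    assert len(subset) == 3


def test_potential_shift_on_knockout(variants):
    model = variants["nonsynaptic_pd"].copy()
    model.reaction(model.atpm_id).lower_bound = 10.62
    base = solve_entropic_fba(model)
    ko = model.copy()
    r = ko.reaction("LDH_L")  # remove the lactate sink for pyruvate
    r.lower_bound = r.upper_bound = 0.0
    pert = solve_entropic_fba(ko)
    assert pert.status == "optimal"
    shifts = potential_shift(base, pert)
    assert abs(shifts["pyr[c]"]) > 1e-6  # the substrate's potential moves
    assert shifts["pyr[c]"] == pytest.approx(
        pert.y_N["pyr[c]"] - base.y_N["pyr[c]"]
    )


def test_potential_shift_rejects_mismatched_metabolomes(min_demand_solutions):
    _, syn = min_demand_solutions["synaptic_pd"]
    _, nonsyn = min_demand_solutions["nonsynaptic_pd"]
    with pytest.raises(ValueError, match="differ"):
        potential_shift(syn, nonsyn)
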
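"""Exchange-change classification and CSF consistency calls, including the
full reproduction of the published control/PD comparison columns."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dopaflux.compare import (
    CsfDirectionEntry,
    build_comparison_table,
    classify_exchange_change,
    consistency_call,
    load_csf_table,
    load_printed_fluxes,
)

LABEL_TO_CLASS = {
    "Lower uptake": "lower_uptake",
    "Higher uptake": "higher_uptake",
    "Lower excrete": "lower_excretion",
    "Higher excrete": "higher_excretion",
    "Same": "same",
    "No excrete": "same",  # zero-flux in both conditions
}
CONSISTENCY = {"Yes": "consistent", "No": "inconsistent", "-": "not_evaluable"}


@pytest.mark.parametrize(
    "control,pd,expected",
    [
        (-1.8909, -1.2779, "lower_uptake"),
        (-6.3213, -7.2753, "higher_uptake"),
        (0.2291, 0.1597, "lower_excretion"),
        (-0.8357, -0.8357, "same"),
        (0.1, 0.5, "higher_excretion"),
        (-0.5, 0.5, "sign_change"),
        (0.0, 0.0, "same"),
    ],
)
def test_change_classification(control, pd, expected):
    assert classify_exchange_change(control, pd) == expected


@pytest.mark.parametrize(
    "change,directions,expected",
    [
        ("lower_uptake", {"increased"}, "consistent"),
        ("higher_uptake", {"increased"}, "inconsistent"),
        ("lower_uptake", {"increased", "decreased"}, "consistent"),
        ("lower_excretion", {"decreased"}, "consistent"),
        ("higher_excretion", {"decreased"}, "inconsistent"),
        ("same", {"increased"}, "not_evaluable"),
        ("sign_change", {"increased"}, "consistent"),
        ("sign_change", {"decreased"}, "consistent"),
    ],
)
def test_consistency_rules(change, directions, expected):
    assert consistency_call(change, directions) == expected


finite = st.floats(min_value=-100, max_value=100, allow_nan=False)


@given(control=finite, pd=finite)
def test_classifier_antisymmetry(control, pd):
    """Swapping the conditions swaps uptake/excretion direction classes and
    flips every consistency call for single-direction entries."""
    fwd = classify_exchange_change(control, pd)
    rev = classify_exchange_change(pd, control)
    swap = {
        "lower_uptake": "higher_uptake",
        "higher_uptake": "lower_uptake",
        "lower_excretion": "higher_excretion",
        "higher_excretion": "lower_excretion",
        "same": "same",
        "sign_change": "sign_change",
    }
    assert rev == swap[fwd]
    if fwd not in ("same", "sign_change"):
        for direction in ("increased", "decreased"):
            a = consistency_call(fwd, {direction})
            b = consistency_call(rev, {direction})
            assert {a, b} == {"consistent", "inconsistent"}


@pytest.mark.parametrize("component,n_yes", [("synaptic", 6), ("nonsynaptic", 6)])
def test_published_flux_pairs_reproduce_printed_columns(component, n_yes):
    """The classifier + consistency rule reproduce the published change and
    consistency columns for all 17 exchange reactions per component."""
    printed = load_printed_fluxes(component)
    directions = {e.reaction_id: e for e in load_csf_table()}
    yes = 0
    for rec in printed.itertuples(index=False):
        entry = directions[rec.reaction_id]
        change = classify_exchange_change(rec.control_flux, rec.pd_flux)
        assert change == LABEL_TO_CLASS[rec.printed_change], rec.reaction_id
        call = consistency_call(change, entry.directions)
        assert call == CONSISTENCY[rec.printed_consistency], rec.reaction_id
        yes += call == "consistent"
    assert yes == n_yes


def test_nonsynaptic_consistent_set_matches_publication():
    printed = load_printed_fluxes("nonsynaptic")
    directions = {e.reaction_id: e for e in load_csf_table()}
    consistent = set()
    for rec in printed.itertuples(index=False):
        change = classify_exchange_change(rec.control_flux, rec.pd_flux)
        if consistency_call(change, directions[rec.reaction_id].directions) == "consistent":
            consistent.add(rec.reaction_id)
    assert consistent == {
        "EX_glc_D[e]", "EX_gln_L[e]", "EX_lys_L[e]", "EX_his_L[e]",
        "EX_glyc_R[e]", "EX_lac_L[e]",
    }


def test_comparison_table_from_printed_fluxes():
    printed = load_printed_fluxes("synaptic")
    entries = load_csf_table()
    control = dict(zip(printed.reaction_id, printed.control_flux))
    pdflux = dict(zip(printed.reaction_id, printed.pd_flux))
    rows, missing = build_comparison_table(control, pdflux, entries)
    assert len(rows) == 17
    assert not missing
    by_id = {r.entry.reaction_id: r for r in rows}
    assert by_id["EX_urea[e]"].printed_change == "Lower excrete"
    assert by_id["EX_trp_L[e]"].printed_change == "Same"
    # same <=> not evaluable (invariant)
    for r in rows:
        assert (r.change_class == "same") == (r.consistency == "not_evaluable")


def test_zero_flux_pair_prints_no_excrete():
    printed = load_printed_fluxes("nonsynaptic")
    entries = load_csf_table()
    control = dict(zip(printed.reaction_id, printed.control_flux))
    pdflux = dict(zip(printed.reaction_id, printed.pd_flux))
    rows, _ = build_comparison_table(control, pdflux, entries)
    dopa = next(r for r in rows if r.entry.reaction_id == "EX_dopa[e]")
    assert dopa.change_class == "same"
    assert dopa.printed_change == "No excrete"
    assert dopa.consistency == "not_evaluable"


def test_missing_reactions_listed_separately(min_demand_solutions):
    _, sol_c = min_demand_solutions["nonsynaptic_control"]
    _, sol_p = min_demand_solutions["nonsynaptic_pd"]
    rows, missing = build_comparison_table(sol_c, sol_p, load_csf_table())
    # dopamine is absent from the non-synaptic models
    assert "EX_dopa[e]" in {e.reaction_id for e in missing}
    assert all(r.entry.reaction_id not in {e.reaction_id for e in missing} for r in rows)


def test_empty_csf_table_gives_empty_output():
    rows, missing = build_comparison_table({}, {}, [])
    assert rows == [] and missing == []


def test_direction_entry_validation():
    with pytest.raises(ValueError, match="nonempty"):
        CsfDirectionEntry("x", "EX_x[e]", frozenset())
    with pytest.raises(ValueError, match="unknown directions"):
        CsfDirectionEntry("x", "EX_x[e]", frozenset({"sideways"}))
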
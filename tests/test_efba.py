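"""Entropic flux solver: closed forms, KKT structure, duals, uniqueness."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from dopaflux.efba import (
    E_MINUS_2,
    EntropicObjective,
    SolverSettings,
    chemical_potentials,
    kkt_residuals,
    solve_entropic_fba,
)
from dopaflux.model import MetabolicModel, Metabolite, Reaction

CLOSED_FORM_VF = (1.0 + math.sqrt(1.0 + 4.0 * E_MINUS_2)) / 2.0


def single_reaction_net(net: float) -> MetabolicModel:
    mets = [Metabolite("A[c]"), Metabolite("B[c]")]
    rxns = [
        Reaction("R1", {"A[c]": -1, "B[c]": 1}, -1000, 1000, subsystem="core"),
        Reaction("EX_A", {"A[c]": -1}, -net, -net),
        Reaction("EX_B", {"B[c]": -1}, -1000, 1000),
    ]
    return MetabolicModel("single", mets, rxns, atpm_id="R1")


def chain_model() -> MetabolicModel:
    # A_ext -> A -> B -> B_ext with the uptake exchange fixed at 1
    mets = [Metabolite("A[e]"), Metabolite("A[c]"), Metabolite("B[c]")]
    rxns = [
        Reaction("T1", {"A[e]": -1, "A[c]": 1}, -1000, 1000, subsystem="core"),
        Reaction("R2", {"A[c]": -1, "B[c]": 1}, -1000, 1000, subsystem="core"),
        Reaction("EX_A", {"A[e]": -1}, -1.0, -1.0),
        Reaction("EX_B", {"B[c]": -1}, 0.0, 1000.0),
    ]
    return MetabolicModel("chain", mets, rxns, atpm_id="R2")


def test_single_reaction_closed_form():
    sol = solve_entropic_fba(single_reaction_net(1.0))
    assert sol.status == "optimal"
    assert sol.vf["R1"] == pytest.approx(CLOSED_FORM_VF, abs=1e-6)
    assert sol.vr["R1"] == pytest.approx(CLOSED_FORM_VF - 1.0, abs=1e-6)
    assert sol.vf["R1"] * sol.vr["R1"] == pytest.approx(E_MINUS_2, abs=1e-8)


def test_zero_net_flux_is_symmetric():
    sol = solve_entropic_fba(single_reaction_net(0.0))
    assert sol.status == "optimal"
    assert sol.vf["R1"] == pytest.approx(math.exp(-1.0), abs=1e-6)
    assert sol.vr["R1"] == pytest.approx(math.exp(-1.0), abs=1e-6)


def test_two_reaction_chain():
    sol = solve_entropic_fba(chain_model())
    assert sol.status == "optimal"
    for rid in ("T1", "R2"):
        assert sol.vf[rid] == pytest.approx(CLOSED_FORM_VF, abs=1e-4)
    report = kkt_residuals(chain_model(), EntropicObjective(), sol)
    assert report.primal <= 1e-8


def test_product_law_independent_of_entropy_weight():
    # vf*vr = e^-2 follows from summing the two stationarity conditions and
    # holds for any positive g
    sol = solve_entropic_fba(single_reaction_net(2.5), EntropicObjective(g=7.0))
    assert sol.vf["R1"] * sol.vr["R1"] == pytest.approx(E_MINUS_2, abs=1e-7)


def test_stationarity_identity_links_duals_and_flux_ratio():
    model = single_reaction_net(1.0)
    obj = EntropicObjective()
    sol = solve_entropic_fba(model, obj)
    y = chemical_potentials(sol)
    nty = y["B[c]"] - y["A[c]"]  # N^T y for column (-1, +1)
    assert 2.0 * math.log(sol.vf["R1"] / sol.vr["R1"]) == pytest.approx(
        2.0 * nty, abs=1e-6
    )


def test_chemical_potential_lookup():
    sol = solve_entropic_fba(single_reaction_net(1.0))
    assert set(chemical_potentials(sol)) == {"A[c]", "B[c]"}
    one = chemical_potentials(sol, ["A[c]"])
    again = chemical_potentials(sol, ["A[c]"])
    assert one == again
    with pytest.raises(KeyError):
        chemical_potentials(sol, ["nope[c]"])


def test_kkt_residuals_flag_perturbed_solution():
    model = single_reaction_net(1.0)
    obj = EntropicObjective()
    sol = solve_entropic_fba(model, obj)
    clean = kkt_residuals(model, obj, sol)
    assert clean.max_residual <= 1e-6
    sol.vf["R1"] += 0.1
    dirty = kkt_residuals(model, obj, sol)
    assert dirty.stationarity > 1e-3


def _brute_force(model, objective=None):
    """Independent oracle: SLSQP over the split-flux variables."""
    from dopaflux.efba import _Problem

    prob = _Problem(model, objective or EntropicObjective())
    ni, ne = prob.ni, prob.ne

    def f(x):
        return prob.objective_value(x)

    cons = []
    if prob.A.shape[0]:
        cons.append({"type": "eq", "fun": lambda x: prob.A @ x - prob.beq})
    if prob.G.shape[0]:
        cons.append({"type": "ineq", "fun": lambda x: prob.q - prob.G @ x})
    best = None
    for start in (0.3, 1.0, 2.0):
        x0 = np.concatenate(
            [np.full(2 * ni, start), np.zeros(ne)]
        )
        res = minimize(
            f, x0, jac=prob.gradient, constraints=cons,
            bounds=[(1e-9, None)] * (2 * ni) + [(None, None)] * ne,
            method="SLSQP", options={"maxiter": 600, "ftol": 1e-14},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    assert best is not None, "oracle failed to converge"
    return best.x, prob


@pytest.mark.parametrize("builder", [
    lambda: single_reaction_net(1.0),
    lambda: single_reaction_net(0.0),
    chain_model,
])
def test_agreement_with_brute_force_minimization(builder):
    model = builder()
    sol = solve_entropic_fba(model)
    x, prob = _brute_force(model)
    vf = dict(zip(prob.internal_ids, x[: prob.ni]))
    vr = dict(zip(prob.internal_ids, x[prob.ni : 2 * prob.ni]))
    for rid in prob.internal_ids:
        assert sol.vf[rid] == pytest.approx(vf[rid], abs=1e-4)
        assert sol.vr[rid] == pytest.approx(vr[rid], abs=1e-4)


def test_uniqueness_across_starting_points(variants):
    model = variants["nonsynaptic_control"].copy()
    model.reaction(model.atpm_id).lower_bound = 10.62
    a = solve_entropic_fba(model, settings=SolverSettings(init_unidirectional=1.0))
    b = solve_entropic_fba(model, settings=SolverSettings(init_unidirectional=0.25))
    assert a.status == b.status == "optimal"
    for rid in a.vf:
        assert a.vf[rid] == pytest.approx(b.vf[rid], abs=1e-5)
        assert a.vr[rid] == pytest.approx(b.vr[rid], abs=1e-5)


def test_toy_solutions_satisfy_interior_product_law(min_demand_solutions):
    for key, (model, sol) in min_demand_solutions.items():
        assert sol.status == "optimal", key
        for rid in sol.vf:
            assert sol.vf[rid] * sol.vr[rid] == pytest.approx(
                E_MINUS_2, abs=1e-5
            ), (key, rid)


def test_toy_solutions_mass_balance_and_kkt(min_demand_solutions):
    for key, (model, sol) in min_demand_solutions.items():
        report = kkt_residuals(model, EntropicObjective(), sol)
        wmax = max(abs(v) for v in sol.w.values())
        assert report.primal <= 1e-6 * max(1.0, wmax), key
        assert report.max_residual <= 1e-6, key


def test_quadratic_penalty_pulls_flux_toward_target():
    # increasing a diagonal H entry never increases |v - h|
    model = single_reaction_net(0.0)
    model.reaction("EX_A").lower_bound = -5.0
    model.reaction("EX_A").upper_bound = 0.0
    gaps = []
    for weight in (0.0, 1.0, 10.0, 100.0):
        obj = EntropicObjective(h={"R1": 2.0}, H={"R1": weight})
        sol = solve_entropic_fba(model, obj)
        assert sol.status == "optimal"
        gaps.append(abs(sol.v["R1"] - 2.0))
    assert all(g2 <= g1 + 1e-9 for g1, g2 in zip(gaps, gaps[1:]))


def test_infeasible_model_reports_binding_bounds():
    model = single_reaction_net(1.0)
    model.reaction("R1").upper_bound = 0.5  # cannot carry the forced net flux
    model.reaction("R1").lower_bound = 0.0
    sol = solve_entropic_fba(model)
    assert sol.status == "infeasible"
    assert sol.infeasibility_hint  # names the forced bounds


def test_objective_requires_target_with_penalty():
    with pytest.raises(ValueError, match="no target"):
        EntropicObjective(H={"R1": 1.0}).validate()
    with pytest.raises(ValueError, match="positive"):
        EntropicObjective(g=0.0).validate()
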
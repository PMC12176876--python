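"""Entropic flux balance analysis.

Solves the strictly convex flux-entropy program

    min_{vf,vr,w}  g∘vf·log(vf) + g∘vr·log(vr) + ce·w + ½(v−h)ᵀH(v−h)
    s.t.           N(vf−vr) + Bw = b          : y_N
                   C(vf−vr) ≤ d               : y_C
                   l ≤ [vf−vr; w] ≤ u         : z_v
                   vf, vr ≥ 0                 : z_vf, z_vr

where every internal reaction is split into nonnegative forward/reverse
components and v = vf − vr is the net flux.  The x·log x terms make the
problem strictly convex in (vf, vr): the optimum is unique and the
unidirectional fluxes are strictly positive (the entropy gradient diverges at
zero, so the nonnegativity constraints are never active and z_vf = z_vr = 0).

The dual variable y_N of the mass-balance equality prices each metabolite's
steady state and is the model analog of a chemical potential.  The sign
convention is fixed by the Lagrangian

    L = f(x) − y_Nᵀ(Nv + Bw − b) + y_Cᵀ(Cv − d) + bound terms,

so for an internal reaction with inactive box and coupling constraints the
stationarity conditions give g·log(vf/vr) = 2·(Nᵀ y_N) and, summed,
vf·vr = e⁻² independently of g.

The solver is a dense primal-dual interior-point method (infeasible start,
fraction-to-boundary steps, regularized Newton/KKT linear algebra).  Dense
factorization is appropriate at the network sizes this package targets
(tens of reactions); every accepted solution is re-verified through
:func:`kkt_residuals`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, assemble_matrices

E_MINUS_2 = math.exp(-2.0)


@dataclass
class EntropicObjective:
    """Objective weights, keyed by reaction id.

    ``g`` is the entropy weight for internal reactions (scalar default 2).
    ``ce`` are linear coefficients on exchange fluxes.  ``h``/``H`` define an
    optional diagonal quadratic penalty ½·H·(flux − h)² on net internal or
    exchange fluxes; wherever H > 0 a target h must be given.
    """

    g: float | dict[str, float] = 2.0
    ce: dict[str, float] = field(default_factory=dict)
    h: dict[str, float] = field(default_factory=dict)
    H: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if isinstance(self.g, dict):
            bad = [k for k, v in self.g.items() if v <= 0]
        else:
            bad = [] if self.g > 0 else ["g"]
        if bad:
            raise ValueError(f"entropy weights must be strictly positive: {bad}")
        for k, v in self.H.items():
            if v < 0:
                raise ValueError(f"quadratic weight H[{k!r}] must be nonnegative")
            if v > 0 and k not in self.h:
                raise ValueError(f"H[{k!r}] > 0 but no target h[{k!r}] given")

    def g_for(self, rxn_id: str) -> float:
        if isinstance(self.g, dict):
            return float(self.g.get(rxn_id, 2.0))
        return float(self.g)


@dataclass
class SolverSettings:
    feasibility_tol: float = 1e-8
    stationarity_tol: float = 1e-6
    complementarity_tol: float = 1e-9
    max_iter: int = 400
    sigma: float = 0.15
    boundary_frac: float = 0.995
    init_unidirectional: float = 1.0  # starting vf=vr value; vary to probe uniqueness


@dataclass
class EntropicSolution:
    status: str  # optimal | infeasible | numerical_failure
    objective_value: float | None = None
    vf: dict[str, float] = field(default_factory=dict)
    vr: dict[str, float] = field(default_factory=dict)
    v: dict[str, float] = field(default_factory=dict)
    w: dict[str, float] = field(default_factory=dict)
    y_N: dict[str, float] = field(default_factory=dict)
    y_C: list[float] = field(default_factory=list)
    z_v: dict[str, float] = field(default_factory=dict)
    z_vf: dict[str, float] = field(default_factory=dict)
    z_vr: dict[str, float] = field(default_factory=dict)
    iterations: int = 0
    mu: float = float("nan")
    infeasibility_hint: list[str] = field(default_factory=list)

    @property
    def fluxes(self) -> dict[str, float]:
        """Net flux for every reaction (internal net plus exchange)."""
        out = dict(self.v)
        out.update(self.w)
        return out


@dataclass
class KktReport:
    stationarity: float
    primal: float
    complementarity: float
    worst_reaction: str
    worst_metabolite: str

    @property
    def max_residual(self) -> float:
        return max(self.stationarity, self.primal, self.complementarity)


class _Problem:
    """Dense problem data for the split-flux formulation."""

    def __init__(self, model: MetabolicModel, objective: EntropicObjective):
        objective.validate()
        mats = assemble_matrices(model)
        self.mats = mats
        self.internal_ids = mats.internal_ids
        self.exchange_ids = mats.exchange_ids
        self.met_ids = mats.metabolite_ids
        ni, ne = len(self.internal_ids), len(self.exchange_ids)
        self.ni, self.ne = ni, ne
        self.nx = 2 * ni + ne
        self.N = mats.N.toarray()
        self.B = mats.B.toarray()
        self.C = mats.C.toarray()
        self.d = mats.d
        self.b = mats.b

        self.g = np.array([objective.g_for(r) for r in self.internal_ids])
        self.ce = np.array([objective.ce.get(r, 0.0) for r in self.exchange_ids])
        self.Hv = np.array([objective.H.get(r, 0.0) for r in self.internal_ids])
        self.hv = np.array([objective.h.get(r, 0.0) for r in self.internal_ids])
        self.Hw = np.array([objective.H.get(r, 0.0) for r in self.exchange_ids])
        self.hw = np.array([objective.h.get(r, 0.0) for r in self.exchange_ids])

        li, ui = mats.lb_internal, mats.ub_internal
        le, ue = mats.lb_exchange, mats.ub_exchange

        # Equalities: mass balance rows, then fixed net fluxes (l == u).
        nmb = len(self.met_ids)
        eq_rows = [np.hstack([self.N, -self.N, self.B])] if nmb else []
        beq = [self.b]
        fixed_rows, fixed_rhs = [], []
        for j in range(ni):
            if li[j] == ui[j]:
                row = np.zeros(self.nx)
                row[j] = 1.0
                row[ni + j] = -1.0
                fixed_rows.append(row)
                fixed_rhs.append(li[j])
        for k in range(ne):
            if le[k] == ue[k]:
                row = np.zeros(self.nx)
                row[2 * ni + k] = 1.0
                fixed_rows.append(row)
                fixed_rhs.append(le[k])
        if fixed_rows:
            eq_rows.append(np.vstack(fixed_rows))
            beq.append(np.asarray(fixed_rhs))
        self.A = (
            np.vstack(eq_rows) if eq_rows else np.zeros((0, self.nx))
        )
        self.beq = np.concatenate(beq) if beq else np.zeros(0)
        self.n_mass = nmb

        # Inequalities G x <= q: net-flux boxes (non-fixed, finite) + coupling.
        rows, rhs, tags = [], [], []
        for j in range(ni):
            if li[j] == ui[j]:
                continue
            if np.isfinite(ui[j]):
                row = np.zeros(self.nx)
                row[j], row[ni + j] = 1.0, -1.0
                rows.append(row)
                rhs.append(ui[j])
                tags.append(("iu", j))
            if np.isfinite(li[j]):
                row = np.zeros(self.nx)
                row[j], row[ni + j] = -1.0, 1.0
                rows.append(row)
                rhs.append(-li[j])
                tags.append(("il", j))
        for k in range(ne):
            if le[k] == ue[k]:
                continue
            if np.isfinite(ue[k]):
                row = np.zeros(self.nx)
                row[2 * ni + k] = 1.0
                rows.append(row)
                rhs.append(ue[k])
                tags.append(("eu", k))
            if np.isfinite(le[k]):
                row = np.zeros(self.nx)
                row[2 * ni + k] = -1.0
                rows.append(row)
                rhs.append(-le[k])
                tags.append(("el", k))
        for i in range(self.C.shape[0]):
            row = np.zeros(self.nx)
            row[:ni] = self.C[i]
            row[ni : 2 * ni] = -self.C[i]
            rows.append(row)
            rhs.append(self.d[i])
            tags.append(("cp", i))
        self.G = np.vstack(rows) if rows else np.zeros((0, self.nx))
        self.q = np.asarray(rhs)
        self.tags = tags

    # -- objective ----------------------------------------------------------

    def split(self, x: np.ndarray):
        ni = self.ni
        return x[:ni], x[ni : 2 * ni], x[2 * ni :]

    def objective_value(self, x: np.ndarray) -> float:
        vf, vr, w = self.split(x)
        v = vf - vr
        ent = float(np.dot(self.g, vf * np.log(vf) + vr * np.log(vr))) if self.ni else 0.0
        return (
            ent
            + float(self.ce @ w)
            + 0.5 * float(self.Hv @ (v - self.hv) ** 2)
            + 0.5 * float(self.Hw @ (w - self.hw) ** 2)
        )

    def gradient(self, x: np.ndarray) -> np.ndarray:
        vf, vr, w = self.split(x)
        v = vf - vr
        qv = self.Hv * (v - self.hv)
        return np.concatenate(
            [
                self.g * (1.0 + np.log(vf)) + qv,
                self.g * (1.0 + np.log(vr)) - qv,
                self.ce + self.Hw * (w - self.hw),
            ]
        )

    def hessian(self, x: np.ndarray) -> np.ndarray:
        vf, vr, _ = self.split(x)
        ni, ne = self.ni, self.ne
        Hm = np.zeros((self.nx, self.nx))
        if ni:
            idx = np.arange(ni)
            Hm[idx, idx] = self.g / vf + self.Hv
            Hm[ni + idx, ni + idx] = self.g / vr + self.Hv
            Hm[idx, ni + idx] = -self.Hv
            Hm[ni + idx, idx] = -self.Hv
        if ne:
            idx = 2 * ni + np.arange(ne)
            Hm[idx, idx] += self.Hw
        return Hm


def _polish(prob: _Problem, x, y, lam, s, settings: SolverSettings):
    """Active-set Newton refinement of a near-converged interior iterate.

    Constraints with λ > s are taken as active and treated as equalities;
    inactive multipliers are set to zero.  Newton's method on the resulting
    smooth KKT system converges quadratically, clearing the degenerate
    complementarity pairs an interior path cannot resolve.  Returns the
    refined (x, y, lam) or None when the guess fails to verify.
    """
    ni = prob.ni
    mI = prob.G.shape[0]
    nA = prob.A.shape[0]
    active = set(np.where(lam > s)[0]) if mI else set()
    x0, y0 = x.copy(), y.copy()
    reg = 1e-12

    for _round in range(30):
        act = np.array(sorted(active), dtype=int)
        Ga = prob.G[act] if act.size else np.zeros((0, prob.nx))
        qa = prob.q[act] if act.size else np.zeros(0)
        na = Ga.shape[0]
        x, y = x0.copy(), y0.copy()
        la = np.maximum(lam[act], 0.0) if act.size else np.zeros(0)
        converged = False
        for _ in range(40):
            grad = prob.gradient(x)
            r1 = grad - (prob.A.T @ y if nA else 0.0)
            if na:
                r1 = r1 + Ga.T @ la
            r2 = (prob.A @ x - prob.beq) if nA else np.zeros(0)
            r3 = (Ga @ x - qa) if na else np.zeros(0)
            worst = max(
                np.abs(r1).max() if r1.size else 0.0,
                np.abs(r2).max() if nA else 0.0,
                np.abs(r3).max() if na else 0.0,
            )
            if worst < 1e-11:
                converged = True
                break
            n = prob.nx + nA + na
            K = np.zeros((n, n))
            K[: prob.nx, : prob.nx] = prob.hessian(x) + reg * np.eye(prob.nx)
            if nA:
                K[: prob.nx, prob.nx : prob.nx + nA] = -prob.A.T
                K[prob.nx : prob.nx + nA, : prob.nx] = prob.A
                K[prob.nx : prob.nx + nA, prob.nx : prob.nx + nA] = -reg * np.eye(nA)
            if na:
                K[: prob.nx, prob.nx + nA :] = Ga.T
                K[prob.nx + nA :, : prob.nx] = Ga
                K[prob.nx + nA :, prob.nx + nA :] = -reg * np.eye(na)
            try:
                step = np.linalg.solve(K, -np.concatenate([r1, r2, r3]))
            except np.linalg.LinAlgError:
                return None
            if not np.all(np.isfinite(step)):
                return None
            dx = step[: prob.nx]
            alpha = 1.0
            uni = x[: 2 * ni]
            duni = dx[: 2 * ni]
            neg = duni < 0
            if neg.any():
                alpha = min(alpha, 0.9 * float(np.min(-uni[neg] / duni[neg])))
            x = x + alpha * dx
            y = y + alpha * step[prob.nx : prob.nx + nA]
            if na:
                la = la + alpha * step[prob.nx + nA :]
        if not converged:
            return None
        # refine the working set: drop negative multipliers, add violations
        changed = False
        if na and la.min() < -1e-9:
            drop = act[la < -1e-9]
            active -= set(int(i) for i in drop)
            changed = True
        if mI:
            slack = prob.q - prob.G @ x
            violated = np.where(slack < -settings.feasibility_tol)[0]
            new = set(int(i) for i in violated) - active
            if new:
                active |= new
                changed = True
        if not changed:
            lam_full = np.zeros(mI)
            if na:
                lam_full[act] = np.maximum(la, 0.0)
            s_full = (
                np.maximum(prob.q - prob.G @ x, 0.0) if mI else np.zeros(0)
            )
            return x, y, lam_full, s_full
    return None


def _verify(prob: _Problem, x, y, lam, s, settings: SolverSettings) -> bool:
    """Full KKT residual check for a refined iterate."""
    nA = prob.A.shape[0]
    mI = prob.G.shape[0]
    r_d = prob.gradient(x) - (prob.A.T @ y if nA else 0.0)
    if mI:
        r_d = r_d + prob.G.T @ lam
    pri = max(
        float(np.abs(prob.A @ x - prob.beq).max()) if nA else 0.0,
        float(np.maximum(prob.G @ x - prob.q, 0.0).max()) if mI else 0.0,
    )
    comp = float(np.abs(lam * (prob.q - prob.G @ x)).max()) if mI else 0.0
    scale = 1.0 + max(
        float(np.abs(prob.beq).max()) if nA else 0.0,
        float(np.abs(prob.q).max()) if mI else 0.0,
    )
    return (
        float(np.abs(r_d).max() if r_d.size else 0.0) <= settings.stationarity_tol
        and pri <= settings.feasibility_tol * scale
        and comp <= 1e-6
    )


def _initial_point(prob: _Problem, settings: SolverSettings):
    ni, ne = prob.ni, prob.ne
    vf0 = np.full(ni, settings.init_unidirectional)
    vr0 = np.full(ni, settings.init_unidirectional)
    le, ue = prob.mats.lb_exchange, prob.mats.ub_exchange
    w0 = np.clip(0.0, le, ue)
    w0 = np.where(np.isfinite(w0), w0, 0.0)
    x = np.concatenate([vf0, vr0, w0])
    y = np.zeros(prob.A.shape[0])
    mI = prob.G.shape[0]
    lam = np.ones(mI)
    s = np.maximum(prob.q - prob.G @ x, 1.0) if mI else np.zeros(0)
    return x, y, lam, s


def _solve_ipm(prob: _Problem, settings: SolverSettings):
    x, y, lam, s = _initial_point(prob, settings)
    ni = prob.ni
    mI = prob.G.shape[0]
    nA = prob.A.shape[0]
    reg = 1e-10
    scale = 1.0 + max(
        np.abs(prob.beq).max() if nA else 0.0,
        np.abs(prob.q).max() if mI else 0.0,
    )

    import warnings

    from scipy.linalg import LinAlgWarning, lu_factor, lu_solve

    def _ratio(val, dval, frac):
        alpha = 1.0
        neg = dval < 0
        if neg.any():
            alpha = min(alpha, frac * float(np.min(-val[neg] / dval[neg])))
        return alpha

    def _step_len(xv, dxv, sv, dsv, lv, dlv, frac):
        return min(_ratio(xv, dxv, frac), _ratio(sv, dsv, frac), _ratio(lv, dlv, frac))

    stalls = 0
    stagnation = 0
    prev_mu = np.inf
    for it in range(settings.max_iter):
        grad = prob.gradient(x)
        r_d = grad - (prob.A.T @ y if nA else 0.0)
        if mI:
            r_d = r_d + prob.G.T @ lam
        r_p = (prob.A @ x - prob.beq) if nA else np.zeros(0)
        r_g = (prob.G @ x + s - prob.q) if mI else np.zeros(0)
        mu = float(lam @ s / mI) if mI else 0.0

        stat = np.abs(r_d).max() if r_d.size else 0.0
        pri = max(
            np.abs(r_p).max() if nA else 0.0,
            np.abs(r_g).max() if mI else 0.0,
        )
        if (
            stat <= settings.stationarity_tol
            and pri <= settings.feasibility_tol * scale
            and mu <= settings.complementarity_tol
        ):
            return "optimal", x, y, lam, s, it, mu

        # degenerate complementarity pairs stall the interior path with mu
        # hovering above tolerance; finish with an active-set polish
        if mu < 1e-3 and mu > 0.5 * prev_mu:
            stagnation += 1
        else:
            stagnation = 0
        prev_mu = mu
        if stagnation > 12:
            polished = _polish(prob, x, y, lam, s, settings)
            if polished is not None:
                px, py, plam, ps = polished
                return "polished", px, py, plam, ps, it, 0.0
            stagnation = -30  # retry later if polish not yet possible

        Hm = prob.hessian(x)
        base_M = Hm
        if mI:
            # clipped scaling keeps the KKT matrix numerically factorizable
            # near weakly active (degenerate) constraints
            D = np.clip(lam / s, 1e-12, 1e12)
            base_M = base_M + prob.G.T @ (D[:, None] * prob.G)

        def _newton(lu, r_c):
            rhs1 = -r_d
            if mI:
                rhs1 = rhs1 - prob.G.T @ ((-r_c + lam * r_g) / s)
            rhs = np.concatenate([rhs1, -r_p]) if nA else rhs1
            sol = lu_solve(lu, rhs)
            if not np.all(np.isfinite(sol)):
                return None
            dx = sol[: prob.nx]
            dy = sol[prob.nx :] if nA else np.zeros(0)
            if mI:
                ds = -r_g - prob.G @ dx
                dlam = (-r_c - lam * ds) / s
            else:
                ds = dlam = np.zeros(0)
            return dx, dy, ds, dlam

        # Factor the regularized KKT matrix, escalating the regularization
        # if it is numerically singular at the current iterate.
        steps = None
        cur_reg = reg
        while cur_reg <= 1e-2:
            M = base_M + cur_reg * np.eye(prob.nx)
            if nA:
                K = np.zeros((prob.nx + nA, prob.nx + nA))
                K[: prob.nx, : prob.nx] = M
                K[: prob.nx, prob.nx :] = -prob.A.T
                K[prob.nx :, : prob.nx] = prob.A
                K[prob.nx :, prob.nx :] = -cur_reg * np.eye(nA)
            else:
                K = M
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", LinAlgWarning)
                    lu = lu_factor(K)
            except Exception:
                cur_reg *= 100.0
                continue
            # Mehrotra predictor-corrector: affine step fixes the centering
            if mI:
                aff = _newton(lu, lam * s)
                if aff is None:
                    cur_reg *= 100.0
                    continue
                dx_a, dy_a, ds_a, dlam_a = aff
                a_aff = _step_len(
                    x[: 2 * ni], dx_a[: 2 * ni], s, ds_a, lam, dlam_a, 1.0
                )
                mu_aff = float((lam + a_aff * dlam_a) @ (s + a_aff * ds_a) / mI)
                sigma = min(1.0, max((mu_aff / mu) ** 3 if mu > 0 else 0.0, 1e-4))
                r_c = lam * s + dlam_a * ds_a - sigma * mu
            else:
                r_c = np.zeros(0)
            steps = _newton(lu, r_c)
            if steps is None:
                cur_reg *= 100.0
                continue
            break
        if steps is None:
            polished = _polish(prob, x, y, lam, s, settings)
            if polished is not None:
                px, py, plam, ps = polished
                return "polished", px, py, plam, ps, it, 0.0
            return "numerical_failure", x, y, lam, s, it, mu
        dx, dy, ds, dlam = steps
        # separate primal/dual step lengths help past weakly active bounds
        a_pri = min(
            _ratio(x[: 2 * ni], dx[: 2 * ni], settings.boundary_frac),
            _ratio(s, ds, settings.boundary_frac),
        )
        a_dual = _ratio(lam, dlam, settings.boundary_frac)
        if min(a_pri, a_dual) < 1e-3:
            stalls += 1
            if stalls > 40:
                polished = _polish(prob, x, y, lam, s, settings)
                if polished is not None:
                    px, py, plam, ps = polished
                    return "polished", px, py, plam, ps, it, 0.0
                return "numerical_failure", x, y, lam, s, it, mu
        else:
            stalls = 0
        if min(a_pri, a_dual) < 1e-14:
            return "numerical_failure", x, y, lam, s, it, mu
        x = x + a_pri * dx
        # clamp unidirectional fluxes: vf·vr = e⁻² at any optimum, so values
        # this small are never optimal and only destabilize the log terms
        if ni:
            x[: 2 * ni] = np.maximum(x[: 2 * ni], 1e-12)
        y = y + a_dual * dy
        lam = np.maximum(lam + a_dual * dlam, 1e-30)
        s = np.maximum(s + a_pri * ds, 1e-30)

    polished = _polish(prob, x, y, lam, s, settings)
    if polished is not None:
        px, py, plam, ps = polished
        return "polished", px, py, plam, ps, settings.max_iter, 0.0
    return "numerical_failure", x, y, lam, s, settings.max_iter, mu


def solve_entropic_fba(
    model: MetabolicModel,
    objective: EntropicObjective | None = None,
    settings: SolverSettings | None = None,
) -> EntropicSolution:
    """Solve the entropic flux program for ``model``.

    Returns a solution with status ``optimal``, ``infeasible`` (with a hint
    listing forced-flux bounds) or ``numerical_failure`` — never silently
    wrong numbers: optimal solutions satisfy the KKT residual tolerances in
    ``settings``.
    """
    objective = objective or EntropicObjective()
    settings = settings or SolverSettings()
    prob = _Problem(model, objective)

    def _attempt(run_settings):
        status, x, y, lam, s, iters, mu = _solve_ipm(prob, run_settings)
        if status == "numerical_failure":
            # final chance: active-set refinement of the failed iterate
            polished = _polish(prob, x, y, lam, s, run_settings)
            if polished is not None:
                x, y, lam, s = polished
                status = "polished"
        if status == "polished":
            status = (
                "optimal"
                if _verify(prob, x, y, lam, s, run_settings)
                else "numerical_failure"
            )
        return status, x, y, lam, s, iters, mu

    status, x, y, lam, s, iters, mu = _attempt(settings)
    if status != "optimal":
        # restart from alternative interior points; the strictly convex
        # problem has one optimum, so any converged run is the answer
        import dataclasses

        for init in (0.5, 2.0, 0.137, 4.0, 0.71, 1.31):
            alt = dataclasses.replace(
                settings, init_unidirectional=init, max_iter=800
            )
            status, x, y, lam, s, iters, mu = _attempt(alt)
            if status == "optimal":
                break
    if status != "optimal":
        from .lp import binding_bounds, is_feasible

        if not is_feasible(model):
            return EntropicSolution(
                status="infeasible",
                iterations=iters,
                infeasibility_hint=binding_bounds(model),
            )
        return EntropicSolution(status="numerical_failure", iterations=iters, mu=mu)

    ni, ne = prob.ni, prob.ne
    vf, vr, w = prob.split(x)
    y_N = dict(zip(prob.met_ids, map(float, y[: prob.n_mass])))

    # net-flux bound duals per reaction: z = lam_upper - lam_lower; coupling duals
    z_int = np.zeros(ni)
    z_exc = np.zeros(ne)
    y_C = np.zeros(prob.C.shape[0])
    for (tag, idx), lam_i in zip(prob.tags, lam):
        if tag == "iu":
            z_int[idx] += lam_i
        elif tag == "il":
            z_int[idx] -= lam_i
        elif tag == "eu":
            z_exc[idx] += lam_i
        elif tag == "el":
            z_exc[idx] -= lam_i
        else:
            y_C[idx] = lam_i
    # fold duals of fixed-flux equality rows into z as well
    fixed_duals = y[prob.n_mass :]
    pos = 0
    li, ui = prob.mats.lb_internal, prob.mats.ub_internal
    le, ue = prob.mats.lb_exchange, prob.mats.ub_exchange
    for j in range(ni):
        if li[j] == ui[j]:
            z_int[j] -= fixed_duals[pos]
            pos += 1
    for k in range(ne):
        if le[k] == ue[k]:
            z_exc[k] -= fixed_duals[pos]
            pos += 1

    z_v = dict(zip(prob.internal_ids, map(float, z_int)))
    z_v.update(zip(prob.exchange_ids, map(float, z_exc)))
    return EntropicSolution(
        status="optimal",
        objective_value=prob.objective_value(x),
        vf=dict(zip(prob.internal_ids, map(float, vf))),
        vr=dict(zip(prob.internal_ids, map(float, vr))),
        v=dict(zip(prob.internal_ids, map(float, vf - vr))),
        w=dict(zip(prob.exchange_ids, map(float, w))),
        y_N=y_N,
        y_C=list(map(float, y_C)),
        z_v=z_v,
        z_vf={r: 0.0 for r in prob.internal_ids},
        z_vr={r: 0.0 for r in prob.internal_ids},
        iterations=iters,
        mu=mu,
    )


def kkt_residuals(
    model: MetabolicModel,
    objective: EntropicObjective,
    solution: EntropicSolution,
) -> KktReport:
    """Independently evaluate KKT residual blocks for an optimal solution.

    Stationarity is checked on the split-flux gradient including duals; primal
    feasibility on mass balance, couplings and boxes; complementarity on
    box/coupling multipliers times slacks.
    """
    if solution.status != "optimal":
        raise ValueError("KKT residuals are defined for optimal solutions only")
    prob = _Problem(model, objective)
    ni, ne = prob.ni, prob.ne
    vf = np.array([solution.vf[r] for r in prob.internal_ids])
    vr = np.array([solution.vr[r] for r in prob.internal_ids])
    w = np.array([solution.w[r] for r in prob.exchange_ids])
    v = vf - vr
    yN = np.array([solution.y_N[m] for m in prob.met_ids])
    yC = np.asarray(solution.y_C)
    z_int = np.array([solution.z_v[r] for r in prob.internal_ids])
    z_exc = np.array([solution.z_v[r] for r in prob.exchange_ids])

    qv = prob.Hv * (v - prob.hv)
    NtY = prob.N.T @ yN
    CtY = prob.C.T @ yC if prob.C.shape[0] else np.zeros(ni)
    stat_f = prob.g * (1.0 + np.log(vf)) + qv - NtY + CtY + z_int if ni else np.zeros(0)
    stat_r = prob.g * (1.0 + np.log(vr)) - qv + NtY - CtY - z_int if ni else np.zeros(0)
    stat_w = prob.ce + prob.Hw * (w - prob.hw) - prob.B.T @ yN + z_exc if ne else np.zeros(0)

    mb = prob.N @ v + prob.B @ w - prob.b if prob.met_ids else np.zeros(0)
    li, ui = prob.mats.lb_internal, prob.mats.ub_internal
    le, ue = prob.mats.lb_exchange, prob.mats.ub_exchange
    box = np.concatenate(
        [
            np.maximum(v - ui, 0.0),
            np.maximum(li - v, 0.0),
            np.maximum(w - ue, 0.0),
            np.maximum(le - w, 0.0),
        ]
    )
    box = box[np.isfinite(box)]
    coup = (
        np.maximum(prob.C @ v - prob.d, 0.0) if prob.C.shape[0] else np.zeros(0)
    )

    comp = []
    for j in range(ni):
        if li[j] == ui[j]:
            continue
        z = z_int[j]
        if np.isfinite(ui[j]) and z > 0:
            comp.append(z * (ui[j] - v[j]))
        if np.isfinite(li[j]) and z < 0:
            comp.append(-z * (v[j] - li[j]))
    for k in range(ne):
        if le[k] == ue[k]:
            continue
        z = z_exc[k]
        if np.isfinite(ue[k]) and z > 0:
            comp.append(z * (ue[k] - w[k]))
        if np.isfinite(le[k]) and z < 0:
            comp.append(-z * (w[k] - le[k]))
    for i in range(prob.C.shape[0]):
        comp.append(yC[i] * (prob.d[i] - float(prob.C[i] @ v)))

    stat_all = np.concatenate([stat_f, stat_r, stat_w])
    worst_rxn = ""
    if stat_all.size:
        ids = prob.internal_ids * 2 + prob.exchange_ids
        worst_rxn = ids[int(np.abs(stat_all).argmax())]
    worst_met = ""
    if mb.size:
        worst_met = prob.met_ids[int(np.abs(mb).argmax())]
    primal = max(
        float(np.abs(mb).max()) if mb.size else 0.0,
        float(box.max()) if box.size else 0.0,
        float(coup.max()) if coup.size else 0.0,
    )
    return KktReport(
        stationarity=float(np.abs(stat_all).max()) if stat_all.size else 0.0,
        primal=primal,
        complementarity=float(np.abs(comp).max()) if comp else 0.0,
        worst_reaction=worst_rxn,
        worst_metabolite=worst_met,
    )


def chemical_potentials(
    solution: EntropicSolution, metabolite_ids: list[str] | None = None
) -> dict[str, float]:
    """Mass-balance duals (chemical potentials) for the requested metabolites."""
    if solution.status != "optimal":
        raise ValueError("chemical potentials require an optimal solution")
    if metabolite_ids is None:
        return dict(solution.y_N)
    out = {}
    for m in metabolite_ids:
        if m not in solution.y_N:
            raise KeyError(f"unknown metabolite id {m!r}")
        out[m] = solution.y_N[m]
    return out


def flux_table(solution: EntropicSolution, model: MetabolicModel):
    """Solution as a tidy DataFrame (reaction, vf, vr, net, bounds)."""
    import pandas as pd

    rows = []
    for r in model.reactions:
        if r.id in solution.v:
            rows.append(
                {
                    "reaction": r.id,
                    "subsystem": r.subsystem,
                    "vf": solution.vf[r.id],
                    "vr": solution.vr[r.id],
                    "net_flux": solution.v[r.id],
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "kind": "internal",
                }
            )
        else:
            rows.append(
                {
                    "reaction": r.id,
                    "subsystem": r.subsystem,
                    "vf": float("nan"),
                    "vr": float("nan"),
                    "net_flux": solution.w[r.id],
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "kind": "exchange",
                }
            )
    return pd.DataFrame(rows)
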
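# Methods

## The entropic flux program

`dopaflux` predicts steady-state fluxes by minimizing a flux-entropy
objective over the split-flux polytope.  Every internal reaction — including
irreversible ones — is represented by nonnegative forward and reverse
components `vf, vr` with net flux `v = vf − vr`; irreversibility is enforced
only through the net-flux box constraints, so the formulation is uniform and
the entropy terms `g·(vf log vf + vr log vr)` apply everywhere.  Exchange
(boundary) reactions carry a single flux `w` with the community sign
convention (negative = uptake) and optional linear costs `ce`.  A diagonal
quadratic penalty `½ H (flux − h)²` can anchor any net flux to a target;
it is used by the flux-increase rescue mode to hold exchanges near a
reference state.

Assumptions: steady state (`Nv + Bw = b`, with `b = 0` unless a pool is
declared to accumulate), optional linear flux-coupling rows `Cv ≤ d`, and a
strictly positive entropy weight (`g = 2` uniformly by default).  Because
x·log x is strictly convex and its gradient diverges at zero, the optimum is
unique, the unidirectional fluxes are strictly positive, and the
nonnegativity multipliers `z_vf, z_vr` vanish identically.  Two consequences
are used as standing correctness oracles:

* summing the two stationarity conditions of any internal reaction cancels
  every linear, box, coupling and quadratic term, leaving
  `vf·vr = e⁻²` regardless of `g`;
* subtracting them gives `g·log(vf/vr) = 2·(Nᵀy_N)` at interior points,
  which ties the flux ratio to the mass-balance duals and fixes the sign
  convention of the reported chemical potentials (Lagrangian
  `f − y_Nᵀ(Nv+Bw−b) + y_Cᵀ(Cv−d) + …`).

For metabolites involved in conserved moieties (adenylate, NAD, quinone
pools) the mass-balance rows are linearly dependent and `y_N` carries the
corresponding gauge freedom; differences of potentials along reactions
(`Nᵀy_N`) are gauge-invariant and are what the analyses use.

### Solver

The program is solved by a purpose-written dense primal-dual interior-point
method: infeasible start, Mehrotra predictor–corrector centering, separate
primal/dual step lengths with fraction-to-boundary 0.995, clipped
complementarity scaling, and regularized KKT factorizations (regularization
escalated when a factorization degenerates).  Iterates of `vf, vr` are
clamped at 1e-12 — far below any optimal value, since `vf·vr = e⁻²` bounds
them away from zero — to keep the log terms stable.  Degenerate
complementarity pairs (a bound both weakly active and weakly priced) stall
any interior path; when progress stagnates the solver switches to an
active-set Newton *polish*: constraints with `λ > s` are treated as
equalities, the smooth KKT system is solved to machine precision, and the
working set is refined by dropping negative multipliers and adding violated
constraints.  A polished point is only accepted if the full KKT residuals
verify (stationarity ≤ 1e-6, feasibility ≤ 1e-8·scale, complementarity
≤ 1e-6); otherwise the solve restarts from alternative interior points and,
failing that, reports `numerical_failure` — never silently wrong numbers.
Feasibility questions (infeasible-demand detection, validity checks,
capacity analyses) go through linear programming (HiGHS), which also
provides the diagnostic hints attached to infeasible solves.

Tolerances: feasibility 1e-8, stationarity 1e-6, complementarity target
1e-9, all reported to the caller and re-checked independently by
`kkt_residuals`.

## Literature-derived constraint arithmetic

`constraints` exposes the unit bookkeeping used to parameterize neuronal
models: the wet→dry conversion of the residual ATP consumption rate
(10 μmol/g/min with 82.3% tissue water → 106.2 μmol/gDW/h), the maintenance
lower bound after the rodent-to-human arborization scaling (106.2/10 =
10.62 μmol/gDW/h; the upper bound 600 μmol/gDW/h is a configured constant),
the PD Complex I capacity factor (1 − 0.18 = 0.82 from the smallest reported
post-mortem reduction), mitochondrial protein density midpoints (5 and
1.25 mg/gWW for free and synaptosomal mitochondria) and an enzyme-activity →
flux converter.  The published wet/dry arithmetic is reproduced by
*multiplying* by the dry-mass fraction; dividing would be the physically
expected direction for a per-gDW basis, and the module documents that it
reproduces the established arithmetic rather than endorsing the direction.

## ATP accounting and scans

A reaction's net ATP production is its net flux times the summed
stoichiometric coefficients of all ATP species (any metabolite with base id
`atp`; the toy's citric-acid-cycle lump phosphorylates ADP directly,
standing in for the GTP→ATP route).  Netting is global across compartments,
so pure translocators contribute zero and are excluded from both contributor
and consumer sets; the classification threshold for "carries flux" is
1e-6 μmol/gDW/h.  Subsystem shares divide contributor flux by the total;
a model with no contributors returns an explicit undefined flag.

Energy-demand scans raise the ATPM net-flux lower bound (not an objective
coefficient) over a grid — default 10…600 step 10, with 10…100 used in
reports — and re-solve; infeasible points are flagged, never dropped.
Complex I inhibition scales the capacity bound of the reaction's active
direction by (1 − α), so α = 1 forces zero flux; the reference capacity is
the unperturbed bound, not the baseline flux, and the reported inflection is
the smallest α with a >1% drop in ATP-synthase flux (configurable).
Substrate scans tighten an exchange's uptake capacity toward zero, reducing
any forced minimum uptake to the scanned capacity so the grid's zero point
is meaningful.

## CSF comparison rules

Control→PD exchange changes are classified with an absolute tolerance of
1e-4 μmol/gDW/h ("same" at the four-decimal precision of published tables):
both fluxes ≤ 0 → lower/higher uptake by magnitude; both ≥ 0 → lower/higher
excretion; opposite strict signs → `sign_change`, a class reachable with
arbitrary models and evaluated permissively against both regimes it spans.
A metabolite increased in PD CSF is consistent with lower uptake or higher
excretion; decreased with higher uptake or lower excretion; entries with
conflicting reports carry both directions and match if any direction does.
A reaction carrying no flux in either condition is reported as
non-operating ("No excrete") in tabular output while remaining class `same`
(not evaluable) at the type level.  The packaged direction table
(`data/csf_pd_directions.tsv`) is a curated input fixture, and the packaged
control/PD flux columns reproduce the published comparison (six consistent
metabolites per component) exactly.

## Rescue analyses

**Knockout mode** zeroes one internal reaction at a time (both bounds 0) and
calls a knockout an energy rescue when ATP-synthase flux *and* summed
glycolytic net ATP reach at least (1 − 0.05) of the matched control values
at every demand in the grid.  **Increase mode** forces each internal
reaction with |baseline net flux| > 1e-6 to 1.1× that flux in its active
direction; in the forced solve the exchange bounds are relaxed to the
generic ±1000 and a quadratic penalty anchors each exchange at its baseline
flux.  The anchoring weight defaults to 100 and the packaged study runs use
1000: at toy scale a weight of 1 fails to anchor (the rescued solve simply
abandons the baseline), and a strong anchor implements the intended
semantics — exchanges move only under stoichiometric compulsion by the
forced reaction, not by soft economic drift.  With factor exactly 1.0 the
forcing is a no-op and the scan returns the baseline (degenerate shortcut).

Improvement calls: energy is improved when the rescued ATP-synthase flux
exceeds the PD baseline by more than 1e-3 μmol/gDW/h; an exchange is
improved when it moved from the PD baseline toward (or past) the control
value, with both movements above 0.01 μmol/gDW/h, and worsened when it moved
the opposite way.  This sign rule is the unique simple rule reproducing all
15 published improvement calls, including overshoot and zero-change rows.
The composite "overall rescue" — energy improvement at all feasible demands,
at least one evaluated exchange improved, none worsened — is one documented
operationalization of "improved bioenergetics and exchanges" and is exposed
through configurable predicates.  Chemical-potential shifts between a
baseline and a perturbed solution are plain differences of `y_N` and require
structurally identical metabolomes.

## The toy fixture

`toy.build_toy_model` emits a deterministic ~50-reaction network in four
variants.  Structure: lumped upper glycolysis (glucose + 2 ATP + 2 NAD →
2 triose-phosphate + 2 NADH) with phosphoglycerate kinase and pyruvate
kinase as separate ATP-producing steps and reversible lactate dehydrogenase;
a malate–aspartate-style NADH shuttle and pyruvate transport; pyruvate
carboxylase anaplerosis; a lumped citric acid cycle with one substrate-level
phosphorylation; Complex I (NADH + Q → NAD + QH₂ + 4 pmf, capacity-bounded),
lumped Complex III/IV (QH₂ + ½O₂ → Q + 6 pmf), reversible ATP synthase
(ADP + 3 pmf ↔ ATP; the reverse is the proton-pumping ATPase of
de-energized mitochondria), a constitutive proton leak with a positive lower
bound, and a reversible adenine-nucleotide translocator; an
ornithine-transaminase/urea fragment (transport-lumped ORNTArm:
2-oxoglutarate + extracellular ornithine ↔ glutamate-5-semialdehyde +
glutamate; glutamate dehydrogenase; a capacity-bounded urea-cycle lump
consuming 2 NH₄⁺ and ATP and secreting urea — the network's only nitrogen
exit; proline overflow consuming NADH; ATP-coupled glutamate export);
amino-acid degradation lumps for histidine, lysine (feeding electrons to
the quinone pool, electron-transfer-flavoprotein style), methionine and
glutamine (regenerating 2-oxoglutarate with both nitrogens as NH₄⁺, a
redox-free transamination-coupled lump); and, in synaptic variants only, a
tyrosine → dopamine branch whose vesicular release costs one ATP.  The
proton-motive force is a pseudo-metabolite lumping the H⁺ gradient; the
4/6/3 stoichiometries are round numbers giving an integer P/O-like ratio.
Elemental balance is not enforced in lumped reactions; steady-state balance
of the declared species is.

A PD variant differs from its control by exactly the disease overlay:
Complex I capacity ×0.82, dopamine-release minimum ×0.25 (synaptic only),
and glucose/oxygen minimum uptake relaxed to zero.  The synaptic Complex I
capacity (7) is below the non-synaptic one (12), encoding the lower enzyme
activities of synaptosomal mitochondria.

All capacity numbers are fixture parameters chosen so the network reproduces
the qualitative study phenomena at desk scale; they are not literature
values.  In particular the glucose capacity and lactate secretion bound are
wide enough that demands up to ~100 μmol/gDW/h stay feasible with glycolysis
absorbing growth beyond the oxidative plateau; the forced oxygen minimum
(2.0) gives the control variants a standing electron requirement; and the
forced ornithine uptake (0.3) with the urea-cycle capacity (0.32) makes the
nitrogen fragment active at baseline, with the control settling at the
capacity and the PD variant at the kink where further urea output would
require amino-acid catabolism.  That asymmetry yields the control > PD urea
ordering and lets the 1.1× ornithine-transaminase forcing raise both
ATP-synthase flux (via glutamate-dehydrogenase NADH) and urea excretion on
both PD variants.  Study demands are fixed in `STUDY_DEMANDS`: minimum
10.62, plateau pair (60, 100), share comparison 60, Complex I scans at 20,
knockout rescue at 25 (synaptic) and 40 (non-synaptic) — the demands where
the PD proton-motive capacity binds while the control's does not — and
increase rescue at (10.62, 20).

What the fixture does *not* emulate: genome-scale redundancy (~2,400
reactions), elemental/charge balance, the dense mesh of literature-derived
enzyme-activity bounds on mitochondrial reactions, and biomass turnover.
Passing tests on the fixture therefore demonstrate the machinery and the
qualitative physics (capacity-limited oxidative phosphorylation, glycolytic
compensation, nitrogen-electron coupling), not quantitative predictions for
real neurons.  One consequence is documented and accepted: at toy scale the
1.1× increase scan flags several oxidative-chain forcings (oxygen transport,
Complex I/III+IV, ATP synthase, the translocator) in addition to the
designed ornithine-transaminase analog, because with so few reactions the
diseased variant's oxidative machinery is not capacity-bound at low demand
and any forced boost both raises ATP-synthase flux and drags the nitrogen
system toward the control state.  Restricting the scan to demands where the
PD oxidative capacity binds excludes those forcings but also voids the
transaminase mechanism (its NADH cannot be oxidized at a binding Complex I
cap).  The single-reaction specificity reported for genome-scale models
depends on their dense enzyme-activity constraints; the fixture demonstrates
the mechanism, not the uniqueness.

## Numerical and design choices

* Default generic bounds ±1000 μmol/gDW/h; unspecified bounds on declared-
  irreversible reactions load as [0, 1000].
* Fixed bounds (l = u) become equality rows; their duals fold into `z_v`.
* Reactions fixed to zero net flux stay in the problem (`vf = vr` at the
  entropy optimum), preserving the product law.
* The JSON dialect is the authoritative on-disk format (bit-stable output);
  SBML export via cobrapy is interoperable but drops coupling constraints
  and the accumulation vector.
* Validity checks relax every forced-flux minimum, open one carbon source at
  a time, and maximize ATPM by LP; on the toy, the anaerobic glucose yield
  equals exactly 2 ATP per glucose at maximal uptake (the closed-form
  fermentative yield), and with all sources closed the maximum is zero.
* Median-of-ratios: genes with zero total count are removed; genes with any
  zero count are excluded from factor estimation but kept in the normalized
  output.  Gene weights are log2 of mean normalized expression with
  threshold −3 (mean ≥ 0.125); the transform is a configuration point since
  the scale on which the published threshold applies is not fixed by the
  method description.  Size factors are invariant under global rescaling;
  scaling a single sample by c moves its factor by c only relative to the
  other samples (the geometric means absorb c^(1/n)).
* The scan tables, comparison reports and rescue reports are tab-separated
  UTF-8 with stable column layouts; the pipeline bundle is byte-identical
  across reruns of the same configuration (timestamps excluded).

## Problem sizes

The packaged analyses run on the four ~50-reaction variants: demand grids of
~10 points, 11-point inhibition grids, and increase-rescue scans over ~35
internal reactions × 2 demands per component.  A full pipeline run
(`dopaflux run-all`) completes in well under a minute on one CPU; the test
suite and the acceptance script each take seconds.
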
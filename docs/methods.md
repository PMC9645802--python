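# Methods

This note documents the models, numerical choices and design decisions
behind `tetrd`, and what the shipped benchmarks do and do not demonstrate.

## Geometry

Meshes are tetrahedral, coordinates SI meters, indices 0-based. Physical
tags partition the elements: every tetrahedron carries exactly one
compartment tag; tagged surface triangles form patches (membranes). The
reader accepts the Gmsh MSH ASCII v2.2 subset ($Nodes, $Elements with
element types 2 and 4, $PhysicalNames); binary and other versions are
rejected explicitly, and a missing $PhysicalNames block produces a tagless
mesh with a warning. An optional `unit_scale` converts files authored in
other length units.

Two structured generators cover the benchmarks:

* **box** — each hexahedral cell is split into 6 tetrahedrons by the
  Kuhn/Freudenthal decomposition (all tets share the cell's main diagonal):
  deterministic, conforming across cells and strictly positive volumes.
* **cable** — a square-section prism whose side `sqrt(pi)/2 * d` matches the
  cross-sectional *area* of a cylinder of nominal diameter `d`. Because the
  cable benchmarks' analytic solutions assume cylindrical surface constants,
  the generator records `surface_ratio` = (ideal cylinder surface, lateral +
  end caps)/(actual mesh surface) ≈ 0.886, and every membrane surface
  density (capacitance, leak, channel density) is multiplied by it at
  binding/assembly time, so conductance and capacitance per unit cable
  length match the ideal cylinder exactly. The cable construction of the
  original benchmark mesh is not published; this area-matched square prism
  with density correction is this package's choice.

Partitioning emulates a distributed mesh in one process: recursive
coordinate bisection along the longest axis (rank counts restricted to
powers of 2, with deterministic index tie-breaks), ghost layers = the
face-adjacent non-owned tetrahedrons of each rank, and interior patch
triangles pinned so both adjacent tetrahedrons share an owner (surface
kinetics never straddle a rank boundary).

## Stochastic kinetics

Every reaction instance, channel-state transition and GHK crossing is a
*kinetic process* bound to one element. Propensities are standard
mass-action with the per-event coefficient `c = k_SI/(N_A V·10³ L/m³)` for
bimolecular reactions (identical-reactant pairs counted as n(n−1)/2 in the
propensity, not in `c`). Reactions above order 2 are rejected — none of the
target model class needs them.

The default operator is the next-reaction method with absolute times:

* firing process: fresh exponential draw;
* dependent process with `a_old, a_new > 0`: time rescaled,
  `t' = t + (a_old/a_new)(t_old − t)`;
* `a_new = 0`: parked at +inf; resuscitation draws fresh.

Ties break on process id, so a fixed seed fixes the event order. The queue
is an authoritative next-time array plus a lazy-deletion binary heap: heap
entries are (time, id) snapshots discarded on pop when stale. This is
observationally identical to a position-indexed heap and lets the
voltage-refresh path rescale thousands of processes vectorized and rebuild
the heap in one O(n) pass. Events drawn beyond the window end are *not*
applied and keep their queue times — exact under absolute-time NRM
semantics.

Voltage-dependent rates are frozen within an EField window and refreshed in
bulk at each window start (the refresh point is this package's documented
choice; per-event voltage lookup would contradict the frozen-voltage
operator splitting anyway). Rate functions are named built-ins (the
Hodgkin–Huxley alpha/beta forms, per-second, resting potential −65 mV),
constants, or tabulated V→rate pairs with linear interpolation; configs
cannot inject code.

A direct-method operator (fresh exponential of the total propensity,
categorical pick) shares the propensity and dependency machinery and is
used as the in-package cross-check: the two operators are distributionally
indistinguishable (two-sample Cramér–von Mises) on small models, as is the
independent-component optimization on/off.

## Diffusion

Voxel coupling `d_k = D·A_k/(V_i·h_k)` between face-adjacent tetrahedrons
of the same compartment (A = shared face area, h = barycenter distance);
boundary faces are reflective. Per window, leavers are
`Binomial(n, 1 − exp(−d_tot Δt))` split multinomially by `d_k/d_tot`. This
is exact for the single-voxel exit process but neglects within-window
re-entry: unbiased mean-field behavior requires `Δt·d_tot ≲ 0.1`. The RD
window rule `Δt_RD = min(ΔT_EField, α / max d_tot)` with α = 1 by default
follows the coarse convention of the solver family this reproduces; users
who care about tight agreement with the diffusion master equation at high
exit rates should set `alpha_rd` to 0.1 or below (the property tests do).

All moves are staged in ΔM, keyed by the destination element's owner rank,
and folded into M only at the synchronization step; each emulated rank draws
from its own RNG stream (`seed + rank`). Conservation is integer-exact per
species for any rank count, and rank count R=1 vs R=4 is distributionally
indistinguishable.

## Membrane potential

Linear FEM stiffness with conductivity 1/Ra (symmetric positive
semidefinite; constant vectors in the null space), membrane capacitance and
conductances lumped per vertex by ⅓-triangle-area weights. One backward-
Euler solve per EField window; ohmic channel currents enter implicitly
through the conductance matrix (unconditional stability), GHK currents
explicitly at the pre-step voltage. The sparse system is factorized with
SuperLU; the factorization is cached and reused while `dt` and the
conductance vector are unchanged (a passive run factorizes once; an active
run refactorizes each window). A Jacobi-preconditioned conjugate-gradient
fallback is available (`solver="cg"`).

GHK flux per open channel:
`I = P z²F²V/(RT) · (c_in − c_out e^(−zFV/RT))/(1 − e^(−zFV/RT))`, with the
V→0 singularity evaluated by series; temperature defaults to 293.15 K. The
stochastic GHK crossing used by the two-tet toy splits the same expression
into its unidirectional one-way fluxes (efflux ∝ c_in, influx ∝ c_out) as
per-ion event propensities.

Stochastic channels are multi-state chains; the Na channel has 8 states
(m0–3 × h0–1, conducting m3h1, single-channel conductance 4 pS by default,
E_Na = +50 mV), the K channel 5 states (n0–4, conducting n4, E_K = −77 mV).
Channel densities are macroscopic conductances (1200 and 360 S/m² — the
cable-benchmark standard values, which the source publication does not
reprint) divided by the single-channel conductance; per-triangle integer
counts come from largest-remainder apportionment over triangle areas (patch
totals exact, no per-triangle truncation bias), and initial state occupancy
is the stationary distribution of the chain at the initial voltage, again
largest-remainder rounded.

A mean-field gating mode replaces the per-channel jump process by the
fraction ODE `df/dt = f·Q(V)` advanced with one classical RK4 step per
EField window (at 5 µs, `dt·max-rate ≪ 1`). This is the exact
infinite-channel limit of the stochastic model and reproduces the classic
four-variable Hodgkin–Huxley ODE system within 0.8 mV through a full action
potential at the 5 µs step (0.25 mV at 1 µs — the residual is the
first-order voltage/gating operator splitting, not the gating integrator).

## Core loop and determinism

Window boundaries are computed as `t0 + k·dt` with integer `k` (no
accumulated addition); trailing partial windows are explicit, and the state
time lands exactly on `T_end`. Recording happens between `run` calls. With
a fixed (seed, rank count) a run is bit-reproducible; the manifest records
seed, ranks, schedule, mesh and model hashes, and per-rank event counts.

## Statistical validation framework

* **Analytic cable solution.** Sealed passive cable with a step current at
  x = 0: steady state `V_ss = I r_a λ cosh((L−x)/λ)/sinh(L/λ)` plus the
  cosine eigenmode transient with `τ_n = τ/(1 + (nπλ/L)²)`; the series is
  truncated when the remaining-amplitude bound at the smallest requested
  positive time drops below 1e−9 V. Cross-checked against an independent
  Crank–Nicolson finite-difference cable solver (with Rannacher startup) to
  below 1 µV.
* **Peak features.** Local maxima above a prominence/separation threshold
  (defaults 10 mV and 2 ms, sized for HH spike trains — the source
  publication does not state its own detection parameters).
* **Batched CVM.** Both sample sets are cut into batches (100 × 100 by
  default) and compared all-pairs, 10,000 p-values; batches under 20 samples
  use the exact permutation distribution. The rejection rule is
  "consistently low p": reject only when the fraction of p < 0.01 exceeds
  1% by more than three binomial standard deviations. Two caveats
  established empirically here: (i) all-pairs p-values are *correlated*
  through batch reuse, so their empirical CDF can wander further from
  uniform than independent p-values would (the uniformity property test
  therefore uses disjoint batch pairs); (ii) heavily tied integer outcomes
  distort the asymptotic tail slightly — the shipped null experiment uses a
  continuous per-run outcome (mean event time of a reversible two-species
  model).
* **Confidence bands.** `ci_band` is the pointwise one-sample Student band.
  For the mean-in-band comparison, `ci_band_compare` widens the containment
  test to the pointwise *two-sample* band: comparing one noisy mean against
  the other set's one-sample band rejects independent replicates of the
  same model at a high rate by construction (the compared mean carries the
  same order of noise as the band half-width). Up to 5% of time points may
  stray — pointwise bands give no simultaneous coverage guarantee.

## Benchmarks and problem sizes

* **Passive cable (Rallpack 1).** Table of constants: leak 0.25 S/m²,
  reversal −65 mV, Ra 1 Ω·m, 0.1 nA, L 1 mm, Cm 0.01 F/m², 5 µs EField
  step, diameter 1 µm (the cable-standard value; the source table omits it).
  The leak sits on *every* surface triangle, caps included, as in the
  benchmark being reproduced. The acceptance run uses 200 axial segments
  (1,200 tets, at least the published 1,135) for 250 ms and achieves MSE
  ≈ 0.0045 mV² (z_min) and 0.0040 mV² (z_max) against the analytic series —
  an order of magnitude below the published 0.069/0.019 mV² on the coarser
  1,135-tet mesh, consistent with the published refinement behavior (steep
  drop, then plateau).
* **Stochastic HH cable (Rallpack 3).** At the published 4 pS single-channel
  conductance the full cable carries ~10⁶ channels (~10⁹ gating events per
  250 ms run) — far beyond a desk-scale interpreted run. The shipped checks
  are (i) the deterministic-limit comparison above and (ii) a scaled run
  (single-channel conductance 1 nS ⇒ ~3,800 Na + ~1,100 K channels, 16
  axial segments, 25 ms) that propagates spikes overshooting +40 mV to the
  far end of the cable with valleys near −65 mV — the same code path at a
  smaller channel population. Full-density runs use identical code and
  remain available by passing `g_single=4e-12`.
* **Ten-species benchmark.** Species A–J, D from 100 down to 10 µm²/s,
  initial counts 1,000–10,000 (total 55,000), four reversible reactions
  with kf/kb = 1000/100, 100/10, 10/1, 1/1 in (µM·s)⁻¹ and s⁻¹, count
  scaling 0.01×–100×. The published cuboid mesh (13,009 tets) is not
  distributed; the generator's 13×13×13 µm box at 1 µm cells (13,182 tets)
  stands in at the same resolution.
* **Two-tet toy.** Three-species cycle in both tets, surface transfer
  C(tet)↔C(tri) and a stochastic GHK crossing on one triangle of tet 0.
  Rates default to 1 s⁻¹ and the GHK permeability to 1e−24 m³/s — the toy
  exercises surface chemistry, GHK flux and the dependency decomposition
  (components of sizes 7 and 3); it reproduces no published numbers.

## What the synthetic benchmarks do not show

The fixtures use idealized structured meshes with near-uniform element
quality; unstructured meshes with high aspect-ratio tetrahedrons will stress
the FEM stiffness and the voxel-coupling diffusion rates differently.
Emulated ranks reproduce the ownership/ghost/synchronization *semantics* of
a distributed run, not its timing, communication or scaling behavior — no
performance claim is made or tested. Surface diffusion (triangle-to-
triangle) is not modeled. The GHK toy treats the extracellular concentration
as a fixed bath.

## Known limitations

* Reactions are capped at order 2; channel chains must have voltage-only
  (not ligand-dependent) rates in this release.
* The diffusion window scheme is first-order in `Δt·d_tot` for mean-field
  quantities (see above).
* The mean-field gating mode and the EField step couple by first-order
  splitting; sub-millivolt agreement with a coupled ODE solution needs
  EField steps of a few microseconds.
* The direct-method operator recomputes the total propensity per event
  (O(n)); it is a correctness reference, not a performance path.
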
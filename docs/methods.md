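# Methods

## The cell network model

Tissue is a rectangular lattice of myocytes. Each cell *k* and its share of
extracellular space form one compartment of size l_x × l_y × l_z; the cell
itself is a solid of revolution (two conical frusta: radius r_end at the
intercalated discs, r_center at mid-cell). Two unknowns live on every node —
the membrane potential v^k and the extracellular potential u_e^k (the
intracellular potential is eliminated as u_i = v + u_e) — plus the membrane
state s^k. Kirchhoff's current law at the cell and at its extracellular
compartment closes the system: the capacitive + ionic membrane current
equals the net intracellular inflow, and the membrane current returns
through the extracellular network.

Assumptions: cells are isopotential (no subcellular gradients), uniform in
size, on a regular lattice; gap junctions are passive resistances; the
extracellular compartments form a resistive network of the same topology.
There is no adjustable spatial resolution — the cells *are* the mesh.

### Geometry and electrical parameters

| parameter | default | units | note |
|---|---|---|---|
| cell length l_x | 120 | μm | frustum pair, 60 μm each |
| end / center radius | 6 / 7 | μm | disc area A_g = π·6² μm² |
| extracellular margin | 2 | μm | compartment side l_y = l_z = 2·(7+2) = 18 μm |
| σ_i / σ_e | 4 / 20 | mS/cm | intra-/extracellular conductivity |
| C_m | 1 | μF/cm² | specific membrane capacitance |
| R_g | 0.0015 | kΩ·cm² | gap-junction resistance density (normal coupling) |

Derived quantities (computed, never stored): volume fractions
δ_i = V_cell/V_compartment ≈ 0.4105 and δ_e = 1 − δ_i; membrane area A_m =
lateral surface of the double frustum ≈ 4.90·10⁻⁵ cm² (end caps are
excluded — the cell ends are intercalated discs and carry junctional, not
ionic, current); disc area A_g ≈ 1.13·10⁻⁶ cm².

Edge conductances: G_e = δ_e A σ_e / l and
G_i = 1/( l/(δ_i A σ_i) + R_g/A_g ) with A the full compartment
cross-section perpendicular to the edge (l_y·l_z for longitudinal edges,
l_x·l_z for transverse) and l the center spacing (l_x, resp. l_y). With R_g
in kΩ·cm², R_g/A_g is in kΩ and adds directly to the bulk term; inverting
the sum gives mS. Transverse contacts reuse the longitudinal disc area by
default — the lateral contact area of staggered myocytes is not well
constrained; it is exposed as `transverse_disc_area` and its main effect is
a uniform scaling of transverse G_i (CV_y ∝ roughly the square root of it
at normal coupling, saturating toward junction-dominated behaviour under
uncoupling). A global `rg_multiplier` (and optional per-edge overrides)
scales R_g to model fibrotic uncoupling.

## Membrane models

The ionic interface is I_ion(v, s) in μA/cm² (positive outward) plus state
dynamics partitioned into Hodgkin–Huxley *gates* — advanced by the
Rush–Larsen exponential update s' = s_∞ + (s − s_∞)·e^(−Δt/τ), exact for
frozen voltage and unconditionally inside [0, 1] — and non-gates, advanced
by forward Euler.

**Passive** (`passive`): I_ion = g_leak (v − E_leak), stateless; defaults
g_leak = 0.05 mS/cm², E_leak = −80 mV (membrane time constant 20 ms). Used
for the algebraic and differential-equation oracles, where exact reference
solutions exist.

**Two-current minimal model** (`mitchell-schaeffer`, Mitchell & Schaeffer
2003) rescaled to mV/ms: with V = (v − v_rest)/amplitude,

    dV/dt = h V²(1−V)/τ_in − V/τ_out,
    h → gate with s_∞(V) = 1/(1+exp((V − V_gate)/k)),  τ(V) between τ_open and τ_close.

Defaults: v_rest = −80 mV, amplitude = 100 mV, τ_in = 0.2 ms,
τ_out = 3.5 ms, τ_open = 100 ms, τ_close = 100 ms, V_gate = 0.13,
k = 0.02. The smooth gate replaces the original discontinuous switch so
convergence-order measurements are clean. I_ion is reported for
C_m = 1 μF/cm²; rest (V = 0, h = s_∞) is an exact equilibrium.

Why these constants. The effective excitation threshold of this model is set
by the balance V(1−V) ≈ τ_in/τ_out (≈ 6 mV above rest here), not by V_gate.
The defaults were chosen as a package-level design decision so that
(a) the action potential is atrial-like — upstroke within a few ms, APD
around 150 ms, full repolarization; (b) normal-coupling CV on the reference
strand is ~43 cm/s; and (c) at 500× R_g the junctional charging current is
close to the discrete propagation-failure limit, the regime where a
cell-resolved description and its homogenized continuum genuinely diverge
(the continuum CV stays ∝ √(effective conductivity) while the discrete
delay per junction grows much faster). That divergence — ~1% at normal
coupling, ~36% at 500× — is what makes the S1–S2 reentry contrast between
the two models possible at all; a very low-threshold parameterization
(e.g. τ_out ≈ 9 ms) makes the two models nearly indistinguishable and both
or neither reenter. The atrial model used in the literature this design
follows is not publicly reprinted; absolute CV values are therefore *not*
comparable across membrane models, and all tissue-level claims the package
tests are structural (conservation, convergence order, monotonicity,
discrete-continuum relations), which are membrane-model-agnostic.

## Numerical scheme

Godunov (first-order) operator splitting per step Δt:

1. **Reaction substep.** Rush–Larsen gate update at frozen v; forward-Euler
   non-gate update; explicit voltage update
   v* = v + Δt(−I_ion(v, s') + I_stim)/C_m. The stimulus is an additive
   depolarizing current density on the membrane, active on steps whose
   midpoint lies in [onset, onset + duration) — unambiguous whether or not
   Δt divides the stimulus duration.
2. **Network substep.** Backward Euler on the linear system: for all nodes,
   A_m C_m (v' − v*)/Δt = −[L_i (v' + u_e')], and current conservation
   L_i v' + (L_i + L_e) u_e' = 0 at ungrounded nodes, where L_i, L_e are the
   conductance-weighted graph Laplacians. Rows at grounded compartments are
   replaced by u_e = 0 (homogeneous Dirichlet); no-flux conditions on the
   intracellular side are natural in this flux form. Grounded compartments
   are the two strand ends in 1D and the whole perimeter in 2D. The 2N×2N
   sparse operator depends only on the network, C_m and Δt, so it is
   factorized once (sparse LU, default) or solved by GMRES to relative
   tolerance 10⁻¹⁰ — the tolerance is a package choice; both solvers must
   satisfy the same conservation contract. A system with no grounded node
   is singular and rejected with an explicit error.

After every network substep the per-node Kirchhoff residual
Σ I_i + Σ I_e is evaluated and its maximum, normalized by the largest total
incident current (floored at 1 μA), is tracked in the trace metadata; every
simulation is required to keep it below 10× the solver tolerance.

**Activation bookkeeping.** Upward crossings of the detection threshold
(default −20 mV) are recorded at full Δt resolution regardless of snapshot
cadence (default 1 ms), with a re-arm requirement (v must first fall below
threshold). Each event stores the step-end time and a linearly interpolated
crossing instant. `conduction_velocity` defaults to the literal step-time
reading; the convergence and acceptance drivers use the interpolated
times, because step-quantized crossings carry O(Δt) noise of non-monotone
sign that would mask the splitting error those studies measure, whereas
linear interpolation leaves an O(Δt²) measurement error well below the
O(Δt) scheme error. CV drivers stop a run 1 ms after every node has
activated once; a wavefront that never reaches a measurement cell raises a
distinct no-propagation error (recorded as "block" by the table drivers).

## The homogenized bidomain reference

The continuum equations (C_m ∂v/∂t = χ⁻¹[∇·(M_i∇v) + ∇·(M_i∇u_e)] − I_ion;
0 = ∇·(M_i∇v) + ∇·((M_i+M_e)∇u_e)) are discretized in flux form on a
cell-centered lattice with spacing (Δx, Δy): each control volume is a node
with membrane area χ·volume, each face an edge with conductance
M·face_area/spacing, and the identical stepping core integrates the result.
Homogenized parameters are fixed by the requirement that one cell length of
continuum have exactly the resistance of one network edge:

    χ = A_m/(l_x l_y l_z),   M_e = δ_e σ_e,
    M_i = δ_i / ( 1/σ_i + R_g δ_i A/(A_g l) )    (per direction).

This choice makes the discrete continuum operator at Δx = l_x equal the
network operator entrywise (verified to 10⁻¹² relative in the tests), which
is the precise sense in which the network model is a discrete continuum.
Stimulus regions and measurement points are defined in μm (the leftmost
cell is x ∈ [0, 120 μm]; measurement at the nodes nearest x = 300 and
1500 μm), so one protocol definition serves both models.

Spatial convergence (1D strand, Δt = 10 μs): CV changes by < 0.05% (1×R_g)
and 1.4% (500×R_g) between Δx = 20 μm and Δx = 5 μm, so Δx = 20 μm (with
Δy = 9 μm, half the cell width) is used as the converged continuum mesh for
the 2D experiments; Δx = 10 μm reproduces the same qualitative outcomes at
about three times the cost.

## Protocols and experiment drivers

* **S1**: 40 μA/cm² for 2 ms over the leftmost cell (1D) or leftmost cell
  column (2D) at t = 0.
* **S1–S2**: S1 plus the same stimulus over the lower-left quarter
  (⌊n_x/2⌋ × ⌊n_y/2⌋ cells; floor rounding for odd grids) after a coupling
  interval, default 240 ms. Undefined (rejected) in 1D. A zero delay is
  allowed (overlapping stimuli).
* **Conduction velocity**: distance between the centers of cells 3 and 13
  divided by the difference of their first threshold crossings; reported in
  cm/s.
* **Reentry detection**: the experiments show sustained rotors as
  re-excitation, so the operational criterion is conjunctive — at least one
  node activates ≥ 2 times later than 50 ms (refractory guard) after the S2
  onset, *and* suprathreshold activity persists beyond 300 ms after S2.
  Both windows are configurable; a persistence window extending past the
  trace is an error. A fully captured but non-reentrant S2 beat satisfies
  the persistence clause alone and is correctly classified as non-reentrant.
* **Studies**: `convergence_study` (CV and percent difference to the finest
  Δt, per gap-junction multiplier), `cv_rg_sweep` (CV vs multiplier for both
  models) and `reentry_experiment` (S1–S2 on the 2D sheet). All drivers are
  deterministic — identical configurations give bit-identical tables.

Problem sizes used throughout the package's own studies: the 15-cell strand
(Δt down to 1 μs; runs end shortly after full activation, so the expensive
fine-Δt runs take tens of seconds), and the 20 × 20 sheet at 500×R_g for
600 ms at Δt = 10 μs for reentry. At these sizes the full study suite
completes in minutes on one CPU.

Measured reference outcomes at the defaults: the cell network reenters at
S2 delays of 220 and 240 ms (not at 200, 260, 280 ms); the continuum at its
converged mesh does not reenter at 240 ms — the standard coupling interval
is the discriminating delay. Because the vulnerable window is set by the
membrane model's restitution, a delay search over
{200, 220, 240, 260, 280} ms is built into the acceptance check.

## Synthetic fixtures

`kirchnet.fixtures` generates all test data programmatically: a dense
differential-algebraic reference solve of the passive network (constraint
eliminated exactly, stiff implicit integration at rtol 10⁻¹⁰) that serves
as the independent oracle for the split scheme; a planar-wave trace with
analytically placed activation times (measurement round-trip must return
the construction velocity exactly); and a rotating-phase trace emulating a
rotor. The two trace fixtures are labelled synthetic in their metadata:
they validate the *analysis* operations in isolation and deliberately
contain no electrophysiology — passing them shows the measurement and
detection logic is correct, not that the simulator produces such dynamics
(the simulation-level tests cover that separately).

What the shipped studies do not emulate: real tissue has cell-size
dispersion, irregular (brick-like) cell packing, anisotropic fiber fields,
heterogeneous R_g, and membrane kinetics far richer than a two-current
model (no rate-dependent restitution portrait, no calcium handling).
Conclusions supported by the tests are therefore structural properties of
the network formulation and its numerics, not quantitative predictions for
any particular species or chamber.

## Known limitations

* One gate, two currents: the membrane model cannot reproduce
  species-specific AP morphology or restitution; absolute CVs and
  vulnerable-window locations shift with any membrane-model change.
* The transverse junctional contact area is an assumption (see above).
* 2D lattices only (n_z = 1); no irregular geometries.
* First-order splitting; no adaptive stepping; the linear operator is
  refactorized only when Δt or the network changes.
* The continuum solver is finite-difference on rectangles; it is a
  reference for the network model, not a general-purpose bidomain code.
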
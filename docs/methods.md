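# Methods

## Tissue representation

A tissue is a planar mesh: `Node`s (2D vertices, optionally `fixed` against
mechanical displacement), `Cell`s (counter-clockwise rings of node ids with
chemical amounts, a target area `A_T`, a type tag, and a birth/"base" area),
and `Wall`s — the apoplast segments between neighboring cells. A wall spans
one or more mesh edges (`node_path`, stored in the orientation of its
`cell_a` ring), carries a rest length `l0`, a stiffness, and two per-side
transporter arrays; boundary walls face the exterior (`cell_b = BOUNDARY`).
Invariants (every internal edge shared by exactly two cells, every edge
covered by exactly one wall, wall paths contiguous in both adjacent rings,
rings simple and positively oriented) are checked by `validate_mesh`, which
reports violations rather than raising.

Chemical state is stored as per-cell **amounts**; concentrations are
derived as amount/area. This makes growth dilution and division
conservation automatic, and it fixes the state variable where "levels" and
"concentrations" would otherwise be interchangeable.

## Mechanics

Elastic equilibration minimizes a Hamiltonian by Metropolis Monte Carlo
over node positions. The four energy functions are listed in the README;
two details matter numerically:

- The `plain`/`modified` spring term runs over **unique** polygon edges
  (each shared edge counted once); double counting would silently double
  `λ_M`.
- `delta_energy` recomputes only the terms incident to the displaced node
  (cells containing it, edges touching it, walls whose path contains it).
  This is exact up to floating-point association order; tests and the
  acceptance script verify agreement with full recomputation to 1e-9.

One MC step visits every non-fixed node once in a fresh random permutation
(removes sweep-order bias); accepted moves apply immediately. A move that
would make an incident cell self-intersecting or non-positive in area is
rejected outright — no repair logic, the mesh invariants are preserved by
construction. Acceptance is Metropolis at temperature `T` (default 0.01 in
energy units; downhill moves always accepted, uphill with `exp(−ΔE/T)`,
never at `T = 0`). Equilibration stops when `−Σ_accepted ΔE < E_th`
(threshold mode, the default) or when the sliding-window mean of
`|Σ ΔE|` over `window_size` MC steps drops below `window_tol`, or after
`max_mc_steps` without convergence (`converged=False` is reported, never
raised).

Default step amplitude is 0.05 length units on unit-sized cells — small
enough that geometry rejections are rare, large enough to relax a 20%
vertex perturbation in a handful of MC steps.

## Chemistry

The slow phase integrates one assembled ODE system per time slice with
`scipy.integrate.solve_ivp` (RK45, rtol 1e-8 / atol 1e-10 by default);
geometry is frozen for the duration of a slice. Terms:

- reaction (pluggable per model): default `dQ_c/dt = s_c·a − k_c·Q_c`,
  production per unit **area** so behavior is stable under mesh refinement;
  `production_by_type` overrides the rate vector per cell type;
- internal transport: `P_c · l(w) · (C_j − C_i)`, antisymmetric by
  construction, so a closed tissue conserves total amount to solver
  round-off (measured drift ~1e-14 over 100 slices on a 5×5 tissue);
  the conductance scales with the shared wall length because the
  permeability carries units of length/time;
- boundary transport: the same law against a fixed external concentration
  per boundary wall (no-flux where unset), plus *virtual interfaces* — per
  (cell, chemical) external concentrations with an explicit conductance
  `g`, used by the coupling layer and the external-driver protocol, where
  no geometric wall exists.

Housekeep rules run once per simulation step, after chemistry and before
division/mechanics:

- geometric growth: cells at or above the trigger concentration θ scale
  `A_T` by `(1 + growth_rate)`; with θ = 0 (and no chemicals) this is
  unconditional growth;
- elastic yielding: walls with `l/l0 > yield_ratio` (default 1.5) grow
  `l0` by `yield_increment` (default 10%), irreversibly;
- Maxwell relaxation: `dl0/dt = (l − l0)/τ`, integrated in closed form per
  step. This exponential rest-length relaxation is a deliberately simple
  viscoelastic surrogate standing in for a full turgor/solute wall model;
  it reproduces the qualitative behavior (stress decays on the τ time
  scale, the elastic limit is τ → ∞).

## Division and node insertion

A cell divides along a line perpendicular to its axis of inertia (principal
axis of the polygon's second area moments; isotropic ties break to +x for
determinism) or along a caller-supplied axis. The line offset is found by
bisection of the clipped-area residual (≤60 iterations, terminating at
relative interval width 1e-15), giving daughter areas within 1e-6 relative
of half the parent (measured: ~1e-15). The cut must cross exactly two ring
edges, else the division fails and the mesh is left untouched (restored
from a snapshot if partially mutated). Cut nodes are threaded into the
neighbor rings and the owning walls' paths; walls spanning the cut are
split with rest length apportioned by actual length; the new daughter–
daughter wall starts at rest (`l0` = actual length) with the parent's mean
stiffness and zero transporters. Chemical amounts and target area split
proportionally to daughter areas with exact-remainder assignment, so every
chemical is conserved to the last ulp. The built-in division trigger is
`a ≥ division_factor × base_area` (factor 2 by default), where `base_area`
is the cell's birth area.

`split_long_edges` bisects every edge exceeding `target_node_distance`
once per call, inserting the midpoint into both rings and the wall path.

## Time stepping and components

A model is a named component per type (chemistry, transport, boundary
transport, housekeep, split rule, daughter rule, Hamiltonian, move
generator, evolver, color, wall-chemistry hook) plus numeric parameters,
all serialized in the tissue file. Meta-components reference other
registered components of the same type (e.g. a division rule dispatching on
cell type); reference cycles are rejected at resolution time.

The `mechanics_last` evolver orders a step as chemistry → housekeep →
division → node insertion → MC equilibration; `chemistry_last` rotates the
same ring so the step ends with chemistry instead. Queued parameter or
component changes take effect at the start of the following step, which
makes mid-run reconfiguration reproducible: switching the Hamiltonian at
step k yields the same trajectory as a fresh run started from the step-k
snapshot.

Chemistry phases never move nodes; mechanics phases never touch amounts.
Given (tissue file, spec, seed, step count) the full trajectory is
deterministic; snapshots serialize the RNG state in the file's extensions
block so resumed runs are bit-identical to uninterrupted ones.

## Coupling

Two simulations advance in lockstep with a shared dt. Each step is divided
into `n_c` slices; at each slice start (optionally slice end) the coupler
copies every linked partner cell's concentration into the other model's
virtual boundary conditions, frozen for the slice, with flux
`g·(C_partner − C_cell)`. Because the partner value is frozen, mass is
conserved only approximately; the error is O(1/n_c) (measured: 1.0%, 0.1%,
0.01% of produced mass at n_c = 1, 10, 100 in the reference producer/
receiver configuration). A strictly conservative variant integrates both
models' chemistry as one joint ODE with live link fluxes and conserves to
solver tolerance; it is provided for comparison, not as the default,
because the frozen-boundary scheme is the one whose n_c-dependence the
package documents. After the slices, each model runs its mechanical phases
independently.

The driver protocol exposes the same virtual-interface mechanism to an
external master script: read coupled-cell concentrations after a step,
install frozen external concentrations before the next. The leaf–root demo
is written against this protocol.

## Demo models and their parameters

The built-in demos define the package's reference conditions:

- `coupling_producer` / `coupling_receiver`: one chemical; areal production
  1 (producer) or 0 (receiver), no decay, internal permeability 1,
  geometrically static (all nodes fixed). Reference coupling: 5×5 grids of
  unit cells, links between the facing boundary-cell pairs, dt = 0.1.
- `leaf`: static 3×3 tissue, two chemicals; produces chemical 0 at areal
  rate 1 with decay 0.1 (both chemicals); production latches off per cell
  once the chemical-1 concentration reaches θ₁ = 0.3.
- `root`: 3×3 tissue, free nodes; no chemical-0 production; target areas
  grow 5% per step in cells whose chemical-0 concentration reaches
  θ₀ = 1.0, and growing cells produce chemical 1 at areal rate 2 (decay
  0.1). Coupled through one leaf–root cell pair with conductance 2.
- `geometric`: no chemistry; unconditional 10% target-area growth, division
  at twice the birth area, node insertion above edge length 2.

The leaf–root thresholds and rates were chosen once so that the full
feedback loop — signal accumulation, growth onset (~step 34 at seed 0),
reverse-signal build-up, production halt (~step 110), growth arrest —
completes within a 250-step run at dt = 0.1. The demo sizes (3×3 and 5×5
grids, 100–250 steps) are the package's reference problem sizes throughout
the tests and the acceptance script.

## What the synthetic tissues do and do not show

All tests run on programmatically generated square-grid tissues (and random
star/convex polygons for division). These exercise the full topology
machinery (shared walls, boundary walls, ring/wall bookkeeping under
division and node insertion) but are far more regular than segmented
microscopy meshes: no pre-existing curvature, uniform initial areas and
wall lengths, and at most the irregularity that MC relaxation and division
introduce. Passing tests therefore demonstrate correctness of the
algorithms and conservation/contract properties, not biological realism of
any particular tissue. Real-data features deliberately absent:
intracellular gradients (cells are well-mixed compartments), apoplastic
lateral diffusion along walls, 3D structure, and T1-type topological
rearrangements.

## Numerical choices and degenerate inputs

- Floats serialize at 17 significant digits; canonical element ordering
  makes tissue files byte-stable across writes.
- Isotropic inertia tensors (e.g. squares) take the +x axis and are
  flagged; the degenerate direction does not affect the equal-area
  guarantee.
- A division line passing exactly through a vertex is nudged off it by a
  relative 1e-11 guard before the cut edges are located.
- Amounts dipping below zero by less than 1e-9 after a solve are clamped
  to zero; larger negatives are left visible (they indicate a genuine
  configuration error and will be caught by `validate_mesh`).
- `modified` Hamiltonian raises on zero-area cells (the relative deviation
  is undefined); zero-area rings are invalid input everywhere else too.
- Mass-conservation claims are for the assembled derivative field
  (antisymmetric wall fluxes); the adaptive solver adds only round-off.

## Known limitations

- One built-in daughter-partitioning rule (area-proportional with exact
  remainder); alternative rules plug in at the registry but none ship.
- The wall-chemistry component is a hook with zero built-in kinetics.
- Sweeps run serially; the results table is independent of execution
  order by construction.
- Only pairwise coupling is exercised; the exchange mechanism itself does
  not limit the number of models.
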
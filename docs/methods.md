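# Methods

`stringnet` infers the functional structure of planar elastic string
networks — synthetic Latex cut-sheets or the finger extensor mechanism
approximated as a network of collagenous strings — from sparse tensile
experiments.  This note documents the mechanical model, the inference
procedure, the synthetic-data generator, the numerical choices and the known
limitations.

## Mechanical model

A network is a set of nodes in the plane joined by tension-only strings.
Three movable *input* nodes receive commanded tensions whose lines of action
are fixed in the global frame (angles from the horizontal, negative =
downward); two grounded *output* nodes supply measured reaction forces.
Strings that cross without sharing a node slide freely past each other: no
contact, no friction.  Units are mm / N / MPa throughout, so `stress ×
area` is directly a force in newtons.

Each taut string is a large-displacement truss element with engineering
strain on the current chord, `eps = (l − l₀)/l₀` — the *large deformation,
small strain* regime appropriate for both Latex and tendon over the 0–5 N
loading range.  A string with `l < l₀` is slack and carries neither force
nor stiffness; slack/taut status is re-evaluated at every solver iteration.
Two constitutive laws are available:

* **linear** (`σ = E·eps`), with E = 1.62 MPa for the Latex strings and a
  1 GPa linear control variant used to show what an incorrect tendon
  constitutive assumption does to inference;
* **tendon**, a C1 exponential-toe + linear curve with linear-region
  modulus 1200 MPa, toe strain 0.015 and shape factor 3.  The toe stress is
  fixed by C1 continuity; shrinking the toe to zero strain reproduces the
  linear law exactly, which the tests exercise.  The parameters are
  configurable because published tendon curves vary considerably between
  specimens.

Equilibrium of the free degrees of freedom solves `g(U) = F(U) − F_e = 0`
by Newton–Raphson from `U = 0`, with the consistently linearised tangent
`K = dF/dU` assembled from taut elements only (material term `E_t A/l₀ · n nᵀ`
plus geometric term `N/l · (I − n nᵀ)`).  Convergence is declared when the
infinity norm of the free-DOF residual falls below `tol` (default 1e-8 N,
max 100 iterations; both configurable).

Two robustness devices handle the pathologies of tension-only assemblies:

* a stiffness floor (default 1e-9 N/mm) added to the free–free tangent
  **only** — the residual is never modified, so the converged solution is
  unaffected; it keeps the linear solve well posed when nodes hang on fully
  slack strings;
* an infinity-norm cap on the Newton step (default 20 mm), because a
  just-taut string has zero transverse stiffness and the first iteration of
  a transversely loaded taut-string problem would otherwise step to
  near-infinity.  The cap turns that into a short sequence of bounded steps.

A singular tangent or iteration-limit exhaustion flags non-convergence; it
never raises.  Model fitness treats a non-converged analysis as worst-case
(sentinel 1e6 %), reflecting that candidate models whose analyses fail are
simply unfit.  Reactions are reported as the Euclidean norm of the net force
transmitted to each grounded node — the physical dynamometers swivel, so
only magnitudes are observable.

Independent fitness evaluations are batched: the per-load-set Newton solves
share one vectorised sweep (`TrussSystem.simulate_batch`), and the hill
climber evaluates a whole population's proposals in a single call.  Batched
and scalar paths agree to round-off and the tests assert it.

## Fitness metrics

For a model simulated against `N_DS` load sets with `N_R = 2` reactions and
`N_D = 6` distances each:

* `obj_R` — mean over all reaction comparisons of
  `|R_model − R_meas| / max(|R_meas|, 1e-3 N)`, in percent; `obj_D` the
  analogue over distances with a 1e-3 mm floor.  The floors guard against
  division by near-zero measurements and are an implementation addition.
* training error `e_training = (obj_R + obj_D)/2`; a force-only mode drops
  the deformation block to study what force information alone can infer.
* cross-validation error `e_cross` — the max-based analogue on the held-out
  sets: the mean of the two per-block maxima.  It quantifies worst-case
  functional disagreement and by construction never falls below the
  average-based error on the same sets.  The average form is reserved for
  training because the max landscape is far less smooth to descend.
* test informativeness `e_test` — for a candidate test simulated on every
  model, the sum over the 8 response components of the across-model
  population standard deviation, measured in instrument-resolution units:
  reactions in multiples of the 0.0196 N dynamometer step, distances in
  multiples of the 1 mm caliper step.  Counting dispersion by its
  observability makes the force and deformation blocks commensurable and
  ties "informative" to what the measurement system can actually resolve.
  (An earlier design normalised each component by its across-model mean;
  that made near-zero-force tests — where relative reaction dispersion
  explodes — look maximally informative, so serving collapsed into the
  low-force corner of the grid and informative runs lost to random ones.
  The instrument-unit form repaired this while preserving every contract
  property: zero iff all models respond identically, permutation
  invariance, invariance under duplicating the whole population, strict
  monotonicity in any single-component divergence.)  Models whose analysis
  fails for the candidate are excluded from the dispersion.

## Estimation–exploration loop

Stage I seeds the exposed set with one training record drawn uniformly.
Each cycle then (II) evolves every model of the population independently by
random-mutation hill climbing on the exposed records, and (III) evolves the
three input magnitudes (angles fixed) to maximise `e_test`, after which the
nearest not-yet-served training record (least-squares distance in input
space, lexicographic tie-break) joins the exposed set.  Serving is without
replacement by default — each physical load set informs once — with a
with-replacement flag for protocol studies.

Mutation follows the bounded multiplicative step law
`c_new = c ± (c_U − c_L)·exp(R1 + r·R2)`, `r ~ U[0,1]`, R1 = −8, R2 = 9, so
step magnitudes span 3.35e-4 to 2.72 times the parameter range before
clamping into the bounds; signs are equiprobable and independent.  Each
parameter mutates with probability `p_rate = 0.08` (must stay below 0.15 or
the climber degenerates into random search).  Two auxiliary regimes are
scheduled per proposal with weights 0.6/0.3/0.1 (standard/fine/coarse):
*fine* restricts steps below 1 % of the range at rate `5·p_rate`, *coarse*
above 20 % at `0.2·p_rate`; the restriction is implemented by windowing the
uniform draw `r`, which preserves the log-uniform step distribution inside
each window.  Proposals are accepted only on strict improvement, so accepted
traces are monotone by construction (asserted on every logged run).

Counters: a favourable change anywhere resets the stagnation counter G to 0
and increments G_L; a fruitless sweep increments G.  Evolution stops when
G > 2·G_L with G at least G_min, at the hard iteration cap, or when every
model is below the 0.5 % training-error threshold (individually converged
models stop evolving early).  When the worst model has not improved for a
configurable window it is crossed over with a random other model by uniform
per-string parameter exchange, the child replacing it only on improvement —
one concrete realisation of a deliberately loosely specified rescue step.

Model topology is read out *functionally*: a string belongs to the inferred
topology iff it is taut under at least one of the tests used during the
model's evolution.  Strings slack under every test are excluded from the
report but kept in the model, since later tests may engage them.

Stage III termination reuses the counter scheme with the threshold replaced
by an iteration budget.  The informativeness landscape is worth a remark:
for models differing in rest-length slack, tests near the engagement
threshold can discriminate strongly, so evolved tests are not always
extreme-force tests; requests between grid points are served by the nearest
available precollected record.

## Synthetic data generator (virtual lab)

The generator emulates the physical measurement sessions: a full-factorial
training grid of four tension levels per input (1.25/2.50/3.75/5.00 N, 4³ =
64 records) plus a 2³ = 8-record cross-validation grid at 1.9/4.4 N,
collected in seed-shuffled order; per-experiment fixed angles (−135/−90/−45°
for the AFH layout, −105/−90/−75° for the adapted Winslow's rhombus,
−115/−90/−75° for the extensor); dynamometer quantization of 0.0196 N (2 gf)
on reactions and 1 mm caliper quantization on distances, with optional
Gaussian noise (default 0).  An `ideal()` protocol variant disables the
instrument quanta for exact-recovery studies.  What it does **not** emulate:
tissue degradation over a testing session, tether compliance, stiction, or
the cross-talk of manually loaded tethers — so passing recovery tests show
correctness of the inference machinery under the stated noise model, not
robustness to every artefact of bench experiments.

Ground-truth targets are built programmatically.  The letter-like and
rhombus targets are regular layouts in a 100×100 mm footprint (50 mm at
extensor scale) with 4 mm² cross-sections and chord-length rest lengths, so
the unloaded state is an equilibrium.  The published string fabrics are
reconstructed as row layouts with exactly the stated string counts (36, 54,
71) and per-fabric length/cross-section bounds; exact node coordinates are
not published, so these layouts are this package's reconstruction and are
recorded in full in the serialized meshes.  The `random` target is the
all-in-all 5-node, 6-string core with seed-drawn rest-length slack factors
(U[1.00, 1.05] × chord) and cross-sections (U[2, 5] mm²) — small enough to
recover exactly, rich enough that both parameter blocks matter.

## Study conditions and problem sizes

The validation suite and `scripts/acceptance.py` run scaled-down study
conditions chosen once for this package: populations of 3 models, at most 8
exposed load sets per run, per-cycle hill-climb caps of 1 500–3 500
iterations with G_min 300–700, and informative-test budgets of a few hundred
iterations (the full-scale defaults — population 8, 20 sets, 100 000-iteration
caps, G_min 5 000 — remain the configuration defaults).  Fresh primordial
strings start at chord rest length (just slack, matching the assumption
that models begin unloaded and slack) with mid-range cross-section.
Recovery is declared when a model explains a noise-free target below the
0.5 % training threshold *and* reproduces its exact taut-string set; the
serving-protocol comparison runs informative and random serving on paired
seeds with instrument quantization on and compares mean final
cross-validation errors.

## Numerical choices and degenerate inputs

* Division floors 1e-3 N / 1e-3 mm in all relative discrepancies.
* A string whose displaced endpoints coincide has zero length, hence is
  slack with zero force (no division by zero reaches the assembly).
* Nearest-neighbour ties break toward the lexicographically smallest
  magnitude triple, making serving deterministic.
* All randomness descends from one seed via spawned generator streams (one
  per model plus auxiliary streams), so entire runs are bit-reproducible
  and the per-model streams are stable under population-size changes.
* Degenerate mutation bounds (`c_L ≥ c_U`) and empty populations or
  databases are usage errors, raised before any simulation starts.

## Known limitations

* 2D only; no wrapping over joint surfaces, no sheet/continuum cells, no
  dynamics, no viscoelasticity or hysteresis, no inter-string contact.
* Green–Lagrange large-strain kinematics are deliberately out of scope; at
  Latex-scale strains (up to ~0.8 under 5 N on a 6.5 N·strand) engineering
  strain on the current chord is an approximation, applied consistently to
  both targets and models so recovery studies remain internally consistent.
* The published experiments' error tables depend on physical measurement
  data that was never deposited; nothing here reproduces those numbers, and
  the validation suite instead checks printed analytic/protocol constants
  and in-silico recovery.
* The topology readout depends on the tests used; a string taut only under
  untested loadings is invisible, which is a property of the inference
  problem, not of the implementation.
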
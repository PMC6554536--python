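# Methods

`scleramap` estimates a spatial map of anisotropic hyperelastic material
parameters for a pressure-inflated posterior scleral shell from surface
displacement fields, using a subdomain inverse finite-element strategy: the
shell is partitioned by surface strain, each subdomain's parameters are fit
independently against the measured displacements, and the assembled map is
verified by a full-shell simulation. This note records the model, the
numerical choices, and what the synthetic experiments do and do not show.

## Constitutive model

The sclera is modeled as an incompressible Holzapfel-type fiber-reinforced
solid with a single in-plane collagen fiber family (N = 1):

    W = C10 (I1 − 3) + k1/(2 k2) [ exp( k2 ⟨Eα⟩² ) − 1 ],
    Eα = κ (I1 − 3) + (1 − 3κ)(I4 − 1),     I4 = A · C · A.

- `C10` (kPa) — ground-matrix shear-like modulus; dominates the low-pressure
  (toe) response.
- `k1` (kPa) — fiber stiffness scale; `k2` (–) — dimensionless exponential
  stiffening rate. Over physiological strain ranges k2 enters only through
  `k2·Eα²`, which makes it the most weakly identified parameter (see below).
- `κ ∈ [0, 1/3]` — fiber dispersion about the mean direction `A`; 0 is
  perfect alignment, 1/3 isotropy. κ and the mean fiber angle are measured
  inputs (e.g. from small-angle light scattering) and are never fitted. The
  dispersion integral `κ = ¼∫ρ(θ) sin³θ dθ` (with ∫ρ sinθ dθ = 2) converts a
  measured π-periodic orientation density into κ.
- The Macaulay bracket ⟨·⟩ deactivates fiber energy under fiber compression.
- Incompressibility is enforced exactly through the thickness stretch,
  `λ3 = 1/det F₂ₓ₂`, which also condenses the through-thickness stress out of
  the membrane: after substitution W depends on the in-plane C alone and
  `S = 2 ∂W/∂C` is the plane-stress second Piola–Kirchhoff stress. The
  analytic stress and fourth-order tangent are verified against central
  finite differences of W in the test suite (1e-6 / 1e-5 relative).
- `k2 → 0` is evaluated by series below 1e-8 to avoid cancellation;
  `k2⟨Eα⟩² > 700` raises an overflow error rather than returning inf.

## Forward model

Total-Lagrangian constant-strain membrane triangles on the reconstructed
outer surface, with per-element reference thickness from the normal-projection
thickness algorithm. Pressure is a follower load on the inner surface
(p/6 · d₁×d₂ per node of each element); its unsymmetric load stiffness is
assembled into the Newton tangent and the linearized systems are solved with
a general sparse LU. The element force/stiffness are expressed in convected
edge coordinates (metric `m_pq = d_p·d_q`), so no per-iteration local frames
are needed; the assembled tangent matches a finite-difference residual to
~1e-9 relative.

The 5 mmHg reference state is treated as stress-free (prestress at reference
is a known limitation of this class of analysis) and the applied load for a
protocol step at pressure p is the difference `p − p_ref` in kPa
(1 mmHg = 0.133322 kPa). Steps are applied sequentially with configurable
sub-increments, proportional ramping of pressure and prescribed boundary
displacements inside a step, Newton iteration with a backtracking line
search (halving, max 10), and convergence at
`‖R‖ ≤ rtol·‖f_ext‖ + atol` (defaults 1e-8 / 1e-10 mN). Non-convergence
retries the step with doubled sub-increments (twice by default); explosive
divergence (residual above 1e8 mN) aborts immediately, since increment
refinement cannot save a physically infeasible parameter set. Closed shells
(the balloon verification fixture) carry six Lagrange constraints removing
rigid-body modes. Wrinkling (membrane compression) is not modeled.

Units throughout: mm, kPa, mN.

## Kinematics and partitioning

Surface strain is computed element-wise from matched reference/deformed
nodal positions via in-plane local frames: `F` (2×2) maps reference to
deformed edge coordinates, `E = ½(FᵀF − I)`, and E1 is the larger eigenvalue.
Nodal displacements are smoothed by iterative uniform-weight neighbor
averaging (default 25 iterations, factor 0.5) *before* differentiation;
strain itself is never smoothed. The smoother obeys the discrete maximum
principle, so it cannot create out-of-range values.

Elements are binned into K subdomains (default 4) by equal-count percentiles
of min–max-normalized E1 from the cumulative (reference → 45 mmHg) field.
Ties go to the lower bin; explicit percentile edges can be supplied. One
element-wide strips of a label trapped between other labels are detected as
same-label connected components without interior elements and reassigned to
the neighboring subdomain whose adjacent elements' mean E1 is closest
(ties to the lower label), iterating to a strip-free fixpoint. A bin that is
spatially disconnected remains a single subdomain (one parameter set).

## Inverse estimation

Each subdomain becomes an independent problem: boundary nodes (shared with
other subdomains or on the rim/hole margin) carry the measured displacements
as prescribed values per pressure step; interior nodes are free and define
the objective, the sum of squared nodal displacement differences over all
steps and components (mm²). The measured field also seeds the Newton
predictor — it is the exact solution at the true parameters and a good
boundary-layer start elsewhere; each objective evaluation remains stateless
and deterministic.

Search runs in log10-space over (C10, k1, k2) because the admissible ranges
(C10 5 kPa–40 MPa, k1 1 Pa–40 MPa, k2 0.1–300) span 3–7.6 decades:

1. **DOE bounding.** An exhaustive log-spaced grid sweep (default 7×9×4;
   k1's axis is densest because its range is widest) records the residual of
   every combination. The swarm's search box per parameter is the union of
   ±1-grid-step neighborhoods of every combination within 10× of the best
   residual. Taking a likelihood region rather than the single best cell is
   deliberate: on this correlated landscape the best coarse cell is often a
   compensating neo-Hookean combination (k1 → 0), and a one-cell box around
   it would exclude the true k1 entirely. Where one cell dominates, the rule
   reduces to a one-cell neighborhood.
2. **Particle swarm.** Global best PSO (default swarm 30, here 20×60 for
   recovery experiments) with linearly damped inertia 0.9 → 0.4, cognitive
   and social coefficients 1.4962, reflective bounds, and a large penalty
   (1e6 × best feasible) for non-convergent forward solves. Deterministic
   for a fixed seed; the best-so-far residual is non-increasing by
   construction.
3. **Hybrid polish.** A derivative-free Nelder–Mead descent from the swarm
   optimum (cap 400 evaluations), mirroring the hybrid option of the MATLAB
   optimizer this workflow descends from. The (k1, k2) ridge is shallow —
   ±25% in k2 moves the noiseless residual by only ~1e-11 mm² at
   physiological strains — and the polish supplies the final one-to-three
   orders of residual decrease that pin it down. On noiseless synthetic
   data the combination recovers all three parameters to machine precision.

Fitted maps are assembled piecewise-constant and relaxed by neighbor
averaging in log-parameter space inside a band (default 3 elements) around
inter-subdomain boundaries, which keeps every smoothed value inside the
convex hull of the subdomain constants. The final global check re-solves the
full shell (rim clamped; hole margin displacement-prescribed from data by
default, configurable to free) and reports two distinctly named error
metrics: the mean over free nodes of the Euclidean displacement difference
averaged over steps (mm), and the literal sum-of-squares residual divided by
node count (mm²). Both are emitted because the originating workflow's
"average difference" is described as the latter but reported on the scale of
the former.

## Synthetic experiments

The generator stands in for the donor-eye data and uses only public pipeline
operations. The default shell is a hemisphere (R = 12 mm) with a 1.75 mm
apical hole (the excised optic nerve head), clamped equatorial rim, uniform
1.0 mm thickness, and circumferential fibers around the hole. Ground-truth
parameters are region-wise constant (azimuthal sectors or equal-count polar
bands), drawn log-uniformly from C10 ∈ [30, 150] kPa, k1 ∈ [150, 1500] kPa,
k2 ∈ [20, 200]; κ cycles through measured scleral values
(0.249, 0.287, 0.248, 0.170). These defaults were set so the simulated
fields have the magnitude of measured posterior-sclera inflation data
(displacement components up to ~0.5–0.7 mm at 45 mmHg, mean surface strains
of a few percent). Measurement noise is independent isotropic Gaussian per
node, component, and loading step (default σ = 5 μm, the scale of
speckle-correlation accuracy); the reference step is exactly zero.

What the synthetic tests show: the solver, partition, and estimator are
internally consistent (residual at the truth is numerically zero; recovery
at zero noise is exact; the global check reproduces its own fields to
<1e-6 mm). What they do not show: robustness to the features of real data —
correlated measurement error, reconstruction bias, geometric irregularity,
regional thickness error, prestress at the reference, and viscoelastic
creep are all absent from the generator.

### Identifiability under noise

With σ = 5 μm noise the objective floor is ~2e-2 mm² per subdomain while the
k2-direction ridge depth at ±25% is ~1e-11 mm²: k2 is formally unidentifiable
under noise and is reported without an accuracy claim. C10 and k1 remain
identifiable when the fiber contribution is comparable to or stiffer than
the matrix; for a weak-fiber region (k1 ≈ 150 kPa against a 6·C10 ≈ 600 kPa
matrix) the *minimum of the noisy objective itself* — verified by simplex
descent started at the truth — sits far from the truth along the matrix–fiber
compensation ridge, so no optimizer can recover k1 there at this noise
level. This is a property of the data content, not of the algorithm, and the
corresponding acceptance-suite assertion is left failing rather than
weakened; the practical reading is that fitted k1 values in compliant,
matrix-dominated regions carry wide uncertainty at speckle-correlation noise
levels.

## Problem sizes and budgets

Recovery experiments run on a ~1.2k-element hemisphere (1.25 mm target edge)
with DOE 7×9×4 and PSO 20×60 per subdomain; the balloon verification uses a
5120-face icosphere; the thickness check uses 10⁴ interior points; mesh
convergence compares a 1.25 mm mesh against its projected 1:4 refinement.
These sizes make a full test run practical on a single CPU while leaving
every tolerance at its stated value.
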
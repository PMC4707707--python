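# Methods

## Governing equations and constitutive model

The package solves quasi-static equilibrium of an incompressible
hyperelastic solid in a total Lagrangian setting. With reference
coordinates `X` (mm), deformed coordinates `x`, deformation gradient
`F = ∂x/∂X`, right Cauchy–Green tensor `C = FᵀF`, Green–Lagrange strain
`E = ½(C − I)` and `J = det F`, the strong form is `div σ = 0` under the
constraint `J = 1`, with `σ = J⁻¹ F T Fᵀ` and `T = ∂W/∂E`.

The passive material is the transversely isotropic exponential
(Fung-type) law with fibre direction `f = e₁` of a local orthonormal
frame `(e₁, e₂, e₃)`:

    W = C_mat/2 (e^Q − 1),
    Q = b_f E₁₁² + b_t (E₂₂² + E₃₃² + E₂₃² + E₃₂²)
      + b_fs (E₁₂² + E₂₁² + E₁₃² + E₃₁²),

where the off-diagonal strain components are counted separately. The
componentwise derivative then gives a symmetric stress without extra
factors: `T_p,ij = C_mat e^Q B_ij E_ij` with `B` the coefficient matrix
(`b_f` on the fibre-fibre slot, `b_fs` on fibre shears, `b_t` elsewhere).
The material constant is stored as `C_mat` to avoid colliding with the
right Cauchy–Green tensor in the volumetric term. Because `W` depends on
`e₂, e₃` only through the transversely isotropic invariants, any rotation
of the completion about `e₁` leaves it unchanged (tested); the specific
completions used are the global axes for the beam and, for the ventricle,
`e₂` = outward transmural normal orthogonalised against `f`,
`e₃ = e₁ × e₂`.

Active contraction is a constant homogeneous fibre tension added in the
reference frame, `T ← T + T_a f fᵀ`, with `f` the *reference* unit fibre
vector; no length or velocity dependence is modelled. Incompressibility
uses the exact Lagrange-multiplier stress `−p J C⁻¹`. Sign convention:
`p > 0` is compressive, i.e. at `F = I` the Cauchy stress is `−p I`;
under an external pressure `q` on all faces of a unit cube the
equilibrium multiplier is `p = +q`.

### Volumetric–deviatoric split

Optionally (default for the two ventricle problems, off for the beam) the
passive law is evaluated on the isochoric strain built from
`F̄ = J^(−1/3) F`, giving `T_p = J^(−2/3) [S̄ − ⅓(S̄:C) C⁻¹]` with
`S̄ = ∂W/∂Ē`. At an exactly incompressible solution the two evaluations
differ only by a multiple of `C⁻¹`, which the multiplier absorbs, so
displacements are unaffected (tested at the constitutive level); on the
way to the solution the split markedly improves the robustness of the
inflation problems, which otherwise stall at a fraction of the target
pressure. The toggle is per problem.

## Geometry, meshes and fibres

Both geometries are analytic. The ventricle wall is the volume between
two truncated ellipsoids, parametrised by
`x = (rs sin u cos v, rs sin u sin v, rl cos u)` with `rs(t) = 7 + 3t`,
`rl(t) = 17 + 3t`, transmural coordinate `t ∈ [0,1]` (0 endocardium,
1 epicardium), `u ∈ [−π, −arccos(5/rl(t))]` (the upper bound realises the
base plane z = 5 mm on both surfaces) and circumferential `v`. Meshes are
structured hexahedral lattices in `(u, v, t)`; `t` is therefore defined
parametrically by construction (linear across the wall by lattice index),
not by Euclidean distance. Every element stores its nodes' exact
`(u, v, t)` (with `v` unwrapped per element across the periodic seam), so
fibre frames at quadrature points come from interpolated parametric
coordinates and the analytic formulas — never from finite differencing of
the discrete geometry.

The fibre angle rule is `α(t) = 90 − 180 t` degrees, measured from the
circumferential tangent `n(∂x/∂v)` toward the apex-to-base tangent
`n(∂x/∂u)`:  `f = n(∂x/∂u) sin α + n(∂x/∂v) cos α`. The two tangents are
orthogonal, so `f` is automatically unit length and tangent to the
constant-`t` surface.

**Apex treatment.** The `u = −π` node ring is collapsed to a single node
per transmural layer, producing degenerate hexahedra whose interior Gauss
points retain positive Jacobians (checked at generation and each Newton
iteration). This collapse is one documented choice among several used in
practice (caps, isotropic patches), not claimed canonical; published
solutions differ most near the apex. At the fibre singularity
(`‖∂x/∂v‖ < 10⁻¹⁰ rs`, which no interior quadrature point reaches) the
fallback is the pure meridional limit `f = n(∂x/∂u)·sign(sin α)` with
`sign(0) = +1` — deterministic and unit-norm.

The beam is a regular lattice on [0,10]×[0,1]×[0,1] mm with constant
fibre (1,0,0); tagged surfaces are "left" (x=0, fixed) and "bottom" (z=0,
pressurised). Ventricle tags: "endocardium", "epicardium", "base".

## Discretisation and solver

* **Element pairs.** Order 1: 8-node trilinear displacement with an
  element-constant multiplier (Q1P0). Order 2: 27-node triquadratic
  displacement with a continuous trilinear multiplier on the corner nodes
  (Taylor–Hood-like Q2Q1). Volume quadrature 2×2×2 / 3×3×3 Gauss; surface
  quadrature one order higher.
* **Follower pressure.** The external virtual work is integrated on the
  reference facets through the deformed tangent vectors,
  `f_ext,a = −p λ ∫ N_a (∂x/∂s × ∂x/∂t) ds dt`, which equals the traction
  `−p n da` on the deformed surface; facet orientation is outward by
  construction.
* **Residual.** Internal forces from the total second Piola–Kirchhoff
  stress; the multiplier rows carry `−∫ M (J−1) dV`. The sign makes the
  coupled tangent exactly symmetric whenever the boundary of the
  pressurised surface is fixed (ventricle problems); the beam's tangent
  is asymmetric because its follower load's patch boundary moves.
* **Tangent.** Analytic element blocks: first-elasticity-tensor form
  `A_iKjL = δ_ij S_KL + F_iM (dS/dE)_MKNL F_jN` for the displacement
  block, `−J F⁻ᵀ M_b` coupling blocks, zero multiplier block; the
  follower-load block is differentiated by complex step. `dS/dE` is
  analytic for the unsplit law and complex-step (exact to double
  precision) for the split path. An independent full complex-step tangent
  of the element residuals is kept and the two routes are required to
  agree to ~1e−13 in the tests; the directional-derivative remainder is
  verified to be O(h²).
* **Constraints.** Dirichlet rows/columns are eliminated (reduction, not
  penalty), so fixed nodes are exact; per-component constraints with
  nonzero values are supported (used by the uniaxial closed-form test)
  and ramped with the load factor.
* **Newton / continuation.** Full Newton, sparse non-symmetric direct
  factorisation (SuperLU, COLAMD) at every iteration; convergence at
  residual 2-norm < 10⁻⁸ mN absolute or 10⁻⁹ relative to the step's
  initial residual. Loads (pressures, T_a, prescribed displacements) ramp
  by a common factor λ: 10 equal steps for problems 1–2, 20 for problem 3,
  with step halving on failure (limit 6). Per-step logs record λ,
  iteration count, residual history and the pointwise incompressibility
  error.

## Verification harness

Material points are tracked by locating the containing element in the
undeformed mesh (inverse isoparametric map: local Newton from the element
centre, 30-iteration cap, 10⁻¹² local tolerance, axis-aligned bounding-box
prefilter) and evaluating the same element of the deformed mesh at those
local coordinates. Points on shared faces resolve to the lowest element
id; mesh nodes (including the collapsed apex, where the inverse map is
singular) are matched directly. Exact-surface sample points can fall
slightly outside a coarse mesh because linear elements chord the curved
wall; within a caller-set physical tolerance the nearest element is
accepted and the (unclamped) local coordinates are used, so the forward
map still reproduces the reference point exactly.

Strains are finite-difference length changes of tracked point pairs in
percent. Beam: pairs along (x, 0.5, 0.5) for axial strain and offsets to
(x, 0.9, 0.5) / (x, 0.5, 0.9) for transverse strain. Ventricle:
apex-to-base lines at parametric depths t ∈ {0.1, 0.5, 0.9} with
`u_i = u₁ + (u₂−u₁)/10 · (i+1) · 0.95` (the 0.95 factor keeps the points
off the apex and base and is applied exactly as stated in the problem
definition); longitudinal strain pairs neighbours along a line,
circumferential strain pairs each point with its v = π/10 rotated copy,
and radial strain pairs endo–mid, mid–epi and endo–epi points, reported
at the endocardium, epicardium and midwall respectively. Comparison
reports give per-point and aggregate displacement differences, absolute
(mm) and relative to the larger of the two displacement magnitudes at the
point; both max and mean are exposed since "typical difference" admits
either reading.

## Reporting resolutions and problem sizes

The suite's reporting choices, balancing discretisation quality against
run time: beam order-1 8×2×2 and 16×4×4, order-2 8×2×2; ventricle
inflation order-2 (n_u, n_v, n_t) = (6,12,2) and (9,18,3) (≈ 14k
unknowns); active contraction order-2 (4,8,2). Circumferential divisions
divisible by 4 make the meshes exactly symmetric under quarter-turn
rotation, and the solved ventricle deformations are required to reproduce
that symmetry to better than 1e−8 mm (they reach round-off in practice).

## Numerical choices and conventions

* Units mm–kPa–mN throughout; no conversions anywhere.
* Complex-step size 1e−200 (derivatives exact to double precision).
* VTK output: legacy ASCII, 17 significant digits, fixed ordering — 
  byte-identical files for identical runs; quadratic elements are written
  as 8 linear sub-hexahedra using their own nodes (no new interpolation
  error at nodes); tagged surfaces ride along as quad cells with an
  integer `surface_id` array.
* Cavity volume by the divergence theorem over the deformed endocardial
  facets plus a triangle fan over the basal ring.

## Known limitations

* **Pointwise incompressibility.** The multiplier enforces `J = 1`
  weakly. The *maximum* quadrature-point |J−1| of a converged solution is
  dominated by the clamped-edge (beam) and apex (ventricle) stress
  concentrations and does not converge pointwise under refinement, while
  median values are several orders of magnitude smaller; per-solve logs
  report the maximum. Tightening the pointwise maximum below ~1e−3 at
  these load levels is not achievable with these element pairs at
  practical resolutions.
* **Trilinear bending accuracy.** Q1P0 shear-locks on the
  bending-dominated beam; its key-point displacement converges only
  ~O(h^1.5) toward the order-2 solution, so order-1/order-2 agreement at
  the percent level requires very fine order-1 meshes. The order-2
  solution at 8×2×2 already matches published consensus values of the
  deformed tip position.
* The active stress is applied everywhere, including the apical
  degenerate elements; codes that regularise the apex with a passive
  isotropic patch will differ most in apical strains.
* Out of scope: dynamics and inertia, fluid–structure and hemodynamic
  coupling, orthotropic laws, length/velocity-dependent active tension,
  time-dependent cardiac cycles, image-based personalisation.
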
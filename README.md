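# cardiobench

Verification benchmarks for cardiac mechanics solvers: a self-contained
nonlinear finite-element implementation of three canonical problems —
bending of a transversely isotropic beam under a follower pressure, passive
inflation of a truncated-ellipsoid left ventricle, and inflation combined
with active contraction through a rule-based transmural fibre field —
plus the point-tracking harness used to compare any two solutions
(deformed key points, line deformations, finite-difference strain
profiles).

It is intended for developers of cardiac (and general soft-tissue)
mechanics codes who need reproducible reference solutions and a neutral
comparison tool: the geometries are analytic, the fibre field is given in
closed form, and solutions are exchanged as VTK unstructured grids, so any
solver can be checked against the same problems.

## The model

Quasi-static finite-deformation equilibrium of an incompressible solid:

    div σ = 0,     J = det F = 1,     J F⁻¹ σ F⁻ᵀ = T = ∂W/∂E,

with `F = ∂x/∂X`, Green–Lagrange strain `E = ½(FᵀF − I)`, and the
transversely isotropic Guccione strain energy in fibre coordinates
(fibres along e₁):

    W = C/2 (e^Q − 1),
    Q = b_f E₁₁² + b_t (E₂₂² + E₃₃² + E₂₃² + E₃₂²)
      + b_fs (E₁₂² + E₂₁² + E₁₃² + E₃₁²).

Active contraction adds a constant second Piola–Kirchhoff fibre tension,
`T = T_p + T_a f fᵀ`, and incompressibility is enforced exactly with a
Lagrange-multiplier field (total stress includes `−p J C⁻¹`). All pressure
loads are followers: direction and magnitude track the deformed surface.

The three problems (units mm / kPa / mN):

| # | geometry | material | loading | constraints |
|---|----------|----------|---------|-------------|
| 1 | beam [0,10]×[0,1]×[0,1], fibres (1,0,0) | C=2, b_f=8, b_t=2, b_fs=4 | 0.004 kPa on the bottom face | left face fixed |
| 2 | truncated ellipsoid (endo rs=7, rl=17; epi rs=10, rl=20; base z=5) | isotropic C=10, b=1 | 10 kPa endocardial | base fixed |
| 3 | same ellipsoid, fibre angle α(t)=90−180t degrees across the wall | C=2, b_f=8, b_t=2, b_fs=4 | 15 kPa endocardial + T_a=60 kPa | base fixed |

Discretisations: structured hexahedral meshes built in the analytic
parametric coordinates (the apex ring is collapsed), with Q1P0 (trilinear
displacement, element-constant multiplier) or Q2Q1 Taylor–Hood-style
(triquadratic displacement, continuous trilinear multiplier) mixed pairs,
full Newton with an exact consistent tangent, and load continuation with
adaptive step halving.

## Worked example

Solve the beam problem with quadratic elements and track its canonical
key point, the corner (10, 0.5, 1):

```
$ cardiobench solve --problem 1 --resolution 8,2,2 --order 2 --out run_beam
problem 1 solved: 1281 dofs, max|J-1|=2.63e-02, archive in run_beam
```

```python
>>> import cardiobench as cb
>>> sol = cb.solve_benchmark(1, (8, 2, 2), order=2)
>>> cb.track_point(sol.problem.mesh, sol.deformed_points, (10.0, 0.5, 1.0)).x
array([9.17812961, 0.5       , 4.16527228])
```

The beam tip rises from z = 1 to z ≈ 4.165 mm under the 0.004 kPa
follower pressure — the upward large-deflection bending that this problem
is designed to exhibit, with the deformed tip at (9.178, 0.5, 4.165).
`max|J-1|` is the worst pointwise incompressibility error over the
quadrature points (the multiplier enforces the constraint weakly; the
median error is orders of magnitude smaller).

For the ventricle problems:

```python
>>> sol2 = cb.solve_benchmark(2, (6, 12, 2), order=2)   # passive inflation
>>> cb.track_point(sol2.problem.mesh, sol2.deformed_points, (0.0, 0.0, -17.0)).x
array([...,  ..., -26.7187982 ])
>>> cb.cavity_volume(sol2.problem.mesh), cb.cavity_volume(sol2.problem.mesh, sol2.deformed_points)
(2489.04..., 10729.57...)
```

The endocardial apex moves from z = −17 to z ≈ −26.72 mm and the cavity
volume roughly quadruples at 10 kPa. Problem 3 instead *shortens* the
ventricle (the apex rises) and twists it about the z axis.

Strain profiles and pairwise comparisons:

```
cardiobench strain  --undeformed run_beam/undeformed.vtk --deformed run_beam/deformed.vtk \
                    --problem 1 --out strain.csv
cardiobench compare run_beam other_solvers_run --problem 1 --out report.json
```

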
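"""Incompressible finite-deformation equilibrium solver for the benchmarks.

Mixed displacement/multiplier finite elements in a total Lagrangian
setting: trilinear displacement with an element-constant multiplier (Q1P0)
for order-1 meshes, triquadratic displacement with a continuous trilinear
multiplier (Taylor-Hood style Q2Q1) for order-2 meshes.  Pressure loads are
followers: the traction is -p n da on the deformed surface, integrated on
the reference surface through the deformed tangent vectors.

The residual carries the internal forces from the total second
Piola-Kirchhoff stress, the (negated) incompressibility residual
-int M (J-1) dV on the multiplier rows, and the follower loads.  The
tangent is the consistent linearisation of this residual: analytic
material/geometric/coupling blocks plus a complex-step follower-load
block, with a full complex-step tangent of the element residuals kept as
an independent oracle (the two agree to machine precision).  It is
asymmetric in general (beam problem) and symmetric, after eliminating the
fixed dofs, when the boundary of the pressurised surface is fixed
(ventricle problems).

Load continuation ramps the applied pressures and the active tension by a
common factor lambda in [0, 1], with adaptive step halving on Newton
failure.  Units are mm / kPa / mN throughout.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements
from .constitutive import (
    ActiveParams,
    MaterialParams,
    material_tangent,
    total_second_pk_from_E,
)
from .geometry import (
    BeamSpec,
    EllipsoidSpec,
    FibreField,
    FibreRule,
    ReferenceMesh,
    attach_fibres,
    generate_beam_mesh,
    generate_ventricle_mesh,
)

logger = logging.getLogger("cardiobench.solver")


class _EBasisShim:
    """Minimal state carrying E and the fibre basis for material_tangent."""

    def __init__(self, E, basis):
        self.E = E
        self.basis = basis

_CSTEP = 1e-200  # complex-step size; exact to double precision


class InvertedElementError(RuntimeError):
    pass


class SingularSystemError(RuntimeError):
    pass


class NonConvergenceError(RuntimeError):
    def __init__(self, message, last_lambda=0.0, history=None):
        super().__init__(message)
        self.last_lambda = last_lambda
        self.history = history or []


@dataclass(frozen=True)
class PressureLoad:
    """Follower pressure of given magnitude (kPa) on a tagged surface."""

    tag: str
    magnitude: float


@dataclass(frozen=True)
class SolverConfig:
    tol_abs: float = 1e-8         # mN, residual 2-norm
    tol_rel: float = 1e-9
    max_iterations: int = 25
    n_steps: int = 10
    max_halvings: int = 6
    linear_solver: str = "spsolve"

    def __post_init__(self):
        if self.tol_abs <= 0 or self.tol_rel <= 0:
            raise ValueError("tolerances must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class ProblemDefinition:
    """A benchmark problem: mesh + fibres, material, loads and constraints.

    dirichlet: (n_bc, 2) int array of (node, component) rows plus a value
    per row (zero for the canonical problems).  Every canonical problem
    fixes all three components of its constrained nodes.
    """

    mesh: ReferenceMesh
    fibres: FibreField
    material: MaterialParams
    active: ActiveParams = field(default_factory=ActiveParams)
    dirichlet_dofs: np.ndarray = None  # (n_bc, 2): node, component
    dirichlet_values: np.ndarray = None
    pressures: list[PressureLoad] = field(default_factory=list)
    split: bool = False
    problem_id: int | None = None

    def __post_init__(self):
        if self.dirichlet_dofs is None or len(self.dirichlet_dofs) == 0:
            raise SingularSystemError("empty Dirichlet set: system would be singular")
        self.dirichlet_dofs = np.asarray(self.dirichlet_dofs, dtype=int)
        if self.dirichlet_values is None:
            self.dirichlet_values = np.zeros(len(self.dirichlet_dofs))
        for load in self.pressures:
            if load.tag not in self.mesh.surface_tags:
                raise ValueError(f"pressure surface '{load.tag}' is not a tagged boundary")


def fix_nodes(nodes: np.ndarray) -> np.ndarray:
    """All-components Dirichlet rows for a node set."""
    nodes = np.asarray(nodes, dtype=int)
    return np.stack(
        [np.repeat(nodes, 3), np.tile(np.arange(3), len(nodes))], axis=-1
    )


@dataclass
class State:
    """Iterate of the discrete system: displacements, multiplier, load."""

    u: np.ndarray       # (n_nodes, 3)
    p: np.ndarray       # (n_multiplier_dofs,)
    lam: float = 1.0


@dataclass
class Solution:
    """Converged solution with the per-load-step convergence log."""

    problem: ProblemDefinition
    state: State
    log: list
    n_dofs: int

    @property
    def deformed_points(self) -> np.ndarray:
        return self.problem.mesh.points + self.state.u

    @property
    def deformed_mesh(self) -> ReferenceMesh:
        return self.problem.mesh.with_points(self.deformed_points)

    @property
    def max_incompressibility_error(self) -> float:
        return self.log[-1]["max_J_err"] if self.log else 0.0


class DiscreteSystem:
    """Vectorised assembly of the mixed residual and complex-step tangent."""

    def __init__(self, problem: ProblemDefinition):
        self.problem = problem
        mesh = problem.mesh
        order = mesh.order
        self.mesh = mesh
        qp, wq = elements.volume_quadrature(order)
        _, dN = elements.shape_functions(order, qp)
        Xe = mesh.points[mesh.cells]
        Jg = np.einsum("qak,eai->eqik", dN, Xe)
        detJ = np.linalg.det(Jg)
        if np.any(detJ <= 0):
            raise InvertedElementError("reference mesh has non-positive Jacobians")
        Jinv = np.linalg.inv(Jg)
        self.gradN = np.einsum("qam,eqmi->eqai", dN, Jinv)  # dN/dX
        self.wdet = wq[None, :] * detJ
        self.qp = qp
        self.basis = problem.fibres.basis_at(qp)  # (nel, nq, 3, 3)

        nn = mesh.n_nodes
        nel = mesh.n_cells
        self.n_u = 3 * nn
        if order == 1:
            self.M = np.ones((qp.shape[0], 1))
            self.p_elem = np.arange(nel)[:, None]
            self.n_p = nel
        else:
            cidx = elements.corner_indices(order)
            corner_nodes = mesh.cells[:, cidx]
            uniq, inv = np.unique(corner_nodes, return_inverse=True)
            self.M, _ = elements.shape_functions(1, qp)
            self.p_elem = inv.reshape(corner_nodes.shape)
            self.n_p = uniq.size
        self.n_dofs = self.n_u + self.n_p

        # element dof map: u dofs then p dofs
        udofs = (3 * mesh.cells[:, :, None] + np.arange(3)[None, None, :]).reshape(nel, -1)
        self.edofs = np.concatenate([udofs, self.n_u + self.p_elem], axis=1)
        self.ndof_el = self.edofs.shape[1]
        self.nn_el = mesh.cells.shape[1]
        self._Krows = np.repeat(self.edofs, self.ndof_el, axis=1).ravel()
        self._Kcols = np.tile(self.edofs, (1, self.ndof_el)).ravel()

        # follower-load facet groups, one per (load, local face id)
        nfq = order + 2  # one order above the volume rule
        self.facet_groups = []
        for load in problem.pressures:
            facets = mesh.surface_tags[load.tag]
            for face_id in np.unique(facets[:, 1]):
                sel = facets[facets[:, 1] == face_id]
                fidx = elements.face_node_indices(order, int(face_id))
                fnodes = mesh.cells[sel[:, 0]][:, fidx]  # (nf, nfn)
                st, wf = elements.face_quadrature(nfq)
                N2, dN2 = elements.face_shape_functions(order, int(face_id), st)
                gdofs = (3 * fnodes[:, :, None] + np.arange(3)).reshape(len(sel), -1)
                self.facet_groups.append(
                    {
                        "magnitude": load.magnitude,
                        "fnodes": fnodes,
                        "gdofs": gdofs,
                        "N": N2,
                        "dN": dN2,
                        "w": wf,
                    }
                )

        # Dirichlet bookkeeping
        bc = problem.dirichlet_dofs
        self.bc_dofs = 3 * bc[:, 0] + bc[:, 1]
        if np.unique(self.bc_dofs).size != self.bc_dofs.size:
            # duplicated rows are harmless but keep the map unique
            _, keep = np.unique(self.bc_dofs, return_index=True)
            self.bc_dofs = self.bc_dofs[keep]
            self.problem.dirichlet_values = problem.dirichlet_values[keep]
        self.free = np.ones(self.n_dofs, dtype=bool)
        self.free[self.bc_dofs] = False

    # -- element-level kernels ------------------------------------------------

    def _element_residuals(self, u_el, p_el, lam):
        """Residual contributions per element, shape (nel, ndof_el).

        Accepts complex arrays (for complex-step tangents).
        """
        pr = self.problem
        F = np.einsum("eai,eqaK->eqiK", u_el, self.gradN)
        F = F + np.eye(3)
        J = np.linalg.det(F)
        if not np.iscomplexobj(F) and np.any(np.real(J) <= 0.0):
            bad = int(np.argwhere(np.any(np.real(J) <= 0, axis=1))[0, 0])
            raise InvertedElementError(f"inverted element {bad} during assembly")
        E = 0.5 * (np.einsum("eqiK,eqiL->eqKL", F, F) - np.eye(3))
        p_q = np.einsum("qb,eb->eq", self.M, p_el)
        S = total_second_pk_from_E(
            E, self.basis, pr.material, ActiveParams(pr.active.T_a * lam), p_q,
            split=pr.split,
        )
        P = np.einsum("eqiM,eqMK->eqiK", F, S)
        r_u = np.einsum("eq,eqiK,eqaK->eai", self.wdet, P, self.gradN)
        r_p = -np.einsum("eq,eq,qb->eb", self.wdet, J - 1.0, self.M)
        return np.concatenate([r_u.reshape(len(u_el), -1), r_p], axis=1)

    def _facet_forces(self, group, x_nodes):
        """External follower nodal forces per facet, (nf, nfn, 3)."""
        xf = x_nodes[group["fnodes"]]
        ds = np.einsum("qa,fai->fqi", group["dN"][..., 0], xf)
        dt = np.einsum("qa,fai->fqi", group["dN"][..., 1], xf)
        nvec = np.cross(ds, dt)  # outward, area-weighted
        return -group["magnitude"] * np.einsum("q,qa,fqi->fai", group["w"], group["N"], nvec)

    def quadrature_J(self, state: State):
        """det F at every volume quadrature point, (nel, nq)."""
        u_el = state.u[self.mesh.cells]
        F = np.einsum("eai,eqaK->eqiK", u_el, self.gradN) + np.eye(3)
        return np.linalg.det(F)

    # -- global assembly ------------------------------------------------------

    def residual(self, state: State) -> np.ndarray:
        mesh = self.mesh
        r_el = self._element_residuals(state.u[mesh.cells], state.p[self.p_elem], state.lam)
        R = np.zeros(self.n_dofs)
        np.add.at(R, self.edofs.ravel(), r_el.ravel())
        x = mesh.points + state.u
        for group in self.facet_groups:
            fext = state.lam * self._facet_forces(group, x)
            np.subtract.at(R, group["gdofs"].ravel(), fext.reshape(len(fext), -1).ravel())
        return R

    def _volume_element_tangents(self, state: State) -> np.ndarray:
        """Analytic element tangent blocks (nel, ndof_el, ndof_el):
        material + volumetric (dS/dE), geometric (S), and the
        multiplier-coupling blocks; the follower-load block is handled
        separately on the facets."""
        pr = self.problem
        mesh = self.mesh
        nel = mesh.n_cells
        u_el = state.u[mesh.cells]
        p_el = state.p[self.p_elem]
        G = self.gradN  # (e,q,a,K)
        F = np.einsum("eai,eqaK->eqiK", u_el, G) + np.eye(3)
        J = np.linalg.det(F)
        if np.any(J <= 0.0):
            raise InvertedElementError("inverted element during tangent assembly")
        Finv = np.linalg.inv(F)
        E = 0.5 * (np.einsum("eqiK,eqiL->eqKL", F, F) - np.eye(3))
        p_q = np.einsum("qb,eb->eq", self.M, p_el)
        active = ActiveParams(pr.active.T_a * state.lam)
        S = total_second_pk_from_E(E, self.basis, pr.material, active, p_q, split=pr.split)
        dSdE, dSdp = material_tangent(
            _EBasisShim(E, self.basis), pr.material, active, p_q, split=pr.split
        )
        dSdE = 0.5 * (dSdE + np.swapaxes(dSdE, -1, -2))  # minor symmetry (N,L)

        w = self.wdet
        nn = self.nn_el
        # material part: K[a,i,b,j] = sum_q w G_aK F_iM dSdE_MKNL F_jN G_bL
        T1 = np.einsum("eqiM,eqMKNL->eqiKNL", F, dSdE)
        T2 = np.einsum("eqiKNL,eqjN->eqiKjL", T1, F)
        B1 = np.einsum("eqaK,eqiKjL->eqaijL", G, T2)
        # batched GEMM over the combined (q, L) axis
        B1m = B1.transpose(0, 2, 3, 4, 1, 5).reshape(nel, nn * 9, -1)   # (e, aij, qL)
        Gm = (w[..., None, None] * G).transpose(0, 2, 1, 3).reshape(nel, nn, -1)  # (e, b, qL)
        Km = B1m @ np.swapaxes(Gm, 1, 2)                                # (e, aij, b)
        K_mat = Km.reshape(nel, nn, 3, 3, nn).transpose(0, 1, 2, 4, 3)  # (e,a,i,b,j)
        # geometric part: delta_ij sum_q w G_aK S_KL G_bL
        GS = np.einsum("eq,eqaK,eqKL->eqaL", w, G, S)
        K_geo_ab = np.einsum("eqaL,eqbL->eab", GS, G)
        # coupling: K_up[a,i,b] = sum_q w (F dSdp)_iK G_aK M_b ( = -w J Finv^T )
        FdSdp = np.einsum("eqiM,eqMK->eqiK", F, dSdp)
        K_up = np.einsum("eq,eqiK,eqaK,qb->eaib", w, FdSdp, G, self.M)

        ndof = self.ndof_el
        K_el = np.zeros((nel, ndof, ndof))
        nu = 3 * nn
        Kuu = K_mat + np.einsum("eab,ij->eaibj", K_geo_ab, np.eye(3))
        K_el[:, :nu, :nu] = Kuu.reshape(nel, nu, nu)
        K_el[:, :nu, nu:] = K_up.reshape(nel, nu, -1)
        K_el[:, nu:, :nu] = K_up.reshape(nel, nu, -1).swapaxes(1, 2)
        return K_el

    def tangent(self, state: State, *, method: str = "analytic") -> sp.csr_matrix:
        """Consistent tangent.  ``method='cstep'`` differentiates the
        element residuals by complex step instead of using the analytic
        blocks; both agree to machine precision (tested) - the complex-step
        route serves as an independent oracle."""
        mesh = self.mesh
        nel = mesh.n_cells
        if method == "analytic":
            K_el = self._volume_element_tangents(state)
        else:
            u_el0 = state.u[mesh.cells].astype(complex)
            p_el0 = state.p[self.p_elem].astype(complex)
            K_el = np.empty((nel, self.ndof_el, self.ndof_el))
            h = _CSTEP
            nu = 3 * self.nn_el
            for d in range(self.ndof_el):
                u_el = u_el0.copy()
                p_el = p_el0.copy()
                if d < nu:
                    u_el[:, d // 3, d % 3] += 1j * h
                else:
                    p_el[:, d - nu] += 1j * h
                K_el[:, :, d] = self._element_residuals(u_el, p_el, state.lam).imag / h
        data = [K_el.ravel()]
        rows = [self._Krows]
        cols = [self._Kcols]
        h = _CSTEP
        x0 = (mesh.points + state.u).astype(complex)
        for group in self.facet_groups:
            nf, nfn = group["fnodes"].shape
            Kf = np.empty((nf, 3 * nfn, 3 * nfn))
            for d in range(3 * nfn):
                xf = x0[group["fnodes"]].copy()
                xf[:, d // 3, d % 3] += 1j * h
                ds = np.einsum("qa,fai->fqi", group["dN"][..., 0], xf)
                dt = np.einsum("qa,fai->fqi", group["dN"][..., 1], xf)
                nvec = np.cross(ds, dt)
                fext = -group["magnitude"] * np.einsum(
                    "q,qa,fqi->fai", group["w"], group["N"], nvec
                )
                Kf[:, :, d] = -state.lam * fext.reshape(nf, -1).imag / h
            data.append(Kf.ravel())
            rows.append(np.repeat(group["gdofs"], 3 * nfn, axis=1).ravel())
            cols.append(np.tile(group["gdofs"], (1, 3 * nfn)).ravel())
        K = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dofs, self.n_dofs),
        )
        return K.tocsr()

    def apply_dirichlet(self, K: sp.csr_matrix, R: np.ndarray):
        """Reduce the system to the free dofs (row/column elimination)."""
        free = self.free
        return K[free][:, free], R[free]

    def initial_state(self, lam: float = 0.0) -> State:
        u = np.zeros((self.mesh.n_nodes, 3))
        bc = self.problem.dirichlet_dofs
        u[bc[:, 0], bc[:, 1]] = lam * self.problem.dirichlet_values
        return State(u=u, p=np.zeros(self.n_p), lam=lam)

    def set_dirichlet(self, state: State):
        bc = self.problem.dirichlet_dofs
        state.u[bc[:, 0], bc[:, 1]] = state.lam * self.problem.dirichlet_values


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def assemble_residual(problem: ProblemDefinition, state: State) -> np.ndarray:
    return DiscreteSystem(problem).residual(state)


def assemble_tangent(problem: ProblemDefinition, state: State) -> sp.csr_matrix:
    return DiscreteSystem(problem).tangent(state)


def apply_dirichlet(system: DiscreteSystem, K, R):
    return system.apply_dirichlet(K, R)


# ---------------------------------------------------------------------------
# Newton and continuation


def newton_solve(system: DiscreteSystem, config: SolverConfig, state: State):
    """Full Newton iteration at fixed load factor.

    Returns (state, info); info['converged'] reports success and
    info['residuals'] the 2-norm history on the free dofs.
    """
    state = State(u=state.u.copy(), p=state.p.copy(), lam=state.lam)
    system.set_dirichlet(state)
    history = []
    ref = None
    for it in range(config.max_iterations + 1):
        try:
            R = system.residual(state)
        except InvertedElementError:
            return state, {"converged": False, "residuals": history, "iterations": it}
        rnorm = float(np.linalg.norm(R[system.free]))
        history.append(rnorm)
        if ref is None:
            ref = rnorm
        if rnorm < config.tol_abs or rnorm < config.tol_rel * ref:
            return state, {"converged": True, "residuals": history, "iterations": it}
        if not np.isfinite(rnorm) or it == config.max_iterations:
            return state, {"converged": False, "residuals": history, "iterations": it}
        K = system.tangent(state)
        Kff, Rf = system.apply_dirichlet(K, R)
        try:
            delta = spla.spsolve(Kff.tocsc(), -Rf)
        except RuntimeError as exc:  # singular factorisation
            raise SingularSystemError(str(exc)) from exc
        if not np.all(np.isfinite(delta)):
            return state, {"converged": False, "residuals": history, "iterations": it}
        du = np.zeros(system.n_dofs)
        du[system.free] = delta
        state.u += du[: system.n_u].reshape(-1, 3)
        state.p += du[system.n_u:]
    return state, {"converged": False, "residuals": history, "iterations": config.max_iterations}


def solve_with_continuation(problem: ProblemDefinition, config: SolverConfig | None = None) -> Solution:
    """Ramp pressures, active tension and Dirichlet values by a common
    factor lambda from 0 to 1, halving increments on Newton failure."""
    config = config or SolverConfig()
    system = DiscreteSystem(problem)
    state = system.initial_state(0.0)
    log = []
    lam = 0.0
    step = 1.0 / config.n_steps
    halvings = 0
    t0 = time.time()
    while lam < 1.0 - 1e-12:
        target = min(lam + step, 1.0)
        trial = State(u=state.u.copy(), p=state.p.copy(), lam=target)
        trial, info = newton_solve(system, config, trial)
        if info["converged"]:
            state = trial
            lam = target
            maxJ = float(np.max(np.abs(system.quadrature_J(state) - 1.0)))
            log.append(
                {
                    "lambda": lam,
                    "iterations": info["iterations"],
                    "residuals": info["residuals"],
                    "max_J_err": maxJ,
                    "wall_s": time.time() - t0,
                }
            )
            logger.info(
                "lambda=%.4f converged in %d iterations, |R|=%.3e, max|J-1|=%.2e",
                lam, info["iterations"], info["residuals"][-1], maxJ,
            )
        else:
            halvings += 1
            step /= 2.0
            logger.info("lambda=%.4f failed, halving step to %.4g", target, step)
            if halvings > config.max_halvings:
                raise NonConvergenceError(
                    f"halving limit exhausted; last converged lambda={lam:.4f}",
                    last_lambda=lam,
                    history=log,
                )
    return Solution(problem=problem, state=state, log=log, n_dofs=int(np.sum(system.free)))


# ---------------------------------------------------------------------------
# canonical problems


def make_benchmark_problem(
    problem_id: int,
    resolution: tuple[int, int, int] | None = None,
    order: int = 1,
) -> ProblemDefinition:
    """Build the canonical problem definition (exact benchmark parameters)."""
    if problem_id == 1:
        res = resolution or (8, 2, 2)
        mesh = generate_beam_mesh(BeamSpec(*res, order=order))
        fib = attach_fibres(mesh)
        return ProblemDefinition(
            mesh=mesh,
            fibres=fib,
            material=MaterialParams(C_mat=2.0, b_f=8.0, b_t=2.0, b_fs=4.0),
            active=ActiveParams(0.0),
            dirichlet_dofs=fix_nodes(mesh.surface_nodes("left")),
            pressures=[PressureLoad("bottom", 0.004)],
            split=False,
            problem_id=1,
        )
    if problem_id == 2:
        res = resolution or (4, 8, 2)
        mesh = generate_ventricle_mesh(EllipsoidSpec(*res, order=order))
        fib = attach_fibres(mesh)
        return ProblemDefinition(
            mesh=mesh,
            fibres=fib,
            material=MaterialParams(C_mat=10.0, b_f=1.0, b_t=1.0, b_fs=1.0),
            active=ActiveParams(0.0),
            dirichlet_dofs=fix_nodes(mesh.surface_nodes("base")),
            pressures=[PressureLoad("endocardium", 10.0)],
            split=True,
            problem_id=2,
        )
    if problem_id == 3:
        res = resolution or (4, 8, 2)
        spec = EllipsoidSpec(*res, order=order)
        mesh = generate_ventricle_mesh(spec)
        fib = attach_fibres(mesh, FibreRule(spec=spec))
        return ProblemDefinition(
            mesh=mesh,
            fibres=fib,
            material=MaterialParams(C_mat=2.0, b_f=8.0, b_t=2.0, b_fs=4.0),
            active=ActiveParams(60.0),
            dirichlet_dofs=fix_nodes(mesh.surface_nodes("base")),
            pressures=[PressureLoad("endocardium", 15.0)],
            split=True,
            problem_id=3,
        )
    raise ValueError("problem_id must be 1, 2 or 3")


def default_config(problem_id: int) -> SolverConfig:
    return SolverConfig(n_steps=20 if problem_id == 3 else 10)


def solve_benchmark(
    problem_id: int,
    resolution: tuple[int, int, int] | None = None,
    order: int = 1,
    config: SolverConfig | None = None,
) -> Solution:
    problem = make_benchmark_problem(problem_id, resolution, order)
    return solve_with_continuation(problem, config or default_config(problem_id))


# ---------------------------------------------------------------------------
# cavity volume


def surface_flux_volume(facet_nodes: np.ndarray, points: np.ndarray, order: int, face_id_hint=None):
    """(1/3) oint x . n da over oriented facets (n is the facet orientation
    normal; the caller is responsible for closing the surface)."""
    nfq = order + 2
    st, wf = elements.face_quadrature(nfq)
    # all facets share the same node layout as face 5 (zeta=+1) topology:
    # use a generic 2D Lagrange basis on the (o+1)^2 grid in facet ordering
    N2, dN2 = elements.face_shape_functions(order, 5 if face_id_hint is None else face_id_hint, st)
    xf = points[facet_nodes]
    x_q = np.einsum("qa,fai->fqi", N2, xf)
    ds = np.einsum("qa,fai->fqi", dN2[..., 0], xf)
    dt = np.einsum("qa,fai->fqi", dN2[..., 1], xf)
    nvec = np.cross(ds, dt)
    return float(np.einsum("q,fqi,fqi->", wf, x_q, nvec)) / 3.0


def cavity_volume(mesh: ReferenceMesh, points: np.ndarray | None = None) -> float:
    """Volume enclosed by the (possibly deformed) endocardial surface and
    the flat cap spanning the basal endocardial ring, by the divergence
    theorem.  ``points`` defaults to the reference configuration."""
    if "endocardium" not in mesh.surface_tags:
        raise ValueError("mesh has no endocardial surface tag")
    points = mesh.points if points is None else np.asarray(points)
    fnodes = mesh.facet_nodes("endocardium")
    face_id = int(mesh.surface_tags["endocardium"][0, 1])
    # endocardial facets are oriented outward from the wall = into the
    # cavity; flip the sign to get the cavity-outward flux
    v_endo = -surface_flux_volume(fnodes, points, mesh.order, face_id_hint=face_id)
    # cap: fan of triangles over the basal ring, cavity-outward (+z)
    ring = np.intersect1d(mesh.surface_nodes("endocardium"), mesh.surface_nodes("base"))
    ref = mesh.points[ring]
    angle = np.arctan2(ref[:, 1], ref[:, 0])
    ring = ring[np.argsort(angle)]
    r = points[ring]
    c = r.mean(axis=0)
    v_cap = 0.0
    for i in range(len(r)):
        a, b = r[i] - c, r[(i + 1) % len(r)] - c
        n = np.cross(a, b)
        xb = (c + r[i] + r[(i + 1) % len(r)]) / 3.0
        v_cap += xb @ n / 6.0
    return v_endo + v_cap
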
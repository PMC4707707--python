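"""Analytic benchmark geometries: beam, truncated-ellipsoid ventricle, fibres.

The beam occupies [0,10] x [0,1] x [0,1] mm with a constant fibre direction
(1,0,0).  The ventricle is the volume between two truncated ellipsoids,

    x(u, v, t) = (rs(t) sin u cos v,  rs(t) sin u sin v,  rl(t) cos u),

with rs(t) = 7 + 3 t mm and rl(t) = 17 + 3 t mm, where t in [0,1] is the
transmural coordinate (0 = endocardium, 1 = epicardium), u in
[-pi, -arccos(5/rl(t))] runs from the apex to the base plane z = 5 mm, and
v is the circumferential angle.  The myofibre direction rotates linearly
across the wall, alpha(t) = 90 - 180 t degrees, measured from the
circumferential tangent toward the apex-to-base tangent:

    f(u, v) = n(dx/du) sin(alpha) + n(dx/dv) cos(alpha),   n(w) = w/||w||.

Meshes are structured hexahedral lattices built directly in (u, v, t)
parametric space, so every node (and hence every quadrature point, by
interpolation) carries exact parametric coordinates.  The apex ring u = -pi
is collapsed to a single node per transmural layer, giving degenerate
hexahedra whose interior quadrature points keep positive Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elements

APEX_TOL = 1e-10  # ||dx/dv|| < APEX_TOL * rs triggers the apex fibre fallback


class DomainError(ValueError):
    """Parametric coordinates outside the geometry's domain."""


class MeshGenerationError(RuntimeError):
    """A generated element has a non-positive quadrature Jacobian."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class BeamSpec:
    """Structured mesh of the 10 x 1 x 1 mm beam."""

    nx: int = 4
    ny: int = 1
    nz: int = 1
    order: int = 1
    lengths: tuple[float, float, float] = (10.0, 1.0, 1.0)

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("divisions must be >= 1")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")


@dataclass(frozen=True)
class EllipsoidSpec:
    """Structured mesh of the truncated-ellipsoid ventricle wall.

    n_u: apex-to-base divisions, n_v: circumferential, n_t: transmural.
    """

    n_u: int = 4
    n_v: int = 8
    n_t: int = 1
    order: int = 1
    rs_endo: float = 7.0
    rl_endo: float = 17.0
    rs_epi: float = 10.0
    rl_epi: float = 20.0
    z_base: float = 5.0

    def __post_init__(self):
        if self.n_u < 2 or self.n_v < 4 or self.n_t < 1:
            raise ValueError("need n_u >= 2, n_v >= 4, n_t >= 1")
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")

    def rs(self, t):
        return self.rs_endo + (self.rs_epi - self.rs_endo) * t

    def rl(self, t):
        return self.rl_endo + (self.rl_epi - self.rl_endo) * t

    def u_base(self, t):
        """Basal u bound: cos(u) = z_base / rl(t) (negative branch)."""
        return -np.arccos(self.z_base / self.rl(t))


@dataclass(frozen=True)
class FibreRule:
    """Linear transmural fibre-angle rule alpha(t) = alpha_endo + slope*t."""

    alpha_endo_deg: float = 90.0
    alpha_epi_deg: float = -90.0
    spec: EllipsoidSpec = field(default_factory=EllipsoidSpec)

    def alpha_deg(self, t):
        return self.alpha_endo_deg + (self.alpha_epi_deg - self.alpha_endo_deg) * np.asarray(t)


# ---------------------------------------------------------------------------
# analytic geometry


def _check_domain(spec: EllipsoidSpec, u, v, t, wrap_v: bool):
    u, v, t = (np.asarray(a, dtype=float) for a in (u, v, t))
    tol = 1e-9
    if np.any(t < -tol) or np.any(t > 1 + tol):
        raise DomainError("t outside [0, 1]")
    if np.any(u < -np.pi - tol) or np.any(u > spec.u_base(np.clip(t, 0, 1)) + tol):
        raise DomainError("u outside [-pi, -arccos(z_base/rl(t))]")
    if not wrap_v and (np.any(v < -np.pi - tol) or np.any(v > np.pi + tol)):
        raise DomainError("v outside [-pi, pi]")
    return u, v, t


def ellipsoid_point(u, v, t, spec: EllipsoidSpec | None = None):
    """Point on/in the ventricle wall, Cartesian mm.  Broadcasts."""
    spec = spec or EllipsoidSpec()
    u, v, t = _check_domain(spec, u, v, t, wrap_v=False)
    rs, rl = spec.rs(t), spec.rl(t)
    return np.stack(
        [rs * np.sin(u) * np.cos(v), rs * np.sin(u) * np.sin(v), rl * np.cos(u)],
        axis=-1,
    )


def _surface_tangents(u, v, t, spec: EllipsoidSpec):
    """dx/du and dx/dv of the constant-t surface (not normalized)."""
    rs, rl = spec.rs(t), spec.rl(t)
    dxdu = np.stack(
        [rs * np.cos(u) * np.cos(v), rs * np.cos(u) * np.sin(v), -rl * np.sin(u)],
        axis=-1,
    )
    dxdv = np.stack(
        [-rs * np.sin(u) * np.sin(v), rs * np.sin(u) * np.cos(v), np.zeros_like(u)],
        axis=-1,
    )
    return dxdu, dxdv


def _normalize(w, axis=-1):
    return w / np.linalg.norm(w, axis=axis, keepdims=True)


def fibre_direction(u, v, t, rule: FibreRule | None = None, *, _validate: bool = True):
    """Unit fibre vector of the rule-based field.  Broadcasts.

    Away from the apex f = n(dx/du) sin(alpha) + n(dx/dv) cos(alpha); at the
    apex singularity (||dx/dv|| < 1e-10 rs) the pure meridional limit
    f = n(dx/du) * sign(sin alpha) is used (with sign(0) taken as +1), so
    the result is always unit length.
    """
    rule = rule or FibreRule()
    spec = rule.spec
    if _validate:
        u, v, t = _check_domain(spec, u, v, t, wrap_v=False)
    else:
        u, v, t = np.broadcast_arrays(
            *(np.asarray(a, dtype=float) for a in (u, v, t))
        )
    a = np.deg2rad(rule.alpha_deg(t))
    dxdu, dxdv = _surface_tangents(u, v, t, spec)
    sin_a = np.sin(a)[..., None]
    cos_a = np.cos(a)[..., None]
    nu = _normalize(dxdu)
    norm_v = np.linalg.norm(dxdv, axis=-1)
    apex = norm_v < APEX_TOL * spec.rs(t)
    safe = np.where(apex[..., None], 1.0, norm_v[..., None])
    nv = dxdv / safe
    f = nu * sin_a + nv * cos_a
    sgn = np.where(sin_a >= 0.0, 1.0, -1.0)
    f = np.where(apex[..., None], nu * sgn, f)
    return _normalize(f)


def surface_normal(u, v, t, spec: EllipsoidSpec | None = None):
    """Outward unit normal of the constant-t ellipsoid surface.

    Computed from the gradient of the implicit surface function
    (x^2+y^2)/rs^2 + z^2/rl^2 = 1, which stays well defined at the apex.
    """
    spec = spec or EllipsoidSpec()
    x = ellipsoid_point(u, np.mod(np.asarray(v) + np.pi, 2 * np.pi) - np.pi, t, spec)
    rs, rl = spec.rs(np.asarray(t, dtype=float)), spec.rl(np.asarray(t, dtype=float))
    g = np.stack(
        [
            2 * x[..., 0] / rs**2,
            2 * x[..., 1] / rs**2,
            2 * x[..., 2] / rl**2,
        ],
        axis=-1,
    )
    return _normalize(g)


# ---------------------------------------------------------------------------
# meshes


@dataclass
class ReferenceMesh:
    """Hexahedral reference configuration with tagged boundary surfaces.

    points : (n_nodes, 3) mm; cells : (n_el, n_nodes_per_el) node indices;
    surface_tags : tag name -> (n_facets, 2) array of (element, local face);
    param_coords : per-element-node (u, v, t), with v unwrapped within each
    element so it interpolates smoothly across the periodic seam (None for
    the beam).
    """

    points: np.ndarray
    cells: np.ndarray
    order: int
    surface_tags: dict[str, np.ndarray]
    param_coords: np.ndarray | None = None
    constant_fibre: np.ndarray | None = None
    spec: object | None = None

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def with_points(self, points: np.ndarray) -> "ReferenceMesh":
        """Topology-preserving copy with new node coordinates."""
        points = np.asarray(points, dtype=float)
        if points.shape != self.points.shape:
            raise ValueError("point array shape must match")
        return ReferenceMesh(
            points=points,
            cells=self.cells,
            order=self.order,
            surface_tags=self.surface_tags,
            param_coords=self.param_coords,
            constant_fibre=self.constant_fibre,
            spec=self.spec,
        )

    def facet_nodes(self, tag: str) -> np.ndarray:
        """Node indices of each tagged facet, outward-oriented, (n_f, m)."""
        facets = self.surface_tags[tag]
        out = []
        for el, face in facets:
            idx = elements.face_node_indices(self.order, int(face))
            out.append(self.cells[int(el), idx])
        return np.array(out, dtype=int)

    def surface_nodes(self, tag: str) -> np.ndarray:
        """Unique node indices on a tagged surface."""
        return np.unique(self.facet_nodes(tag))

    def evaluate(self, elems, local, points=None):
        """Map element-local coordinates to physical space.

        elems : (k,) element ids; local : (k, 3); points defaults to the
        mesh's own nodes (pass deformed coordinates to evaluate a deformed
        configuration).
        """
        points = self.points if points is None else points
        N, _ = elements.shape_functions(self.order, np.asarray(local, dtype=float))
        return np.einsum("ka,kai->ki", N, points[self.cells[np.asarray(elems, dtype=int)]])

    def check_jacobians(self):
        """Raise MeshGenerationError if any volume quadrature Jacobian <= 0."""
        qp, _ = elements.volume_quadrature(self.order)
        _, dN = elements.shape_functions(self.order, qp)
        Xe = self.points[self.cells]  # (nel, nn, 3)
        J = np.einsum("qak,eai->eqik", dN, Xe)
        det = np.linalg.det(J)
        bad = np.where(np.any(det <= 0.0, axis=1))[0]
        if bad.size:
            raise MeshGenerationError(
                f"non-positive quadrature Jacobian in element(s) {bad[:5].tolist()}"
            )
        return det


def generate_beam_mesh(spec: BeamSpec) -> ReferenceMesh:
    """Structured beam mesh with "left" (x=0) and "bottom" (z=0) tags."""
    o = spec.order
    Lx, Ly, Lz = spec.lengths
    Nx, Ny, Nz = o * spec.nx, o * spec.ny, o * spec.nz
    xs = np.linspace(0.0, Lx, Nx + 1)
    ys = np.linspace(0.0, Ly, Ny + 1)
    zs = np.linspace(0.0, Lz, Nz + 1)

    def nid(ix, iy, iz):
        return ix + (Nx + 1) * (iy + (Ny + 1) * iz)

    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack(
        [X.transpose(2, 1, 0).ravel(), Y.transpose(2, 1, 0).ravel(), Z.transpose(2, 1, 0).ravel()],
        axis=-1,
    )
    trips = elements._node_index_triples(o)
    cells = []
    for ez in range(spec.nz):
        for ey in range(spec.ny):
            for ex in range(spec.nx):
                cells.append([nid(o * ex + i, o * ey + j, o * ez + k) for i, j, k in trips])
    cells = np.array(cells, dtype=int)

    def cell_id(ex, ey, ez):
        return ex + spec.nx * (ey + spec.ny * ez)

    left = np.array([(cell_id(0, ey, ez), 0) for ez in range(spec.nz) for ey in range(spec.ny)])
    bottom = np.array([(cell_id(ex, ey, 0), 4) for ey in range(spec.ny) for ex in range(spec.nx)])
    mesh = ReferenceMesh(
        points=pts,
        cells=cells,
        order=o,
        surface_tags={"left": left, "bottom": bottom},
        constant_fibre=np.array([1.0, 0.0, 0.0]),
        spec=spec,
    )
    mesh.check_jacobians()
    return mesh


def generate_ventricle_mesh(spec: EllipsoidSpec) -> ReferenceMesh:
    """Structured ventricle mesh in (u, v, t) with a collapsed apex.

    Local element axes are (xi, eta, zeta) = (u, t, v), which makes the
    physical Jacobian positive.  Tags: "endocardium" (t=0), "epicardium"
    (t=1), "base" (z = z_base).
    """
    o = spec.order
    Nu, Nv, Nt = o * spec.n_u, o * spec.n_v, o * spec.n_t

    def t_of(it):
        return it / Nt

    def u_of(iu, it):
        t = t_of(it)
        return -np.pi + (spec.u_base(t) + np.pi) * iu / Nu

    def v_of(iv):  # unwrapped
        return -np.pi + 2.0 * np.pi * iv / Nv

    # node ids: apex nodes first (one per t layer), then the (iu, iv, it)
    # lattice with iu >= 1 and iv taken modulo Nv
    def nid(iu, iv, it):
        if iu == 0:
            return it
        return (Nt + 1) + (((iu - 1) * Nv + (iv % Nv)) * (Nt + 1)) + it

    n_nodes = (Nt + 1) * (1 + Nu * Nv)
    pts = np.zeros((n_nodes, 3))
    for it in range(Nt + 1):
        t = t_of(it)
        pts[it] = [0.0, 0.0, -spec.rl(t)]  # apex
        for iu in range(1, Nu + 1):
            u = u_of(iu, it)
            for iv in range(Nv):
                pts[nid(iu, iv, it)] = ellipsoid_point(u, v_of(iv), t, spec)

    trips = elements._node_index_triples(o)
    cells = []
    params = []
    for ev in range(spec.n_v):
        for et in range(spec.n_t):
            for eu in range(spec.n_u):
                conn = []
                par = []
                for i, j, k in trips:  # i->u, j->t, k->v
                    iu = o * eu + i
                    it = o * et + j
                    iv = o * ev + k  # unwrapped
                    conn.append(nid(iu, iv, it))
                    par.append([u_of(iu, it), v_of(iv), t_of(it)])
                cells.append(conn)
                params.append(par)
    cells = np.array(cells, dtype=int)
    params = np.array(params)

    def cell_id(eu, et, ev):
        return eu + spec.n_u * (et + spec.n_t * ev)

    endo = np.array(
        [(cell_id(eu, 0, ev), 2) for ev in range(spec.n_v) for eu in range(spec.n_u)]
    )
    epi = np.array(
        [(cell_id(eu, spec.n_t - 1, ev), 3) for ev in range(spec.n_v) for eu in range(spec.n_u)]
    )
    base = np.array(
        [(cell_id(spec.n_u - 1, et, ev), 1) for ev in range(spec.n_v) for et in range(spec.n_t)]
    )
    mesh = ReferenceMesh(
        points=pts,
        cells=cells,
        order=o,
        surface_tags={"endocardium": endo, "epicardium": epi, "base": base},
        param_coords=params,
        spec=spec,
    )
    mesh.check_jacobians()
    return mesh


# ---------------------------------------------------------------------------
# fibre fields


class FibreField:
    """Orthonormal fibre frame (e1=f, e2=transmural, e3=e1 x e2) evaluable at
    arbitrary element-local points (e.g. quadrature points)."""

    def __init__(self, mesh: ReferenceMesh, rule: FibreRule | None = None):
        self.mesh = mesh
        self.rule = rule

    def basis_at(self, local_pts: np.ndarray) -> np.ndarray:
        """Fibre frames at shared element-local points.

        local_pts : (nq, 3); returns Q of shape (n_el, nq, 3, 3) whose
        columns are (e1, e2, e3).
        """
        mesh = self.mesh
        nq = np.asarray(local_pts).shape[0]
        if mesh.constant_fibre is not None:
            f = mesh.constant_fibre
            Q = np.zeros((mesh.n_cells, nq, 3, 3))
            e1 = f / np.linalg.norm(f)
            # complete with the global axis least aligned with f
            helper = np.eye(3)[np.argmin(np.abs(e1))]
            e2 = helper - e1 * (helper @ e1)
            e2 /= np.linalg.norm(e2)
            e3 = np.cross(e1, e2)
            Q[..., 0], Q[..., 1], Q[..., 2] = e1, e2, e3
            return Q
        if mesh.param_coords is None:
            raise ValueError("mesh carries no parametric coordinates for fibre evaluation")
        rule = self.rule or FibreRule(spec=mesh.spec)
        N, _ = elements.shape_functions(mesh.order, np.asarray(local_pts, dtype=float))
        par = np.einsum("qa,eac->eqc", N, mesh.param_coords)  # (nel, nq, 3)
        u, v, t = par[..., 0], par[..., 1], np.clip(par[..., 2], 0.0, 1.0)
        u = np.minimum(u, rule.spec.u_base(t))  # guard rounding at the base
        f = fibre_direction(u, v, t, rule, _validate=False)
        ns = surface_normal(u, v, t, rule.spec)
        e2 = _normalize(ns - f * np.sum(ns * f, axis=-1, keepdims=True))
        e3 = np.cross(f, e2)
        Q = np.stack([f, e2, e3], axis=-1)
        return Q

    def fibre_at(self, local_pts: np.ndarray) -> np.ndarray:
        return self.basis_at(local_pts)[..., 0]


def attach_fibres(mesh: ReferenceMesh, rule: FibreRule | None = None) -> FibreField:
    """Build the fibre field for a mesh (constant for the beam, rule-based
    from the stored parametric coordinates for the ventricle)."""
    if mesh.constant_fibre is None and mesh.param_coords is None:
        raise ValueError("mesh has neither a constant fibre nor parametric coordinates")
    return FibreField(mesh, rule)
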
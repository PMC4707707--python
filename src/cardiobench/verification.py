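"""Solution comparison harness: point tracking, line extraction, strains.

Deformed locations of material points are found by locating the element
containing the point in the undeformed mesh (inverse isoparametric map,
local Newton iteration with an axis-aligned bounding-box prefilter) and
evaluating the same element of the deformed configuration at the local
coordinates found.  Strains are finite-difference length changes between
tracked point pairs,

    S_i = ( ||x1_i - x2_i|| / ||X1_i - X2_i|| - 1 ) * 100  [%],

evaluated at fixed point sets: for the beam, neighbouring points along the
midline (x, 0.5, 0.5) for axial strain and transverse offsets to
(x, 0.9, 0.5) / (x, 0.5, 0.9); for the ventricle, points along apex-to-base
lines at parametric depths t = 0.1 (endocardial), 0.5 (midwall) and 0.9
(epicardial), with circumferential pairs obtained by rotating each line to
v = pi/10 and radial pairs taken across layers (endo-mid reported at the
endocardium, mid-epi at the epicardium, endo-epi at the midwall).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import elements
from .geometry import EllipsoidSpec, ReferenceMesh, ellipsoid_point

_LOCAL_TOL = 1e-8     # inclusion tolerance in local coordinates
_NEWTON_TOL = 1e-12
_NEWTON_MAXIT = 30


class PointNotFoundError(ValueError):
    def __init__(self, X, nearest_element=None):
        super().__init__(
            f"point {np.asarray(X).tolist()} not inside any element"
            + (f" (nearest element {nearest_element})" if nearest_element is not None else "")
        )
        self.nearest_element = nearest_element


@dataclass
class TrackedPoint:
    X: np.ndarray
    element: int
    local: np.ndarray
    x: np.ndarray


class _Locator:
    """Per-mesh acceleration structures for locate_point."""

    def __init__(self, mesh: ReferenceMesh):
        pts = mesh.points[mesh.cells]
        self.lo = pts.min(axis=1)
        self.hi = pts.max(axis=1)
        self.tree = cKDTree(mesh.points)


def _locator(mesh: ReferenceMesh) -> _Locator:
    loc = mesh.__dict__.get("_locator")
    if loc is None:
        loc = _Locator(mesh)
        mesh.__dict__["_locator"] = loc
    return loc


def _invert_in_element(mesh, elem, X):
    """Local Newton for the inverse isoparametric map; None on failure."""
    Xe = mesh.points[mesh.cells[elem]]
    xi = np.zeros(3)
    for _ in range(_NEWTON_MAXIT):
        N, dN = elements.shape_functions(mesh.order, xi)
        r = X - N @ Xe
        J = np.einsum("ak,ai->ik", dN, Xe)
        try:
            dxi = np.linalg.solve(J, r)
        except np.linalg.LinAlgError:
            return None
        xi = xi + dxi
        if not np.all(np.isfinite(xi)) or np.max(np.abs(xi)) > 4.0:
            return None
        if np.linalg.norm(dxi) < _NEWTON_TOL:
            return xi
    return None


def locate_point(mesh: ReferenceMesh, X, tol: float = 1e-6):
    """Containing element and local coordinates of a physical point.

    When the point lies on a shared face or edge the containing element
    with the lowest id wins.  Mesh nodes are matched directly first, which
    also covers the collapsed-apex elements whose inverse map is singular
    at the apex itself.
    """
    X = np.asarray(X, dtype=float)
    loc = _locator(mesh)
    d, node = loc.tree.query(X)
    if d < _LOCAL_TOL:
        elem = int(np.argwhere(np.any(mesh.cells == node, axis=1))[0, 0])
        a = int(np.argwhere(mesh.cells[elem] == node)[0, 0])
        return elem, elements.local_nodes(mesh.order)[a].copy()
    candidates = np.where(
        np.all(X >= loc.lo - tol, axis=1) & np.all(X <= loc.hi + tol, axis=1)
    )[0]
    best = None
    for elem in candidates:
        xi = _invert_in_element(mesh, int(elem), X)
        if xi is None:
            continue
        excess = np.max(np.abs(xi)) - 1.0
        if excess <= _LOCAL_TOL:
            return int(elem), xi
        # point outside this element; measure the physical distance to it
        # (curved domains chorded by linear elements leave exact-surface
        # points slightly outside the mesh)
        N, _ = elements.shape_functions(mesh.order, np.clip(xi, -1.0, 1.0))
        dist = float(np.linalg.norm(N @ mesh.points[mesh.cells[elem]] - X))
        if best is None or dist < best[0]:
            best = (dist, int(elem), xi)
    if best is not None and best[0] <= tol:
        # accept the nearest element; the unclamped local coordinates keep
        # the forward map exact (smooth isoparametric extrapolation)
        return best[1], best[2]
    raise PointNotFoundError(X, nearest_element=None if best is None else best[1])


def _deformed_points_of(deformed) -> np.ndarray:
    return deformed.points if isinstance(deformed, ReferenceMesh) else np.asarray(deformed)


def track_point(undeformed: ReferenceMesh, deformed, X, tol: float = 1e-6) -> TrackedPoint:
    """Deformed location of the material point X (Lagrangian tracking)."""
    pts = _deformed_points_of(deformed)
    if isinstance(deformed, ReferenceMesh) and not np.array_equal(
        deformed.cells, undeformed.cells
    ):
        raise ValueError("undeformed and deformed meshes must share their topology")
    if pts.shape != undeformed.points.shape:
        raise ValueError("deformed point array does not match the mesh")
    X = np.asarray(X, dtype=float)
    elem, xi = locate_point(undeformed, X, tol=tol)
    N, _ = elements.shape_functions(undeformed.order, xi)
    x = N @ pts[undeformed.cells[elem]]
    return TrackedPoint(X=X, element=elem, local=xi, x=x)


def track_points(undeformed, deformed, Xs, tol: float = 1e-6) -> np.ndarray:
    return np.array(
        [track_point(undeformed, deformed, X, tol=tol).x for X in np.asarray(Xs, dtype=float)]
    )


# ---------------------------------------------------------------------------
# strain profiles


@dataclass
class StrainProfile:
    """Finite-difference strains in percent at the canonical point sets."""

    problem: str
    rows: list = field(default_factory=list)  # (direction, layer, index, value)

    def add(self, direction, layer, index, value):
        self.rows.append((direction, layer, int(index), float(value)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["direction", "layer", "index", "strain_percent"]
        ).assign(problem=self.problem)[
            ["problem", "direction", "layer", "index", "strain_percent"]
        ]

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def values(self, direction, layer=None) -> np.ndarray:
        sel = [
            r[3]
            for r in self.rows
            if r[0] == direction and (layer is None or r[1] == layer)
        ]
        return np.array(sel)


def strain_percent(X1, X2, x1, x2) -> float:
    L0 = np.linalg.norm(np.asarray(X1) - np.asarray(X2))
    L = np.linalg.norm(np.asarray(x1) - np.asarray(x2))
    return (L / L0 - 1.0) * 100.0


def _pair_strains(undeformed, deformed, pairs, tol=1e-6):
    out = []
    for X1, X2 in pairs:
        x1 = track_point(undeformed, deformed, X1, tol=tol).x
        x2 = track_point(undeformed, deformed, X2, tol=tol).x
        out.append(strain_percent(X1, X2, x1, x2))
    return out


def beam_strain_profiles(undeformed: ReferenceMesh, deformed) -> StrainProfile:
    """Axial (x) and transverse (y, z) strains along the beam midline."""
    prof = StrainProfile(problem="beam")
    for i in range(9):
        (s,) = _pair_strains(
            undeformed, deformed, [((i, 0.5, 0.5), (i + 1, 0.5, 0.5))]
        )
        prof.add("x", "", i, s)
    for i in range(10):
        (sy,) = _pair_strains(undeformed, deformed, [((i, 0.5, 0.5), (i, 0.9, 0.5))])
        prof.add("y", "", i, sy)
        (sz,) = _pair_strains(undeformed, deformed, [((i, 0.5, 0.5), (i, 0.5, 0.9))])
        prof.add("z", "", i, sz)
    return prof


_LAYERS = (("endo", 0.1), ("mid", 0.5), ("epi", 0.9))
_N_LINE = 10


def ventricle_line_points(t: float, v: float = 0.0, spec: EllipsoidSpec | None = None):
    """The ten apex-to-base sample points of the strain lines at depth t:
    u_i = u1 + (u2 - u1)/n_u * (i+1) * 0.95 with u1 = -pi and u2 the basal
    u bound at that depth."""
    spec = spec or EllipsoidSpec()
    u1 = -np.pi
    u2 = spec.u_base(t)
    i = np.arange(_N_LINE)
    u = u1 + (u2 - u1) / _N_LINE * (i + 1) * 0.95
    return ellipsoid_point(u, v, t, spec)


def ventricle_strain_profiles(
    undeformed: ReferenceMesh, deformed, spec: EllipsoidSpec | None = None, tol: float = 1.0
) -> StrainProfile:
    """Longitudinal, circumferential and radial strains on the apex-to-base
    lines at the endocardial, midwall and epicardial depths."""
    spec = spec or (undeformed.spec if isinstance(undeformed.spec, EllipsoidSpec) else EllipsoidSpec())
    prof = StrainProfile(problem="ventricle")
    ref = {}
    x = {}
    for name, t in _LAYERS:
        for v, key in ((0.0, name), (np.pi / 10.0, name + "_rot")):
            P = ventricle_line_points(t, v, spec)
            ref[key] = P
            x[key] = track_points(undeformed, deformed, P, tol=tol)
    for name, _t in _LAYERS:
        P, xP = ref[name], x[name]
        for i in range(_N_LINE - 1):
            prof.add("longitudinal", name, i, strain_percent(P[i], P[i + 1], xP[i], xP[i + 1]))
        Q, xQ = ref[name + "_rot"], x[name + "_rot"]
        for i in range(_N_LINE):
            prof.add("circumferential", name, i, strain_percent(P[i], Q[i], xP[i], xQ[i]))
    radial_pairs = (("endo", "endo", "mid"), ("epi", "mid", "epi"), ("mid", "endo", "epi"))
    for report_at, a, b in radial_pairs:
        for i in range(_N_LINE):
            prof.add(
                "radial",
                report_at,
                i,
                strain_percent(ref[a][i], ref[b][i], x[a][i], x[b][i]),
            )
    return prof


# ---------------------------------------------------------------------------
# line deformation


def midwall_line(n_samples: int = 81) -> np.ndarray:
    """Reference midwall line (8.5 sin u, 0, 18.5 cos u) from the apex to
    the base plane."""
    u = np.linspace(-np.pi, -np.arccos(5.0 / 18.5), n_samples)
    return np.stack([8.5 * np.sin(u), np.zeros_like(u), 18.5 * np.cos(u)], axis=-1)


def beam_midline(n_samples: int = 41) -> np.ndarray:
    x = np.linspace(0.0, 10.0, n_samples)
    return np.stack([x, np.full_like(x, 0.5), np.full_like(x, 0.5)], axis=-1)


def line_deformation(undeformed: ReferenceMesh, deformed, line_spec, n_samples: int = 41, tol: float = 1.0):
    """Track a reference polyline; returns (reference, deformed) arrays.

    line_spec may be an array of reference points or a callable mapping
    s in [0, 1] to reference points.
    """
    if callable(line_spec):
        pts = np.asarray(line_spec(np.linspace(0.0, 1.0, n_samples)))
    else:
        pts = np.asarray(line_spec, dtype=float)
    return pts, track_points(undeformed, deformed, pts, tol=tol)


# ---------------------------------------------------------------------------
# solution comparison


@dataclass
class ComparisonReport:
    """Pointwise displacement differences between two solutions."""

    points: np.ndarray
    x_a: np.ndarray
    x_b: np.ndarray
    max_abs_mm: float
    mean_abs_mm: float
    max_rel_percent: float
    dof_a: int | None = None
    dof_b: int | None = None

    def to_dict(self):
        return {
            "points": np.asarray(self.points).tolist(),
            "difference_mm": np.linalg.norm(self.x_a - self.x_b, axis=1).tolist(),
            "max_abs_mm": self.max_abs_mm,
            "mean_abs_mm": self.mean_abs_mm,
            "max_rel_percent": self.max_rel_percent,
            "dof_a": self.dof_a,
            "dof_b": self.dof_b,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def compare_solutions(pair_a, pair_b, sample_points, dof_a=None, dof_b=None, tol: float = 1e-6) -> ComparisonReport:
    """Track sample points through two solution pairs and report their
    displacement differences, absolute (mm) and relative to the larger of
    the two displacement magnitudes at each point (percent).

    Each pair is (undeformed ReferenceMesh, deformed mesh or point array).
    """
    sample_points = np.asarray(sample_points, dtype=float)
    if sample_points.ndim == 1:
        sample_points = sample_points[None, :]
    xa = track_points(pair_a[0], pair_a[1], sample_points, tol=tol)
    xb = track_points(pair_b[0], pair_b[1], sample_points, tol=tol)
    diff = np.linalg.norm(xa - xb, axis=1)
    ua = np.linalg.norm(xa - sample_points, axis=1)
    ub = np.linalg.norm(xb - sample_points, axis=1)
    denom = np.maximum(np.maximum(ua, ub), 1e-300)
    rel = 100.0 * diff / denom
    return ComparisonReport(
        points=sample_points,
        x_a=xa,
        x_b=xb,
        max_abs_mm=float(diff.max()),
        mean_abs_mm=float(diff.mean()),
        max_rel_percent=float(rel.max()),
        dof_a=dof_a,
        dof_b=dof_b,
    )
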
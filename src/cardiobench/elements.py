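"""Lagrange hexahedral elements: shape functions, quadrature and face templates.

Two element geometries are supported: the 8-node trilinear hexahedron
(``order=1``, local nodes in VTK ordering) and the 27-node triquadratic
hexahedron (``order=2``, local nodes in tensor-lexicographic ordering with
the xi index fastest).  All shape-function evaluations are table driven so
the same code path serves volume quadrature, surface quadrature and the
inverse isoparametric map.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# VTK ordering of the 8 corners: bottom face counter-clockwise, then top.
_VTK_CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def _lagrange_1d(order: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and derivatives of the 1D Lagrange basis on [-1,1].

    Nodes are (-1, 1) for order 1 and (-1, 0, 1) for order 2.  Returns
    arrays of shape ``x.shape + (order+1,)``.
    """
    x = np.asarray(x, dtype=float)
    if order == 1:
        vals = np.stack([(1.0 - x) / 2.0, (1.0 + x) / 2.0], axis=-1)
        ders = np.stack([np.full_like(x, -0.5), np.full_like(x, 0.5)], axis=-1)
    elif order == 2:
        vals = np.stack(
            [x * (x - 1.0) / 2.0, 1.0 - x * x, x * (x + 1.0) / 2.0], axis=-1
        )
        ders = np.stack([x - 0.5, -2.0 * x, x + 0.5], axis=-1)
    else:
        raise ValueError(f"unsupported element order {order}")
    return vals, ders


@lru_cache(maxsize=None)
def local_nodes(order: int) -> np.ndarray:
    """Local coordinates of the element nodes, shape (n_nodes, 3)."""
    if order == 1:
        return _VTK_CORNERS.copy()
    if order == 2:
        g = np.array([-1.0, 0.0, 1.0])
        pts = np.array([[g[i], g[j], g[k]] for k in range(3) for j in range(3) for i in range(3)])
        return pts
    raise ValueError(f"unsupported element order {order}")


def n_nodes(order: int) -> int:
    return (order + 1) ** 3


@lru_cache(maxsize=None)
def _node_index_triples(order: int) -> np.ndarray:
    """(i,j,k) 1D-node indices of each local node, matching local_nodes()."""
    if order == 1:
        # map VTK corner coordinates back to 0/1 indices
        return ((_VTK_CORNERS + 1.0) / 2.0).astype(int)
    return np.array([[i, j, k] for k in range(3) for j in range(3) for i in range(3)])


def shape_functions(order: int, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate N and dN/dxi at local points.

    Parameters
    ----------
    pts : array (..., 3) of local coordinates in [-1,1]^3.

    Returns
    -------
    N : array (..., n_nodes)
    dN : array (..., n_nodes, 3)
    """
    pts = np.asarray(pts, dtype=float)
    trip = _node_index_triples(order)
    vx, dx = _lagrange_1d(order, pts[..., 0])
    vy, dy = _lagrange_1d(order, pts[..., 1])
    vz, dz = _lagrange_1d(order, pts[..., 2])
    i, j, k = trip[:, 0], trip[:, 1], trip[:, 2]
    N = vx[..., i] * vy[..., j] * vz[..., k]
    dN = np.stack(
        [
            dx[..., i] * vy[..., j] * vz[..., k],
            vx[..., i] * dy[..., j] * vz[..., k],
            vx[..., i] * vy[..., j] * dz[..., k],
        ],
        axis=-1,
    )
    return N, dN


@lru_cache(maxsize=None)
def gauss_rule(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Legendre rule with n points per direction."""
    x, w = np.polynomial.legendre.leggauss(n)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    W = np.einsum("i,j,k->ijk", w, w, w)
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    return pts, W.ravel()


def volume_quadrature(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Default volume rule: 2^3 points for order 1, 3^3 for order 2."""
    return gauss_rule(order + 1)


# Face templates.  Each face fixes one local axis at +-1; the two in-plane
# axes (s, t) are ordered so that e_s x e_t points OUTWARD in local
# coordinates (and hence outward in physical space for positively oriented
# elements).
_FACES = (
    (0, -1.0, 2, 1),  # xi = -1: s=zeta, t=eta
    (0, +1.0, 1, 2),  # xi = +1: s=eta,  t=zeta
    (1, -1.0, 0, 2),  # eta = -1
    (1, +1.0, 2, 0),  # eta = +1
    (2, -1.0, 1, 0),  # zeta = -1
    (2, +1.0, 0, 1),  # zeta = +1
)

N_FACES = 6


def face_local_points(face_id: int, st: np.ndarray) -> np.ndarray:
    """Map 2D face coordinates (..., 2) to 3D element-local coordinates."""
    axis, val, s_axis, t_axis = _FACES[face_id]
    st = np.asarray(st, dtype=float)
    out = np.empty(st.shape[:-1] + (3,))
    out[..., axis] = val
    out[..., s_axis] = st[..., 0]
    out[..., t_axis] = st[..., 1]
    return out


def face_tangent_axes(face_id: int) -> tuple[int, int]:
    _, _, s_axis, t_axis = _FACES[face_id]
    return s_axis, t_axis


@lru_cache(maxsize=None)
def face_quadrature(npts: int) -> tuple[np.ndarray, np.ndarray]:
    """2D tensor Gauss rule on the reference face, shape (npts^2, 2)."""
    x, w = np.polynomial.legendre.leggauss(npts)
    S, T = np.meshgrid(x, x, indexing="ij")
    W = np.einsum("i,j->ij", w, w)
    return np.stack([S.ravel(), T.ravel()], axis=-1), W.ravel()


@lru_cache(maxsize=None)
def face_node_indices(order: int, face_id: int) -> np.ndarray:
    """Element-local node indices lying on a face, ordered so that the
    implied outward orientation matches the face template.

    The first four entries are the face corners in counter-clockwise order
    seen from outside; quadratic faces append edge/centre nodes.
    """
    nodes = local_nodes(order)
    axis, val, _, _ = _FACES[face_id]
    on_face = np.where(np.abs(nodes[:, axis] - val) < 1e-12)[0]
    # order corners first, CCW as seen from outside
    if order == 1:
        corners2d = [(-1.0, -1.0), (1.0, -1.0), (1.0, 1.0), (-1.0, 1.0)]
        s_axis, t_axis = face_tangent_axes(face_id)
        ordered = []
        for s, t in corners2d:
            for idx in on_face:
                if abs(nodes[idx, s_axis] - s) < 1e-12 and abs(nodes[idx, t_axis] - t) < 1e-12:
                    ordered.append(idx)
        return np.array(ordered)
    return on_face


@lru_cache(maxsize=None)
def _face_node_1d_indices(order: int, face_id: int) -> tuple[np.ndarray, np.ndarray]:
    nodes = local_nodes(order)[face_node_indices(order, face_id)]
    s_axis, t_axis = face_tangent_axes(face_id)
    to_idx = (lambda c: int(round((c + 1.0) / 2.0))) if order == 1 else (lambda c: int(round(c + 1.0)))
    si = np.array([to_idx(c) for c in nodes[:, s_axis]])
    ti = np.array([to_idx(c) for c in nodes[:, t_axis]])
    return si, ti


def face_shape_functions(order: int, face_id: int, st: np.ndarray):
    """2D Lagrange basis of a face's own nodes at face coordinates.

    st : (..., 2).  Returns N (..., n_face_nodes) and dN (..., nfn, 2),
    node ordering matching :func:`face_node_indices`.
    """
    st = np.asarray(st, dtype=float)
    si, ti = _face_node_1d_indices(order, face_id)
    vs, ds = _lagrange_1d(order, st[..., 0])
    vt, dt = _lagrange_1d(order, st[..., 1])
    N = vs[..., si] * vt[..., ti]
    dN = np.stack([ds[..., si] * vt[..., ti], vs[..., si] * dt[..., ti]], axis=-1)
    return N, dN


def corner_indices(order: int) -> np.ndarray:
    """Element-local indices of the 8 corner nodes, in VTK corner order."""
    nodes = local_nodes(order)
    out = []
    for c in _VTK_CORNERS:
        match = np.where(np.all(np.abs(nodes - c) < 1e-12, axis=1))[0]
        out.append(match[0])
    return np.array(out)
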
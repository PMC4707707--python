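"""Legacy-VTK (ASCII) unstructured-grid reading/writing and archives.

Output uses the legacy "# vtk DataFile Version 2.0" dialect with linear
hexahedra (cell type 12), the lowest common denominator across solvers.
Coordinates are printed in scientific notation with 17 significant digits,
so writing and re-reading an order-1 mesh is bit-faithful and identical
inputs produce byte-identical files.  Quadratic (27-node) elements are
subdivided into eight linear hexahedra through their own geometric nodes
before writing, which leaves nodal coordinates untouched.  Tagged boundary
surfaces are appended as quad cells (type 9) carrying the integer
cell-data array ``surface_id`` (0 = volume/untagged, 1 = left/endocardium,
2 = bottom/epicardium, 3 = base); the tag names are recorded in the title
line so a round trip restores them.  A minimal reader for ASCII ``.vtu``
(XML) files is included for interoperability with external archives.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import elements
from .geometry import ReferenceMesh

_FMT = "%.16e"  # 17 significant digits

SURFACE_IDS = {
    "left": 1,
    "endocardium": 1,
    "bottom": 2,
    "epicardium": 2,
    "base": 3,
}

VTK_HEX = 12
VTK_QUAD = 9


class VTKParseError(ValueError):
    def __init__(self, message, line=None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# order reduction


def convert_to_vtk_compatible(mesh: ReferenceMesh) -> ReferenceMesh:
    """Subdivide quadratic elements into 8 linear hexahedra each.

    Order-1 meshes are returned unchanged.  The subdivision uses the
    elements' own geometric nodes, so no interpolation error is introduced
    at any node, and tagged facets are mapped onto the four sub-facets that
    tile them.
    """
    if mesh.order == 1:
        return mesh
    # lexicographic (i,j,k) -> local index for the 27-node element
    def lex(i, j, k):
        return i + 3 * j + 9 * k

    sub_corner = []  # per sub-cell: 8 lex indices in VTK corner order
    sub_offsets = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    vtk_corner = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    for (i0, j0, k0) in sub_offsets:
        sub_corner.append([lex(i0 + di, j0 + dj, k0 + dk) for di, dj, dk in vtk_corner])
    sub_corner = np.array(sub_corner)

    cells = mesh.cells[:, sub_corner].reshape(-1, 8)
    # facet mapping: each quadratic face becomes 4 linear sub-facets; a
    # sub-cell touches face f of the parent iff its offset lies on it
    face_axis = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1), 4: (2, 0), 5: (2, 1)}
    tags = {}
    for name, facets in mesh.surface_tags.items():
        out = []
        for el, face in facets:
            ax, side = face_axis[int(face)]
            for s, (i0, j0, k0) in enumerate(sub_offsets):
                if (i0, j0, k0)[ax] == side:
                    out.append((8 * int(el) + s, int(face)))
        tags[name] = np.array(out, dtype=int)
    params = None
    if mesh.param_coords is not None:
        params = mesh.param_coords[:, sub_corner].reshape(-1, 8, 3)
    return ReferenceMesh(
        points=mesh.points,
        cells=cells,
        order=1,
        surface_tags=tags,
        param_coords=params,
        constant_fibre=mesh.constant_fibre,
        spec=mesh.spec,
    )


# ---------------------------------------------------------------------------
# legacy ASCII writer / reader


def write_vtk(mesh: ReferenceMesh, path, points: np.ndarray | None = None):
    """Write a mesh (or a deformed copy of it via ``points``) as legacy
    ASCII VTK.  Quadratic meshes are subdivided first."""
    mesh = convert_to_vtk_compatible(mesh)
    pts = mesh.points if points is None else np.asarray(points, dtype=float)
    if pts.shape != mesh.points.shape:
        raise ValueError("points array shape mismatch")
    tag_note = ",".join(f"{name}={SURFACE_IDS.get(name, 9)}" for name in sorted(mesh.surface_tags))
    lines = [
        "# vtk DataFile Version 2.0",
        f"cardiobench mesh tags:{tag_note}",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(pts)} double",
    ]
    lines += [" ".join(_FMT % v for v in p) for p in pts]
    quads = []
    quad_ids = []
    for name in sorted(mesh.surface_tags):
        fn = mesh.facet_nodes(name)
        quads += fn.tolist()
        quad_ids += [SURFACE_IDS.get(name, 9)] * len(fn)
    ncell = mesh.n_cells + len(quads)
    size = mesh.n_cells * 9 + len(quads) * 5
    lines.append(f"CELLS {ncell} {size}")
    lines += ["8 " + " ".join(str(i) for i in c) for c in mesh.cells]
    lines += ["4 " + " ".join(str(i) for i in q) for q in quads]
    lines.append(f"CELL_TYPES {ncell}")
    lines += [str(VTK_HEX)] * mesh.n_cells + [str(VTK_QUAD)] * len(quads)
    lines.append(f"CELL_DATA {ncell}")
    lines.append("SCALARS surface_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines += ["0"] * mesh.n_cells + [str(i) for i in quad_ids]
    Path(path).write_text("\n".join(lines) + "\n")


def _read_legacy(text: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    lines = text.splitlines()
    title = lines[1] if len(lines) > 1 else ""
    idx = 0

    def find(keyword):
        nonlocal idx
        for i in range(idx, len(lines)):
            if lines[i].strip().upper().startswith(keyword):
                idx = i
                return i
        raise VTKParseError(f"missing {keyword} block", line=len(lines))

    i = find("POINTS")
    n_pts = int(lines[i].split()[1])
    vals = []
    j = i + 1
    while len(vals) < 3 * n_pts:
        vals += [float(v) for v in lines[j].split()]
        j += 1
    pts = np.array(vals).reshape(n_pts, 3)
    idx = j
    i = find("CELLS")
    n_cells = int(lines[i].split()[1])
    cells_raw = []
    j = i + 1
    for _ in range(n_cells):
        row = [int(v) for v in lines[j].split()]
        if len(row) != row[0] + 1:
            raise VTKParseError("malformed cell row", line=j + 1)
        cells_raw.append(row[1:])
        j += 1
    idx = j
    try:
        i = find("CELL_TYPES")
    except VTKParseError:
        raise VTKParseError("file lacks a CELL_TYPES block", line=j + 1) from None
    types = []
    j = i + 1
    while len(types) < n_cells:
        types += [int(v) for v in lines[j].split()]
        j += 1
    types = np.array(types)
    idx = j
    surface_id = None
    try:
        i = find("SCALARS SURFACE_ID")
        find("LOOKUP_TABLE")
        vals = []
        j = idx + 1
        while len(vals) < n_cells:
            vals += [int(v) for v in lines[j].split()]
            j += 1
        surface_id = np.array(vals)
    except VTKParseError:
        pass
    meta = {"title": title, "types": types, "surface_id": surface_id}
    return pts, cells_raw, types, meta


def _mesh_from_cells(pts, cells_raw, types, meta) -> ReferenceMesh:
    bad = set(types.tolist()) - {VTK_HEX, VTK_QUAD}
    if bad:
        raise VTKParseError(f"unsupported VTK cell type id(s) {sorted(bad)}")
    hexes = np.array([c for c, t in zip(cells_raw, types) if t == VTK_HEX], dtype=int)
    if hexes.size == 0:
        raise VTKParseError("no hexahedral cells in file")
    quads = [(k, c) for k, (c, t) in enumerate(zip(cells_raw, types)) if t == VTK_QUAD]
    # rebuild facet tags from quads + surface_id + title tag names
    tag_names = {}
    title = meta.get("title", "")
    if "tags:" in title:
        for part in title.split("tags:")[1].split(","):
            if "=" in part:
                name, sid = part.split("=")
                tag_names.setdefault(int(sid), name.strip())
    face_lookup = {}
    for el in range(len(hexes)):
        for f in range(elements.N_FACES):
            fidx = elements.face_node_indices(1, f)
            face_lookup[frozenset(hexes[el, fidx].tolist())] = (el, f)
    tags: dict[str, list] = {}
    sid_arr = meta.get("surface_id")
    for k, conn in quads:
        sid = int(sid_arr[k]) if sid_arr is not None else 9
        name = tag_names.get(sid, f"surface_{sid}")
        hit = face_lookup.get(frozenset(conn))
        if hit is not None:
            tags.setdefault(name, []).append(hit)
    return ReferenceMesh(
        points=pts,
        cells=hexes,
        order=1,
        surface_tags={k: np.array(v, dtype=int) for k, v in tags.items()},
    )


def _read_vtu(path) -> ReferenceMesh:
    root = ET.parse(path).getroot()
    grid = root.find("UnstructuredGrid")
    if grid is None:
        raise VTKParseError("not a VTU UnstructuredGrid file")
    piece = grid.find("Piece")

    def parse(da):
        if da.get("format", "ascii") != "ascii":
            raise VTKParseError("only ascii-format VTU DataArrays are supported")
        return np.array(da.text.split(), dtype=float)

    def data_array(parent, name):
        for da in parent.iter("DataArray"):
            if da.get("Name") == name:
                return parse(da)
        raise VTKParseError(f"missing DataArray {name}")

    pts = parse(piece.find("Points").find("DataArray")).reshape(-1, 3)
    cells_el = piece.find("Cells")
    conn = data_array(cells_el, "connectivity").astype(int)
    offsets = data_array(cells_el, "offsets").astype(int)
    types = data_array(cells_el, "types").astype(int)
    cells_raw = [conn[(0 if k == 0 else offsets[k - 1]): offsets[k]].tolist() for k in range(len(offsets))]
    return _mesh_from_cells(pts, cells_raw, types, {"title": "", "surface_id": None})


def read_vtk(path) -> ReferenceMesh:
    """Read a legacy ASCII or ascii-VTU unstructured grid (linear hexes,
    optional tagged boundary quads)."""
    path = Path(path)
    head = path.read_text()[:512]
    if head.lstrip().startswith("<"):
        return _read_vtu(path)
    if not head.startswith("# vtk"):
        raise VTKParseError("not a legacy VTK file (missing '# vtk' header)", line=1)
    pts, cells_raw, types, meta = _read_legacy(path.read_text())
    return _mesh_from_cells(pts, cells_raw, types, meta)


# ---------------------------------------------------------------------------
# solution archives


@dataclass
class SolutionArchive:
    """A solved benchmark as files: undeformed/deformed VTK plus metadata."""

    undeformed: Path
    deformed: Path
    metadata: dict = field(default_factory=dict)

    @property
    def metadata_path(self) -> Path:
        return self.undeformed.parent / "solution.json"


def write_archive(solution, outdir) -> SolutionArchive:
    """Write undeformed.vtk, deformed.vtk and solution.json for a Solution."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mesh = solution.problem.mesh
    write_vtk(mesh, outdir / "undeformed.vtk")
    write_vtk(mesh, outdir / "deformed.vtk", points=solution.deformed_points)
    spec = mesh.spec
    res = None
    if spec is not None:
        fields = [f for f in ("nx", "ny", "nz", "n_u", "n_v", "n_t") if hasattr(spec, f)]
        res = [getattr(spec, f) for f in fields]
    meta = {
        "problem": solution.problem.problem_id,
        "resolution": res,
        "order": mesh.order,
        "n_dofs": solution.n_dofs,
        "max_incompressibility_error": solution.max_incompressibility_error,
        "multiplier": solution.state.p.tolist(),
        "log": [
            {k: v for k, v in rec.items() if k != "residuals"}
            | {"residuals": [float(r) for r in rec["residuals"]]}
            for rec in solution.log
        ],
    }
    arch = SolutionArchive(outdir / "undeformed.vtk", outdir / "deformed.vtk", meta)
    with open(arch.metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return arch


def load_archive(outdir) -> tuple[ReferenceMesh, ReferenceMesh, dict]:
    """Load (undeformed mesh, deformed mesh, metadata) from a directory."""
    outdir = Path(outdir)
    und = read_vtk(outdir / "undeformed.vtk")
    de = read_vtk(outdir / "deformed.vtk")
    if not np.array_equal(und.cells, de.cells):
        raise VTKParseError("undeformed/deformed archives have different topology")
    meta = {}
    mpath = outdir / "solution.json"
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    return und, de, meta
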
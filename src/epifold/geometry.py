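"""Hexagonal-prism monolayer meshes and per-cell shape measurements.

The tissue is a flat monolayer of hexagonal prisms: each cell is described by
an ordered apical vertex loop (at larger z) and the corresponding basal loop.
Vertices are shared between neighbouring cells; lateral quad faces are
registered once each and tagged shared or boundary.  Model units: one length
unit corresponds to 10 micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

#: Circumradius and height of the columnar reference cell.  These are the
#: unique prism dimensions for which the force-balance relations reproduce the
#: default mechanical parameter set (see :mod:`epifold.analysis`): a slender
#: columnar cell with aspect ratio a/h = 0.25, slightly volume-compressed.
DEFAULT_RADIUS = 0.4503163835524867
DEFAULT_HEIGHT = 1.797324145961788


class GeometryError(ValueError):
    """Raised for degenerate geometry (zero-area face, zero volume)."""


@dataclass
class CellShapeSummary:
    """Derived geometry of one cell.

    ``a`` and ``b`` are the mean centroid-to-vertex distances of the apical and
    basal faces (the hexagon "radius"), ``ell`` the mean lateral edge length,
    and ``L = a + b + ell`` the half cell perimeter on which the membrane
    polarity fields live.  ``psi`` is the surface-to-volume ratio
    (A_a + A_b + A_ell) / V.
    """

    a: float
    b: float
    ell: float
    L: float
    A_a: float
    A_b: float
    A_ell: float
    V: float
    psi: float
    P_hat_a: float


@dataclass
class TissueMesh:
    """Vertex-sharing mesh of hexagonal-prism cells.

    ``apical`` and ``basal`` are (n_cells, 6) vertex-index arrays with
    consistent orientation: the apical loop is counter-clockwise when viewed
    from outside the apical (+z) side, and ``basal[c, k]`` lies directly under
    ``apical[c, k]``.  ``lateral_faces`` is (n_faces, 4) with vertex order
    (a_k, a_{k+1}, b_{k+1}, b_k); ``face_owners`` is (n_faces, 2) with -1 in
    the second slot for boundary faces.
    """

    positions: np.ndarray
    apical: np.ndarray
    basal: np.ndarray
    lateral_faces: np.ndarray
    face_owners: np.ndarray
    boundary_cells: np.ndarray
    axial_coords: np.ndarray  # (n_cells, 2) hex-grid coordinates of cell centres
    _incidence: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_cells(self) -> int:
        return self.apical.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "TissueMesh":
        m = TissueMesh(
            self.positions.copy(), self.apical, self.basal,
            self.lateral_faces, self.face_owners, self.boundary_cells,
            self.axial_coords,
        )
        m._incidence = self._incidence
        return m

    def is_shared(self) -> np.ndarray:
        """Boolean mask over lateral faces: True where two cells share the face."""
        return self.face_owners[:, 1] >= 0

    def vertex_incidence(self):
        """CSR vertex->cells and vertex->lateral-faces incidence (cached)."""
        if self._incidence is None:
            nV = self.n_vertices
            vcells: list[list[int]] = [[] for _ in range(nV)]
            for c in range(self.n_cells):
                for v in self.apical[c]:
                    vcells[v].append(c)
                for v in self.basal[c]:
                    vcells[v].append(c)
            vfaces: list[list[int]] = [[] for _ in range(nV)]
            for f in range(self.lateral_faces.shape[0]):
                for v in self.lateral_faces[f]:
                    vfaces[v].append(f)
            vc_ptr = np.zeros(nV + 1, dtype=np.int64)
            vf_ptr = np.zeros(nV + 1, dtype=np.int64)
            for v in range(nV):
                vc_ptr[v + 1] = vc_ptr[v] + len(vcells[v])
                vf_ptr[v + 1] = vf_ptr[v] + len(vfaces[v])
            vc_idx = np.array([c for lst in vcells for c in lst], dtype=np.int64)
            vf_idx = np.array([f for lst in vfaces for f in lst], dtype=np.int64)
            self._incidence = (vc_ptr, vc_idx, vf_ptr, vf_idx)
        return self._incidence


def build_hexagonal_tissue(n_rings: int,
                           apical_radius: float = DEFAULT_RADIUS,
                           height: float = DEFAULT_HEIGHT) -> TissueMesh:
    """Build a flat monolayer patch of 1 + 3*n_rings*(n_rings+1) congruent prisms.

    Cells are regular hexagonal prisms of circumradius ``apical_radius`` and
    height ``height``, packed hexagonally; the apical surface sits at
    z = height, the basal surface at z = 0.
    """
    if n_rings < 0:
        raise ValueError("n_rings must be >= 0")
    if apical_radius <= 0 or height <= 0:
        raise ValueError("apical_radius and height must be positive")

    R = float(apical_radius)
    centers = []
    axial = []
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            if abs(q + r) > n_rings:
                continue
            x = R * np.sqrt(3.0) * (q + 0.5 * r)
            y = R * 1.5 * r
            centers.append((x, y))
            axial.append((q, r))
    order = np.lexsort((np.array([a[0] for a in axial]), np.array([a[1] for a in axial])))
    centers = [centers[i] for i in order]
    axial = [axial[i] for i in order]
    n_cells = len(centers)

    # pointy-top hexagon corner angles; CCW seen from +z
    angles = np.deg2rad(30.0 + 60.0 * np.arange(6))
    vert_key: dict[tuple, int] = {}
    positions: list[tuple] = []

    def vid(x, y, z):
        key = (round(x, 9), round(y, 9), round(z, 9))
        i = vert_key.get(key)
        if i is None:
            i = len(positions)
            vert_key[key] = i
            positions.append((x, y, z))
        return i

    apical = np.empty((n_cells, 6), dtype=np.int64)
    basal = np.empty((n_cells, 6), dtype=np.int64)
    for c, (cx, cy) in enumerate(centers):
        for k in range(6):
            x = cx + R * np.cos(angles[k])
            y = cy + R * np.sin(angles[k])
            apical[c, k] = vid(x, y, height)
            basal[c, k] = vid(x, y, 0.0)

    # register lateral faces once, tagging shared/boundary
    face_map: dict[tuple, int] = {}
    faces: list[list[int]] = []
    owners: list[list[int]] = []
    for c in range(n_cells):
        for k in range(6):
            k1 = (k + 1) % 6
            quad = [apical[c, k], apical[c, k1], basal[c, k1], basal[c, k]]
            key = tuple(sorted(quad))
            f = face_map.get(key)
            if f is None:
                face_map[key] = len(faces)
                faces.append(quad)
                owners.append([c, -1])
            else:
                owners[f][1] = c
    faces_arr = np.array(faces, dtype=np.int64)
    owners_arr = np.array(owners, dtype=np.int64)
    boundary = np.unique(owners_arr[owners_arr[:, 1] < 0, 0])

    pos = np.array(positions, dtype=np.float64)
    return TissueMesh(pos, apical, basal, faces_arr, owners_arr, boundary,
                      np.array(axial, dtype=np.int64))


def initiating_cell_ids(mesh: TissueMesh, mode: str) -> np.ndarray:
    """Cells in which the polarity perturbation is applied.

    ``concentric``: the central cell plus its first ring of neighbours (7 cells
    on patches with at least one ring).  ``line``: the straight axial row of
    cells through the centre, producing a furrow-like fold.
    """
    ax = mesh.axial_coords
    if mode == "concentric":
        dist = np.maximum.reduce([np.abs(ax[:, 0]), np.abs(ax[:, 1]), np.abs(ax[:, 0] + ax[:, 1])])
        return np.flatnonzero(dist <= 1)
    if mode == "line":
        return np.flatnonzero(ax[:, 1] == 0)
    raise ValueError(f"unknown initiating-cell mode: {mode!r}")


def central_cell_id(mesh: TissueMesh) -> int:
    ax = mesh.axial_coords
    return int(np.flatnonzero((ax[:, 0] == 0) & (ax[:, 1] == 0))[0])


def cell_shape_summary(mesh: TissueMesh, cell_id: int) -> CellShapeSummary:
    """Measure one cell: lengths a, b, ell, half perimeter L, areas, volume, psi."""
    pos = mesh.positions
    ap = mesh.apical[cell_id]
    bp = mesh.basal[cell_id]
    pa = pos[ap]
    pb = pos[bp]
    ca = pa.mean(axis=0)
    cb = pb.mean(axis=0)
    a = float(np.linalg.norm(pa - ca, axis=1).mean())
    b = float(np.linalg.norm(pb - cb, axis=1).mean())
    ell = float(np.linalg.norm(pa - pb, axis=1).mean())
    A_a = float(_kernels.loop_area(pos, ap))
    A_b = float(_kernels.loop_area(pos, bp))
    A_ell = 0.0
    for k in range(6):
        k1 = (k + 1) % 6
        quad = np.array([ap[k], ap[k1], bp[k1], bp[k]], dtype=np.int64)
        A_ell += float(_kernels.face_area(pos, quad))
    V = float(_kernels.cell_volume(pos, ap, bp))
    if A_a <= 0 or A_b <= 0 or V <= 0:
        raise GeometryError(f"degenerate cell {cell_id}: A_a={A_a}, A_b={A_b}, V={V}")
    L = a + b + ell
    psi = (A_a + A_b + A_ell) / V
    P_hat_a = float(_kernels.loop_perimeter(pos, ap))
    return CellShapeSummary(a=a, b=b, ell=ell, L=L, A_a=A_a, A_b=A_b,
                            A_ell=A_ell, V=V, psi=psi, P_hat_a=P_hat_a)


def boundary_constraint_mask(mesh: TissueMesh, mode: str) -> np.ndarray:
    """Per-vertex mask of constrained vertical motion.

    ``free``: nothing constrained (the default boundary condition).
    ``pin_plane``: every vertex of a rim cell keeps its z coordinate, confining
    the outer boundary cells to a horizontal plane.
    """
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    if mode == "free":
        return mask
    if mode == "pin_plane":
        for c in mesh.boundary_cells:
            mask[mesh.apical[c]] = True
            mask[mesh.basal[c]] = True
        return mask
    raise ValueError(f"unknown boundary mode: {mode!r}")


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------


def _cell_triangles(mesh: TissueMesh):
    """Triangulated closed surface of every cell (vertex index triples)."""
    tris = []
    for c in range(mesh.n_cells):
        ap = mesh.apical[c]
        bp = mesh.basal[c]
        for k in range(1, 5):
            tris.append((ap[0], ap[k], ap[k + 1]))
            tris.append((bp[0], bp[k + 1], bp[k]))
        for k in range(6):
            k1 = (k + 1) % 6
            tris.append((ap[k], bp[k], bp[k1]))
            tris.append((ap[k], bp[k1], ap[k1]))
    return tris


def export_obj(mesh: TissueMesh, path) -> None:
    with open(path, "w") as fh:
        for p in mesh.positions:
            fh.write(f"v {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        for t in _cell_triangles(mesh):
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def export_vtk(mesh: TissueMesh, path) -> None:
    """Legacy-ASCII VTK polydata of the triangulated cell surfaces."""
    tris = _cell_triangles(mesh)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nepifold tissue mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.positions:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
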